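import pytest

import luthy


@pytest.fixture(scope="session")
def small_screen():
    """A 12-pair, 2-replicate screen with 5% noise and its truth table."""
    params = luthy.SimulationParams(seed=123, n_pairs=12, noise_cv=0.05)
    return luthy.simulate_screen(params)


@pytest.fixture(scope="session")
def noiseless_screen():
    params = luthy.SimulationParams(seed=321, n_pairs=10, noise_cv=0.0)
    return luthy.simulate_screen(params)


@pytest.fixture(scope="session")
def benchmark():
    """The standing regression benchmark screen, scored and called once."""
    params = luthy.default_benchmark_params(seed=42)
    dataset, truth = luthy.simulate_screen(params)
    scores = luthy.score_screen(dataset)
    calls = luthy.call_screen(scores)
    return dataset, truth, scores, calls


def make_profile(pair_means, noise_frac, rng, readouts=("c_bret", "c_luc"),
                 n_replicates=2):
    """Synthetic per-partner InteractionScore profiles for differential tests."""
    out = {}
    for partner, means in pair_means.items():
        s = luthy.InteractionScore(pair_id=partner)
        for r in range(n_replicates):
            kwargs = {}
            for attr, mu in zip(readouts, means):
                kwargs[attr] = mu * (1.0 + noise_frac * rng.standard_normal())
            s.replicates[f"exp{r + 1}"] = luthy.ReplicateScore(**kwargs)
        out[partner] = s
    return out
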