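"""Variant-vs-wild-type differential interaction profiling.

Given the same partner panel screened against a wild-type bait and a variant
(e.g. a disease mutation), each partner's interaction is classified per
readout as lost / gained (the positive call flips), decreased / increased
(call retained in both profiles but the corrected ratio moved significantly
and by more than an effect floor), or unchanged.

Significance is resampling-based throughout.  Two routes are provided:

* :func:`resampling_many_to_one` — a seeded max-T permutation analog of
  Dunnett's many-to-one post hoc comparison, for designs where several
  groups share one control (e.g. per-variant comparisons of whole profiles);
* per-partner p-values inside :func:`compare_variant_profiles`, which use a
  pooled-residual resampling null: replicate residuals are pooled across all
  partners of both profiles and resampled to form null deltas, with max-T
  family-wise adjustment across partners.  With the typical 2-replicate
  design, a within-partner permutation cannot reach p < 1/3, so borrowing
  the replicate noise across partners is what makes per-partner inference
  possible at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calling import CallResult, CutoffScheme, call_interaction, cutoff_class
from .io import LocalizationAnnotation
from .scoring import InteractionScore

__all__ = [
    "VariantComparison",
    "resampling_many_to_one",
    "compare_variant_profiles",
]

READOUTS = ("bret", "luc")


@dataclass
class VariantComparison:
    """Per-partner comparison of a variant profile against wild type."""

    partner: str
    delta_cbret: float
    delta_cluc: float
    p_bret: float
    p_luc: float
    class_bret: str
    class_luc: str

    @property
    def disturbed(self) -> bool:
        return any(
            c in ("lost", "gained", "decreased", "increased")
            for c in (self.class_bret, self.class_luc)
        )


def resampling_many_to_one(
    control: Sequence[float],
    groups: Mapping[str, Sequence[float]],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Max-T permutation comparison of several groups against one control.

    The statistic per group is the absolute difference of group and control
    means.  Observations are pooled and permuted ``n_permutations`` times
    (seeded, hence deterministic); each group's family-wise adjusted p-value
    is the fraction of permutations whose *maximum* statistic over groups
    reaches that group's observed statistic (add-one estimator).

    This is the resampling analog of a parametric many-to-one post hoc test:
    it controls the family-wise error without distributional assumptions,
    which matters for the tiny replicate counts of plate screens.
    """
    ctrl = np.asarray(control, dtype=float)
    names = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in names]
    if ctrl.size < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 replicates in the control and every group")
    pooled = np.concatenate([ctrl] + arrs)
    sizes = [ctrl.size] + [a.size for a in arrs]
    bounds = np.cumsum(sizes)

    obs = np.array([abs(a.mean() - ctrl.mean()) for a in arrs])

    rng = np.random.default_rng(seed)
    n = pooled.size
    # vectorized permutations: argsort of iid uniforms = random permutation
    keys = rng.random((n_permutations, n))
    perm_idx = np.argsort(keys, axis=1)
    perm_vals = pooled[perm_idx]  # (n_permutations, n)
    ctrl_mean = perm_vals[:, : bounds[0]].mean(axis=1)
    stats = np.empty((n_permutations, len(names)))
    for gi in range(len(names)):
        grp = perm_vals[:, bounds[gi]: bounds[gi + 1]]
        stats[:, gi] = np.abs(grp.mean(axis=1) - ctrl_mean)
    max_t = stats.max(axis=1)

    out = {}
    for gi, name in enumerate(names):
        out[name] = float((1 + np.sum(max_t >= obs[gi] - 1e-12)) / (1 + n_permutations))
    return out


def _pooled_residual_pvalues(
    deltas: np.ndarray,
    residuals: np.ndarray,
    n1: int,
    n2: int,
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Max-T adjusted p-values for per-partner deltas against a null built by
    resampling pooled replicate residuals.

    Null delta* = mean of n2 resampled residuals − mean of n1 resampled
    residuals; the family-wise adjustment compares each observed |delta| to
    the max over partners of |delta*| per resample.
    """
    k = deltas.size
    draw = rng.choice(residuals, size=(n_resamples, k, n1 + n2), replace=True)
    null = draw[:, :, :n2].mean(axis=2) - draw[:, :, n2:].mean(axis=2)
    max_null = np.abs(null).max(axis=1)
    p = np.empty(k)
    for i in range(k):
        p[i] = (1 + np.sum(max_null >= abs(deltas[i]) - 1e-15)) / (1 + n_resamples)
    return p


def _rep_values(score: InteractionScore, readout: str) -> np.ndarray:
    attr = "c_bret" if readout == "bret" else "c_luc"
    vals = [getattr(r, attr) for r in score.replicates.values()]
    return np.asarray([v for v in vals if np.isfinite(v)], dtype=float)


def compare_variant_profiles(
    wt: Mapping[str, InteractionScore],
    variant: Mapping[str, InteractionScore],
    scheme: CutoffScheme = CutoffScheme(),
    annotation: LocalizationAnnotation | None = None,
    bait_protein: str | None = None,
    alpha: float = 0.05,
    delta_floor: tuple[float, float] = (0.01, 0.03),
    n_resamples: int = 10_000,
    seed: int = 0,
) -> list[VariantComparison]:
    """Classify every partner's interaction change between two profiles.

    ``wt`` and ``variant`` map partner protein -> :class:`InteractionScore`
    with >= 2 replicates each.  Partners present in only one profile are
    reported with class ``incomparable`` (never silently dropped).

    Per readout and partner: delta = variant aggregate − wild-type
    aggregate; the call flip decides lost/gained; a retained call is
    decreased/increased only when the max-T adjusted resampling p is below
    ``alpha`` *and* |delta| clears the effect floor (defaults mirror the
    calling cutoffs: 0.01 for cBRET, 0.03 for cLuC); otherwise unchanged.
    Both-negative partners are always unchanged — movement below the
    detection cutoffs is not interpreted.
    """
    rng = np.random.default_rng(seed)
    partners = sorted(set(wt) | set(variant))
    shared = [p for p in partners if p in wt and p in variant]

    for name, prof in (("wild-type", wt), ("variant", variant)):
        for p in prof:
            if len(prof[p].replicates) < 2:
                raise ValueError(
                    f"{name} profile partner {p!r} has < 2 replicates"
                )

    # calls (both profiles use the same localization class per partner)
    def _call(score: InteractionScore, partner: str) -> CallResult:
        cls = (
            cutoff_class(bait_protein, partner, annotation)
            if bait_protein is not None
            else "default"
        )
        return call_interaction(score, scheme, cls)

    calls_wt = {p: _call(wt[p], p) for p in shared}
    calls_var = {p: _call(variant[p], p) for p in shared}

    results: dict[str, dict] = {
        p: {"delta": {}, "p": {}, "class": {}} for p in partners
    }
    for p in partners:
        if p not in wt or p not in variant:
            for ro in READOUTS:
                results[p]["delta"][ro] = np.nan
                results[p]["p"][ro] = np.nan
                results[p]["class"][ro] = "incomparable"

    for ro_idx, ro in enumerate(READOUTS):
        attr = "c_bret" if ro == "bret" else "c_luc"
        pos_attr = f"{ro}_positive"
        valid = [
            p for p in shared
            if np.isfinite(getattr(wt[p], attr)) and np.isfinite(getattr(variant[p], attr))
        ]
        for p in shared:
            if p not in valid:
                results[p]["delta"][ro] = np.nan
                results[p]["p"][ro] = np.nan
                results[p]["class"][ro] = "incomparable"
        if not valid:
            continue
        deltas = np.array(
            [getattr(variant[p], attr) - getattr(wt[p], attr) for p in valid]
        )
        # replicate residuals pooled across partners and profiles
        resid = []
        for prof in (wt, variant):
            for p in valid:
                reps = _rep_values(prof[p], ro)
                resid.extend(reps - reps.mean())
        resid = np.asarray(resid, dtype=float)
        n1 = min(len(_rep_values(wt[p], ro)) for p in valid)
        n2 = min(len(_rep_values(variant[p], ro)) for p in valid)
        pvals = _pooled_residual_pvalues(deltas, resid, n1, n2, n_resamples, rng)

        floor = delta_floor[ro_idx]
        for p, delta, pval in zip(valid, deltas, pvals):
            wt_pos = getattr(calls_wt[p], pos_attr)
            var_pos = getattr(calls_var[p], pos_attr)
            if wt_pos and not var_pos:
                cls = "lost"
            elif var_pos and not wt_pos:
                cls = "gained"
            elif wt_pos and var_pos and pval < alpha and abs(delta) >= floor:
                cls = "decreased" if delta < 0 else "increased"
            else:
                cls = "unchanged"
            results[p]["delta"][ro] = float(delta)
            results[p]["p"][ro] = float(pval)
            results[p]["class"][ro] = cls

    return [
        VariantComparison(
            partner=p,
            delta_cbret=results[p]["delta"]["bret"],
            delta_cluc=results[p]["delta"]["luc"],
            p_bret=results[p]["p"]["bret"],
            p_luc=results[p]["p"]["luc"],
            class_bret=results[p]["class"]["bret"],
            class_luc=results[p]["class"]["luc"],
        )
        for p in partners
    ]
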