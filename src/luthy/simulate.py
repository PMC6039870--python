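"""Generative simulator of double-readout interaction screens.

The simulator produces the same tables the plate reader would, plus the
ground truth behind them, so every pipeline stage can be tested end to end
at desk scale:

* each pair is assigned a label (interacting or not), a dissociation
  constant KD (log-uniform), a per-pair BRET ceiling, and per-replicate
  donor/acceptor expression levels (lognormal);
* the fraction of donor in complex is the exact two-species equilibrium
  occupancy for (donor, acceptor, KD);
* channels follow the assay's physics: short-wavelength luminescence tracks
  donor expression; the long/short ratio is donor bleed-through plus
  BRETmax x occupancy; input luminescence tracks donor expression; output
  (post-precipitation) luminescence is a bait-dependent capture of the prey,
  linear in occupancy on top of a nonspecific background;
* every replicate carries the four reference constructs: per-pair single-tag
  controls (free donor / free acceptor), and per-plate donor-only (PA-NL)
  and tandem (PA-mCit-NL) wells;
* all channel noise is multiplicative lognormal (luminescence noise scales
  with signal); expressions vary lognormally between wells and replicates.

Concentrations are abstract molar-scale scalars; the expression-to-counts
mapping is an arbitrary constant because every downstream score is a ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Construct, ScreenDataset
from .titration import SaturationSeries, _logistic

__all__ = [
    "SimulationParams",
    "equilibrium_occupancy",
    "simulate_screen",
    "simulate_saturation_series",
    "simulate_dose_response",
    "simulate_image_pair",
    "default_benchmark_params",
]

# counts per molar unit for each instrument channel; arbitrary but fixed
_SWL_SCALE = 1.0e12
_NLIN_SCALE = 5.0e11
_FLUOR_SCALE = 2.0e11


def equilibrium_occupancy(donor_total, acceptor_total, kd):
    """Fraction of donor bound at equilibrium for a 1:1 complex.

    Solves the two-species binding quadratic
    ``c^2 - c (D + A + KD) + D A = 0`` for the complex concentration c
    (taking the physical root ``c <= min(D, A)``) and returns ``c / D``.
    Vectorized over any broadcastable combination of inputs.
    """
    D = np.asarray(donor_total, dtype=float)
    A = np.asarray(acceptor_total, dtype=float)
    K = np.asarray(kd, dtype=float)
    if np.any(K <= 0):
        raise ValueError("kd must be > 0")
    if np.any(D < 0) or np.any(A < 0):
        raise ValueError("concentrations must be >= 0")
    S = D + A + K
    # numerically stable smaller quadratic root: c = 2DA / (S + sqrt(S^2-4DA))
    disc = np.sqrt(np.maximum(S**2 - 4.0 * D * A, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = np.where(D > 0, 2.0 * A / (S + disc), 0.0)
    occ = np.clip(occ, 0.0, 1.0)
    return float(occ) if occ.ndim == 0 else occ


@dataclass
class SimulationParams:
    """Generative parameters of a simulated screen.

    Defaults are the package's standing desk-scale study conditions; the
    rationale for each is in the methods note.  ``seed`` is mandatory —
    identical params and seed give byte-identical datasets.
    """

    seed: int
    n_pairs: int = 160
    fraction_positive: float = 0.5
    n_replicates: int = 2
    kd_log10_range: tuple[float, float] = (-9.0, -5.0)
    donor_expression: tuple[float, float] = (1.0e-7, 0.5)  # (median M, CV)
    acceptor_expression: tuple[float, float] = (2.0e-7, 0.5)
    cf_true: float = 0.2
    pir_true: float = 0.2
    bret_max_range: tuple[float, float] = (0.1, 0.6)
    tandem_bret: float = 0.5
    capture_efficiency: float = 0.6
    luc_background: float = 0.01
    noise_cv: float = 0.05
    volume_factor: float = 3.0
    include_luc: bool = True
    n_panl_wells: int = 2
    fraction_membrane: float = 0.0
    crowding_occupancy: float = 0.0  # additive BRET occupancy for co-membrane pairs
    plate_wells: int = 384

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_positive <= 1.0):
            raise ValueError("fraction_positive must be in [0, 1]")
        if not (0.0 <= self.fraction_membrane <= 1.0):
            raise ValueError("fraction_membrane must be in [0, 1]")
        for name in ("cf_true", "pir_true", "capture_efficiency", "volume_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0 or self.luc_background < 0:
            raise ValueError("noise_cv and luc_background must be >= 0")
        if self.n_pairs < 1 or self.n_replicates < 1:
            raise ValueError("need at least one pair and one replicate")


def default_benchmark_params(seed: int = 42) -> SimulationParams:
    """The standing regression benchmark: 160 pairs, 2 replicates, 5% noise."""
    return SimulationParams(seed=seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def _lognormal_level(rng: np.random.Generator, median: float, cv: float, size):
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0
    return median * np.exp(rng.normal(0.0, sigma, size))


class _PlateFiller:
    """Row-major well-id allocator over as many plates as needed.

    The last ``reserve`` positions of every plate are held back for that
    plate's reference wells, so sample and reference well ids never collide.
    """

    def __init__(self, plate_wells: int, prefix: str, reserve: int = 0):
        self.rows = "ABCDEFGHIJKLMNOP" if plate_wells == 384 else "ABCDEFGH"
        self.cols = 24 if plate_wells == 384 else 12
        capacity = len(self.rows) * self.cols
        self.usable = capacity - reserve
        self.capacity = capacity
        self.prefix = prefix
        self.i = 0
        self._reserved_used: dict[str, int] = {}

    def _well(self, k: int) -> str:
        return f"{self.rows[k // self.cols]}{k % self.cols + 1}"

    def next(self) -> tuple[str, str]:
        plate = f"{self.prefix}{self.i // self.usable + 1}"
        well = self._well(self.i % self.usable)
        self.i += 1
        return plate, well

    def next_reserved(self, plate: str) -> str:
        used = self._reserved_used.get(plate, 0)
        if self.usable + used >= self.capacity:
            raise RuntimeError(f"reserved wells exhausted on plate {plate}")
        self._reserved_used[plate] = used + 1
        return self._well(self.usable + used)


def simulate_screen(params: SimulationParams) -> tuple[ScreenDataset, pd.DataFrame]:
    """Generate a full multi-replicate screen plus its ground truth.

    Returns ``(dataset, truth)`` where ``truth`` has one row per pair per
    replicate with the generative label, KD, occupancy, expressions, BRETmax
    and the exact expected corrected ratios (``expected_cbret`` =
    BRETmax x occupancy; ``expected_cluc`` = capture_efficiency x occupancy).
    At ``noise_cv=0`` the scored screen reproduces these expectations to
    machine precision.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    n_pos = int(round(p.n_pairs * p.fraction_positive))
    labels = np.zeros(p.n_pairs, dtype=bool)
    labels[rng.permutation(p.n_pairs)[:n_pos]] = True
    lo, hi = p.kd_log10_range
    kd = 10.0 ** rng.uniform(lo, hi, p.n_pairs)
    bmax = rng.uniform(*p.bret_max_range, p.n_pairs)
    membrane_d = rng.random(p.n_pairs) < p.fraction_membrane
    membrane_a = rng.random(p.n_pairs) < p.fraction_membrane

    pair_ids = [f"pair{i + 1:04d}" for i in range(p.n_pairs)]
    donor_ids = [f"NL-D{i + 1:04d}" for i in range(p.n_pairs)]
    acceptor_ids = [f"PAmCit-A{i + 1:04d}" for i in range(p.n_pairs)]

    constructs: dict[str, Construct] = {
        "NL": Construct("NL", "none", "donor_control"),
        "PA-mCit": Construct("PA-mCit", "none", "acceptor_control"),
        "PA-NL": Construct("PA-NL", "none", "panl_reference"),
        "PA-mCit-NL": Construct("PA-mCit-NL", "none", "tandem_reference"),
    }
    for i in range(p.n_pairs):
        constructs[donor_ids[i]] = Construct(
            donor_ids[i], f"D{i + 1:04d}", "donor", "N"
        )
        constructs[acceptor_ids[i]] = Construct(
            acceptor_ids[i], f"A{i + 1:04d}", "acceptor", "N"
        )
    pairs = {pair_ids[i]: (donor_ids[i], acceptor_ids[i]) for i in range(p.n_pairs)}

    rows: list[dict] = []
    truth_rows: list[dict] = []

    def emit(plate, well, pair_id, role, exp, donor, acceptor,
             d_conc, a_conc, bret_x, luc_x):
        """One well: channels from donor/acceptor levels and the two signal
        fractions (bret_x = BRETmax*occ contribution, luc_x = capture term)."""
        eps = _lognormal_factor(rng, p.noise_cv, 5)
        swl = _SWL_SCALE * d_conc * eps[0]
        lwl = swl * (p.cf_true + bret_x) * eps[1]
        fluor = _FLUOR_SCALE * a_conc * eps[2]
        row = dict(
            plate_id=plate, well_id=well, pair_id=pair_id, role=role,
            experiment=exp, donor=donor, acceptor=acceptor,
            swl_lum=swl, lwl_lum=lwl, cell_fluor=fluor,
        )
        if p.include_luc:
            nl_in = _NLIN_SCALE * d_conc * eps[3]
            nl_out = p.volume_factor * nl_in * p.pir_true * luc_x * eps[4]
            row.update(nl_in=nl_in, mcit_in=fluor * 0.5, nl_out=nl_out,
                       mcit_out=nl_out * 1e-3)
        rows.append(row)

    for r in range(p.n_replicates):
        exp = f"exp{r + 1}"
        filler = _PlateFiller(p.plate_wells, f"{exp}-P", reserve=p.n_panl_wells + 1)
        d_med, d_cv = p.donor_expression
        a_med, a_cv = p.acceptor_expression
        d_conc = _lognormal_level(rng, d_med, d_cv, p.n_pairs)
        a_conc = _lognormal_level(rng, a_med, a_cv, p.n_pairs)
        occ = np.where(
            labels, equilibrium_occupancy(d_conc, a_conc, kd), 0.0
        )
        bret_occ = occ.copy()
        if p.crowding_occupancy > 0:
            both_mem = membrane_d & membrane_a
            bret_occ = np.minimum(bret_occ + p.crowding_occupancy * both_mem, 1.0)

        plates_used: set[str] = set()

        for i in range(p.n_pairs):
            plate, well = filler.next()
            plates_used.add(plate)
            emit(plate, well, pair_ids[i], "interaction", exp,
                 donor_ids[i], acceptor_ids[i], d_conc[i], a_conc[i],
                 bmax[i] * bret_occ[i],
                 p.luc_background + p.capture_efficiency * occ[i])
            # control 1: free donor with this pair's acceptor (no complex)
            plate1, well1 = filler.next()
            plates_used.add(plate1)
            ctrl_d = _lognormal_level(rng, d_med, d_cv, None)
            emit(plate1, well1, f"c1:{acceptor_ids[i]}", "control1", exp,
                 "NL", acceptor_ids[i], ctrl_d, a_conc[i],
                 0.0, p.luc_background)
            # control 2: this pair's donor with free acceptor
            plate2, well2 = filler.next()
            plates_used.add(plate2)
            ctrl_a = _lognormal_level(rng, a_med, a_cv, None)
            emit(plate2, well2, f"c2:{donor_ids[i]}", "control2", exp,
                 donor_ids[i], "PA-mCit", d_conc[i], ctrl_a,
                 0.0, p.luc_background)

            truth_rows.append(dict(
                pair_id=pair_ids[i], experiment=exp,
                label=bool(labels[i]), kd=kd[i], bret_max=bmax[i],
                donor_conc=d_conc[i], acceptor_conc=a_conc[i],
                occupancy=occ[i],
                donor_membrane=bool(membrane_d[i]),
                acceptor_membrane=bool(membrane_a[i]),
                expected_cbret=bmax[i] * bret_occ[i],
                expected_cluc=p.capture_efficiency * occ[i],
            ))

        # per-plate references: PA-NL (bleed-through / precipitation) and
        # the tandem fusion (1:1 acceptor:donor, high BRET positive control)
        for plate in sorted(plates_used):
            for _ in range(p.n_panl_wells):
                well = filler.next_reserved(plate)
                ref_d = _lognormal_level(rng, d_med, d_cv, None)
                emit(plate, well, "ref:PA-NL", "panl", exp,
                     "PA-NL", None, ref_d, 0.0, 0.0, 1.0)
            well = filler.next_reserved(plate)
            ref_d = _lognormal_level(rng, d_med, d_cv, None)
            emit(plate, well, "ref:tandem", "tandem", exp,
                 "PA-mCit-NL", "PA-mCit-NL", ref_d, ref_d,
                 p.tandem_bret, 1.0)

    wells = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    dataset = ScreenDataset(wells=wells, constructs=constructs, pairs=pairs)
    return dataset, truth


def expected_aggregate(truth: pd.DataFrame) -> pd.DataFrame:
    """Across-replicate means of the generative expectations, per pair."""
    agg = truth.groupby("pair_id").agg(
        label=("label", "first"),
        kd=("kd", "first"),
        bret_max=("bret_max", "first"),
        expected_cbret=("expected_cbret", "mean"),
        expected_cluc=("expected_cluc", "mean"),
    )
    return agg.reset_index()


def simulate_saturation_series(
    kd: float,
    donor_total: float,
    acceptor_totals: Sequence[float],
    bret_max: float = 0.5,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[SaturationSeries, dict]:
    """One donor-saturation titration with ground truth.

    BRET at each acceptor level is ``bret_max x occupancy`` with
    multiplicative noise.  The truth records the closed-form acceptor/donor
    ratio at half-maximal occupancy, ``r_half = 0.5 + KD/D`` (set occupancy
    = 1/2 in the binding quadratic and solve for A/D).
    """
    A = np.asarray(acceptor_totals, dtype=float)
    if A.ndim != 1 or np.any(np.diff(A) <= 0):
        raise ValueError("acceptor grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    occ = equilibrium_occupancy(donor_total, A, kd)
    bret = bret_max * occ * _lognormal_factor(rng, noise_cv, A.size)
    series = SaturationSeries(ratios=A / donor_total, bret=bret)
    truth = dict(
        kd=kd,
        donor_total=donor_total,
        bret_max=bret_max,
        occupancy=occ,
        half_max_ratio=0.5 + kd / donor_total,
    )
    return series, truth


def simulate_dose_response(
    bottom: float,
    top: float,
    hill: float,
    ec50: float,
    doses: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Responses from a four-parameter logistic plus multiplicative noise."""
    d = np.asarray(doses, dtype=float)
    if np.unique(d).size < 5:
        raise ValueError("need >= 5 dose levels")
    rng = np.random.default_rng(seed)
    nonzero = d[d > 0]
    floor = nonzero.min() / 100.0
    x = np.log10(np.where(d > 0, d, floor))
    y = _logistic(x, bottom, top, hill, np.log10(ec50))
    y = y * _lognormal_factor(rng, noise_cv, d.size)
    truth = dict(bottom=bottom, top=top, hill=hill, ec50=ec50,
                 direction="stimulation" if top >= bottom else "inhibition")
    return d, y, truth


def _default_intensity(shape: tuple[int, int]) -> np.ndarray:
    """A smooth two-blob luminescence field (deterministic in shape)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    blob = lambda cy, cx, s, amp: amp * np.exp(
        -(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * s**2))
    )
    return blob(h * 0.35, w * 0.35, min(h, w) * 0.12, 1000.0) + blob(
        h * 0.65, w * 0.65, min(h, w) * 0.15, 800.0
    )


def simulate_image_pair(
    shape: tuple[int, int],
    ratio_map,
    shift: tuple[int, int] = (0, 0),
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    intensity=None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two-channel luminescence image pair with a known ratio map and shift.

    The short-wavelength channel is the intensity field plus background and
    noise; the long-wavelength channel is intensity x ratio, translated by
    ``shift`` (integer pixels, wrap-around), plus background and noise.
    """
    h, w = shape
    dy, dx = int(shift[0]), int(shift[1])
    if abs(dy) >= h // 4 or abs(dx) >= w // 4:
        raise ValueError("shift magnitude must be < image extent / 4")
    ratio = np.broadcast_to(np.asarray(ratio_map, dtype=float), shape)
    field = _default_intensity(shape) if intensity is None else np.asarray(
        intensity, dtype=float
    )
    rng = np.random.default_rng(seed)
    ch_short = field + background + rng.normal(0.0, noise_sd, shape)
    ch_long = (
        np.roll(field * ratio, (dy, dx), axis=(0, 1))
        + background
        + rng.normal(0.0, noise_sd, shape)
    )
    truth = dict(shift=(dy, dx), background=background,
                 ratio_map=np.array(ratio), intensity=field)
    return np.maximum(ch_short, 0.0), np.maximum(ch_long, 0.0), truth
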