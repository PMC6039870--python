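"""Donor-saturation (BRET50) fitting, dose-response (EC50/IC50) fitting, and
perturbation time-course / tagging-orientation normalizations.

Donor saturation assays titrate the acceptor at fixed donor and trace BRET
versus the acceptor:donor expression ratio r.  The ratio itself is estimated
from in-cell fluorescence/luminescence, calibrated against the tandem
acceptor-donor fusion whose stoichiometry is 1:1 by construction.  The
saturation model is the one-site rectangular hyperbola

    BRET(r) = BRETmax * r / (BRET50 + r)

so BRET50 is the ratio at half-maximal BRET; it rank-correlates with the
dissociation constant of the pair (weaker binders need more acceptor to
reach half-saturation).

Dose-response curves are fitted with the four-parameter logistic on
log10(dose); the inflection concentration is reported as EC50 (stimulation)
or IC50 (inhibition), by the sign of the high-dose minus low-dose asymptote.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SaturationSeries",
    "SaturationFit",
    "DoseResponseFit",
    "normalize_acceptor_donor",
    "fit_saturation",
    "fit_dose_response",
    "normalize_timecourse",
    "normalize_orientation_matrix",
]

_REL_TOL = 1e-8  # relative parameter-change tolerance for both fitters


def normalize_acceptor_donor(
    fluor: float, lum: float, tandem_ref_ratio: float
) -> float:
    """Estimate the acceptor:donor molar ratio of a well.

    ``(fluor/lum) / tandem_ref_ratio`` — the tandem fusion's
    fluorescence/luminescence ratio defines what a 1:1 stoichiometry looks
    like on the instrument, so dividing by it converts the raw ratio to
    molar units.
    """
    if lum <= 0:
        raise ValueError("luminescence must be > 0")
    if tandem_ref_ratio <= 0:
        raise ValueError("tandem reference ratio must be > 0")
    return (fluor / lum) / tandem_ref_ratio


@dataclass
class SaturationSeries:
    """(acceptor/donor ratio, BRET or cBRET) points for one pair.

    Either raw BRET or corrected cBRET is accepted as the response; the fit
    is indifferent to which, only the asymptote changes meaning.
    """

    ratios: np.ndarray
    bret: np.ndarray
    tandem_ref_ratio: float | None = None

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.bret = np.asarray(self.bret, dtype=float)
        if self.ratios.shape != self.bret.shape or self.ratios.ndim != 1:
            raise ValueError("ratios and bret must be 1-D and paired")
        if np.any(self.ratios < 0):
            raise ValueError("acceptor/donor ratios must be >= 0")


@dataclass
class SaturationFit:
    bret_max: float
    bret50: float
    rss: float
    converged: bool
    message: str = ""


def fit_saturation(series: SaturationSeries) -> SaturationFit:
    """Least-squares fit of the one-site hyperbola to a saturation series.

    Requires >= 4 distinct ratio values spanning at least a 4-fold range.
    Initialization: BRETmax = max observed response, BRET50 = the ratio whose
    response is nearest half-max.  Non-convergence or BRET50 pinned at the
    bounds is reported as ``converged=False`` — no silent value.
    """
    r, y = series.ratios, series.bret
    distinct = np.unique(r[r > 0])
    if distinct.size < 4:
        return SaturationFit(np.nan, np.nan, np.nan, False,
                             "need >= 4 distinct nonzero ratios")
    if distinct.max() / distinct.min() < 4.0:
        return SaturationFit(np.nan, np.nan, np.nan, False,
                             "ratio range spans < 4-fold")
    if np.ptp(y) <= 1e-12 * max(1.0, np.max(np.abs(y))):
        return SaturationFit(np.nan, np.nan, np.nan, False,
                             "flat response: BRET50 unidentifiable")

    ymax = float(np.max(y))
    half_idx = int(np.argmin(np.abs(y - ymax / 2.0)))
    p0 = np.array([ymax, max(r[half_idx], distinct.min())])
    lo = np.array([-np.inf, distinct.min() * 1e-6])
    hi = np.array([np.inf, distinct.max() * 1e6])

    def resid(p):
        bmax, b50 = p
        return bmax * r / (b50 + r) - y

    sol = least_squares(resid, p0, bounds=(lo, hi), xtol=_REL_TOL,
                        ftol=_REL_TOL, gtol=1e-12)
    bmax, b50 = sol.x
    rss = float(np.sum(sol.fun**2))
    at_bound = b50 <= lo[1] * (1 + 1e-6) or b50 >= hi[1] * (1 - 1e-6)
    converged = bool(sol.success and not at_bound and b50 > 0)
    msg = "" if converged else (sol.message if not sol.success
                                else "BRET50 pinned at search bound")
    return SaturationFit(float(bmax), float(b50), rss, converged, msg)


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    hill: float
    ec50: float
    direction: str  # "stimulation" | "inhibition"
    rss: float
    converged: bool
    message: str = ""


def _logistic(x, bottom, top, hill, log_ec50):
    # 4PL on log10(dose); hill > 0, top = high-dose asymptote
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - x)))


def fit_dose_response(
    doses: Sequence[float],
    responses: Sequence[float],
    zero_dose_floor: float | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> DoseResponseFit:
    """Four-parameter logistic fit on log10(dose).

    ``doses`` must provide >= 5 levels including a zero/vehicle anchor or a
    similarly low dose.  Zero doses are mapped to ``zero_dose_floor``
    (default: two decades below the lowest nonzero dose) — a plotting/fitting
    convention, not a physical claim.  The direction is inferred from the
    sign of (top − bottom): rising responses give an EC50 (stimulation),
    falling ones an IC50 (inhibition); either is returned in ``ec50`` as the
    inflection concentration.  On solver failure up to ``n_starts`` seeded
    restarts with jittered initial values are attempted.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("doses and responses must be 1-D and paired")
    if np.unique(d).size < 5:
        raise ValueError("need >= 5 dose levels")
    nonzero = d[d > 0]
    if nonzero.size == 0:
        raise ValueError("all doses are zero")
    floor = zero_dose_floor if zero_dose_floor is not None else nonzero.min() / 100.0
    x = np.log10(np.where(d > 0, d, floor))

    if np.ptp(y) <= 1e-12 * max(1.0, np.max(np.abs(y))):
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, "stimulation",
                               np.nan, False, "flat response: slope unidentifiable")

    order = np.argsort(x)
    y_lo = float(np.mean(y[order[:2]]))
    y_hi = float(np.mean(y[order[-2:]]))
    p0 = np.array([y_lo, y_hi, 1.0, float(np.median(x))])
    lo = np.array([-np.inf, -np.inf, 0.05, x.min() - 3.0])
    hi = np.array([np.inf, np.inf, 20.0, x.max() + 3.0])

    def resid(p):
        return _logistic(x, *p) - y

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max(1, n_starts)):
        start = p0 if attempt == 0 else p0 * rng.uniform(0.5, 1.5, 4) + rng.normal(
            0, [abs(y_lo) + 0.01, abs(y_hi) + 0.01, 0.3, 0.5]
        )
        start = np.clip(start, lo + 1e-9, hi - 1e-9)
        sol = least_squares(resid, start, bounds=(lo, hi), xtol=_REL_TOL,
                            ftol=_REL_TOL, gtol=1e-12)
        if best is None or (sol.success and np.sum(sol.fun**2) < best[1]):
            best = (sol, float(np.sum(sol.fun**2)))
        if sol.success and attempt == 0:
            break
    sol, rss = best
    bottom, top, hill, log_ec50 = sol.x
    at_edge = log_ec50 <= lo[3] + 1e-6 or log_ec50 >= hi[3] - 1e-6
    converged = bool(sol.success and not at_edge)
    direction = "stimulation" if top >= bottom else "inhibition"
    return DoseResponseFit(
        float(bottom), float(top), float(hill), float(10.0**log_ec50),
        direction, rss, converged,
        "" if converged else (sol.message if not sol.success
                              else "inflection pinned at search bound"),
    )


def normalize_timecourse(
    treated: Sequence[tuple[float, float]],
    reference: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Pointwise treated/reference ratio at exactly matching time points.

    Normalizing a perturbation series to its untreated (or non-heat-treated)
    control removes plate- and time-dependent drifts.  No interpolation:
    time labels must match exactly, missing matches are an error.
    """
    ref = {t: v for t, v in reference}
    out = []
    for t, v in treated:
        if t not in ref:
            raise ValueError(f"no reference value at time point {t!r}")
        if ref[t] == 0:
            raise ValueError(f"reference value is 0 at time point {t!r}")
        out.append((t, v / ref[t]))
    return out


def normalize_orientation_matrix(values: Mapping[str, float]) -> dict[str, float]:
    """Scale an eight-orientation tagging matrix to its maximum entry.

    Each of the (up to) eight donor/acceptor tag placements of a pair is
    divided by the largest obtained value, so the best orientation reads 1.0
    and negative entries keep their sign.
    """
    finite = {k: v for k, v in values.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("all orientation entries are non-finite")
    peak = max(finite.values())
    if peak == 0:
        raise ValueError("maximum orientation value is 0; cannot normalize")
    return {k: (v / peak if np.isfinite(v) else np.nan) for k, v in values.items()}
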