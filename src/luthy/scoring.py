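"""Core assay statistics: BRET and LuC ratios, correction factors, corrected
scores, and sensitized-emission FRET efficiency.

The double readout measures each construct pair twice in one workflow:

* in-cell BRET: ``BRET = LWL/SWL − Cf`` where ``Cf`` is the donor
  bleed-through, i.e. the long/short emission ratio of cells expressing the
  donor-only PA-NL reference (``Cf = LWL_PA-NL / SWL_PA-NL``);
* co-precipitation LuC: ``LuC = (NL_OUT / (v × NL_IN)) / PIR_PA-NL`` with
  ``PIR_PA-NL = NL_OUT,PA-NL / (v × NL_IN,PA-NL)`` the precipitation ratio of
  the PA-NL reference and ``v`` the liquid-handling volume factor (default 3:
  15 µl precipitated vs 5 µl input).

Corrected ratios subtract the larger of the two single-tag control ratios
(control 1: free donor with the pair's acceptor; control 2: the pair's donor
with free acceptor)::

    cBRET = BRET − max(BRET_control1, BRET_control2)
    cLuC  = LuC  − max(LuC_control1,  LuC_control2)

Corrected values may be negative; nothing here clips them — the calling layer
handles signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .io import (
    BRET_CHANNELS,
    LUC_CHANNELS,
    ChannelMissingError,
    ScreenDataset,
    WellReading,
)

__all__ = [
    "CorrectionFactors",
    "ReplicateScore",
    "InteractionScore",
    "FretChannels",
    "compute_cf",
    "compute_bret_ratio",
    "compute_pir_panl",
    "compute_luc_ratio",
    "correct_ratio",
    "score_screen",
    "compute_fret_efficiency",
]

DEFAULT_VOLUME_FACTOR = 3.0


@dataclass(frozen=True)
class CorrectionFactors:
    """Per-scope correction constants used when scoring a replicate.

    ``scope`` records where the PA-NL reference wells came from (a plate id,
    or an experiment id when plate-level references were unavailable).
    """

    cf: float
    pir_panl: float | None = None
    volume_factor: float = DEFAULT_VOLUME_FACTOR
    scope: str = ""

    def __post_init__(self) -> None:
        if self.volume_factor <= 0:
            raise ValueError("volume_factor must be > 0")


@dataclass
class ReplicateScore:
    """Raw and corrected ratios for one pair in one replicate experiment."""

    bret: float = np.nan
    control1_bret: float = np.nan
    control2_bret: float = np.nan
    c_bret: float = np.nan
    luc: float = np.nan
    control1_luc: float = np.nan
    control2_luc: float = np.nan
    c_luc: float = np.nan


def _nanmean(values) -> float:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0 or np.all(np.isnan(arr)):
        return np.nan
    return float(np.nanmean(arr))


@dataclass
class InteractionScore:
    """Per-pair scores across replicates.

    Aggregates are the mean of the *corrected* per-replicate values — raw
    channels are never averaged across experiments.
    """

    pair_id: str
    replicates: dict[str, ReplicateScore] = field(default_factory=dict)
    factors: dict[str, CorrectionFactors] = field(default_factory=dict)
    uncorrected: bool = False

    @property
    def c_bret(self) -> float:
        return _nanmean(r.c_bret for r in self.replicates.values())

    @property
    def c_luc(self) -> float:
        return _nanmean(r.c_luc for r in self.replicates.values())

    @property
    def mean_bret(self) -> float:
        return _nanmean(r.bret for r in self.replicates.values())

    @property
    def mean_luc(self) -> float:
        return _nanmean(r.luc for r in self.replicates.values())


def _well_values(wells, channel: str) -> np.ndarray:
    """Extract one channel from WellReading objects or a DataFrame."""
    if isinstance(wells, pd.DataFrame):
        if channel not in wells.columns:
            raise ChannelMissingError(f"channel {channel!r} absent")
        return wells[channel].to_numpy(dtype=float)
    vals = []
    for w in wells:
        v = getattr(w, channel)
        vals.append(np.nan if v is None else float(v))
    return np.asarray(vals, dtype=float)


def compute_cf(panl_wells, scope: str = "") -> float:
    """Donor bleed-through factor: mean over PA-NL wells of ``LWL/SWL``.

    Mean-of-ratios (not ratio-of-means) so per-well expression differences
    cancel.  Raises when no PA-NL well is available or any SWL is 0/absent.
    """
    lwl = _well_values(panl_wells, "lwl_lum")
    swl = _well_values(panl_wells, "swl_lum")
    if lwl.size == 0:
        raise ValueError(f"no PA-NL reference wells available (scope {scope!r})")
    if np.any(~np.isfinite(swl)) or np.any(swl <= 0):
        raise ValueError(
            f"PA-NL wells with zero or missing short-wavelength luminescence "
            f"(scope {scope!r}); cannot form bleed-through ratio"
        )
    return float(np.mean(lwl / swl))


def compute_bret_ratio(well, cf: float) -> float:
    """``LWL/SWL − Cf`` for one well; may be negative (retained, not clipped)."""
    if isinstance(well, WellReading):
        swl, lwl = well.swl_lum, well.lwl_lum
    else:
        swl, lwl = well  # (swl, lwl) tuple convenience
    if swl is None or lwl is None:
        raise ChannelMissingError("BRET ratio needs both swl_lum and lwl_lum")
    if swl <= 0:
        raise ValueError("swl_lum must be > 0 to form a BRET ratio")
    return lwl / swl - cf


def compute_pir_panl(
    panl_wells, volume_factor: float = DEFAULT_VOLUME_FACTOR, scope: str = ""
) -> float:
    """Precipitation ratio of the PA-NL reference.

    Mean over wells of ``NL_OUT / (volume_factor × NL_IN)``.
    """
    nl_out = _well_values(panl_wells, "nl_out")
    nl_in = _well_values(panl_wells, "nl_in")
    if nl_out.size == 0:
        raise ValueError(f"no PA-NL reference wells available (scope {scope!r})")
    if np.any(~np.isfinite(nl_in)) or np.any(nl_in <= 0):
        raise ValueError(
            f"PA-NL wells with zero or missing input luminescence (scope {scope!r})"
        )
    if np.any(~np.isfinite(nl_out)):
        raise ChannelMissingError(f"PA-NL wells missing nl_out (scope {scope!r})")
    return float(np.mean(nl_out / (volume_factor * nl_in)))


def compute_luc_ratio(
    well, pir_panl: float, volume_factor: float = DEFAULT_VOLUME_FACTOR
) -> float:
    """Normalized co-precipitation ratio for one well.

    ``(NL_OUT / (volume_factor × NL_IN)) / PIR_PA-NL``.
    """
    if isinstance(well, WellReading):
        nl_in, nl_out = well.nl_in, well.nl_out
    else:
        nl_in, nl_out = well
    if nl_in is None or nl_out is None:
        raise ChannelMissingError("LuC ratio needs both nl_in and nl_out")
    if nl_in <= 0:
        raise ValueError("nl_in must be > 0 to form a LuC ratio")
    if pir_panl is None or pir_panl <= 0:
        raise ValueError("pir_panl must be > 0 to normalize LuC ratios")
    return (nl_out / (volume_factor * nl_in)) / pir_panl


def correct_ratio(interaction: float, control1: float, control2: float) -> float:
    """Subtract the larger of the two control ratios (serves cBRET and cLuC)."""
    for name, val in (("control1", control1), ("control2", control2),
                      ("interaction", interaction)):
        if val is None or not np.isfinite(val):
            raise ValueError(f"missing {name} ratio; cannot correct")
    return interaction - max(control1, control2)


@dataclass(frozen=True)
class FretChannels:
    """Three-filter sensitized-emission FRET measurement with bleed-through
    fractions measured on donor-only / acceptor-only samples."""

    dd: float
    aa: float
    da: float
    c_d: float
    c_a: float


def compute_fret_efficiency(ch: FretChannels) -> float:
    """Apparent acceptor FRET efficiency in percent.

    ``E = 100 × (DA − c_D·DD − c_A·AA) / AA``.
    """
    if ch.aa <= 0:
        raise ValueError("acceptor channel signal must be > 0")
    if ch.c_d < 0 or ch.c_a < 0:
        raise ValueError("bleed-through fractions must be >= 0")
    return 100.0 * (ch.da - ch.c_d * ch.dd - ch.c_a * ch.aa) / ch.aa


# ---------------------------------------------------------------------------
# screen scoring


def _per_well_ratios(df: pd.DataFrame, cf: float, pir: float | None,
                     volume_factor: float, want_luc: bool) -> tuple[float, float]:
    """Mean BRET and LuC over the wells in ``df`` (NaN when not computable)."""
    bret = np.nan
    if {"swl_lum", "lwl_lum"}.issubset(df.columns):
        swl = df["swl_lum"].to_numpy(dtype=float)
        lwl = df["lwl_lum"].to_numpy(dtype=float)
        ok = np.isfinite(swl) & np.isfinite(lwl) & (swl > 0)
        if ok.any():
            bret = float(np.mean(lwl[ok] / swl[ok] - cf))
    luc = np.nan
    if want_luc and pir is not None and pir > 0 and {"nl_in", "nl_out"}.issubset(df.columns):
        nl_in = df["nl_in"].to_numpy(dtype=float)
        nl_out = df["nl_out"].to_numpy(dtype=float)
        ok = np.isfinite(nl_in) & np.isfinite(nl_out) & (nl_in > 0)
        if ok.any():
            luc = float(np.mean((nl_out[ok] / (volume_factor * nl_in[ok])) / pir))
    return bret, luc


def score_screen(
    dataset: ScreenDataset,
    volume_factor: float = DEFAULT_VOLUME_FACTOR,
    cf_scope: str = "plate",
    readouts: str = "auto",
) -> list[InteractionScore]:
    """Score every interaction pair of a screen.

    For each replicate experiment, correction factors (Cf and, when the LuC
    channels are present, PIR) are computed from the PA-NL wells of each
    plate; when a plate carries none, the experiment's pooled PA-NL wells are
    used instead (``cf_scope="experiment"`` forces pooling).  Controls are
    resolved by construct identity: control 1 shares the pair's acceptor,
    control 2 shares its donor.  Pairs lacking either control are scored with
    ``uncorrected=True`` and are refused by the calling layer.

    ``readouts`` is ``"auto"`` (score whatever channels exist), ``"bret"``,
    or ``"luc"``/``"both"`` (fail fast if LuC channels are absent).
    """
    if readouts not in ("auto", "bret", "luc", "both"):
        raise ValueError(f"unknown readouts {readouts!r}")
    dataset.require_channels(BRET_CHANNELS, "score_screen")
    want_luc = dataset.has_luc
    if readouts in ("luc", "both") and not dataset.has_luc:
        raise ChannelMissingError(
            "LuC readout requested but dataset is BRET-only "
            f"(needs {list(LUC_CHANNELS)})"
        )
    if readouts == "bret":
        want_luc = False

    wells = dataset.wells
    scores: dict[str, InteractionScore] = {}

    for exp, exp_wells in wells.groupby("experiment"):
        panl = exp_wells[exp_wells["role"] == "panl"]
        if panl.empty:
            raise ValueError(f"experiment {exp!r} has no PA-NL reference wells")

        def factors_for(plate: str) -> CorrectionFactors:
            plate_panl = panl[panl["plate_id"] == plate]
            src, scope = (plate_panl, plate) if (
                cf_scope == "plate" and not plate_panl.empty
            ) else (panl, f"experiment:{exp}")
            cf = compute_cf(src, scope=scope)
            pir = (
                compute_pir_panl(src, volume_factor, scope=scope)
                if want_luc
                else None
            )
            return CorrectionFactors(cf=cf, pir_panl=pir,
                                     volume_factor=volume_factor, scope=str(scope))

        factors_cache: dict[str, CorrectionFactors] = {}
        by_role = {role: grp for role, grp in exp_wells.groupby("role")}
        ctrl1 = by_role.get("control1", exp_wells.iloc[0:0])
        ctrl2 = by_role.get("control2", exp_wells.iloc[0:0])

        for pair_id, pair_wells in by_role.get(
            "interaction", exp_wells.iloc[0:0]
        ).groupby("pair_id"):
            plate = str(pair_wells["plate_id"].iloc[0])
            if plate not in factors_cache:
                factors_cache[plate] = factors_for(plate)
            fac = factors_cache[plate]

            rep = ReplicateScore()
            rep.bret, rep.luc = _per_well_ratios(
                pair_wells, fac.cf, fac.pir_panl, volume_factor, want_luc
            )

            donor_id, acceptor_id = dataset.pairs.get(pair_id, (None, None))
            c1 = ctrl1[ctrl1["acceptor"] == acceptor_id] if "acceptor" in ctrl1 else ctrl1.iloc[0:0]
            c2 = ctrl2[ctrl2["donor"] == donor_id] if "donor" in ctrl2 else ctrl2.iloc[0:0]
            # fall back to pair_id-linked control wells for catalogues
            # without construct columns
            if c1.empty:
                c1 = ctrl1[ctrl1["pair_id"] == pair_id]
            if c2.empty:
                c2 = ctrl2[ctrl2["pair_id"] == pair_id]

            uncorrected = c1.empty or c2.empty
            if not uncorrected:
                rep.control1_bret, rep.control1_luc = _per_well_ratios(
                    c1, fac.cf, fac.pir_panl, volume_factor, want_luc
                )
                rep.control2_bret, rep.control2_luc = _per_well_ratios(
                    c2, fac.cf, fac.pir_panl, volume_factor, want_luc
                )
                if np.isfinite(rep.bret):
                    rep.c_bret = correct_ratio(
                        rep.bret, rep.control1_bret, rep.control2_bret
                    )
                if want_luc and np.isfinite(rep.luc):
                    rep.c_luc = correct_ratio(
                        rep.luc, rep.control1_luc, rep.control2_luc
                    )

            score = scores.setdefault(pair_id, InteractionScore(pair_id=pair_id))
            score.replicates[str(exp)] = rep
            score.factors[str(exp)] = fac
            score.uncorrected = score.uncorrected or uncorrected

    return [scores[p] for p in sorted(scores)]
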