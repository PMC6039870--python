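"""Data model and table I/O for double-readout interaction screens.

A screen is stored long-format: one row per well, with the raw channels as
columns.  Channels that were not measured are absent (NaN), never zero —
downstream operations declare which channels they need and fail fast when a
required one is missing.

Canonical channel columns
-------------------------
``swl_lum``    luminescence at the short wavelength band (370–480 nm)
``lwl_lum``    luminescence at the long wavelength band (520–570 nm)
``cell_fluor`` in-cell acceptor fluorescence (Ex 500 / Em 530)
``nl_in``      lysate input luminescence (before precipitation)
``mcit_in``    lysate input fluorescence
``nl_out``     luminescence after IgG co-precipitation
``mcit_out``   fluorescence after co-precipitation (carried as QC only)

Well roles
----------
``interaction``  the tagged pair of interest (donor NL-X, acceptor PA-mCit-Y)
``control1``     free donor with the pair's acceptor (NL / PA-mCit-Y)
``control2``     the pair's donor with free acceptor (NL-X / PA-mCit)
``panl``         the PA-NL bleed-through / precipitation reference
``tandem``       the PA-mCit-NL tandem fusion (1:1 acceptor:donor)
``blank``        empty or substrate-only well
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNEL_COLUMNS",
    "META_COLUMNS",
    "ROLES",
    "Construct",
    "WellReading",
    "ScreenDataset",
    "LocalizationAnnotation",
    "ValidationError",
    "ChannelMissingError",
    "read_measurements",
    "write_measurements",
    "read_constructs",
    "read_localization",
    "write_results",
    "read_results",
    "write_mitab",
]

CHANNEL_COLUMNS = (
    "swl_lum",
    "lwl_lum",
    "cell_fluor",
    "nl_in",
    "mcit_in",
    "nl_out",
    "mcit_out",
)

#: columns every measurement table must provide (channel columns come on top)
META_COLUMNS = ("plate_id", "well_id", "pair_id", "role")

ROLES = frozenset(
    {"interaction", "control1", "control2", "panl", "tandem", "blank"}
)

TAG_KINDS = frozenset(
    {
        "donor",
        "acceptor",
        "donor_control",
        "acceptor_control",
        "panl_reference",
        "tandem_reference",
    }
)

_WELL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")

# channels required by each readout
BRET_CHANNELS = ("swl_lum", "lwl_lum")
LUC_CHANNELS = ("nl_in", "nl_out")


class ValidationError(ValueError):
    """Input table failed validation; ``.diagnostics`` lists row-level issues."""

    def __init__(self, message: str, diagnostics: Sequence[str] = ()):
        super().__init__(message)
        self.diagnostics = list(diagnostics)

    def __str__(self) -> str:  # pragma: no cover - formatting only
        base = super().__str__()
        if self.diagnostics:
            return base + "\n  " + "\n  ".join(self.diagnostics)
        return base


class ChannelMissingError(ValueError):
    """An operation needs a channel the dataset does not carry."""


@dataclass(frozen=True)
class Construct:
    """A tagged fusion construct (or one of the four controls).

    ``panl_reference`` and ``tandem_reference`` constructs carry no protein of
    interest (``protein == "none"``); donor/acceptor fusions must name one.
    """

    construct_id: str
    protein: str
    tag_kind: str
    orientation: str = "not_applicable"

    def __post_init__(self) -> None:
        if self.tag_kind not in TAG_KINDS:
            raise ValueError(
                f"unknown tag_kind {self.tag_kind!r}; allowed: {sorted(TAG_KINDS)}"
            )
        if self.orientation not in ("N", "C", "not_applicable"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.tag_kind in ("panl_reference", "tandem_reference"):
            if self.protein != "none":
                raise ValueError(
                    f"{self.tag_kind} constructs carry protein='none', "
                    f"got {self.protein!r}"
                )
        if self.tag_kind in ("donor", "acceptor") and (
            not self.protein or self.protein == "none"
        ):
            raise ValueError(
                f"{self.tag_kind} construct {self.construct_id!r} needs a protein symbol"
            )


@dataclass
class WellReading:
    """One well's raw channels plus metadata; absent channels are ``None``."""

    plate_id: str
    well_id: str
    pair_id: str
    role: str
    swl_lum: float | None = None
    lwl_lum: float | None = None
    cell_fluor: float | None = None
    nl_in: float | None = None
    mcit_in: float | None = None
    nl_out: float | None = None
    mcit_out: float | None = None
    experiment: str = "exp1"
    donor: str | None = None
    acceptor: str | None = None


def validate_well_id(well_id: str, plate_format: str = "auto") -> tuple[str, int]:
    """Parse ``A1``-style well names; raise ``ValueError`` if out of range.

    ``plate_format`` is ``"96"``, ``"384"`` or ``"auto"`` (384-well bounds).
    """
    m = _WELL_RE.match(str(well_id).strip())
    if not m:
        raise ValueError(f"malformed well id {well_id!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if plate_format == "96":
        max_row, max_col = "H", 12
    else:  # 384-well bounds also serve as the permissive "auto" envelope
        max_row, max_col = "P", 24
    if row > max_row or not (1 <= col <= max_col):
        raise ValueError(
            f"well {well_id!r} outside the {plate_format if plate_format != 'auto' else '384'}-well "
            f"range A1–{max_row}{max_col}"
        )
    return row, col


@dataclass
class LocalizationAnnotation:
    """protein symbol -> {"membrane", "non_membrane"}; unknown symbols default
    to non_membrane (the two-level scheme used by the cutoff rules)."""

    classes: dict[str, str] = field(default_factory=dict)
    default: str = "non_membrane"

    ALLOWED = ("membrane", "non_membrane")

    def __post_init__(self) -> None:
        for protein, cls in self.classes.items():
            if cls not in self.ALLOWED:
                raise ValueError(
                    f"unknown localization class {cls!r} for {protein!r}; "
                    f"allowed: {list(self.ALLOWED)}"
                )

    def __getitem__(self, protein: str) -> str:
        return self.classes.get(protein, self.default)

    def is_membrane(self, protein: str) -> bool:
        return self[protein] == "membrane"


@dataclass
class ScreenDataset:
    """A validated screen: wells table + construct and pair catalogues.

    ``wells`` is a tidy DataFrame with columns ``plate_id, well_id, pair_id,
    role, experiment, donor, acceptor`` plus whichever channel columns were
    measured.  Unknown input columns are preserved as extra columns.
    """

    wells: pd.DataFrame
    constructs: dict[str, Construct] = field(default_factory=dict)
    pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    experiment_id: str | None = None

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(c for c in CHANNEL_COLUMNS if c in self.wells.columns)

    @property
    def experiments(self) -> list[str]:
        return sorted(self.wells["experiment"].unique())

    @property
    def has_bret(self) -> bool:
        return all(c in self.wells.columns for c in BRET_CHANNELS)

    @property
    def has_luc(self) -> bool:
        return all(c in self.wells.columns for c in LUC_CHANNELS)

    @property
    def bret_only(self) -> bool:
        return self.has_bret and not self.has_luc

    def require_channels(self, channels: Iterable[str], operation: str) -> None:
        missing = [c for c in channels if c not in self.wells.columns]
        if missing:
            raise ChannelMissingError(
                f"{operation} needs channel(s) {missing}; dataset carries "
                f"{list(self.channels)}"
            )

    def interaction_pairs(self) -> list[str]:
        sel = self.wells["role"] == "interaction"
        return sorted(self.wells.loc[sel, "pair_id"].unique())


def _open(source, mode="r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def _read_table(source, delimiter: str | None) -> pd.DataFrame:
    handle, close = _open(source)
    try:
        if delimiter is None:
            # sniff: python engine autodetects common delimiters
            return pd.read_csv(handle, sep=None, engine="python")
        return pd.read_csv(handle, sep=delimiter)
    finally:
        if close:
            handle.close()


def read_measurements(
    source,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    plate_format: str = "auto",
    constructs: Mapping[str, Construct] | None = None,
) -> ScreenDataset:
    """Read a long-format measurement table into a validated ``ScreenDataset``.

    Parameters
    ----------
    source
        Path or open text stream of a delimited table with a header row.
    schema
        Optional mapping canonical-name -> column-name-in-file, for vendor
        exports with different headers.  Canonical names not in the mapping
        are looked up verbatim.
    delimiter
        Explicit field delimiter; autodetected when ``None``.
    plate_format
        ``"96"``, ``"384"`` or ``"auto"`` — bounds for well-id validation.
    constructs
        Optional catalogue of :class:`Construct` by id.  When the table has
        ``donor``/``acceptor`` columns and no catalogue is given, minimal
        constructs are synthesised with the construct id doubling as the
        protein symbol.

    Raises
    ------
    ValidationError
        With one diagnostic per offending row (malformed well ids, negative
        channel values, duplicate (plate, well) keys, unknown roles).
    """
    raw = _read_table(source, delimiter)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in META_COLUMNS + CHANNEL_COLUMNS + (
        "experiment", "donor", "acceptor")}
    raw = raw.rename(columns={k: v for k, v in rename.items() if k in raw.columns})

    missing_meta = [c for c in META_COLUMNS if c not in raw.columns]
    if missing_meta:
        raise ValidationError(f"missing required column(s): {missing_meta}")
    present_channels = [c for c in CHANNEL_COLUMNS if c in raw.columns]
    if not present_channels:
        raise ValidationError(
            f"no channel column found; expected at least one of {list(CHANNEL_COLUMNS)}"
        )

    wells = raw.copy()
    if "experiment" not in wells.columns:
        wells["experiment"] = "exp1"
    wells["experiment"] = wells["experiment"].astype(str)
    for col in ("plate_id", "well_id", "pair_id", "role"):
        wells[col] = wells[col].astype(str).str.strip()
    for col in present_channels:
        wells[col] = pd.to_numeric(wells[col], errors="coerce")

    diagnostics: list[str] = []
    for idx, row in wells.iterrows():
        rowno = idx + 2  # 1-based with header line
        try:
            validate_well_id(row["well_id"], plate_format)
        except ValueError as exc:
            diagnostics.append(f"row {rowno}: {exc}")
        if row["role"] not in ROLES:
            diagnostics.append(
                f"row {rowno}: unknown role {row['role']!r}; allowed: {sorted(ROLES)}"
            )
        for col in present_channels:
            val = row[col]
            if pd.notna(val):
                if not np.isfinite(val):
                    diagnostics.append(f"row {rowno}: non-finite {col}")
                elif val < 0:
                    diagnostics.append(f"row {rowno}: negative {col} ({val})")

    dup_key = ["experiment", "plate_id", "well_id"]
    dups = wells.duplicated(subset=dup_key, keep=False)
    if dups.any():
        for idx in wells.index[dups]:
            r = wells.loc[idx]
            diagnostics.append(
                f"row {idx + 2}: duplicate (plate, well) key "
                f"({r['plate_id']}, {r['well_id']}) in experiment {r['experiment']}"
            )
    if diagnostics:
        raise ValidationError(
            f"{len(diagnostics)} invalid row(s) in measurement table", diagnostics
        )

    construct_cat = dict(constructs or {})
    pairs: dict[str, tuple[str, str]] = {}
    if "donor" in wells.columns and "acceptor" in wells.columns:
        inter = wells[wells["role"] == "interaction"]
        for pair_id, grp in inter.groupby("pair_id"):
            donors = grp["donor"].dropna().unique()
            acceptors = grp["acceptor"].dropna().unique()
            if len(donors) != 1 or len(acceptors) != 1:
                raise ValidationError(
                    f"pair {pair_id!r} maps to {len(donors)} donor / "
                    f"{len(acceptors)} acceptor constructs; expected exactly one of each"
                )
            d, a = str(donors[0]), str(acceptors[0])
            pairs[pair_id] = (d, a)
            for cid, kind in ((d, "donor"), (a, "acceptor")):
                construct_cat.setdefault(
                    cid, Construct(cid, protein=cid, tag_kind=kind, orientation="N")
                )
    else:
        for pair_id in wells.loc[wells["role"] == "interaction", "pair_id"].unique():
            pairs[pair_id] = (f"{pair_id}:donor", f"{pair_id}:acceptor")
        wells["donor"] = wells["pair_id"].map(
            {p: d for p, (d, a) in pairs.items()}
        )
        wells["acceptor"] = wells["pair_id"].map(
            {p: a for p, (d, a) in pairs.items()}
        )
        for pair_id, (d, a) in pairs.items():
            construct_cat.setdefault(d, Construct(d, pair_id, "donor", "N"))
            construct_cat.setdefault(a, Construct(a, pair_id, "acceptor", "N"))

    return ScreenDataset(wells=wells, constructs=construct_cat, pairs=pairs)


def write_measurements(dataset: ScreenDataset, destination, delimiter: str = "\t") -> None:
    """Write the wells table back to a delimited file (lossless round-trip)."""
    handle, close = _open(destination, "w")
    try:
        dataset.wells.to_csv(handle, sep=delimiter, index=False)
    finally:
        if close:
            handle.close()


def read_constructs(source, delimiter: str | None = None) -> dict[str, Construct]:
    """Read a construct catalogue table.

    Columns: ``construct_id, protein, tag_kind`` and optional ``orientation``.
    """
    df = _read_table(source, delimiter)
    required = {"construct_id", "protein", "tag_kind"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"construct table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out: dict[str, Construct] = {}
    for _, row in df.iterrows():
        c = Construct(
            construct_id=str(row["construct_id"]),
            protein=str(row["protein"]),
            tag_kind=str(row["tag_kind"]),
            orientation=str(row.get("orientation", "not_applicable")),
        )
        out[c.construct_id] = c
    return out


def read_localization(source, delimiter: str | None = None) -> LocalizationAnnotation:
    """Read a two-column (protein, class) table into a LocalizationAnnotation.

    Duplicate symbols with conflicting classes are rejected; unknown class
    labels raise with the allowed labels listed.
    """
    df = _read_table(source, delimiter)
    if df.shape[1] < 2:
        raise ValidationError("localization table needs two columns (protein, class)")
    prot_col, cls_col = df.columns[:2]
    classes: dict[str, str] = {}
    diagnostics = []
    for idx, row in df.iterrows():
        protein = str(row[prot_col]).strip()
        cls = str(row[cls_col]).strip()
        if cls not in LocalizationAnnotation.ALLOWED:
            diagnostics.append(
                f"row {idx + 2}: unknown class {cls!r}; allowed: "
                f"{list(LocalizationAnnotation.ALLOWED)}"
            )
            continue
        if protein in classes and classes[protein] != cls:
            diagnostics.append(
                f"row {idx + 2}: conflicting class for {protein!r} "
                f"({classes[protein]!r} vs {cls!r})"
            )
            continue
        classes[protein] = cls
    if diagnostics:
        raise ValidationError("invalid localization table", diagnostics)
    return LocalizationAnnotation(classes=classes)


# ---------------------------------------------------------------------------
# results

RESULT_COLUMNS = [
    "pair_id",
    "experiment",
    "bret",
    "control1_bret",
    "control2_bret",
    "c_bret",
    "luc",
    "control1_luc",
    "control2_luc",
    "c_luc",
    "cf",
    "pir_panl",
    "uncorrected",
    "cutoff_class",
    "bret_positive",
    "luc_positive",
    "double_positive",
    "any_positive",
]


def results_frame(scores, calls=None) -> pd.DataFrame:
    """Long-format results: one row per pair per replicate plus an
    ``aggregate`` row carrying across-replicate means and call flags."""
    from .scoring import InteractionScore  # local import to avoid cycle

    call_by_pair = {c.pair_id: c for c in (calls or [])}
    rows = []
    for s in scores:
        assert isinstance(s, InteractionScore)
        for exp, rep in sorted(s.replicates.items()):
            fac = s.factors.get(exp)
            rows.append(
                dict(
                    pair_id=s.pair_id,
                    experiment=exp,
                    bret=rep.bret,
                    control1_bret=rep.control1_bret,
                    control2_bret=rep.control2_bret,
                    c_bret=rep.c_bret,
                    luc=rep.luc,
                    control1_luc=rep.control1_luc,
                    control2_luc=rep.control2_luc,
                    c_luc=rep.c_luc,
                    cf=None if fac is None else fac.cf,
                    pir_panl=None if fac is None else fac.pir_panl,
                    uncorrected=s.uncorrected,
                )
            )
        agg = dict(
            pair_id=s.pair_id,
            experiment="aggregate",
            bret=s.mean_bret,
            c_bret=s.c_bret,
            luc=s.mean_luc,
            c_luc=s.c_luc,
            uncorrected=s.uncorrected,
        )
        call = call_by_pair.get(s.pair_id)
        if call is not None:
            agg.update(
                cutoff_class=call.cutoff_class,
                bret_positive=call.bret_positive,
                luc_positive=call.luc_positive,
                double_positive=call.double_positive,
                any_positive=call.any_positive,
            )
        rows.append(agg)
    df = pd.DataFrame(rows)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[RESULT_COLUMNS]


def write_results(scores, destination, calls=None, delimiter: str = "\t") -> None:
    """Write the long-format results TSV (header-only when ``scores`` empty)."""
    df = results_frame(scores, calls)
    handle, close = _open(destination, "w")
    try:
        df.to_csv(handle, sep=delimiter, index=False)
    finally:
        if close:
            handle.close()


def read_results(source, delimiter: str = "\t") -> pd.DataFrame:
    df = _read_table(source, delimiter)
    return df


_MITAB_HEADER = [
    "#ID(s) interactor A",
    "ID(s) interactor B",
    "Alt. ID(s) interactor A",
    "Alt. ID(s) interactor B",
    "Alias(es) interactor A",
    "Alias(es) interactor B",
    "Interaction detection method(s)",
    "Publication 1st author(s)",
    "Publication Identifier(s)",
    "Taxid interactor A",
    "Taxid interactor B",
    "Interaction type(s)",
    "Source database(s)",
    "Interaction identifier(s)",
    "Confidence value(s)",
]


def write_mitab(scores, calls, destination, pair_proteins=None) -> int:
    """Export positive pairs as a minimal PSI-MI TAB 2.7-style table.

    One row per ``any_positive`` pair; confidence column carries the
    aggregate corrected ratios.  Returns the number of rows written.
    """
    call_by_pair = {c.pair_id: c for c in calls}
    handle, close = _open(destination, "w")
    n = 0
    try:
        handle.write("\t".join(_MITAB_HEADER) + "\n")
        for s in scores:
            call = call_by_pair.get(s.pair_id)
            if call is None or not call.any_positive:
                continue
            if pair_proteins and s.pair_id in pair_proteins:
                a, b = pair_proteins[s.pair_id]
            else:
                a, b = s.pair_id, s.pair_id
            conf = []
            if s.c_bret is not None and np.isfinite(s.c_bret):
                conf.append(f"cbret:{s.c_bret:.6g}")
            if s.c_luc is not None and np.isfinite(s.c_luc):
                conf.append(f"cluc:{s.c_luc:.6g}")
            row = [
                a, b, "-", "-", "-", "-",
                "bioluminescence resonance energy transfer and "
                "luminescence-based co-precipitation (double readout)",
                "-", "-", "taxid:9606(human)", "taxid:9606(human)",
                "psi-mi:\"MI:0915\"(physical association)",
                "-", s.pair_id, "|".join(conf) or "-",
            ]
            handle.write("\t".join(row) + "\n")
            n += 1
    finally:
        if close:
            handle.close()
    return n
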