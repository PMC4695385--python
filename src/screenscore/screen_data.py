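"""Data model and CSV I/O for arrayed 96-well viability screens.

The canonical interchange format is a long-format CSV with one row per
well x selection arm x replicate:

    plate_id,row,column,reagent_id,target_gene,control_class,selection_arm,replicate_index,signal

``row`` is a plate row letter (A-H on a 96-well plate), ``column`` a plate
column number (1-12); both are labels, never indices.  ``control_class``
assigns the well its role in scoring: negative-control hairpins (shLUC /
shRFP / shLACZ, targeting genes absent from the cells), positive-control
hairpins (shGFP / shKRAS, silencing the driver), candidate-gene hairpins,
empty-vector wells and virus-free medium wells.  ``signal`` is the raw
viability readout (luminescence or absorbance, arbitrary units, >= 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

CONTROL_CLASSES = (
    "negative_control",
    "positive_control",
    "candidate",
    "vector_only",
    "medium_only",
)
SELECTION_ARMS = ("selected", "unselected")

#: Canonical column order of the interchange CSV.
REQUIRED_COLUMNS = (
    "plate_id",
    "row",
    "column",
    "reagent_id",
    "target_gene",
    "control_class",
    "selection_arm",
    "replicate_index",
    "signal",
)

#: Columns that uniquely identify one measured well record.
WELL_KEY = ["plate_id", "row", "column", "selection_arm", "replicate_index"]

#: Columns identifying a physical well position, ignoring arm/replicate.
POSITION_KEY = ["plate_id", "row", "column"]

PLATE_ROWS = tuple("ABCDEFGH")
PLATE_COLUMNS = tuple(range(1, 13))

#: Conventional reagent-name -> control-class vocabulary from the screen design.
CONTROL_VOCABULARY = {
    "shLUC": "negative_control",
    "shRFP": "negative_control",
    "shLACZ": "negative_control",
    "shGFP": "positive_control",
    "shKRAS": "positive_control",
    "PGW": "vector_only",
    "medium": "medium_only",
}


@dataclass(frozen=True)
class WellRecord:
    """One well's annotation plus raw signal; the atomic unit of a screen."""

    plate_id: str
    row: str
    column: int
    reagent_id: str
    target_gene: str
    control_class: str
    selection_arm: str
    replicate_index: int
    signal: float


@dataclass(frozen=True)
class Issue:
    """One machine-readable validation finding."""

    code: str
    location: str
    message: str


class ScreenDataset:
    """A screen (or control-plate set) as a validated long-format table.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; extra
    columns are preserved untouched as opaque metadata.
    """

    def __init__(self, wells: pd.DataFrame, cell_line: str = ""):
        missing = [c for c in REQUIRED_COLUMNS if c not in wells.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df = wells.copy()
        for col in ("plate_id", "row", "reagent_id", "target_gene",
                    "control_class", "selection_arm"):
            df[col] = df[col].fillna("").astype(str)
        df["column"] = df["column"].astype(int)
        df["replicate_index"] = df["replicate_index"].astype(int)
        df["signal"] = df["signal"].astype(float)
        self.wells = df.reset_index(drop=True)
        self.cell_line = cell_line

    @property
    def plate_ids(self) -> list[str]:
        """Distinct plate labels in first-appearance order."""
        return list(dict.fromkeys(self.wells["plate_id"]))

    def __len__(self) -> int:
        return len(self.wells)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScreenDataset):
            return NotImplemented
        if self.cell_line != other.cell_line:
            return False
        if set(self.wells.columns) != set(other.wells.columns):
            return False
        a = self.wells.sort_values(WELL_KEY).reset_index(drop=True)
        b = other.wells.sort_values(WELL_KEY).reset_index(drop=True)
        return a.equals(b[a.columns.tolist()])

    def subset(self, mask) -> "ScreenDataset":
        """New dataset containing only rows where ``mask`` is true."""
        return ScreenDataset(self.wells.loc[mask], cell_line=self.cell_line)

    @classmethod
    def from_records(cls, records, cell_line: str = "") -> "ScreenDataset":
        """Build from an iterable of :class:`WellRecord` (or mappings)."""
        rows = [r.__dict__ if isinstance(r, WellRecord) else dict(r) for r in records]
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
        return cls(df, cell_line=cell_line)

    def to_records(self) -> list[WellRecord]:
        return [
            WellRecord(**{k: row[k] for k in REQUIRED_COLUMNS})
            for row in self.wells[list(REQUIRED_COLUMNS)].to_dict("records")
        ]


def read_screen_table(path, cell_line: str = "") -> ScreenDataset:
    """Read the canonical long-format CSV into a validated dataset.

    Raises :class:`FormatError` for a missing column or a non-numeric /
    negative signal (naming the offending line), and
    :class:`ValidationError` for duplicate well keys.  A header-only file
    yields an empty dataset.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "row": str, "reagent_id": str,
                                  "target_gene": str, "control_class": str,
                                  "selection_arm": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    signals = pd.to_numeric(df["signal"], errors="coerce")
    bad = ~np.isfinite(signals) | (signals < 0)
    if bad.any():
        # +2: one for the header row, one for 1-based numbering.
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(f"{path}: line {line}: signal must be a finite number >= 0 "
                          f"(got {df['signal'].iloc[line - 2]!r})")
    df["signal"] = signals
    dup = df.duplicated(subset=WELL_KEY, keep=False)
    if dup.any():
        key = tuple(df.loc[dup.idxmax(), WELL_KEY])
        raise ValidationError(f"{path}: duplicate well key {key}")
    return ScreenDataset(df, cell_line=cell_line)


def write_screen_table(ds: ScreenDataset, path) -> None:
    """Write a dataset back out in the canonical CSV schema."""
    cols = list(REQUIRED_COLUMNS) + [c for c in ds.wells.columns
                                     if c not in REQUIRED_COLUMNS]
    # repr gives the shortest decimal that round-trips the exact float
    ds.wells[cols].to_csv(path, index=False,
                          float_format=lambda x: repr(float(x)))


def validate_dataset(ds: ScreenDataset) -> list[Issue]:
    """Report every structural-invariant violation; never raises.

    Issue codes: ``duplicate_well``, ``bad_signal``, ``bad_row``,
    ``bad_column``, ``bad_control_class``, ``bad_selection_arm``,
    ``bad_replicate_index``, ``medium_with_reagent``,
    ``candidate_missing_gene``, ``no_negative_controls``.
    """
    issues: list[Issue] = []
    df = ds.wells

    def loc(row) -> str:
        return (f"{row.plate_id}/{row.row}{row.column}"
                f"/{row.selection_arm}/rep{row.replicate_index}")

    dup = df.duplicated(subset=WELL_KEY, keep="first")
    for row in df.loc[dup].itertuples():
        issues.append(Issue("duplicate_well", loc(row),
                            "well key occurs more than once"))
    for row in df.itertuples():
        if not (math.isfinite(row.signal) and row.signal >= 0):
            issues.append(Issue("bad_signal", loc(row),
                                f"signal must be finite and >= 0, got {row.signal}"))
        if row.row not in PLATE_ROWS:
            issues.append(Issue("bad_row", loc(row),
                                f"row must be one of A-H, got {row.row!r}"))
        if row.column not in PLATE_COLUMNS:
            issues.append(Issue("bad_column", loc(row),
                                f"column must be 1-12, got {row.column}"))
        if row.control_class not in CONTROL_CLASSES:
            issues.append(Issue("bad_control_class", loc(row),
                                f"unknown control class {row.control_class!r}"))
        if row.selection_arm not in SELECTION_ARMS:
            issues.append(Issue("bad_selection_arm", loc(row),
                                f"unknown selection arm {row.selection_arm!r}"))
        if row.replicate_index < 1:
            issues.append(Issue("bad_replicate_index", loc(row),
                                "replicate index must be a positive integer"))
        if row.control_class == "medium_only" and (row.reagent_id or row.target_gene):
            issues.append(Issue("medium_with_reagent", loc(row),
                                "medium-only wells must carry no reagent or gene"))
        if row.control_class == "candidate" and not row.target_gene:
            issues.append(Issue("candidate_missing_gene", loc(row),
                                "candidate wells must name a target gene"))

    # Every plate with selected-arm candidate wells needs at least one
    # selected-arm negative control -- percent-of-control needs a denominator.
    sel = df[df["selection_arm"] == "selected"]
    for plate_id, grp in sel.groupby("plate_id"):
        has_candidates = (grp["control_class"] == "candidate").any()
        has_negatives = (grp["control_class"] == "negative_control").any()
        if has_candidates and not has_negatives:
            issues.append(Issue("no_negative_controls", str(plate_id),
                                "plate has candidate wells but no selected-arm "
                                "negative-control wells"))
    return issues
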