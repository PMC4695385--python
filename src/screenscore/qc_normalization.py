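"""Replicate QC, well exclusion and percent-of-control relative growth.

The screen carries two arms per well: replicates selected with puromycin
(the proliferation readout proper) and replicates left unselected (a
transduction-efficiency control).  QC correlates the two arms well-by-well;
scoring then uses selected-arm signals only, expressed per plate as a
percentage of the mean signal of that plate's negative-control wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, NormalizationError, UndefinedStatisticError
from .screen_data import POSITION_KEY, ScreenDataset


@dataclass
class QCReport:
    """Replicate-quality summary for one screen dataset.

    ``excluded_wells`` lists one ``(well_key, reason)`` pair per excluded
    well position, reason in {vector_only, medium_only, sd_outlier};
    ``per_well_sd`` maps well position -> SD of its selected-arm replicate
    signals (raw signal units); ``single_replicate_wells`` lists positions
    exempt from the SD rule for lack of replication.
    """

    arm_correlation_r: float = float("nan")
    n_wells_used: int = 0
    excluded_wells: list = field(default_factory=list)
    per_well_sd: dict = field(default_factory=dict)
    single_replicate_wells: list = field(default_factory=list)


@dataclass(frozen=True)
class RelativeGrowthRecord:
    """Pooled growth of one reagent on one plate, as % of control."""

    reagent_id: str
    target_gene: str
    plate_id: str
    control_class: str
    n_replicates: int
    relative_growth_pct: float


def _non_assay_mask(df: pd.DataFrame):
    return df["control_class"].isin(["vector_only", "medium_only"])


def arm_correlation(ds: ScreenDataset) -> tuple[float, int]:
    """Pearson r between selected- and unselected-arm well signals.

    Vector-only and medium-only wells are dropped first.  Each well
    position contributes its replicate-mean signal in each arm; positions
    present in only one arm are dropped.  Returns ``(r, n_wells_used)``.

    Raises :class:`InsufficientDataError` with fewer than 3 paired wells
    and :class:`UndefinedStatisticError` if either arm has zero variance.
    """
    df = ds.wells[~_non_assay_mask(ds.wells)]
    means = (df.groupby(POSITION_KEY + ["selection_arm"], sort=False)["signal"]
               .mean().unstack("selection_arm"))
    if "selected" not in means.columns or "unselected" not in means.columns:
        raise InsufficientDataError("dataset must contain wells in both arms")
    paired = means[["selected", "unselected"]].dropna()
    if len(paired) < 3:
        raise InsufficientDataError(
            f"need >= 3 wells paired across arms, got {len(paired)}")
    x = paired["selected"].to_numpy()
    y = paired["unselected"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in one arm; correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r), int(len(paired))


def _upper_adjacent_value(values: np.ndarray) -> float:
    """Tukey upper adjacent value: largest observation <= Q3 + 1.5*IQR.

    Quartiles by linear interpolation (the numpy default, "type 7"), so
    the rule is reproducible.
    """
    q1, q3 = np.quantile(values, [0.25, 0.75])
    fence = q3 + 1.5 * (q3 - q1)
    inside = values[values <= fence]
    # Q3 itself is always an observation-bounded quantity <= fence.
    return float(inside.max())


def exclude_wells(ds: ScreenDataset, sd_rule_group: str = "plate",
                  ) -> tuple[ScreenDataset, QCReport]:
    """Drop non-assay wells and replicate-SD outliers.

    All vector-only (empty lentiviral vector) and medium-only wells are
    removed unconditionally.  For the remaining wells, the SD of each
    well's selected-arm replicate signals is computed and wells whose SD
    exceeds the Tukey upper adjacent value of the SD distribution
    (grouped per ``sd_rule_group``: "plate" or "global") are removed as
    ``sd_outlier``.  Wells with a single selected replicate are exempt
    and listed in the report.  Excluding a position removes all of its
    arms and replicates.
    """
    if sd_rule_group not in ("plate", "global"):
        raise ValueError("sd_rule_group must be 'plate' or 'global'")
    report = QCReport()
    df = ds.wells

    non_assay = df[_non_assay_mask(df)]
    for key in non_assay.groupby(POSITION_KEY + ["control_class"]).groups:
        report.excluded_wells.append((key[:3], key[3]))
    keep = ~_non_assay_mask(df)
    df = df[keep]

    sel = df[df["selection_arm"] == "selected"]
    sd = sel.groupby(POSITION_KEY)["signal"].agg(["std", "count"])
    multi = sd[sd["count"] >= 2]
    report.per_well_sd = {k: float(v) for k, v in multi["std"].items()}
    report.single_replicate_wells = list(sd.index[sd["count"] < 2])

    outliers: set = set()
    if len(multi):
        if sd_rule_group == "plate":
            groups = multi.groupby(level="plate_id")
        else:
            groups = [(None, multi)]
        for _, grp in groups:
            uav = _upper_adjacent_value(grp["std"].to_numpy())
            outliers.update(grp.index[grp["std"] > uav])
    for key in sorted(outliers):
        report.excluded_wells.append((key, "sd_outlier"))

    if outliers:
        pos = pd.MultiIndex.from_frame(df[POSITION_KEY])
        df = df[~pos.isin(outliers)]
    filtered = ScreenDataset(df, cell_line=ds.cell_line)
    return filtered, report


def relative_growth(ds: ScreenDataset) -> list[RelativeGrowthRecord]:
    """Per-reagent pooled growth as % of same-plate negative-control mean.

    For each reagent on each plate (selected arm only), replicate signals
    are pooled by arithmetic mean and divided by the mean of all
    selected-arm negative-control signals on that plate, times 100.
    Records are returned for every class except the non-assay wells, so
    control wells get relative-growth values too.

    Raises :class:`NormalizationError` if a plate's control mean is zero
    and :class:`InsufficientDataError` if a plate has no selected-arm
    negative-control wells.
    """
    df = ds.wells
    sel = df[(df["selection_arm"] == "selected") & ~_non_assay_mask(df)]
    records: list[RelativeGrowthRecord] = []
    for plate_id, plate in sel.groupby("plate_id", sort=False):
        controls = plate.loc[plate["control_class"] == "negative_control", "signal"]
        if controls.empty:
            raise InsufficientDataError(
                f"plate {plate_id}: no selected-arm negative-control wells")
        denom = controls.mean()
        if denom == 0:
            raise NormalizationError(f"plate {plate_id}: control mean is zero")
        pooled = (plate.groupby(["reagent_id", "target_gene", "control_class"],
                                sort=False)["signal"].agg(["mean", "count"]))
        for (reagent, gene, cls), row in pooled.iterrows():
            records.append(RelativeGrowthRecord(
                reagent_id=reagent, target_gene=gene, plate_id=str(plate_id),
                control_class=cls, n_replicates=int(row["count"]),
                relative_growth_pct=float(100.0 * row["mean"] / denom)))
    return records


def well_relative_growth(ds: ScreenDataset,
                         control_class: str | None = None) -> pd.DataFrame:
    """Per-well (not per-reagent) relative growth, % of plate control mean.

    Each well position's selected-arm replicate-mean signal divided by the
    plate's negative-control mean.  Used for the ROC control sets and as
    the control sample of the per-gene t-tests, where individual control
    wells are the unit of observation.
    """
    df = ds.wells
    sel = df[(df["selection_arm"] == "selected") & ~_non_assay_mask(df)]
    out = []
    for plate_id, plate in sel.groupby("plate_id", sort=False):
        controls = plate.loc[plate["control_class"] == "negative_control", "signal"]
        if controls.empty:
            raise InsufficientDataError(
                f"plate {plate_id}: no selected-arm negative-control wells")
        denom = controls.mean()
        if denom == 0:
            raise NormalizationError(f"plate {plate_id}: control mean is zero")
        per_well = plate.groupby(POSITION_KEY + ["reagent_id", "control_class"],
                                 sort=False)["signal"].mean().reset_index()
        per_well["relative_growth_pct"] = 100.0 * per_well["signal"] / denom
        out.append(per_well.drop(columns="signal"))
    result = pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=POSITION_KEY + ["reagent_id", "control_class", "relative_growth_pct"])
    if control_class is not None:
        result = result[result["control_class"] == control_class].reset_index(drop=True)
    return result


def growth_table(records: list[RelativeGrowthRecord]) -> pd.DataFrame:
    """Relative-growth records as a DataFrame (one row per reagent/plate)."""
    return pd.DataFrame([r.__dict__ for r in records])
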