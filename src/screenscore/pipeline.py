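"""One-shot orchestration of the full screen analysis.

Stage order: well exclusion (both datasets) -> arm-correlation QC ->
percent-of-control relative growth -> ROC/FDR calibration on the external
control plates -> per-gene scoring with q-values -> hit calling.  Every
intermediate is kept on the result so stages can be inspected or re-run
individually.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

import pandas as pd

from . import qc_normalization as qc
from . import scoring
from .errors import PipelineStageError
from .screen_data import ScreenDataset, validate_dataset


@dataclass
class PipelineParams:
    """All scoring thresholds, defaulting to the standard hit rule."""

    target_fdr: float = scoring.DEFAULT_TARGET_FDR
    p_cut: float = scoring.DEFAULT_P_CUT
    q_cut: float = scoring.DEFAULT_Q_CUT
    min_shrnas: int = scoring.DEFAULT_MIN_SHRNAS
    q_method: str = "bh"
    equal_var: bool = True
    sd_rule_group: str = "plate"


@dataclass
class PipelineResult:
    qc: qc.QCReport
    calibration: scoring.ROCCalibration | None
    gene_scores: list[scoring.GeneScore]
    hit_table: pd.DataFrame
    growth_records: list[qc.RelativeGrowthRecord]
    provenance: dict = field(default_factory=dict)

    @property
    def scores_table(self) -> pd.DataFrame:
        return scoring.scores_table(self.gene_scores)


def _dataset_digest(ds: ScreenDataset) -> str:
    key = ["plate_id", "row", "column", "selection_arm", "replicate_index"]
    canonical = ds.wells.sort_values(key).to_csv(index=False)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _package_version() -> str:
    try:
        return version("screenscore")
    except PackageNotFoundError:
        return "unknown"


def run_screen_pipeline(screen: ScreenDataset, controls: ScreenDataset,
                        params: PipelineParams | None = None) -> PipelineResult:
    """Score a screen end to end against its external control plates.

    ``screen`` carries the candidate-gene plates; ``controls`` the
    positive/negative calibration plates.  Both must validate cleanly.
    A screen without candidate wells completes with QC and calibration
    only (empty gene scores and hit table).
    """
    params = params or PipelineParams()

    for name, ds in (("screen", screen), ("controls", controls)):
        issues = validate_dataset(ds)
        if issues:
            raise PipelineStageError(
                "validate", ValueError(
                    f"{name} dataset has {len(issues)} issue(s); first: "
                    f"{issues[0].code} at {issues[0].location}"))

    try:
        screen_f, report = qc.exclude_wells(screen, params.sd_rule_group)
        controls_f, _ = qc.exclude_wells(controls, params.sd_rule_group)
    except Exception as exc:  # noqa: BLE001 - annotate with stage
        raise PipelineStageError("exclude_wells", exc) from exc

    # Correlation on the assay wells before SD-based exclusion, matching
    # the QC-scatter-first ordering of the screen protocol.
    try:
        r, n_used = qc.arm_correlation(screen)
        report.arm_correlation_r, report.n_wells_used = r, n_used
    except Exception as exc:
        raise PipelineStageError("arm_correlation", exc) from exc

    try:
        records = qc.relative_growth(screen_f)
        screen_controls = qc.well_relative_growth(screen_f, "negative_control")
        ctrl_wells = qc.well_relative_growth(controls_f)
    except Exception as exc:
        raise PipelineStageError("relative_growth", exc) from exc

    try:
        pos = ctrl_wells.loc[ctrl_wells["control_class"] == "positive_control",
                             "relative_growth_pct"]
        neg = ctrl_wells.loc[ctrl_wells["control_class"] == "negative_control",
                             "relative_growth_pct"]
        calibration = scoring.roc_calibration(pos, neg, params.target_fdr)
    except Exception as exc:
        raise PipelineStageError("roc_calibration", exc) from exc

    candidates = [rec for rec in records if rec.control_class == "candidate"]
    gene_scores: list[scoring.GeneScore] = []
    if candidates:
        try:
            gene_scores = scoring.score_genes(
                candidates, screen_controls["relative_growth_pct"],
                calibration, q_method=params.q_method,
                equal_var=params.equal_var, p_cut=params.p_cut,
                q_cut=params.q_cut, min_shrnas=params.min_shrnas)
        except Exception as exc:
            raise PipelineStageError("score_genes", exc) from exc

    hit_table = scoring.call_hits(gene_scores, params.p_cut, params.q_cut,
                                  params.min_shrnas)

    provenance = {
        "screen_sha256": _dataset_digest(screen),
        "controls_sha256": _dataset_digest(controls),
        "params": params.__dict__.copy(),
        "screenscore_version": _package_version(),
    }
    return PipelineResult(qc=report, calibration=calibration,
                          gene_scores=gene_scores, hit_table=hit_table,
                          growth_records=records, provenance=provenance)


def write_results(result: PipelineResult, outdir) -> None:
    """Write genes.tsv, hits.tsv, calibration.tsv, qc.tsv, provenance.json."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.scores_table.to_csv(out / "genes.tsv", sep="\t", index=False)
    result.hit_table.to_csv(out / "hits.tsv", sep="\t", index=False)
    if result.calibration is not None:
        result.calibration.to_frame().to_csv(out / "calibration.tsv",
                                             sep="\t", index=False)
    qc_rows = [{"plate_id": key[0], "row": key[1], "column": key[2],
                "reason": reason} for key, reason in result.qc.excluded_wells]
    pd.DataFrame(qc_rows, columns=["plate_id", "row", "column", "reason"]) \
        .to_csv(out / "qc.tsv", sep="\t", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2)
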