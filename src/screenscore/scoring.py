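"""Control-set ROC/FDR calibration and gene-level hit calling.

The screen's decision rule is calibrated on labeled control wells:
positive-control hairpins (which silence the driver oncogene and suppress
growth) versus negative-control hairpins (targets absent from the cells).
Sweeping a relative-growth cutoff t and calling every well with growth
below t, the control-set false discovery rate at t is FP/(FP+TP) where
positives that fall below t are true positives and negatives below t are
false positives.  The chosen per-hairpin cutoff is the most permissive t
that keeps this FDR at or under the target (30% by default).

Genes are then scored by a two-sample t-test of their hairpins'
relative-growth values against the negative-control wells, with
multiple-testing q-values, and called hits when p < 1e-4, q < 0.01 and at
least 3 of the gene's hairpins fall below the calibrated cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CalibrationError, DomainError, InsufficientDataError
from .qc_normalization import RelativeGrowthRecord

#: Hit rule defaults: the screen's significance conjunction.
DEFAULT_P_CUT = 1e-4
DEFAULT_Q_CUT = 0.01
DEFAULT_MIN_SHRNAS = 3
DEFAULT_TARGET_FDR = 0.30


@dataclass
class ROCCalibration:
    """Control-set ROC sweep with its FDR curve and selected cutoff.

    ``thresholds`` ascend; a well is called at cutoff t iff its relative
    growth is strictly below t, so ``tpr`` and ``fpr`` are nondecreasing.
    ``fdr`` entries are NaN where no well is called.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    fdr: np.ndarray
    auc: float
    target_fdr: float
    chosen_threshold_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "tpr": self.tpr,
                             "fpr": self.fpr, "fdr": self.fdr})


@dataclass
class GeneScore:
    """Per-gene screen score.

    ``p_value``/``q_value`` are NaN when the gene had a single surviving
    hairpin value (flagged, never dropped).  ``significance_level`` follows
    the 5-hairpin design convention: 1 when all 5 hairpins score below the
    calibrated cutoff, 2 when 4 do, 3 when 3 do, None otherwise.
    """

    target_gene: str
    mean_relative_growth_pct: float
    t_statistic: float
    p_value: float
    q_value: float
    n_shrnas_total: int
    n_shrnas_below_cutoff: int
    significance_level: int | None
    is_hit: bool


def roc_calibration(positives, negatives,
                    target_fdr: float = DEFAULT_TARGET_FDR) -> ROCCalibration:
    """Sweep growth cutoffs over control wells and pick the FDR-bounded one.

    Parameters
    ----------
    positives, negatives
        Relative-growth percentages of positive- and negative-control
        wells.  Positives are expected low (growth-suppressed).
    target_fdr
        Maximum admissible control-set FDR, in (0, 1).

    Cutoffs are the sorted distinct observed values plus one point above
    the maximum; calls are strict ("growth < cutoff").  The chosen cutoff
    is the largest with FDR <= target and at least one true positive.
    AUC is the Mann-Whitney probability that a random positive grows less
    than a random negative, ties counted half.

    Raises :class:`CalibrationError` (carrying the curve) when no cutoff
    achieves the target.
    """
    pos = np.asarray(list(positives), dtype=float)
    neg = np.asarray(list(negatives), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("both control sets must be non-empty")
    if not 0 < target_fdr < 1:
        raise DomainError(f"target_fdr must be in (0, 1), got {target_fdr}")

    values = np.concatenate([pos, neg])
    thresholds = np.unique(values)
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)

    # searchsorted('left') counts values strictly below each cutoff.
    tp = np.searchsorted(np.sort(pos), thresholds, side="left").astype(float)
    fp = np.searchsorted(np.sort(neg), thresholds, side="left").astype(float)
    called = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(called > 0, fp / called, np.nan)
    tpr = tp / pos.size
    fpr = fp / neg.size

    # Rank (Mann-Whitney) AUC with ties counted 1/2.
    ranks = stats.rankdata(values)
    r_neg = ranks[pos.size:].sum()
    auc = (r_neg - neg.size * (neg.size + 1) / 2) / (pos.size * neg.size)

    ok = (tp >= 1) & ~np.isnan(fdr) & (fdr <= target_fdr)
    cal = ROCCalibration(thresholds=thresholds, tpr=tpr, fpr=fpr, fdr=fdr,
                         auc=float(auc), target_fdr=float(target_fdr),
                         chosen_threshold_pct=float("nan"))
    if not ok.any():
        raise CalibrationError(
            f"no cutoff achieves control-set FDR <= {target_fdr}", calibration=cal)
    cal.chosen_threshold_pct = float(thresholds[np.flatnonzero(ok)[-1]])
    return cal


def estimate_qvalues(p_values, method: str = "bh", storey_lambda: float = 0.5):
    """False-discovery-rate q-values for a family of p-values.

    ``bh`` gives Benjamini-Hochberg step-up adjusted p-values; ``storey``
    scales them by a pi0 estimate, pi0 = #{p > lambda} / (m (1 - lambda))
    clipped to (0, 1], at a fixed lambda (default 0.5).  Output order
    matches input order.  NaN entries pass through as NaN and do not
    count toward the family size.
    """
    p = np.asarray(list(p_values), dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] <= 0) | (p[finite] > 1)).any():
        raise DomainError("p-values must lie in (0, 1]")
    q = np.full_like(p, np.nan)
    if finite.sum() == 0:
        return q
    q_bh = multipletests(p[finite], method="fdr_bh")[1]
    if method == "bh":
        q[finite] = q_bh
    elif method == "storey":
        m = finite.sum()
        pi0 = (p[finite] > storey_lambda).sum() / (m * (1.0 - storey_lambda))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
        q[finite] = np.minimum(pi0 * q_bh, 1.0)
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    return q


def _significance_level(n_below: int) -> int | None:
    # 1/2/3 = all / 4 / 3 hairpins below cutoff, 5-hairpin designs.
    return {5: 1, 4: 2, 3: 3}.get(n_below)


def score_genes(records: list[RelativeGrowthRecord] | pd.DataFrame,
                control_values,
                calibration: ROCCalibration | float,
                q_method: str = "bh",
                equal_var: bool = True,
                p_cut: float = DEFAULT_P_CUT,
                q_cut: float = DEFAULT_Q_CUT,
                min_shrnas: int = DEFAULT_MIN_SHRNAS) -> list[GeneScore]:
    """Score every candidate gene against the negative-control wells.

    Each gene's per-hairpin relative-growth values are compared with the
    per-well control values by a two-sided two-sample t-test.  Student's
    pooled-variance test is the default: the hairpin sample is tiny
    (typically 5), and pooling its variance with the large control-well
    sample gives the test the degrees of freedom that make the p < 1e-4
    hit criterion attainable; Welch's unequal-variance form is available
    with ``equal_var=False``.  Hairpins below the
    calibrated cutoff are counted, q-values are attached across the gene
    family, and the hit conjunction is applied.

    A gene with a single surviving hairpin value is emitted with NaN
    p/q and ``is_hit`` False rather than silently dropped.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    if len(df):
        df = df[df["control_class"] == "candidate"] if "control_class" in df else df
    controls = np.asarray(list(control_values), dtype=float)
    if controls.size < 2:
        raise InsufficientDataError("need >= 2 control values for the t-test")
    cutoff = (calibration.chosen_threshold_pct
              if isinstance(calibration, ROCCalibration) else float(calibration))

    scores: list[GeneScore] = []
    if len(df) == 0:
        return scores
    for gene, grp in df.groupby("target_gene", sort=True):
        values = grp["relative_growth_pct"].to_numpy(dtype=float)
        n_below = int((values < cutoff).sum())
        if values.size >= 2:
            t, p = stats.ttest_ind(values, controls, equal_var=equal_var)
            t, p = float(t), float(p)
        else:
            t, p = float("nan"), float("nan")
        scores.append(GeneScore(
            target_gene=str(gene),
            mean_relative_growth_pct=float(values.mean()),
            t_statistic=t, p_value=p, q_value=float("nan"),
            n_shrnas_total=int(values.size),
            n_shrnas_below_cutoff=n_below,
            significance_level=_significance_level(n_below),
            is_hit=False))

    qs = estimate_qvalues([s.p_value for s in scores], method=q_method)
    for s, q in zip(scores, qs):
        s.q_value = float(q)
        s.is_hit = _hit_rule(s, p_cut, q_cut, min_shrnas)
    return scores


def _hit_rule(s: GeneScore, p_cut: float, q_cut: float, min_shrnas: int) -> bool:
    return (not math.isnan(s.p_value) and not math.isnan(s.q_value)
            and s.p_value < p_cut and s.q_value < q_cut
            and s.n_shrnas_below_cutoff >= min_shrnas)


def call_hits(scores: list[GeneScore],
              p_cut: float = DEFAULT_P_CUT,
              q_cut: float = DEFAULT_Q_CUT,
              min_shrnas: int = DEFAULT_MIN_SHRNAS) -> pd.DataFrame:
    """Apply the hit conjunction and return the ordered hit table.

    Hits satisfy p < ``p_cut`` and q < ``q_cut`` and at least
    ``min_shrnas`` hairpins below the calibrated cutoff; they are sorted
    by mean relative growth ascending (strongest dependency first), gene
    symbol as the deterministic tiebreak.
    """
    rows = [{**s.__dict__, "is_hit": True}
            for s in scores if _hit_rule(s, p_cut, q_cut, min_shrnas)]
    table = pd.DataFrame(rows, columns=["target_gene", "mean_relative_growth_pct",
                                        "t_statistic", "p_value", "q_value",
                                        "n_shrnas_total", "n_shrnas_below_cutoff",
                                        "significance_level", "is_hit"])
    return (table.sort_values(["mean_relative_growth_pct", "target_gene"])
                 .reset_index(drop=True))


def scores_table(scores: list[GeneScore]) -> pd.DataFrame:
    """All gene scores as a DataFrame, strongest growth reduction first."""
    df = pd.DataFrame([s.__dict__ for s in scores])
    if len(df):
        df = (df.sort_values(["mean_relative_growth_pct", "target_gene"])
                .reset_index(drop=True))
    return df
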