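"""Synthetic arrayed-screen generator.

Emulates the statistical structure the scoring pipeline assumes: ten
96-well screen plates carrying 141 candidate genes x 5 hairpins plus
per-plate negative controls (shLUC/shRFP/shLACZ, true growth 1.0),
positive controls (strong growth suppression), empty-vector and
medium-only wells; paired puromycin-selected and unselected arms with a
tunable shared-variance fraction that sets the between-arm correlation;
log-normal plate baselines and multiplicative well noise, appropriate
for luminescence-style viability readouts.

Signals follow, for well w on plate p, arm a, replicate r:

    signal = baseline_p * growth_fraction_w * exp(shared_w + eps_{w,a,r})

with log-normal baseline (sd ``plate_effect_sd``), a per-well effect
``shared_w`` common to both arms holding ``arm_shared_fraction`` of the
log noise variance, and independent per-replicate noise with overall
coefficient of variation ``noise_cv``.  Every generated dataset comes
with a truth table of per-hairpin growth fractions for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .screen_data import REQUIRED_COLUMNS, ScreenDataset

_NEGATIVE_REAGENTS = ("shLUC", "shRFP", "shLACZ")

# Fixed substream tags so adding a component never perturbs existing draws.
_STREAM_SCREEN = 0
_STREAM_CONTROL = 1
_STREAM_DOSE = 2


@dataclass(frozen=True)
class SyntheticScreenConfig:
    """Generative parameters for a desk-scale synthetic screen.

    Defaults mirror a standard arrayed screen design: ten 96-well plates,
    141 genes x 5 hairpins, 3 puromycin-selected and 2 unselected
    replicates, few active genes with strong growth suppression
    (~0.30 of control) and incomplete penetrance.
    """

    n_plates: int = 10
    wells_per_plate: int = 96
    n_genes: int = 141
    shrnas_per_gene: int = 5
    n_negative_controls_per_plate: int = 8
    n_positive_controls_per_plate: int = 4
    n_vector_only: int = 2
    n_medium_only: int = 2
    replicates_selected: int = 3
    replicates_unselected: int = 2
    active_gene_fraction: float = 0.02
    active_growth_fraction_mean: float = 0.30
    active_growth_fraction_sd: float = 0.10
    penetrance: int = 4
    positive_control_growth_fraction: float = 0.3
    noise_cv: float = 0.15
    plate_effect_sd: float = 0.10
    arm_shared_fraction: float = 0.30
    baseline_signal: float = 1e5
    n_control_plates: int = 2
    cell_line: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        controls = (self.n_negative_controls_per_plate
                    + self.n_positive_controls_per_plate
                    + self.n_vector_only + self.n_medium_only)
        if controls > self.wells_per_plate:
            raise ValueError("control wells exceed plate capacity")
        capacity = self.n_plates * (self.wells_per_plate - controls)
        needed = self.n_genes * self.shrnas_per_gene
        if needed > capacity:
            raise ValueError(
                f"layout overflow: {needed} candidate hairpins exceed the "
                f"{capacity} candidate wells available")
        if not 0 <= self.active_gene_fraction <= 1:
            raise ValueError("active_gene_fraction must lie in [0, 1]")
        if not 0 <= self.arm_shared_fraction <= 1:
            raise ValueError("arm_shared_fraction must lie in [0, 1]")
        if not 0 <= self.penetrance <= self.shrnas_per_gene:
            raise ValueError("penetrance must lie in [0, shrnas_per_gene]")
        if self.noise_cv < 0 or self.plate_effect_sd < 0:
            raise ValueError("noise_cv and plate_effect_sd must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config_seed, stream)))


def _well_positions(n: int):
    """Row-major A1, A2 ... H12 coordinates for the first n wells."""
    rows = "ABCDEFGH"
    return [(rows[i // 12], i % 12 + 1) for i in range(n)]


def _log_noise_sd(noise_cv: float) -> float:
    # CV of a log-normal exp(N(0, s)) is sqrt(exp(s^2) - 1).
    return float(np.sqrt(np.log1p(noise_cv ** 2)))


def _emit_well(rows, cfg, rng, plate_id, row, col, reagent, gene, cls,
               growth_sel, growth_unsel, baseline, sigma_shared, sigma_eps):
    shared = rng.normal(0.0, sigma_shared) if sigma_shared > 0 else 0.0
    for arm, n_rep, growth in (("selected", cfg.replicates_selected, growth_sel),
                               ("unselected", cfg.replicates_unselected, growth_unsel)):
        for rep in range(1, n_rep + 1):
            eps = rng.normal(0.0, sigma_eps) if sigma_eps > 0 else 0.0
            signal = baseline * growth * np.exp(shared + eps)
            rows.append((plate_id, row, col, reagent, gene, cls, arm, rep,
                         float(signal)))


def simulate_screen(config: SyntheticScreenConfig,
                    ) -> tuple[ScreenDataset, pd.DataFrame]:
    """Generate the candidate screen plus its per-hairpin truth table.

    Returns ``(dataset, truth)`` where ``truth`` has one row per
    candidate hairpin: reagent_id, target_gene, plate_id, growth_fraction
    (1.0 for null hairpins) and the active flag.  Same config and seed
    give a byte-identical dataset.
    """
    config.validate()
    cfg = config
    rng = _rng(cfg.seed, _STREAM_SCREEN)

    genes = [f"Gene{i + 1:03d}" for i in range(cfg.n_genes)]
    n_active = int(round(cfg.active_gene_fraction * cfg.n_genes))
    active_genes = set(rng.choice(cfg.n_genes, size=n_active, replace=False).tolist())

    # Per-hairpin true growth fractions.
    growth: dict[str, tuple[str, float, bool]] = {}
    hairpins: list[tuple[str, str]] = []
    for gi, gene in enumerate(genes):
        if gi in active_genes:
            which = set(rng.choice(cfg.shrnas_per_gene, size=cfg.penetrance,
                                   replace=False).tolist())
        else:
            which = set()
        for k in range(cfg.shrnas_per_gene):
            reagent = f"sh{gene}_{k + 1}"
            if k in which:
                gf = float(np.clip(rng.normal(cfg.active_growth_fraction_mean,
                                              cfg.active_growth_fraction_sd),
                                   0.01, 0.95))
                growth[reagent] = (gene, gf, True)
            else:
                growth[reagent] = (gene, 1.0, False)
            hairpins.append((reagent, gene))

    sigma = _log_noise_sd(cfg.noise_cv)
    sigma_shared = float(np.sqrt(cfg.arm_shared_fraction) * sigma)
    sigma_eps = float(np.sqrt(1.0 - cfg.arm_shared_fraction) * sigma)

    n_controls = (cfg.n_negative_controls_per_plate
                  + cfg.n_positive_controls_per_plate
                  + cfg.n_vector_only + cfg.n_medium_only)
    per_plate = np.array_split(np.arange(len(hairpins)), cfg.n_plates)

    rows: list = []
    truth_rows: list = []
    for p in range(cfg.n_plates):
        plate_id = f"SCREEN{p + 1:02d}"
        baseline = cfg.baseline_signal * (
            np.exp(rng.normal(0.0, cfg.plate_effect_sd))
            if cfg.plate_effect_sd > 0 else 1.0)
        idx = per_plate[p]
        positions = _well_positions(n_controls + len(idx))
        cursor = 0
        for j in range(cfg.n_negative_controls_per_plate):
            row, col = positions[cursor]; cursor += 1
            reagent = _NEGATIVE_REAGENTS[j % len(_NEGATIVE_REAGENTS)]
            _emit_well(rows, cfg, rng, plate_id, row, col, reagent, "",
                       "negative_control", 1.0, 1.0, baseline,
                       sigma_shared, sigma_eps)
        for j in range(cfg.n_positive_controls_per_plate):
            row, col = positions[cursor]; cursor += 1
            _emit_well(rows, cfg, rng, plate_id, row, col, "shKRAS", "",
                       "positive_control",
                       cfg.positive_control_growth_fraction,
                       cfg.positive_control_growth_fraction, baseline,
                       sigma_shared, sigma_eps)
        for _ in range(cfg.n_vector_only):
            row, col = positions[cursor]; cursor += 1
            # Empty vector confers puromycin resistance: full growth.
            _emit_well(rows, cfg, rng, plate_id, row, col, "PGW", "",
                       "vector_only", 1.0, 1.0, baseline,
                       sigma_shared, sigma_eps)
        for _ in range(cfg.n_medium_only):
            row, col = positions[cursor]; cursor += 1
            # No virus: puromycin kills (selected arm), full growth unselected.
            _emit_well(rows, cfg, rng, plate_id, row, col, "", "",
                       "medium_only", 0.02, 1.0, baseline,
                       sigma_shared, sigma_eps)
        for i in idx:
            reagent, gene = hairpins[i]
            row, col = positions[cursor]; cursor += 1
            _, gf, active = growth[reagent]
            _emit_well(rows, cfg, rng, plate_id, row, col, reagent, gene,
                       "candidate", gf, gf, baseline, sigma_shared, sigma_eps)
            truth_rows.append((reagent, gene, plate_id, gf, active))

    wells = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    truth = pd.DataFrame(truth_rows, columns=["reagent_id", "target_gene",
                                              "plate_id", "growth_fraction",
                                              "active"])
    return ScreenDataset(wells, cell_line=cfg.cell_line), truth


def simulate_control_plate(config: SyntheticScreenConfig) -> ScreenDataset:
    """Generate the external calibration plates (positives vs negatives).

    Each of ``n_control_plates`` plates carries only shGFP positive
    controls and shLUC/shRFP/shLACZ negative controls (split evenly over
    the non-vector, non-medium wells) under the same generative model as
    the screen plates.
    """
    config.validate()
    cfg = config
    rng = _rng(cfg.seed, _STREAM_CONTROL)
    sigma = _log_noise_sd(cfg.noise_cv)
    sigma_shared = float(np.sqrt(cfg.arm_shared_fraction) * sigma)
    sigma_eps = float(np.sqrt(1.0 - cfg.arm_shared_fraction) * sigma)

    n_assay = cfg.wells_per_plate - cfg.n_vector_only - cfg.n_medium_only
    n_pos = n_assay // 2
    n_neg = n_assay - n_pos

    rows: list = []
    for p in range(cfg.n_control_plates):
        plate_id = f"CTRL{p + 1:02d}"
        baseline = cfg.baseline_signal * (
            np.exp(rng.normal(0.0, cfg.plate_effect_sd))
            if cfg.plate_effect_sd > 0 else 1.0)
        positions = _well_positions(cfg.wells_per_plate)
        cursor = 0
        for j in range(n_neg):
            row, col = positions[cursor]; cursor += 1
            reagent = _NEGATIVE_REAGENTS[j % len(_NEGATIVE_REAGENTS)]
            _emit_well(rows, cfg, rng, plate_id, row, col, reagent, "",
                       "negative_control", 1.0, 1.0, baseline,
                       sigma_shared, sigma_eps)
        for _ in range(n_pos):
            row, col = positions[cursor]; cursor += 1
            _emit_well(rows, cfg, rng, plate_id, row, col, "shGFP", "",
                       "positive_control",
                       cfg.positive_control_growth_fraction,
                       cfg.positive_control_growth_fraction, baseline,
                       sigma_shared, sigma_eps)
        for _ in range(cfg.n_vector_only):
            row, col = positions[cursor]; cursor += 1
            _emit_well(rows, cfg, rng, plate_id, row, col, "PGW", "",
                       "vector_only", 1.0, 1.0, baseline,
                       sigma_shared, sigma_eps)
        for _ in range(cfg.n_medium_only):
            row, col = positions[cursor]; cursor += 1
            _emit_well(rows, cfg, rng, plate_id, row, col, "", "",
                       "medium_only", 0.02, 1.0, baseline,
                       sigma_shared, sigma_eps)

    wells = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    return ScreenDataset(wells, cell_line=cfg.cell_line)


def simulate_dose_response(bottom: float, top: float, ec50: float, hill: float,
                           doses, noise_cv: float = 0.0,
                           n_replicates: int = 1, seed: int = 0) -> pd.DataFrame:
    """Responses on a known 4PL curve with multiplicative log-normal noise.

    Returns a tidy table (dose, replicate, response), deterministic per
    seed; with ``noise_cv`` 0 the responses lie exactly on the curve.
    """
    from .downstream import four_param_logistic  # local: avoid cycle at import

    d = np.asarray(list(doses), dtype=float)
    if (d <= 0).any():
        raise ValueError("doses must be strictly positive")
    rng = _rng(seed, _STREAM_DOSE)
    sigma = _log_noise_sd(noise_cv)
    rows = []
    for rep in range(1, n_replicates + 1):
        mu = four_param_logistic(d, bottom, top, ec50, hill)
        noise = np.exp(rng.normal(0.0, sigma, size=d.size)) if sigma > 0 else 1.0
        resp = mu * noise
        for dose, r in zip(d, np.atleast_1d(resp)):
            rows.append((float(dose), rep, float(r)))
    return pd.DataFrame(rows, columns=["dose", "replicate", "response"])
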