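"""Synthetic screens, dose panels, expression matrices and gene universes
with known ground truth.

Every downstream stage of the pipeline is testable against these generators
without external data. Defaults emulate the screen's stated conditions: 96-well
plates with >= 8 wells of each control class plus a 48+48 control plate per
batch, negative controls at a sub-maximal differentiation level (~30% of
maximal) and positive controls near-maximal (~95%), a negative linear
confound between log live-cell count and percent-positive present only in the
sub-maximal regulatory-lineage condition, 8-dose titrations spanning a
1000-fold concentration range, and planted concordant signature genes at a
target signal-to-noise ratio.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    Assay,
    ExpressionMatrix,
    GeneSet,
    PlateGrid,
    ScreenBatch,
    ValidationError,
    Well,
    WellRole,
)
from .doseresponse import ImpulseParams, impulse_response

__all__ = [
    "ScreenParams",
    "ScreenTruth",
    "generate_screen",
    "DoseTruth",
    "random_dose_truths",
    "generate_dose_panel",
    "ExpressionTruth",
    "generate_expression",
    "generate_universe",
]

ROWS = "ABCDEFGH"


# ---------------------------------------------------------------------------
# primary screen


@dataclass(frozen=True)
class ScreenParams:
    """Generating conditions for a synthetic primary screen.

    Levels are percent lineage-positive cells. The cellularity confound
    (``pct = intercept + slope * ln(live_cells)``) applies to negative-control
    and compound wells of the sub-maximal regulatory condition only.
    """

    neg_level: float = 30.0  # sub-maximal control level (% positive)
    pos_level: float = 95.0  # near-maximal control level (% positive)
    noise_sd: float = 3.0  # percent-scale Gaussian noise, truncated to [0,100]
    cellularity_slope: float = -8.0  # percent per log(live cells), TREG_LOW only
    median_live_cells: float = 5e4
    live_cells_sigma_log: float = 0.4  # lognormal shape of well cellularity
    plate_effect_sd: float = 2.0  # additive per-plate offset (percent)
    plates_per_batch: int = 10
    frac_toxic: float = 0.02  # purely cytotoxic non-enhancers
    toxic_multiplier_range: tuple[float, float] = (0.02, 0.10)  # viability fraction
    enhancer_effect_range: tuple[float, float] = (0.3, 1.0)  # true Fr enhance
    qc_fail_frac_controls: float = 0.3125  # 5 of 16 controls displaced on QC-fail plates

    @property
    def cellularity_intercept(self) -> float:
        """Intercept placing the expected sub-maximal level at the median
        cellularity: ``neg_level - slope * ln(median_live_cells)``."""
        return self.neg_level - self.cellularity_slope * math.log(self.median_live_cells)


@dataclass
class ScreenTruth:
    """Ground truth of a generated screen."""

    enhancer_compounds: dict[str, float]  # compound -> true fractional enhancement
    toxic_compounds: dict[str, float]  # compound -> true viability multiplier
    qc_fail_plates: set[str]
    cellularity_slope: float
    cellularity_intercept: float
    noise_sd: float
    neg_level: float
    pos_level: float

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


def generate_screen(
    n_compounds: int,
    frac_enhancers: float = 0.02,
    params: ScreenParams | None = None,
    seed: int = 0,
    n_qc_fail_plates: int = 0,
    assay: Assay = Assay.TREG_LOW,
) -> tuple[list[ScreenBatch], ScreenTruth]:
    """Generate a one-well-per-compound primary screen with known truth.

    Each 96-well plate carries 8 positive controls (column 1), 8 negative
    controls (column 12) and up to 80 compound wells. QC-fail plates have a
    >25% subset of their controls displaced far out of range.
    """
    if n_compounds < 1:
        raise ValidationError("n_compounds must be >= 1")
    if not 0.0 <= frac_enhancers <= 1.0:
        raise ValidationError("frac_enhancers must be within [0, 1]")
    p = params or ScreenParams()
    if assay is Assay.TREG_LOW and p.cellularity_slope >= 0:
        raise ValidationError("cellularity_slope must be negative for TREG_LOW truth")
    rng = np.random.default_rng(seed)

    compounds = [f"CPD{i:05d}" for i in range(n_compounds)]
    n_enh = int(round(frac_enhancers * n_compounds))
    n_tox = int(round(p.frac_toxic * n_compounds))
    special = rng.choice(n_compounds, size=min(n_enh + n_tox, n_compounds), replace=False)
    enh_idx, tox_idx = special[:n_enh], special[n_enh : n_enh + n_tox]
    enhancers = {
        compounds[i]: float(rng.uniform(*p.enhancer_effect_range)) for i in enh_idx
    }
    toxics = {
        compounds[i]: float(rng.uniform(*p.toxic_multiplier_range)) for i in tox_idx
    }

    slope = p.cellularity_slope if assay is Assay.TREG_LOW else 0.0
    intercept = (
        p.cellularity_intercept if assay is Assay.TREG_LOW else p.neg_level
    )
    span = p.pos_level - p.neg_level

    n_per_plate = 80
    n_plates = math.ceil(n_compounds / n_per_plate)
    plate_ids = [f"P{i:04d}" for i in range(n_plates)]
    qc_fail = {
        str(p)
        for p in rng.choice(plate_ids, size=min(n_qc_fail_plates, n_plates), replace=False)
    }

    def draw_cells(n: int, multiplier: np.ndarray | float = 1.0) -> np.ndarray:
        base = p.median_live_cells * np.exp(
            rng.normal(0.0, p.live_cells_sigma_log, size=n)
        )
        return np.maximum(base * multiplier, 1.0)

    def well_pct(cells: np.ndarray, effect: np.ndarray, offset: float) -> np.ndarray:
        mu = intercept + slope * np.log(cells) + effect + offset
        return np.clip(mu + rng.normal(0.0, p.noise_sd, size=len(cells)), 0.0, 100.0)

    batches: list[ScreenBatch] = []
    plate_iter = iter(plate_ids)
    ci = 0  # compound cursor
    batch_no = 0
    remaining_plates = n_plates
    while remaining_plates > 0:
        batch_id = f"B{batch_no:03d}"
        n_here = min(p.plates_per_batch, remaining_plates)
        plates: list[PlateGrid] = []
        for _ in range(n_here):
            plate_id = next(plate_iter)
            offset = float(rng.normal(0.0, p.plate_effect_sd))
            wells: list[Well] = []

            # positive controls, column 1 (near-maximal condition: no confound)
            pos_cells = draw_cells(8)
            pos_pct = np.clip(
                p.pos_level + offset + rng.normal(0.0, p.noise_sd, 8), 0.0, 100.0
            )
            for r, c_, v in zip(ROWS, pos_cells, pos_pct):
                wells.append(
                    Well(plate_id, r, 1, WellRole.POS_CTRL, float(v), float(c_))
                )

            # negative controls, column 12
            neg_cells = draw_cells(8)
            neg_pct = well_pct(neg_cells, np.zeros(8), offset)
            for r, c_, v in zip(ROWS, neg_cells, neg_pct):
                wells.append(
                    Well(plate_id, r, 12, WellRole.NEG_CTRL, float(v), float(c_))
                )

            # compound wells, columns 2-11
            plate_compounds = compounds[ci : ci + n_per_plate]
            mult = np.array([toxics.get(c, 1.0) for c in plate_compounds])
            effect = np.array([enhancers.get(c, 0.0) for c in plate_compounds]) * span
            cells = draw_cells(len(plate_compounds), mult)
            pct = well_pct(cells, effect, offset)
            k = 0
            for col in range(2, 12):
                for r in ROWS:
                    if k >= len(plate_compounds):
                        break
                    wells.append(
                        Well(
                            plate_id,
                            r,
                            col,
                            WellRole.COMPOUND,
                            float(pct[k]),
                            float(cells[k]),
                            compound_id=plate_compounds[k],
                        )
                    )
                    k += 1
            ci += len(plate_compounds)

            if plate_id in qc_fail:
                wells = _displace_controls(wells, p, rng)
            plates.append(PlateGrid(plate_id, batch_id, assay, wells))

        batches.append(
            ScreenBatch(batch_id, plates, _control_plate(batch_id, assay, p, rng))
        )
        remaining_plates -= n_here
        batch_no += 1

    truth = ScreenTruth(
        enhancer_compounds=enhancers,
        toxic_compounds=toxics,
        qc_fail_plates=qc_fail,
        cellularity_slope=slope if assay is Assay.TREG_LOW else 0.0,
        cellularity_intercept=intercept,
        noise_sd=p.noise_sd,
        neg_level=p.neg_level,
        pos_level=p.pos_level,
    )
    return batches, truth


def _displace_controls(
    wells: list[Well], p: ScreenParams, rng: np.random.Generator
) -> list[Well]:
    """Displace a >=25% subset of a plate's controls far beyond the expected
    range (positives pushed down, negatives up, by ~12 noise SD)."""
    ctrl_idx = [
        i
        for i, w in enumerate(wells)
        if w.role in (WellRole.POS_CTRL, WellRole.NEG_CTRL)
    ]
    n_displace = max(int(math.ceil(p.qc_fail_frac_controls * len(ctrl_idx))), 1)
    chosen = rng.choice(ctrl_idx, size=n_displace, replace=False)
    shift = 12.0 * p.noise_sd
    out = list(wells)
    for i in chosen:
        w = out[i]
        new = w.pct_positive - shift if w.role is WellRole.POS_CTRL else w.pct_positive + shift
        out[i] = Well(
            w.plate_id, w.row, w.col, w.role,
            float(np.clip(new, 0.0, 100.0)), w.live_cells, w.compound_id, w.dose_uM,
        )
    return out


def _control_plate(
    batch_id: str, assay: Assay, p: ScreenParams, rng: np.random.Generator
) -> PlateGrid:
    """48 positive + 48 negative control wells (columns 1-6 / 7-12)."""
    plate_id = f"{batch_id}_CTRL"
    slope = p.cellularity_slope if assay is Assay.TREG_LOW else 0.0
    intercept = p.cellularity_intercept if assay is Assay.TREG_LOW else p.neg_level
    offset = float(rng.normal(0.0, p.plate_effect_sd))
    wells: list[Well] = []
    for col in range(1, 13):
        role = WellRole.POS_CTRL if col <= 6 else WellRole.NEG_CTRL
        for r in ROWS:
            cells = float(
                max(p.median_live_cells * math.exp(rng.normal(0, p.live_cells_sigma_log)), 1.0)
            )
            if role is WellRole.POS_CTRL:
                mu = p.pos_level + offset
            else:
                mu = intercept + slope * math.log(cells) + offset
            pct = float(np.clip(mu + rng.normal(0.0, p.noise_sd), 0.0, 100.0))
            wells.append(Well(plate_id, r, col, role, pct, cells))
    return PlateGrid(plate_id, batch_id, assay, wells)


# ---------------------------------------------------------------------------
# dose-response panels


@dataclass
class DoseTruth:
    """True impulse parameters per compound for the enhancement response and
    for viability, plus the shared 8-dose grid."""

    doses_uM: np.ndarray
    response: dict[str, ImpulseParams] = field(default_factory=dict)
    viability: dict[str, ImpulseParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses_uM = np.asarray(self.doses_uM, dtype=float)
        if len(self.doses_uM) != 8:
            raise ValidationError("dose grid must hold exactly 8 doses")
        if self.doses_uM.max() / self.doses_uM.min() < 1000.0:
            raise ValidationError("dose grid must span >= 1000-fold")


def random_dose_truths(
    n_compounds: int,
    seed: int = 0,
    doses_uM: np.ndarray | None = None,
) -> DoseTruth:
    """Draw plausible rise-then-fall enhancement truths and declining
    viability truths for ``n_compounds`` compounds."""
    rng = np.random.default_rng(seed)
    doses = np.geomspace(0.01, 10.0, 8) if doses_uM is None else np.asarray(doses_uM)
    lo, hi = math.log10(doses.min()), math.log10(doses.max())
    truth = DoseTruth(doses_uM=doses)
    for i in range(n_compounds):
        cid = f"CPD{i:05d}"
        d1 = rng.uniform(lo + 0.4, hi - 1.2)
        truth.response[cid] = ImpulseParams(
            d1=d1,
            d2=d1 + rng.uniform(0.8, 2.2),
            rl=rng.uniform(0.0, 0.05),
            rp=rng.uniform(0.5, 1.2),
            rh=rng.uniform(0.0, 0.4),
            alpha1=rng.uniform(0.6, 2.0),
            alpha2=rng.uniform(0.6, 2.0),
        )
        d_tox = rng.uniform(lo + 1.0, hi + 0.5)
        truth.viability[cid] = ImpulseParams(
            d1=lo - 2.0,  # no rise: viability starts at its peak of 1
            d2=d_tox,
            rl=1.0,
            rp=1.0,
            rh=rng.uniform(0.0, 0.3),
            alpha1=1.0,
            alpha2=rng.uniform(0.6, 2.0),
        )
    return truth


def generate_dose_panel(
    truth: DoseTruth,
    replicates: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Measured 8-dose titrations: impulse-model evaluations plus Gaussian
    noise, clipped to the valid measurement range.

    Returns a tidy table with columns compound_id, dose_uM, replicate,
    fr_enhance, viability.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    log_d = np.log10(truth.doses_uM)
    rows = []
    for cid in sorted(truth.response):
        r_true = impulse_response(log_d, truth.response[cid])
        v_true = impulse_response(log_d, truth.viability[cid])
        for rep in range(replicates):
            r = r_true + rng.normal(0.0, noise_sd, size=len(log_d))
            v = v_true + rng.normal(0.0, noise_sd, size=len(log_d))
            for dose, ri_, vi_ in zip(truth.doses_uM, r, v):
                rows.append(
                    {
                        "compound_id": cid,
                        "dose_uM": float(dose),
                        "replicate": rep,
                        "fr_enhance": float(np.clip(ri_, -1.0, 2.0)),
                        "viability": float(np.clip(vi_, 0.0, 1.5)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression matrices and gene universes


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted signature genes and their concordant direction (+1 up in group
    A, -1 down) shared across the paired experiments."""

    planted: GeneSet
    direction: dict[str, int]
    snr_target: float
    within_group_sd: float


def generate_expression(
    n_genes: int = 20000,
    n_per_group: int = 5,
    n_signature: int = 111,
    snr_target: float = 2.0,
    seed: int = 0,
    within_group_sd: float = 0.5,
    experiment_names: tuple[str, str] = ("mouse", "human"),
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionTruth]:
    """Two paired two-group expression experiments with concordantly planted
    signature genes.

    Planted genes receive a group-A mean shift of ``snr_target * 2 * sd`` with
    a shared random sign, so the population signal-to-noise ratio
    ``(mu_A - mu_B) / (sd_A + sd_B)`` equals ``snr_target`` in both
    experiments; all other genes share a common null.
    """
    if snr_target <= 0:
        raise ValidationError("snr_target must be > 0")
    if n_signature > n_genes:
        raise ValidationError("n_signature must be <= n_genes")
    if n_per_group < 2:
        raise ValidationError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    planted_idx = rng.choice(n_genes, size=n_signature, replace=False)
    signs = rng.choice([-1, 1], size=n_signature)
    shift = snr_target * 2.0 * within_group_sd

    def one_experiment(name: str) -> ExpressionMatrix:
        base = rng.normal(7.0, 1.0, size=n_genes)
        vals = np.empty((n_genes, 2 * n_per_group))
        vals[:, :n_per_group] = base[:, None] + rng.normal(
            0.0, within_group_sd, size=(n_genes, n_per_group)
        )
        vals[:, n_per_group:] = base[:, None] + rng.normal(
            0.0, within_group_sd, size=(n_genes, n_per_group)
        )
        vals[planted_idx, :n_per_group] += (signs * shift)[:, None]
        samples = [f"{name}_A{i}" for i in range(n_per_group)] + [
            f"{name}_B{i}" for i in range(n_per_group)
        ]
        groups = {s: ("A" if "_A" in s else "B") for s in samples}
        return ExpressionMatrix(genes, samples, vals, groups)

    expr_a = one_experiment(experiment_names[0])
    expr_b = one_experiment(experiment_names[1])
    truth = ExpressionTruth(
        planted=GeneSet.from_genes("planted_signature", [genes[i] for i in planted_idx]),
        direction={genes[i]: int(s) for i, s in zip(planted_idx, signs)},
        snr_target=snr_target,
        within_group_sd=within_group_sd,
    )
    return expr_a, expr_b, truth


def generate_universe(
    n_universe: int,
    disease_set_size: int,
    signature_set: GeneSet,
    n_overlap: int,
    seed: int = 0,
) -> tuple[list[str], GeneSet]:
    """A gene universe embedding ``signature_set`` and a disease gene set that
    overlaps it in exactly ``n_overlap`` genes."""
    if disease_set_size > n_universe:
        raise ValidationError("disease_set_size must be <= n_universe")
    if n_overlap > min(disease_set_size, len(signature_set)):
        raise ValidationError("planted overlap exceeds a set size")
    if len(signature_set) > n_universe:
        raise ValidationError("signature set larger than universe")
    rng = np.random.default_rng(seed)
    sig_genes = sorted(signature_set.gene_ids)
    n_fill = n_universe - len(sig_genes)
    universe = sig_genes + [f"U{i:06d}" for i in range(n_fill)]
    rng.shuffle(universe)

    in_sig = rng.choice(len(sig_genes), size=n_overlap, replace=False)
    non_sig = [g for g in universe if g not in signature_set]
    out_sig = rng.choice(len(non_sig), size=disease_set_size - n_overlap, replace=False)
    disease = GeneSet.from_genes(
        "disease",
        [sig_genes[i] for i in in_sig] + [non_sig[i] for i in out_sig],
    )
    return universe, disease
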