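"""Primary-screen normalization and hit selection.

The pipeline per experimental batch:

1. median-center every plate on all wells except positive controls;
2. pool centered controls batch-wide (including the dedicated 48+48 control
   plate) to estimate per-class medians and robust standard deviations
   (1.4826 x median absolute deviation);
3. QC each plate — a plate fails when <= 75% of its controls fall within
   +-3 batch robust SD of their class median, or when the separation between
   positive and negative control medians is below 3 pooled robust SD;
4. on the sub-maximal regulatory-lineage condition, regress centered
   percent-positive on log live-cell count (the cellularity confound) and
   re-center residuals at the negative-control median cellularity;
5. pool centered negative-control and compound wells, trim to a negative
   reference within +-2 robust SD of the pooled median, and transform wells
   to robust Z-scores about the reference mean;
6. calibrate Z-scores to fraction-of-positive-control activity with a
   Gaussian/identity GLM fitted to the control classes;
7. call hits at >= 30% of positive-control activity (the fractional
   enhancement of artemisinin, the weakest validated enhancer).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import PlateGrid, ScreenBatch, WellRole

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessingError",
    "CalibrationError",
    "HitCallConfig",
    "median_center_plate",
    "robust_sd",
    "BatchControlStats",
    "PlateQCReport",
    "qc_plate",
    "select_negative_reference",
    "zscore_wells",
    "Calibration",
    "calibrate_to_positive",
    "CellularityFit",
    "correct_cellularity",
    "fractional_enhancement",
    "fractional_inhibition",
    "call_hits",
    "ScreenModel",
    "ScreenResults",
]

MAD_CONSTANT = 1.4826  # consistency factor: robust SD = 1.4826 x MAD for a Gaussian


class ProcessingError(RuntimeError):
    """A pipeline stage cannot proceed on the given data."""


class CalibrationError(ProcessingError):
    """Control calibration failed (e.g. inverted controls)."""


@dataclass(frozen=True)
class HitCallConfig:
    """Tunable thresholds of the hit-calling stage."""

    hit_threshold: float = 0.3  # fraction of positive-control activity
    qc_in_range_k: float = 3.0  # controls within +-k batch robust SD of class median
    qc_min_in_range: float = 0.75  # plates with <= this fraction in range fail
    qc_dynamic_range_floor: float = 3.0  # (pos - neg median) >= floor x pooled robust SD
    reference_k: float = 2.0  # negative-reference trim, robust SD units
    correct_cellularity: bool = True
    exclude_toxic: bool = True
    toxic_floor_frac: float = 0.1  # live cells below this fraction of neg median

    def __post_init__(self) -> None:
        if not 0 < self.hit_threshold <= 1.0:
            raise ValueError("hit_threshold must be in (0, 1]")
        if not 0 < self.qc_min_in_range < 1.0:
            raise ValueError("qc_min_in_range must be in (0, 1)")


# ---------------------------------------------------------------------------
# elementary operations


def median_center_plate(plate: PlateGrid | pd.DataFrame) -> np.ndarray:
    """Centered values: each well's percent-positive minus the median over all
    wells of the plate except positive controls."""
    df = plate.to_frame() if isinstance(plate, PlateGrid) else plate
    non_pos = df.loc[df["role"] != WellRole.POS_CTRL.value, "pct_positive"]
    if non_pos.empty:
        raise ProcessingError(
            f"plate {df['plate_id'].iloc[0]}: no non-positive-control wells to center on"
        )
    return (df["pct_positive"] - float(non_pos.median())).to_numpy()


def robust_sd(values) -> float:
    """Robust scale estimate: 1.4826 x median absolute deviation about the median."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ProcessingError("robust_sd needs >= 2 values")
    return MAD_CONSTANT * float(np.median(np.abs(v - np.median(v))))


@dataclass(frozen=True)
class BatchControlStats:
    """Batch-pooled control statistics on the centered scale."""

    neg_median: float
    neg_rsd: float
    pos_median: float
    pos_rsd: float
    pooled_rsd: float  # robust SD of control deviations about class medians


def batch_control_stats(centered: np.ndarray, roles: np.ndarray) -> BatchControlStats:
    neg = centered[roles == WellRole.NEG_CTRL.value]
    pos = centered[roles == WellRole.POS_CTRL.value]
    if neg.size < 2 or pos.size < 2:
        raise ProcessingError("batch needs >= 2 wells of each control class")
    neg_med, pos_med = float(np.median(neg)), float(np.median(pos))
    deviations = np.concatenate([neg - neg_med, pos - pos_med])
    return BatchControlStats(
        neg_median=neg_med,
        neg_rsd=robust_sd(neg),
        pos_median=pos_med,
        pos_rsd=robust_sd(pos),
        pooled_rsd=robust_sd(deviations),
    )


@dataclass(frozen=True)
class PlateQCReport:
    plate_id: str
    n_controls: int
    n_in_range: int
    pct_in_range: float  # percent
    dynamic_range_ok: bool
    passed: bool


def qc_plate(
    plate_centered: pd.DataFrame,
    batch_stats: BatchControlStats,
    in_range_k: float = 3.0,
    min_in_range: float = 0.75,
    dynamic_range_floor: float = 3.0,
) -> PlateQCReport:
    """Plate QC against batch control statistics.

    ``plate_centered`` needs columns plate_id, role, centered. A plate passes
    only if strictly more than ``min_in_range`` of its controls lie within
    ``in_range_k`` batch robust SD of their class median AND the separation of
    the plate's control medians reaches the dynamic-range floor.
    """
    plate_id = str(plate_centered["plate_id"].iloc[0])
    is_neg = plate_centered["role"] == WellRole.NEG_CTRL.value
    is_pos = plate_centered["role"] == WellRole.POS_CTRL.value
    ctrl = plate_centered[is_neg | is_pos]
    if ctrl.empty:
        raise ProcessingError(f"plate {plate_id}: no control wells")
    med = np.where(
        ctrl["role"] == WellRole.NEG_CTRL.value,
        batch_stats.neg_median,
        batch_stats.pos_median,
    )
    rsd = np.where(
        ctrl["role"] == WellRole.NEG_CTRL.value,
        batch_stats.neg_rsd,
        batch_stats.pos_rsd,
    )
    in_range = np.abs(ctrl["centered"].to_numpy() - med) <= in_range_k * rsd
    n_ctrl, n_in = len(ctrl), int(in_range.sum())
    pct_in = 100.0 * n_in / n_ctrl

    separation = float(
        plate_centered.loc[is_pos, "centered"].median()
        - plate_centered.loc[is_neg, "centered"].median()
    )
    dyn_ok = separation >= dynamic_range_floor * batch_stats.pooled_rsd
    passed = (pct_in > 100.0 * min_in_range) and dyn_ok
    return PlateQCReport(plate_id, n_ctrl, n_in, pct_in, bool(dyn_ok), bool(passed))


def select_negative_reference(centered, k: float = 2.0) -> np.ndarray:
    """Boolean mask of the negative-reference wells: those within ``k`` robust
    SD of the pooled median of negative-control plus compound wells."""
    v = np.asarray(centered, dtype=float)
    rsd = robust_sd(v)
    med = float(np.median(v))
    if rsd == 0:
        return np.ones_like(v, dtype=bool)
    return np.abs(v - med) <= k * rsd


def zscore_wells(values, reference_mean: float, scale: float) -> np.ndarray:
    """Robust Z-scores ``(value - reference_mean) / scale``."""
    if scale <= 0:
        raise ProcessingError("robust SD must be > 0 for Z-scoring")
    return (np.asarray(values, dtype=float) - reference_mean) / scale


@dataclass(frozen=True)
class Calibration:
    """Linear mapping from Z-scores to fraction of positive-control activity,
    from a Gaussian/identity GLM fitted to the two control classes."""

    z_neg: float
    z_pos: float

    def frac_of_pos(self, z) -> np.ndarray:
        return (np.asarray(z, dtype=float) - self.z_neg) / (self.z_pos - self.z_neg)


def calibrate_to_positive(z_controls, is_positive) -> Calibration:
    """Fit ``z ~ control class`` (Gaussian family, identity link) and return
    the fitted control levels. Raises :class:`CalibrationError` when the
    fitted positive level does not exceed the negative level."""
    z = np.asarray(z_controls, dtype=float)
    ind = np.asarray(is_positive, dtype=float)
    if ind.min() == ind.max():
        raise CalibrationError("both control classes are required for calibration")
    X = sm.add_constant(ind)
    res = sm.GLM(z, X, family=sm.families.Gaussian()).fit()
    z_neg = float(res.params[0])
    z_pos = float(res.params[0] + res.params[1])
    if z_pos <= z_neg:
        raise CalibrationError(
            f"inverted controls: fitted positive level {z_pos:.3g} <= "
            f"negative level {z_neg:.3g}"
        )
    return Calibration(z_neg=z_neg, z_pos=z_pos)


@dataclass(frozen=True)
class CellularityFit:
    """Linear fit of centered percent-positive on log live-cell count."""

    slope: float
    intercept: float
    r_squared: float  # 1 - SS_res/SS_tot of the fitted line
    slope_conf_int: tuple[float, float]  # 95% CI
    n_wells: int
    reference_log_cells: float  # negative-control median, correction anchor
    skipped: bool = False


def correct_cellularity(
    centered,
    live_cells,
    roles,
    plate_ids=None,
    robust: bool = True,
    min_wells: int = 10,
) -> tuple[np.ndarray, CellularityFit]:
    """Remove the cellularity confound from sub-maximal-condition wells.

    Regresses centered percent-positive on log live-cell count over negative
    control and compound wells, then replaces each such well's value by its
    residual plus the fitted value at the negative-control median log
    cellularity. Positive-control wells pass through unchanged.

    When ``plate_ids`` is given, log cellularity is centered on the plate
    median (over the same fit wells) so the covariate is normalized the same
    way the response was; leaving the covariate raw lets the plate-median
    operation leak into the regression and attenuates the slope. By default
    the line is fitted robustly (Huber M-estimation) so wells carrying real
    compound effects do not distort the confound model; ``robust=False``
    falls back to ordinary least squares.
    """
    centered = np.asarray(centered, dtype=float)
    cells = np.asarray(live_cells, dtype=float)
    roles = np.asarray(roles)
    fitmask = (
        np.isin(roles, [WellRole.NEG_CTRL.value, WellRole.COMPOUND.value]) & (cells > 0)
    )
    if fitmask.sum() < min_wells:
        raise ProcessingError(
            f"cellularity correction needs >= {min_wells} wells with live cells, "
            f"got {int(fitmask.sum())}"
        )
    log_cells = np.full(len(cells), np.nan)
    log_cells[cells > 0] = np.log(cells[cells > 0])
    if plate_ids is not None:
        plate_ids = np.asarray(plate_ids)
        x = log_cells.copy()
        for pid in np.unique(plate_ids[fitmask]):
            sel = plate_ids == pid
            x[sel] = log_cells[sel] - np.nanmedian(log_cells[sel & fitmask])
    else:
        x = log_cells

    neg_mask = (roles == WellRole.NEG_CTRL.value) & (cells > 0)
    ref_x = float(np.median(x[neg_mask])) if neg_mask.any() else float(
        np.median(x[fitmask])
    )
    if np.ptp(x[fitmask]) == 0:
        logger.warning("cellularity correction skipped: zero variance in log live cells")
        fit = CellularityFit(0.0, float(np.mean(centered[fitmask])), 0.0, (0.0, 0.0),
                             int(fitmask.sum()), ref_x, skipped=True)
        return centered.copy(), fit

    X = sm.add_constant(x[fitmask])
    y = centered[fitmask]
    if robust:
        res = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
    else:
        res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    resid = y - res.fittedvalues
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    fit = CellularityFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0,
        slope_conf_int=(float(ci[1][0]), float(ci[1][1])),
        n_wells=int(fitmask.sum()),
        reference_log_cells=ref_x,
    )
    corrected = centered.copy()
    fitted_at_ref = fit.intercept + fit.slope * ref_x
    corrected[fitmask] = (y - res.fittedvalues) + fitted_at_ref
    return corrected, fit


def fractional_enhancement(x_pct: float, neg_pct: float, pos_pct: float):
    """Compound effect normalized to the positive-negative control span:
    ``(x - neg) / (pos - neg)``. May exceed 1 or be negative."""
    if pos_pct <= neg_pct:
        raise ProcessingError(
            f"positive control level ({pos_pct}) must exceed negative ({neg_pct})"
        )
    return (np.asarray(x_pct, dtype=float) - neg_pct) / (pos_pct - neg_pct)


def fractional_inhibition(x_pct: float, dmso_pct: float):
    """Differentiation decrease relative to DMSO-treated wells:
    ``(dmso - x) / dmso``."""
    if dmso_pct <= 0:
        raise ProcessingError("DMSO reference percent must be > 0")
    return (dmso_pct - np.asarray(x_pct, dtype=float)) / dmso_pct


def call_hits(hit_table: pd.DataFrame, threshold: float = 0.3,
              column: str = "corrected_frac_of_pos") -> pd.DataFrame:
    """Flag hits at ``value >= threshold`` (ties at the threshold are hits);
    excluded compounds are never hits."""
    out = hit_table.copy()
    excluded = out["excluded"] if "excluded" in out else False
    out["is_hit"] = (out[column] >= threshold) & ~excluded
    return out


# ---------------------------------------------------------------------------
# model / results


class ScreenModel:
    """Hit-calling model over one or more screen batches.

    ``fit()`` runs the full normalization/QC/calibration pipeline and returns
    a :class:`ScreenResults`.
    """

    def __init__(
        self, batches: list[ScreenBatch] | ScreenBatch, config: HitCallConfig | None = None
    ) -> None:
        self.batches = [batches] if isinstance(batches, ScreenBatch) else list(batches)
        if not self.batches:
            raise ValueError("at least one batch is required")
        self.config = config or HitCallConfig()

    def fit(self) -> "ScreenResults":
        cfg = self.config
        well_frames: list[pd.DataFrame] = []
        qc_rows: list[PlateQCReport] = []
        cellularity_fits: dict[str, CellularityFit] = {}
        calibrations: dict[str, Calibration] = {}

        for batch in self.batches:
            df = batch.to_frame(include_control_plate=True).copy()
            df["is_control_plate"] = df["plate_id"] == batch.control_plate.plate_id

            # 1. plate median centering
            df["centered"] = np.nan
            for _, idx in df.groupby("plate_id").groups.items():
                df.loc[idx, "centered"] = median_center_plate(df.loc[idx])

            # 2. batch control statistics
            stats = batch_control_stats(
                df["centered"].to_numpy(), df["role"].to_numpy()
            )

            # 3. plate QC (experimental plates only; control plate sets the pool)
            failed_plates: set[str] = set()
            for plate_id, pdf in df[~df["is_control_plate"]].groupby("plate_id"):
                report = qc_plate(
                    pdf,
                    stats,
                    in_range_k=cfg.qc_in_range_k,
                    min_in_range=cfg.qc_min_in_range,
                    dynamic_range_floor=cfg.qc_dynamic_range_floor,
                )
                qc_rows.append(report)
                if not report.passed:
                    failed_plates.add(str(plate_id))
            df["excluded"] = df["plate_id"].isin(failed_plates)
            df["exclusion_reason"] = np.where(df["excluded"], "plate_qc_failed", "")
            if failed_plates:
                logger.info(
                    "batch %s: %d/%d plates failed QC (%s)",
                    batch.batch_id,
                    len(failed_plates),
                    df["plate_id"].nunique(),
                    ", ".join(sorted(failed_plates)),
                )

            ok = ~df["excluded"] & ~df["is_control_plate"]

            # 4. cellularity correction (sub-maximal regulatory condition only)
            df["corrected"] = df["centered"]
            assay = df["assay"].iloc[0]
            if cfg.correct_cellularity and assay == "TREG_LOW" and ok.any():
                sub = df[ok]
                try:
                    corrected, cfit = correct_cellularity(
                        sub["centered"].to_numpy(),
                        sub["live_cells"].to_numpy(),
                        sub["role"].to_numpy(),
                        plate_ids=sub["plate_id"].to_numpy(),
                    )
                    df.loc[ok, "corrected"] = corrected
                    cellularity_fits[batch.batch_id] = cfit
                except ProcessingError as exc:
                    logger.warning(
                        "batch %s: cellularity correction skipped (%s)",
                        batch.batch_id,
                        exc,
                    )

            # 5./6. z-scores + calibration, on raw-centered and corrected tracks
            for col, zcol, fcol in (
                ("centered", "z", "frac_of_pos"),
                ("corrected", "z_corrected", "corrected_frac_of_pos"),
            ):
                pool_mask = ok & df["role"].isin(
                    [WellRole.NEG_CTRL.value, WellRole.COMPOUND.value]
                )
                pool = df.loc[pool_mask, col].to_numpy()
                rsd = robust_sd(pool)
                if rsd == 0:
                    raise ProcessingError(
                        f"batch {batch.batch_id}: zero robust SD in the "
                        "negative-reference pool"
                    )
                ref = select_negative_reference(pool, k=cfg.reference_k)
                ref_mean = float(np.mean(pool[ref]))
                zscore_mask = ok | df["is_control_plate"]
                df.loc[zscore_mask, zcol] = zscore_wells(
                    df.loc[zscore_mask, col].to_numpy(), ref_mean, rsd
                )
                ctrl_mask = zscore_mask & df["role"].isin(
                    [WellRole.NEG_CTRL.value, WellRole.POS_CTRL.value]
                )
                calib = calibrate_to_positive(
                    df.loc[ctrl_mask, zcol].to_numpy(),
                    (df.loc[ctrl_mask, "role"] == WellRole.POS_CTRL.value).to_numpy(),
                )
                df.loc[zscore_mask, fcol] = calib.frac_of_pos(
                    df.loc[zscore_mask, zcol].to_numpy()
                )
                if col == "corrected":
                    calibrations[batch.batch_id] = calib

            # 7. toxic-well exclusion
            if cfg.exclude_toxic:
                neg_cells = df.loc[
                    ok & (df["role"] == WellRole.NEG_CTRL.value), "live_cells"
                ]
                floor = cfg.toxic_floor_frac * float(neg_cells.median())
                toxic = (
                    ok
                    & (df["role"] == WellRole.COMPOUND.value)
                    & (df["live_cells"] < floor)
                )
                df.loc[toxic, "excluded"] = True
                df.loc[toxic, "exclusion_reason"] = "toxic_low_cellularity"
                if toxic.any():
                    logger.info(
                        "batch %s: %d compound wells excluded as toxic "
                        "(live cells < %.0f)",
                        batch.batch_id,
                        int(toxic.sum()),
                        floor,
                    )

            # raw-scale fractional enhancement against batch control medians
            raw_neg = float(
                df.loc[ok & (df["role"] == WellRole.NEG_CTRL.value), "pct_positive"].median()
            )
            raw_pos = float(
                df.loc[ok & (df["role"] == WellRole.POS_CTRL.value), "pct_positive"].median()
            )
            if raw_pos > raw_neg:
                df["fr_enhance"] = fractional_enhancement(
                    df["pct_positive"].to_numpy(), raw_neg, raw_pos
                )
            else:
                df["fr_enhance"] = np.nan

            well_frames.append(df)

        wells = pd.concat(well_frames, ignore_index=True)
        hits = self._hit_table(wells)
        return ScreenResults(
            config=cfg,
            wells=wells,
            qc=pd.DataFrame([vars(r) for r in qc_rows]),
            hits=hits,
            cellularity_fits=cellularity_fits,
            calibrations=calibrations,
        )

    def _hit_table(self, wells: pd.DataFrame) -> pd.DataFrame:
        cfg = self.config
        cw = wells[wells["role"] == WellRole.COMPOUND.value]
        usable = cw[~cw["excluded"]]
        agg = usable.groupby("compound_id").agg(
            assay=("assay", "first"),
            frac_of_pos=("frac_of_pos", "mean"),
            corrected_frac_of_pos=("corrected_frac_of_pos", "mean"),
            fr_enhance=("fr_enhance", "mean"),
            n_wells=("frac_of_pos", "size"),
        )
        excluded_only = (
            cw[~cw["compound_id"].isin(usable["compound_id"])]
            .groupby("compound_id")
            .agg(
                assay=("assay", "first"),
                reason=("exclusion_reason", "first"),
            )
        )
        table = agg.reset_index()
        table["excluded"] = False
        table["exclusion_reason"] = ""
        if not excluded_only.empty:
            extra = excluded_only.reset_index()
            extra["frac_of_pos"] = np.nan
            extra["corrected_frac_of_pos"] = np.nan
            extra["fr_enhance"] = np.nan
            extra["n_wells"] = 0
            extra["excluded"] = True
            extra = extra.rename(columns={"reason": "exclusion_reason"})
            table = pd.concat([table, extra], ignore_index=True)
        table = table.sort_values("compound_id").reset_index(drop=True)
        call_col = (
            "corrected_frac_of_pos" if cfg.correct_cellularity else "frac_of_pos"
        )
        return call_hits(table, threshold=cfg.hit_threshold, column=call_col)


@dataclass
class ScreenResults:
    """Fitted hit-calling results: normalized wells, QC reports, the hit
    table, and per-batch regression/calibration diagnostics."""

    config: HitCallConfig
    wells: pd.DataFrame
    qc: pd.DataFrame
    hits: pd.DataFrame
    cellularity_fits: dict[str, CellularityFit] = field(default_factory=dict)
    calibrations: dict[str, Calibration] = field(default_factory=dict)

    @property
    def hit_compounds(self) -> list[str]:
        return self.hits.loc[self.hits["is_hit"], "compound_id"].tolist()

    def summary(self) -> str:
        n_plates = int(self.qc.shape[0])
        n_failed = int((~self.qc["passed"]).sum())
        n_cpd = int(self.hits.shape[0])
        n_hits = len(self.hit_compounds)
        n_excl = int(self.hits["excluded"].sum())
        lines = [
            "Screen hit-calling results",
            f"  plates            : {n_plates} ({n_failed} failed QC)",
            f"  compounds         : {n_cpd} ({n_excl} excluded)",
            f"  hits (frac >= {self.config.hit_threshold:g})"
            f" : {n_hits} ({100.0 * n_hits / max(n_cpd, 1):.2f}%)",
        ]
        for batch_id, cfit in self.cellularity_fits.items():
            lines.append(
                f"  cellularity fit {batch_id}: slope {cfit.slope:+.2f} %/log-cell "
                f"(95% CI {cfit.slope_conf_int[0]:+.2f}..{cfit.slope_conf_int[1]:+.2f}, "
                f"R^2 {cfit.r_squared:.3f}, n={cfit.n_wells})"
            )
        return "\n".join(lines)
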