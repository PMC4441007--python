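"""Dose-response modelling for compound titration panels.

Two curve families are fitted to 8-dose titrations on the log10-dose scale:

* a single sigmoid ``s(d) = r_i + (r_f - r_i) / (1 + exp(-4*alpha*(d - d_m)))``
  for asymptotic responses (slope at the midpoint is ``alpha * sign(r_f - r_i)``),
* an impulse (double sigmoid) ``f(d) = s_on(d) * s_off(d) / r_p`` for
  rise-then-fall responses, where ``s_on`` rises from the initial response
  ``r_l`` to the peak ``r_p`` around the onset dose ``d_1`` and ``s_off``
  falls from ``r_p`` to the final response ``r_h`` around the offset dose
  ``d_2``.

Both candidates are fitted by bounded trust-region least squares from a
seeded Latin-hypercube multistart and the reported model is the one with
lower AICc. Fitted curves are reverse-queried for the smallest tested dose
at which half the peak response is attained (EC50 on the enhancement scale,
LD50 on the viability scale); queries that never reach half-peak within the
tested range are right-censored at the highest dose.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import qmc

logger = logging.getLogger(__name__)

__all__ = [
    "SigmoidParams",
    "ImpulseParams",
    "ModelKind",
    "sigmoid_response",
    "impulse_response",
    "invert_sigmoid",
    "HalfPeakDose",
    "CurveFit",
    "DoseResponseModel",
    "fit_dose_response",
    "DoseResponseFit",
    "fit_compound_profile",
    "TherapeuticIndex",
    "compute_therapeutic_index",
    "SpecificityCall",
    "classify_specific_enhancer",
    "FitError",
]

RSS_FLOOR = 1e-12  # keeps log-likelihood finite on (near-)perfect fits
_FLAT_TOL = 1e-9


class FitError(RuntimeError):
    """Optimisation failed on every start, or inputs preclude a fit."""


class ModelKind(enum.Enum):
    SINGLE = "SINGLE"
    IMPULSE = "IMPULSE"


@dataclass(frozen=True)
class SigmoidParams:
    """Single-sigmoid parameters on the log10-dose scale."""

    dm: float  # midpoint dose (log10 uM)
    ri: float  # initial response
    rf: float  # final response
    alpha: float  # slope parameter, >= 0 (direction carried by sign(rf - ri))

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.dm, self.ri, self.rf, self.alpha])


@dataclass(frozen=True)
class ImpulseParams:
    """Impulse (double-sigmoid) parameters on the log10-dose scale."""

    d1: float  # onset dose
    d2: float  # offset dose, >= d1
    rl: float  # initial response at lowest dose
    rp: float  # peak response (nonzero; also the normaliser)
    rh: float  # final response at highest dose
    alpha1: float  # onset slope, >= 0
    alpha2: float  # offset slope, >= 0

    def __post_init__(self) -> None:
        if self.d1 > self.d2:
            raise ValueError("impulse requires d1 <= d2")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("slopes must be >= 0")
        if self.rp == 0:
            raise ValueError("peak response rp must be nonzero")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.d1, self.d2, self.rl, self.rp, self.rh, self.alpha1, self.alpha2]
        )


def sigmoid_response(d, p: SigmoidParams):
    """Evaluate the single sigmoid at log10 dose ``d``."""
    d = np.asarray(d, dtype=float)
    return p.ri + (p.rf - p.ri) / (1.0 + np.exp(-4.0 * p.alpha * (d - p.dm)))


def impulse_response(d, p: ImpulseParams, normalizer: str = "peak"):
    """Evaluate the impulse model at log10 dose ``d``.

    ``normalizer="peak"`` divides the product of onset and offset sigmoids by
    the shared peak ``rp`` (default); ``"initial"`` divides by the initial
    response ``rl`` instead (an alternative reading of the normalising factor,
    exposed for comparison).
    """
    d = np.asarray(d, dtype=float)
    s_on = p.rl + (p.rp - p.rl) / (1.0 + np.exp(-4.0 * p.alpha1 * (d - p.d1)))
    s_off = p.rh + (p.rp - p.rh) / (1.0 + np.exp(4.0 * p.alpha2 * (d - p.d2)))
    if normalizer == "peak":
        norm = p.rp
    elif normalizer == "initial":
        if p.rl == 0:
            raise ValueError('normalizer="initial" requires rl != 0')
        norm = p.rl
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    return s_on * s_off / norm


def invert_sigmoid(p: SigmoidParams, y: float) -> float:
    """Analytic dose (log10) at which the single sigmoid attains response ``y``.

    ``d = d_m + ln((y - r_i) / (r_f - y)) / (4 alpha)``; raises ValueError when
    ``y`` is outside the open response range or the curve is flat.
    """
    if p.alpha == 0 or p.rf == p.ri:
        raise ValueError("flat sigmoid cannot be inverted")
    ratio = (y - p.ri) / (p.rf - y)
    if ratio <= 0:
        raise ValueError(f"target {y} outside open response range ({p.ri}, {p.rf})")
    return p.dm + math.log(ratio) / (4.0 * p.alpha)


@dataclass(frozen=True)
class HalfPeakDose:
    """A reverse-query result: dose in uM, right-censored at the highest
    tested dose when the target response is never attained in range."""

    dose_uM: float
    censored: bool = False

    def __str__(self) -> str:
        return f">{self.dose_uM:g}" if self.censored else f"{self.dose_uM:g}"


def aicc(n: int, k: int, rss: float) -> float:
    """Small-sample-corrected Akaike criterion for a Gaussian least-squares fit.

    The correction denominator ``n - k - 1`` is floored at 1 so the criterion
    stays finite for saturated models (e.g. the 7-parameter impulse on a bare
    8-point panel); the floor only ever increases the penalty ordering in the
    saturated direction.
    """
    rss = max(rss, RSS_FLOOR)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / max(n - k - 1, 1)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class CurveFit:
    """Fitted dose-response curve for one compound x readout."""

    model: ModelKind
    params: SigmoidParams | ImpulseParams
    rss: float
    aicc: float
    log_dose_range: tuple[float, float]  # log10 uM, tested range
    success: bool
    candidates: dict = field(default_factory=dict)  # ModelKind -> (params, rss, aicc)

    @property
    def peak(self) -> float:
        """Peak response parameter: rp for IMPULSE, rf for SINGLE."""
        if self.model is ModelKind.IMPULSE:
            return self.params.rp
        return self.params.rf

    def predict(self, dose_uM) -> np.ndarray:
        d = np.log10(np.asarray(dose_uM, dtype=float))
        return self.predict_log(d)

    def predict_log(self, d) -> np.ndarray:
        if self.model is ModelKind.IMPULSE:
            return impulse_response(d, self.params)
        return sigmoid_response(d, self.params)

    def max_response(self, n_grid: int = 512) -> float:
        lo, hi = self.log_dose_range
        return float(np.max(self.predict_log(np.linspace(lo, hi, n_grid))))

    def half_peak(self, frac: float = 0.5, target: float | None = None) -> HalfPeakDose:
        return reverse_query_half_peak(self, frac=frac, target=target)

    def summary(self) -> str:
        lines = [
            f"Dose-response fit ({self.model.value})",
            f"  rss  = {self.rss:.6g}",
            f"  aicc = {self.aicc:.6g}",
        ]
        for name, val in zip(_param_names(self.model), self.params.as_array()):
            lines.append(f"  {name:7s}= {val:.6g}")
        return "\n".join(lines)


def _param_names(kind: ModelKind) -> list[str]:
    if kind is ModelKind.SINGLE:
        return ["dm", "ri", "rf", "alpha"]
    return ["d1", "d2", "rl", "rp", "rh", "alpha1", "alpha2"]


class DoseResponseModel:
    """Nonlinear dose-response model for one response curve.

    Parameters
    ----------
    doses_uM : dose for each measurement (uM; replicate doses allowed)
    responses : measured response at each dose (fractional-enhancement or
        viability-fraction scale)
    """

    MIN_DISTINCT_SINGLE = 5
    MIN_DISTINCT_IMPULSE = 8

    def __init__(self, doses_uM: Sequence[float], responses: Sequence[float]) -> None:
        self.doses_uM = np.asarray(doses_uM, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if self.doses_uM.shape != self.responses.shape:
            raise ValueError("doses and responses must have the same length")
        if np.any(self.doses_uM <= 0):
            raise ValueError("doses must be positive (uM)")
        self.log_doses = np.log10(self.doses_uM)
        self.n_distinct = len(np.unique(self.log_doses))
        if self.n_distinct < self.MIN_DISTINCT_SINGLE:
            raise FitError(
                f"need >= {self.MIN_DISTINCT_SINGLE} distinct doses, "
                f"got {self.n_distinct}"
            )

    # -- candidate models ---------------------------------------------------

    def _bounds_single(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.log_doses.min(), self.log_doses.max()
        rmin, rmax = self.responses.min(), self.responses.max()
        span = max(rmax - rmin, 0.1)
        return (
            np.array([lo - 1.0, rmin - span, rmin - span, 0.0]),
            np.array([hi + 1.0, rmax + span, rmax + span, 8.0]),
        )

    def _bounds_impulse(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.log_doses.min(), self.log_doses.max()
        rmin, rmax = self.responses.min(), self.responses.max()
        span = max(rmax - rmin, 0.1)
        # x = (d1, delta, rl, rp, rh, alpha1, alpha2) with d2 = d1 + delta
        return (
            np.array([lo - 1.0, 0.0, rmin - span, 1e-3, rmin - span, 0.0, 0.0]),
            np.array(
                [hi + 1.0, (hi - lo) + 2.0, rmax + span, rmax + span, rmax + span, 8.0, 8.0]
            ),
        )

    def _resid_single(self, x: np.ndarray) -> np.ndarray:
        dm, ri, rf, alpha = x
        return (
            ri
            + (rf - ri) / (1.0 + np.exp(-4.0 * alpha * (self.log_doses - dm)))
            - self.responses
        )

    def _resid_impulse(self, x: np.ndarray) -> np.ndarray:
        d1, delta, rl, rp, rh, a1, a2 = x
        d2 = d1 + delta
        s_on = rl + (rp - rl) / (1.0 + np.exp(-4.0 * a1 * (self.log_doses - d1)))
        s_off = rh + (rp - rh) / (1.0 + np.exp(4.0 * a2 * (self.log_doses - d2)))
        return s_on * s_off / rp - self.responses

    def _heuristic_start_single(self) -> np.ndarray:
        order = np.argsort(self.log_doses)
        return np.array(
            [
                0.5 * (self.log_doses.min() + self.log_doses.max()),
                self.responses[order[0]],
                self.responses[order[-1]],
                1.0,
            ]
        )

    def _heuristic_start_impulse(self) -> np.ndarray:
        lo, hi = self.log_doses.min(), self.log_doses.max()
        order = np.argsort(self.log_doses)
        rp0 = max(self.responses.max(), 1e-2)
        return np.array(
            [
                lo + (hi - lo) / 3.0,
                (hi - lo) / 2.0,
                self.responses[order[0]],
                rp0,
                self.responses[order[-1]],
                1.0,
                1.0,
            ]
        )

    def _multistart(self, resid, bounds, x0_heuristic, n_starts, seed):
        lb, ub = bounds
        sampler = qmc.LatinHypercube(d=len(lb), seed=seed)
        starts = [x0_heuristic]
        if n_starts > 1:
            pts = qmc.scale(sampler.random(n_starts - 1), lb, ub)
            starts.extend(list(pts))
        best = None
        for x0 in starts:
            x0 = np.clip(x0, lb, ub)
            try:
                res = least_squares(
                    resid, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12,
                    gtol=1e-12, max_nfev=2000,
                )
            except Exception:  # noqa: BLE001 - a single start may fail numerically
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[1]:
                best = (res.x, rss, res.success)
        if best is None:
            raise FitError("optimizer failed to converge on every start")
        return best

    # -- public fit ---------------------------------------------------------

    def fit(
        self,
        n_starts: int = 10,
        seed: int = 0,
        models: Sequence[ModelKind] = (ModelKind.SINGLE, ModelKind.IMPULSE),
    ) -> CurveFit:
        """Fit the candidate models and select by AICc (ties favour the
        model with fewer parameters)."""
        n = len(self.responses)
        candidates: dict[ModelKind, tuple] = {}
        success = True

        if ModelKind.SINGLE in models:
            x, rss, ok = self._multistart(
                self._resid_single,
                self._bounds_single(),
                self._heuristic_start_single(),
                n_starts,
                seed,
            )
            params = SigmoidParams(dm=x[0], ri=x[1], rf=x[2], alpha=x[3])
            candidates[ModelKind.SINGLE] = (params, rss, aicc(n, 4, rss))
            success = success and ok

        if ModelKind.IMPULSE in models and self.n_distinct >= self.MIN_DISTINCT_IMPULSE:
            x, rss, ok = self._multistart(
                self._resid_impulse,
                self._bounds_impulse(),
                self._heuristic_start_impulse(),
                n_starts,
                seed + 1,
            )
            params = ImpulseParams(
                d1=x[0], d2=x[0] + x[1], rl=x[2], rp=x[3], rh=x[4],
                alpha1=x[5], alpha2=x[6],
            )
            candidates[ModelKind.IMPULSE] = (params, rss, aicc(n, 7, rss))
            success = success and ok

        if not candidates:
            raise FitError("no candidate model could be fitted")

        # lower AICc wins; exact tie -> fewer parameters (SINGLE sorts first)
        order = {ModelKind.SINGLE: 0, ModelKind.IMPULSE: 1}
        kind = min(candidates, key=lambda k: (candidates[k][2], order[k]))
        params, rss, crit = candidates[kind]
        return CurveFit(
            model=kind,
            params=params,
            rss=rss,
            aicc=crit,
            log_dose_range=(float(self.log_doses.min()), float(self.log_doses.max())),
            success=success,
            candidates=candidates,
        )


def fit_dose_response(
    doses_uM: Sequence[float],
    responses: Sequence[float],
    n_starts: int = 10,
    seed: int = 0,
) -> CurveFit:
    """Convenience wrapper: build a :class:`DoseResponseModel` and fit it."""
    return DoseResponseModel(doses_uM, responses).fit(n_starts=n_starts, seed=seed)


def curve_from_params(
    params: SigmoidParams | ImpulseParams, log_dose_range: tuple[float, float]
) -> CurveFit:
    """Wrap known parameters as a zero-residual :class:`CurveFit` so that the
    same prediction / reverse-query machinery applies to ground-truth curves."""
    kind = ModelKind.IMPULSE if isinstance(params, ImpulseParams) else ModelKind.SINGLE
    return CurveFit(
        model=kind,
        params=params,
        rss=0.0,
        aicc=float("nan"),
        log_dose_range=log_dose_range,
        success=True,
    )


# ---------------------------------------------------------------------------
# reverse query


def reverse_query_half_peak(
    fit: CurveFit, frac: float = 0.5, target: float | None = None, n_grid: int = 1024
) -> HalfPeakDose:
    """Smallest tested dose at which the fitted curve attains ``frac`` of its
    peak response parameter (or an explicit ``target`` response).

    Analytic inversion is used for the single sigmoid, bisection for the
    impulse. A curve that attains the target at or below the lowest tested
    dose reports the lowest tested dose; one that never attains it in range
    is censored at the highest tested dose.
    """
    lo, hi = fit.log_dose_range
    if target is None:
        target = frac * fit.peak
    grid = np.linspace(lo, hi, n_grid)
    vals = fit.predict_log(grid)
    if float(np.max(vals) - np.min(vals)) < _FLAT_TOL:
        return HalfPeakDose(10.0**hi, censored=True)

    if fit.model is ModelKind.SINGLE:
        try:
            d = invert_sigmoid(fit.params, target)
        except ValueError:
            return HalfPeakDose(10.0**hi, censored=True)
        if d > hi:
            return HalfPeakDose(10.0**hi, censored=True)
        return HalfPeakDose(10.0 ** max(d, lo), censored=False)

    # impulse: bisection on the evaluation grid, first crossing from the left
    above = vals >= target
    if above[0]:
        return HalfPeakDose(10.0**lo, censored=False)
    crossings = np.nonzero(above[1:] != above[:-1])[0]
    if len(crossings) == 0:
        return HalfPeakDose(10.0**hi, censored=True)
    i = crossings[0]
    d = brentq(lambda x: float(fit.predict_log(x)) - target, grid[i], grid[i + 1],
               xtol=1e-10)
    return HalfPeakDose(10.0**d, censored=False)


# ---------------------------------------------------------------------------
# compound-level profile


@dataclass
class DoseResponseFit:
    """Joint enhancement + viability characterisation of one compound x assay."""

    compound_id: str
    assay: str
    response_fit: CurveFit
    viability_fit: CurveFit
    ec50: HalfPeakDose
    ld50: HalfPeakDose
    max_fr_enhance: float

    @property
    def model(self) -> ModelKind:
        return self.response_fit.model

    @property
    def rss(self) -> float:
        return self.response_fit.rss

    @property
    def aicc(self) -> float:
        return self.response_fit.aicc

    def therapeutic_index(self) -> "TherapeuticIndex":
        return compute_therapeutic_index(self.ec50, self.ld50)

    def summary(self) -> str:
        ti: str
        try:
            ti = str(self.therapeutic_index())
        except ValueError:
            ti = "undefined (EC50 censored)"
        return "\n".join(
            [
                f"Compound {self.compound_id} [{self.assay}]",
                f"  response model : {self.response_fit.model.value} "
                f"(rss {self.response_fit.rss:.4g})",
                f"  EC50           : {self.ec50} uM",
                f"  LD50           : {self.ld50} uM",
                f"  max enhancement: {self.max_fr_enhance:.3f}",
                f"  LD50/EC50      : {ti}",
            ]
        )


def fit_compound_profile(
    compound_id: str,
    assay: str,
    doses_uM: Sequence[float],
    enhancement: Sequence[float],
    viability: Sequence[float],
    n_starts: int = 10,
    seed: int = 0,
) -> DoseResponseFit:
    """Fit enhancement and viability titrations and extract EC50 / LD50.

    EC50 is the smallest tested dose at 50% of the fitted peak enhancement;
    LD50 the smallest tested dose at which fitted viability falls to 50% of
    its fitted value at the lowest tested dose (i.e. 50% cytotoxicity).
    """
    rfit = DoseResponseModel(doses_uM, enhancement).fit(n_starts=n_starts, seed=seed)
    vfit = DoseResponseModel(doses_uM, viability).fit(n_starts=n_starts, seed=seed + 7)
    ec50 = rfit.half_peak()
    v0 = float(vfit.predict_log(np.array([vfit.log_dose_range[0]]))[0])
    ld50 = reverse_query_half_peak(vfit, target=0.5 * v0)
    return DoseResponseFit(
        compound_id=compound_id,
        assay=assay,
        response_fit=rfit,
        viability_fit=vfit,
        ec50=ec50,
        ld50=ld50,
        max_fr_enhance=rfit.max_response(),
    )


@dataclass(frozen=True)
class TherapeuticIndex:
    """LD50/EC50 ratio; a censored LD50 yields a lower bound."""

    value: float
    is_lower_bound: bool = False

    def __str__(self) -> str:
        return f">={self.value:g}" if self.is_lower_bound else f"{self.value:g}"


def compute_therapeutic_index(ec50: HalfPeakDose, ld50: HalfPeakDose) -> TherapeuticIndex:
    """LD50/EC50 (therapeutic-index analogue). An LD50 censored at the top
    tested dose gives the lower bound max_dose/EC50; a censored EC50 is an
    error (the compound is not an enhancer at tested doses)."""
    if ec50.censored:
        raise ValueError("therapeutic index undefined: EC50 censored")
    return TherapeuticIndex(
        value=ld50.dose_uM / ec50.dose_uM, is_lower_bound=ld50.censored
    )


@dataclass(frozen=True)
class SpecificityCall:
    compound_id: str
    is_enhancer: bool  # max Treg enhancement >= threshold at some dose
    is_specific: bool  # enhancer AND Th1/Th17 enhancement < threshold at all doses
    max_enhancement: Mapping[str, float]


def classify_specific_enhancer(
    compound_id: str,
    max_enhancement: Mapping[str, float],
    threshold: float = 0.3,
    treg_key: str = "TREG",
    other_keys: Sequence[str] = ("TH1", "TH17"),
) -> SpecificityCall:
    """Call a compound a lineage-specific enhancer of the regulatory lineage.

    ``max_enhancement`` maps lineage key -> maximal fitted fractional
    enhancement across the tested dose range.
    """
    missing = [k for k in (treg_key, *other_keys) if k not in max_enhancement]
    if missing:
        raise ValueError(f"missing lineage panels: {missing}")
    is_enh = max_enhancement[treg_key] >= threshold
    is_specific = is_enh and all(max_enhancement[k] < threshold for k in other_keys)
    return SpecificityCall(
        compound_id=compound_id,
        is_enhancer=bool(is_enh),
        is_specific=bool(is_specific),
        max_enhancement=dict(max_enhancement),
    )
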