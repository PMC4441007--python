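"""Cross-experiment gene-signature derivation and disease-set enrichment.

A concordant signature is built from two two-group experiments (e.g. a mouse
compound-treated vs control comparison and a human lineage comparison):
per-gene Student's t-tests flag differential genes at nominal p <= 0.05 in
each experiment (no multiple-testing correction), genes moving the same
direction in both are intersected, each experiment is per-gene min-max
scaled, and marker selection retains genes whose combined signal-to-noise
ratio ``(mu_A - mu_B) / (sd_A + sd_B)`` exceeds 1 in magnitude.

Enrichment of the signature in a disease gene set is tested against an
empirical null built by repeatedly drawing disease-set-sized gene sets
uniformly from the universe (one-sided permutation test; fold enrichment is
the observed overlap over the mean null overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "differential_expression",
    "minmax_normalize",
    "SignatureGene",
    "snr_marker_selection",
    "concordant_signature",
    "OverlayCounts",
    "volcano_overlay_counts",
    "EnrichmentResult",
    "permutation_enrichment",
]


def _group_columns(expr: ExpressionMatrix, group) -> list[int]:
    if isinstance(group, str):
        samples = expr.samples_in_group(group)
    else:
        samples = list(group)
    idx = {s: i for i, s in enumerate(expr.sample_ids)}
    missing = [s for s in samples if s not in idx]
    if missing:
        raise ValidationError(f"samples not in matrix: {missing[:10]}")
    if len(samples) < 2:
        raise ValidationError("each group needs >= 2 samples")
    return [idx[s] for s in samples]


def differential_expression(
    expr: ExpressionMatrix,
    group_a,
    group_b,
    p_threshold: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sided two-sample t-test (pooled variance by default;
    ``equal_var=False`` gives Welch's test).

    Genes at nominal ``p <= p_threshold`` are flagged; no multiple-testing
    correction is applied. Returns a frame indexed by gene with columns
    mean_a, mean_b, sd_a, sd_b, t, p, direction (+1/-1/0), flagged.
    """
    ia, ib = _group_columns(expr, group_a), _group_columns(expr, group_b)
    A, B = expr.values[:, ia], expr.values[:, ib]
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    # identical groups give 0/0 -> nan; by convention no evidence: t=0, p=1
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    diff = mean_a - mean_b
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "sd_a": A.std(axis=1, ddof=1),
            "sd_b": B.std(axis=1, ddof=1),
            "t": t,
            "p": p,
            "direction": np.sign(diff).astype(int),
            "flagged": p <= p_threshold,
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


def minmax_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene min-max scaling to [0, 1]; zero-range genes are set to 0
    with a logged warning. Idempotent."""
    v = expr.values
    lo, hi = v.min(axis=1, keepdims=True), v.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    if flat.any():
        logger.warning("%d constant gene(s) set to 0 by min-max scaling", flat.sum())
    out = np.where(span == 0, 0.0, (v - lo) / np.where(span == 0, 1.0, span))
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, out, expr.group_of_sample)


@dataclass(frozen=True)
class SignatureGene:
    gene_id: str
    direction: int  # +1 up in group A, -1 down
    snr: float  # signed signal-to-noise ratio


def snr_marker_selection(
    expr: ExpressionMatrix,
    group_a,
    group_b,
    snr_threshold: float = 1.0,
    sd_floor: bool = False,
) -> list[SignatureGene]:
    """Marker selection by signal-to-noise ratio ``(mu_A - mu_B)/(sd_A + sd_B)``.

    Genes with ``|snr| > snr_threshold`` are retained with their direction.
    ``sd_floor=True`` applies the GenePattern-style floor
    ``sd <- max(sd, 0.2 * |mu|)`` per group; otherwise genes with zero total
    spread are skipped with a warning.
    """
    ia, ib = _group_columns(expr, group_a), _group_columns(expr, group_b)
    A, B = expr.values[:, ia], expr.values[:, ib]
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    sd_a, sd_b = A.std(axis=1, ddof=1), B.std(axis=1, ddof=1)
    if sd_floor:
        sd_a = np.maximum(sd_a, 0.2 * np.abs(mu_a))
        sd_b = np.maximum(sd_b, 0.2 * np.abs(mu_b))
    denom = sd_a + sd_b
    zero = denom == 0
    if zero.any():
        logger.warning("%d gene(s) skipped: zero spread in both groups", zero.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(zero, np.nan, (mu_a - mu_b) / denom)
    keep = ~zero & (np.abs(snr) > snr_threshold)
    return [
        SignatureGene(g, int(np.sign(s)), float(s))
        for g, s, k in zip(expr.gene_ids, snr, keep)
        if k
    ]


def concordant_signature(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    groups_a: tuple = ("A", "B"),
    groups_b: tuple = ("A", "B"),
    ortholog_map: Mapping[str, str] | None = None,
    p_threshold: float = 0.05,
    snr_threshold: float = 1.0,
    equal_var: bool = True,
) -> list[SignatureGene]:
    """Concordant cross-experiment signature.

    Genes flagged by the per-experiment t-test (nominal ``p <= p_threshold``)
    with the same direction in both experiments are intersected (identifiers
    of experiment B mapped through ``ortholog_map`` when supplied, a
    B-gene -> A-gene table), each experiment is min-max scaled per gene, and
    the SNR filter is applied to the combined (concatenated-sample) data.
    """
    de_a = differential_expression(expr_a, *groups_a, p_threshold, equal_var)
    de_b = differential_expression(expr_b, *groups_b, p_threshold, equal_var)

    if ortholog_map:
        mapped = {g: ortholog_map[g] for g in expr_b.gene_ids if g in ortholog_map}
    else:
        mapped = {g: g for g in expr_b.gene_ids}

    flagged_a = de_a[de_a["flagged"] & (de_a["direction"] != 0)]
    flagged_b = de_b[de_b["flagged"] & (de_b["direction"] != 0)]
    dir_b = {
        mapped[g]: int(d)
        for g, d in flagged_b["direction"].items()
        if g in mapped and mapped[g] is not None
    }
    concordant = [
        g
        for g, d in flagged_a["direction"].items()
        if g in dir_b and dir_b[g] == int(d)
    ]
    if not concordant:
        return []

    norm_a = minmax_normalize(expr_a.subset_genes(concordant))
    b_names = {v: k for k, v in mapped.items()}  # A-gene -> B-gene
    norm_b = minmax_normalize(expr_b.subset_genes([b_names[g] for g in concordant]))

    cols_a_a = _group_columns(norm_a, groups_a[0])
    cols_a_b = _group_columns(norm_a, groups_a[1])
    cols_b_a = _group_columns(norm_b, groups_b[0])
    cols_b_b = _group_columns(norm_b, groups_b[1])
    combined_vals = np.hstack(
        [
            norm_a.values[:, cols_a_a],
            norm_b.values[:, cols_b_a],
            norm_a.values[:, cols_a_b],
            norm_b.values[:, cols_b_b],
        ]
    )
    n_a = len(cols_a_a) + len(cols_b_a)
    samples = [f"s{i}" for i in range(combined_vals.shape[1])]
    groups = {s: ("A" if i < n_a else "B") for i, s in enumerate(samples)}
    combined = ExpressionMatrix(concordant, samples, combined_vals, groups)
    return snr_marker_selection(combined, "A", "B", snr_threshold=snr_threshold)


@dataclass(frozen=True)
class OverlayCounts:
    """Volcano-plot overlay: signature genes up/down in the observed
    comparison, with a 2x2 chi-square test of direction concordance."""

    n_up: int
    n_down: int
    chi2: float
    p: float
    table: np.ndarray  # rows: signature direction (up/down); cols: observed


def volcano_overlay_counts(
    de: pd.DataFrame, signature: Iterable[SignatureGene]
) -> OverlayCounts:
    """Count signature genes moving up/down in an observed comparison and test
    independence of signature direction vs observed direction (1 df
    chi-square, no continuity correction)."""
    sig = list(signature)
    missing = [s.gene_id for s in sig if s.gene_id not in de.index]
    if missing:
        raise ValidationError(f"signature genes absent from DE results: {missing[:10]}")
    obs_dir = de["direction"]
    table = np.zeros((2, 2), dtype=float)
    n_up = n_down = 0
    for s in sig:
        od = int(obs_dir[s.gene_id])
        if od > 0:
            n_up += 1
        elif od < 0:
            n_down += 1
        if od == 0:
            continue
        table[0 if s.direction > 0 else 1, 0 if od > 0 else 1] += 1
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        logger.warning("degenerate 2x2 table (zero marginal); chi-square undefined")
        return OverlayCounts(n_up, n_down, float("nan"), float("nan"), table)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return OverlayCounts(n_up, n_down, float(chi2), float(p), table)


@dataclass(frozen=True)
class EnrichmentResult:
    """Permutation-test enrichment of a signature in a disease gene set."""

    observed_overlap: int
    null_mean: float
    null_sd: float
    fold_enrichment: float
    p_one_sided: float
    n_iterations: int
    universe_size: int
    signature_size: int
    disease_set_size: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Permutation enrichment",
                f"  universe           : {self.universe_size} genes",
                f"  signature / disease: {self.signature_size} / {self.disease_set_size}",
                f"  observed overlap   : {self.observed_overlap}",
                f"  null mean overlap  : {self.null_mean:.3f} (sd {self.null_sd:.3f}, "
                f"{self.n_iterations} iterations)",
                f"  fold enrichment    : {self.fold_enrichment:.2f}",
                f"  one-sided p        : {self.p_one_sided:.4g}",
            ]
        )


def permutation_enrichment(
    signature: GeneSet,
    disease: GeneSet,
    universe: Sequence[str],
    n_iter: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """One-sided permutation test of signature/disease-set overlap.

    Each iteration draws ``len(disease)`` genes uniformly without replacement
    from the universe and records the overlap with the signature. Fold
    enrichment is the observed overlap over the mean null overlap; the
    one-sided p uses add-one smoothing:
    ``p = (1 + #{null >= observed}) / (1 + n_iter)``.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    uni = list(universe)
    pos = {g: i for i, g in enumerate(uni)}
    if len(pos) != len(uni):
        raise ValidationError("universe contains duplicate genes")
    stray_sig = sorted(g for g in signature.gene_ids if g not in pos)
    if stray_sig:
        raise ValidationError(f"signature genes outside the universe: {stray_sig[:10]}")
    stray_dis = sorted(g for g in disease.gene_ids if g not in pos)
    if stray_dis:
        raise ValidationError(f"disease genes outside the universe: {stray_dis[:10]}")

    N, n = len(uni), len(disease)
    mask = np.zeros(N, dtype=bool)
    mask[[pos[g] for g in signature.gene_ids]] = True
    observed = len(signature.gene_ids & disease.gene_ids)

    rng = np.random.default_rng(seed)
    nulls = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        nulls[i] = int(mask[rng.choice(N, size=n, replace=False)].sum())

    null_mean = float(nulls.mean())
    fold = 0.0 if observed == 0 else (
        float("inf") if null_mean == 0 else observed / null_mean
    )
    p = (1 + int((nulls >= observed).sum())) / (1 + n_iter)
    return EnrichmentResult(
        observed_overlap=observed,
        null_mean=null_mean,
        null_sd=float(nulls.std(ddof=1)) if n_iter > 1 else 0.0,
        fold_enrichment=fold,
        p_one_sided=float(p),
        n_iterations=n_iter,
        universe_size=N,
        signature_size=len(signature),
        disease_set_size=n,
    )
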