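"""End-to-end orchestration: simulate -> hitcall -> fitdr -> prioritize ->
cluster -> signature -> enrich, reproducibly from a single config and seed.

Each invocation writes one run directory holding a copy of the resolved
configuration, every stage's TSV outputs, and a run summary with the counts
at each stage. Re-running with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import Assay, GeneSet
from .doseresponse import FitError, classify_specific_enhancer, fit_compound_profile
from .hitcalling import HitCallConfig, ScreenModel
from .io import write_gct, write_gmt, write_gene_list, write_plate_table
from .phenoclust import correlation_cluster, euclidean_cluster, pca_reduce, standardize_features
from .signature import concordant_signature, permutation_enrichment
from .synthdata import (
    DoseTruth,
    ScreenParams,
    generate_dose_panel,
    generate_expression,
    generate_screen,
    generate_universe,
    random_dose_truths,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained in the run directory."""


@dataclass
class RunConfig:
    """Thresholds, iteration counts and simulation scale for one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    # thresholds
    hit_threshold: float = 0.3
    snr_threshold: float = 1.0
    p_threshold: float = 0.05
    qc_min_in_range: float = 0.75
    variance_target: float = 0.90
    # iteration counts
    n_iter: int = 10000
    n_starts: int = 10
    # simulation scale
    n_compounds: int = 3281
    frac_enhancers: float = 0.02
    n_qc_fail_plates: int = 1
    dose_replicates: int = 2
    dose_noise_sd: float = 0.05
    n_genes: int = 4000
    n_per_group: int = 5
    n_signature: int = 111
    snr_target: float = 2.0
    universe_size: int = 20077
    disease_set_size: int = 1437

    def __post_init__(self) -> None:
        checks = [
            ("hit_threshold", 0.0, 1.0, self.hit_threshold),
            ("snr_threshold", 0.0, float("inf"), self.snr_threshold),
            ("p_threshold", 0.0, 1.0, self.p_threshold),
            ("qc_min_in_range", 0.0, 1.0, self.qc_min_in_range),
            ("variance_target", 0.0, 1.0, self.variance_target),
        ]
        for name, lo, hi, val in checks:
            if not lo < val <= hi:
                raise ValueError(f"{name}={val} outside ({lo}, {hi}]")
        if self.n_iter < 1 or self.n_starts < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must fit in a signed 32-bit integer")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, offset: int) -> int:
        return int((self.seed + 1009 * (offset + 1)) % 2**31)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on synthetic data and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: list[str] = [f"tregscreen {__version__} pipeline run (seed {config.seed})"]

    stage = "simulate"
    try:
        batches, truth = generate_screen(
            config.n_compounds,
            frac_enhancers=config.frac_enhancers,
            seed=config.stage_seed(0),
            n_qc_fail_plates=config.n_qc_fail_plates,
        )
        write_plate_table(batches, out / "plates.csv")
        with open(out / "truth.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "enhancer_compounds": truth.enhancer_compounds,
                    "toxic_compounds": truth.toxic_compounds,
                    "qc_fail_plates": sorted(truth.qc_fail_plates),
                    "cellularity_slope": truth.cellularity_slope,
                    "noise_sd": truth.noise_sd,
                },
                fh,
                sort_keys=True,
            )
        summary.append(
            f"simulate: {config.n_compounds} compounds, "
            f"{len(truth.enhancer_compounds)} planted enhancers, "
            f"{len(truth.qc_fail_plates)} QC-fail plates"
        )

        stage = "hitcall"
        results = ScreenModel(
            batches,
            HitCallConfig(
                hit_threshold=config.hit_threshold,
                qc_min_in_range=config.qc_min_in_range,
            ),
        ).fit()
        _write_tsv(results.hits, out / "hits.tsv")
        _write_tsv(results.qc, out / "qc.tsv")
        hit_ids = sorted(results.hit_compounds)
        summary.append(
            f"hitcall: {len(results.qc)} plates "
            f"({int((~results.qc['passed']).sum())} excluded), {len(hit_ids)} hits"
        )

        stage = "fitdr"
        lineages = {"TREG": 1.0, "TH1": 0.15, "TH17": 0.10}
        fits_rows = []
        max_enh: dict[str, dict[str, float]] = {c: {} for c in hit_ids}
        ec50_ld50: dict[str, tuple] = {}
        for li, (lineage, scale) in enumerate(lineages.items()):
            base = random_dose_truths(len(hit_ids), seed=config.stage_seed(10 + li))
            remap = dict(zip(sorted(base.response), hit_ids))
            dt = DoseTruth(
                doses_uM=base.doses_uM,
                response={
                    remap[c]: dataclasses.replace(p, rp=p.rp * scale, rh=p.rh * scale,
                                                  rl=p.rl * scale)
                    for c, p in base.response.items()
                },
                viability={remap[c]: p for c, p in base.viability.items()},
            )
            panel = generate_dose_panel(
                dt,
                replicates=config.dose_replicates,
                noise_sd=config.dose_noise_sd,
                seed=config.stage_seed(20 + li),
            )
            panel.insert(1, "lineage", lineage)
            panel.to_csv(out / f"dose_panel_{lineage}.csv", index=False)
            for cid, cdf in panel.groupby("compound_id"):
                try:
                    fit = fit_compound_profile(
                        str(cid),
                        lineage,
                        cdf["dose_uM"].to_numpy(),
                        cdf["fr_enhance"].to_numpy(),
                        cdf["viability"].to_numpy(),
                        n_starts=config.n_starts,
                        seed=config.stage_seed(30 + li),
                    )
                except FitError as exc:
                    logger.warning("fit failed for %s/%s: %s", cid, lineage, exc)
                    continue
                max_enh[str(cid)][lineage] = fit.max_fr_enhance
                if lineage == "TREG":
                    ec50_ld50[str(cid)] = (fit.ec50, fit.ld50)
                fits_rows.append(
                    {
                        "compound_id": cid,
                        "lineage": lineage,
                        "model": fit.model.value,
                        "rss": fit.rss,
                        "aicc": fit.aicc,
                        "ec50_uM": fit.ec50.dose_uM,
                        "ec50_censored": fit.ec50.censored,
                        "ld50_uM": fit.ld50.dose_uM,
                        "ld50_censored": fit.ld50.censored,
                        "max_fr_enhance": fit.max_fr_enhance,
                    }
                )
        fits = pd.DataFrame(fits_rows)
        _write_tsv(fits, out / "fits.tsv")
        summary.append(f"fitdr: {len(fits)} compound x lineage fits")

        stage = "prioritize"
        prio_rows = []
        for cid in hit_ids:
            if len(max_enh[cid]) != len(lineages) or cid not in ec50_ld50:
                continue
            call = classify_specific_enhancer(
                cid, max_enh[cid], threshold=config.hit_threshold
            )
            ec50, ld50 = ec50_ld50[cid]
            ratio = np.nan if ec50.censored else ld50.dose_uM / ec50.dose_uM
            prio_rows.append(
                {
                    "compound_id": cid,
                    "max_treg_enhance": max_enh[cid]["TREG"],
                    "max_th1_enhance": max_enh[cid]["TH1"],
                    "max_th17_enhance": max_enh[cid]["TH17"],
                    "ld50_ec50_ratio": ratio,
                    "ratio_is_lower_bound": ld50.censored,
                    "is_specific_enhancer": call.is_specific,
                }
            )
        prio = pd.DataFrame(prio_rows)
        _write_tsv(prio, out / "prioritization.tsv")
        specific = prio[prio["is_specific_enhancer"]] if len(prio) else prio
        summary.append(f"prioritize: {len(specific)} specific enhancers")

        stage = "cluster"
        if len(specific) >= 3:
            feats = specific.set_index("compound_id")[
                ["ld50_ec50_ratio", "max_treg_enhance", "max_th1_enhance",
                 "max_th17_enhance"]
            ].dropna()
            if len(feats) >= 3 and (feats.std(ddof=1) > 0).all():
                dend = correlation_cluster(standardize_features(feats))
                _write_tsv(dend.merges, out / "pheno_cluster.tsv")
                summary.append(f"cluster: {len(feats)} compounds, "
                               f"{len(dend.merges)} merges")
            else:
                summary.append("cluster: skipped (degenerate features)")
        else:
            summary.append("cluster: skipped (<3 specific enhancers)")

        stage = "signature"
        expr_a, expr_b, expr_truth = generate_expression(
            n_genes=config.n_genes,
            n_per_group=config.n_per_group,
            n_signature=config.n_signature,
            snr_target=config.snr_target,
            seed=config.stage_seed(40),
        )
        write_gct(expr_a, out / "expr_mouse.gct")
        write_gct(expr_b, out / "expr_human.gct")
        red = pca_reduce(expr_a, variance_target=config.variance_target)
        dend_expr = euclidean_cluster(red.scores)
        _write_tsv(dend_expr.merges, out / "expr_cluster.tsv")
        sig = concordant_signature(
            expr_a, expr_b,
            p_threshold=config.p_threshold,
            snr_threshold=config.snr_threshold,
        )
        sig_df = pd.DataFrame(
            {
                "gene_id": [s.gene_id for s in sig],
                "direction": [s.direction for s in sig],
                "snr": [s.snr for s in sig],
            }
        )
        _write_tsv(sig_df, out / "signature.tsv")
        sig_set = GeneSet.from_genes("signature", sig_df["gene_id"])
        write_gmt([sig_set], out / "signature.gmt")
        summary.append(
            f"signature: {len(sig)} genes "
            f"(PCA k={red.k} at {config.variance_target:.0%} variance)"
        )

        stage = "enrich"
        universe, disease = generate_universe(
            n_universe=config.universe_size,
            disease_set_size=config.disease_set_size,
            signature_set=sig_set,
            n_overlap=min(16, len(sig_set)),
            seed=config.stage_seed(50),
        )
        write_gene_list(universe, out / "universe.txt")
        write_gmt([disease], out / "disease.gmt")
        enr = permutation_enrichment(
            sig_set, disease, universe, n_iter=config.n_iter,
            seed=config.stage_seed(60),
        )
        _write_tsv(
            pd.DataFrame([dataclasses.asdict(enr)]), out / "enrichment.tsv"
        )
        summary.append(
            f"enrich: overlap {enr.observed_overlap}, "
            f"fold {enr.fold_enrichment:.2f}, p {enr.p_one_sided:.4g}"
        )
    except Exception as exc:
        (out / "summary.txt").write_text(
            "\n".join(summary + [f"FAILED at stage {stage}: {exc}"]) + "\n",
            encoding="utf-8",
        )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "summary.txt").write_text("\n".join(summary) + "\n", encoding="utf-8")
    logger.info("pipeline run complete: %s", out)
    return out
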