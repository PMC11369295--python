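"""End-to-end orchestration: simulate -> preprocess -> screen -> enrich ->
MR -> replicate, with a JSON run manifest and per-stage TSV outputs.

All thresholds printed in the analysis (screen/MR/replication alpha, the
instrument filter p-value 0.001, the Spearman pruning cutoff 0.9, the 25%
expression filter) are configuration defaults, never hard-coded in stage
logic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortData
from .enrichment import AnnotationSet, correct_terms, fisher_enrichment, summarize_parents
from .io import write_fixtures
from .jointmodel import linear_screen, transcriptome_screen
from .mr import mr_screen, select_instruments
from .preprocess import normalize_expression
from .replication import replication_pipeline
from .simulate import (
    SimConfig,
    make_go_fixture,
    make_known_gene_fixture,
    simulate_cohort,
    simulate_replication_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "annotate_known", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline thresholds and synthetic-cohort settings."""

    alpha_screen: float = 0.05
    alpha_mr: float = 0.05
    alpha_replication: float = 0.05
    p_thresh_filters: float = 0.001
    rho_max: float = 0.9
    min_expr_fraction: float = 0.25
    min_term_size: int = 5
    seed: int = 0
    # synthetic-cohort block
    n_discovery: int = 160
    n_replication: int = 1000
    n_genes: int = 60
    n_snvs_per_gene: int = 4
    n_causal: int = 6
    beta_sat: float = 0.6
    beta_ratio: float = 0.1
    eqtl_r2: float = 0.10
    tau: float = 0.36
    copula_theta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_screen", "alpha_mr", "alpha_replication",
                     "p_thresh_filters", "rho_max", "min_expr_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sim_config(self, n: int, seed_offset: int = 0) -> SimConfig:
        return SimConfig(
            n_samples=n,
            n_genes=self.n_genes,
            n_snvs_per_gene=self.n_snvs_per_gene,
            eqtl_r2=self.eqtl_r2,
            beta_sat=self.beta_sat,
            beta_ratio=self.beta_ratio,
            n_causal=self.n_causal,
            tau=self.tau,
            copula_theta=self.copula_theta,
            seed=self.seed + seed_offset,
        )


def annotate_known(genes, known_lists: dict[str, set[str]]):
    """Case-insensitive overlap of study genes with named known-gene lists.

    Returns ``(table, counts)``: per-gene flags per list plus a pooled
    ``known`` flag, and novel/known counts.
    """
    genes = list(genes)
    if not any(known_lists.values()):
        logger.warning("all known-gene lists are empty; every gene is novel")
    lowered = {name: {g.lower() for g in gs} for name, gs in known_lists.items()}
    table = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for name, gs in lowered.items():
        table[name] = [g.lower() in gs for g in genes]
    pooled = set().union(*lowered.values()) if lowered else set()
    table["known"] = [g.lower() in pooled for g in genes]
    counts = {
        "n_genes": len(genes),
        "known": int(table["known"].sum()),
        "novel": int((~table["known"]).sum()),
    }
    return table, counts


def _stage(manifest, name, t0, **counts):
    elapsed = time.time() - t0
    logger.info("stage %-12s %6.1fs %s", name, elapsed, counts)
    manifest["stages"][name] = {"seconds": round(elapsed, 2), **counts}
    return time.time()


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage on synthetic cohorts and write a report directory.

    Writes per-stage TSVs, a JSON manifest with per-stage counts and timings,
    and a human-readable summary.  Raises RuntimeError naming the failing
    stage on error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    stage = "simulate"
    try:
        t0 = time.time()
        cfg_a = config.sim_config(config.n_discovery)
        cohort_a, eqtl, weights = simulate_cohort(cfg_a)
        cfg_b = config.sim_config(config.n_replication, seed_offset=1)
        cohort_b = simulate_replication_cohort(cfg_b, weights, cohort_a.snv_meta)
        genes = cohort_a.expression.index
        gene2go, ancestors, go_names = make_go_fixture(genes, seed=config.seed)
        known = make_known_gene_fixture(genes, seed=config.seed + 7)
        write_fixtures(cohort_a, outdir / "discovery", eqtl_table=eqtl,
                       gene2go=gene2go, ancestors=ancestors, known_genes=known)
        write_fixtures(cohort_b, outdir / "replication")
        t0 = _stage(manifest, stage, t0,
                    n_discovery=cohort_a.n_samples, n_replication=cohort_b.n_samples,
                    n_genes=len(genes), n_snvs=len(cohort_a.genotypes))

        stage = "preprocess"
        norm = normalize_expression(
            cohort_a.expression, min_fraction=config.min_expr_fraction
        )
        analysis_cohort = CohortData(
            expression=norm.transformed,
            genotypes=cohort_a.genotypes,
            snv_meta=cohort_a.snv_meta,
            phenotypes=cohort_a.phenotypes,
            covariates=cohort_a.covariates,
        )
        t0 = _stage(manifest, stage, t0, genes_kept=len(norm.kept_genes))

        stage = "screen"
        screen, screen_counts = transcriptome_screen(
            analysis_cohort, alpha=config.alpha_screen, pre_transformed=True
        )
        screen.to_csv(outdir / "screen.tsv", sep="\t")
        lin, lin_counts = linear_screen(
            analysis_cohort, alpha=config.alpha_screen, pre_transformed=True
        )
        lin.to_csv(outdir / "screen_linear.tsv", sep="\t")
        t0 = _stage(manifest, stage, t0, copula=screen_counts, linear=lin_counts)

        stage = "enrich"
        assoc = screen.index[
            screen["significant_sat"] | screen["significant_ratio"]
        ]
        ann = AnnotationSet.from_frames(gene2go, ancestors, go_names)
        enrichment_counts = {}
        for label, mask in (
            ("sat", screen["significant_sat"]),
            ("ratio", screen["significant_ratio"]),
        ):
            study = set(screen.index[mask])
            if study:
                rows = fisher_enrichment(study, set(screen.index), ann,
                                         min_term_size=config.min_term_size)
                rows = correct_terms(rows, alpha=config.alpha_screen)
                rows.to_csv(outdir / f"enrichment_{label}.tsv", sep="\t")
                parents = summarize_parents(rows.index[rows["significant"]], ann)
                parents.rename("n_terms").to_csv(
                    outdir / f"enrichment_{label}_parents.tsv", sep="\t"
                )
                enrichment_counts[label] = {
                    "analyzed_terms": int(rows.attrs["n_analyzed_terms"]),
                    "significant_terms": int(rows["significant"].sum()),
                }
            else:
                enrichment_counts[label] = {"analyzed_terms": 0, "significant_terms": 0}
        known_table, known_counts = annotate_known(
            assoc, {"known": set(known["gene_symbol"])}
        )
        known_table.to_csv(outdir / "known_overlap.tsv", sep="\t")
        t0 = _stage(manifest, stage, t0, **enrichment_counts, known=known_counts)

        stage = "mr"
        assoc_map = {
            "sat": list(screen.index[screen["significant_sat"]]),
            "ratio": list(screen.index[screen["significant_ratio"]]),
        }
        mr_results, mr_counts = mr_screen(
            assoc_map, eqtl, analysis_cohort, alpha=config.alpha_mr,
            p_thresh=config.p_thresh_filters, rho_max=config.rho_max,
            seed=config.seed,
        )
        mr_results.to_csv(outdir / "mr.tsv", sep="\t", index=False)
        t0 = _stage(manifest, stage, t0, **mr_counts)

        stage = "replicate"
        instruments = {}
        for _, row in mr_results.loc[mr_results["causal"]].iterrows():
            inst = select_instruments(
                row["gene_id"], row["outcome"], eqtl, analysis_cohort,
                p_thresh=config.p_thresh_filters, rho_max=config.rho_max,
                seed=config.seed,
            )
            if inst is not None:
                instruments[(row["gene_id"], row["outcome"])] = inst
        rep_results, rep_counts = replication_pipeline(
            mr_results, instruments, analysis_cohort, cohort_b,
            alpha=config.alpha_replication, pre_transformed=True,
        )
        rep_results.to_csv(outdir / "replication.tsv", sep="\t", index=False)
        t0 = _stage(manifest, stage, t0, **rep_counts)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    n_assoc = int(len(assoc))
    n_analyzable = sum(c["analyzable"] for c in mr_counts.values())
    n_causal = sum(c["causal"] for c in mr_counts.values())
    manifest["counts"] = {
        "associated": n_assoc,
        "mr_analyzable": n_analyzable,
        "mr_causal": n_causal,
        "replication_investigated": rep_counts["investigated"],
        "replicated": rep_counts["confirmed"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summary = [
        f"adipocop {__version__} pipeline (seed {config.seed})",
        f"associated genes (screen, alpha={config.alpha_screen}): {n_assoc}",
        f"  SAT only {screen_counts['sat_only']}, ratio only "
        f"{screen_counts['ratio_only']}, both {screen_counts['both']}",
        f"MR-analyzable genes: {n_analyzable}; causal at alpha={config.alpha_mr}: {n_causal}",
        f"replication: investigated {rep_counts['investigated']}, "
        f"confirmed {rep_counts['confirmed']} at alpha={config.alpha_replication}",
    ]
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    return outdir
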