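"""End-to-end orchestration of the analysis stages.

A `RunConfig` (loadable from YAML) either points at existing input tables
or requests a synthetic cohort; `run` executes the enabled stages in
order, writes every stage's tables under one output directory and records
a manifest (seeds, config hash, package version) so reruns with the same
config are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as hio
from .actionability import annotate, summarize_cohort
from .cohort_comparison import (MatchSpec, build_matched_cohort,
                                cn_calls_from_fold_change,
                                differential_mutation_test, pool_gene_columns)
from .discovery import (ConsensusNMF, NoNovelClusteringError,
                        characterize_clusters, select_variable_genes)
from .expression import dge, gss, normalize
from .panel import DEFAULT_PANEL, HOUSEKEEPING_GENES
from .signatures import (build_96_catalog, fit_signatures,
                         synthetic_reference_signatures)
from .synth import CohortConfig, generate_cohort, generate_control_pool
from .variant_stats import (compute_tmb, group_mean_test, msi_table_scores,
                            mutation_frequency_table, oncoprint_matrix)
from . import __version__

log = logging.getLogger("hlbc")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    synthetic: bool = True
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)    # paths when not synthetic
    stages: list[str] = field(default_factory=lambda: [
        "variant_stats", "comparison", "expression", "discovery", "actionability",
    ])
    alpha: float = 0.05
    msi_threshold: float = 0.20
    tmb_high_threshold: float = 10.0
    overlap_ari_threshold: float = 0.6
    nmf_k_min: int = 2
    nmf_k_max: int = 6
    nmf_runs: int = 30
    match_target_size: int = 545
    pool_size: int = 5000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        needed_by_stage = {
            "variant_stats": ["variants", "clinical"],
            "comparison": ["variants", "clinical"],
            "expression": ["expression", "clinical"],
            "discovery": ["expression", "clinical"],
            "actionability": ["variants"],
        }
        if not self.synthetic:
            for stage in self.stages:
                for key in needed_by_stage.get(stage, []):
                    if key not in self.inputs:
                        raise ValueError(
                            f"stage {stage!r} enabled but input {key!r} missing"
                        )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: RunConfig, outdir: Path):
    if config.synthetic:
        cohort = generate_cohort(CohortConfig(seed=config.seed))
        hio.write_cohort(cohort, outdir / "inputs")
        return (cohort.samples, cohort.variants, cohort.cn_table,
                cohort.msi_table, cohort.expression)
    paths = config.inputs
    samples = hio.read_clinical(paths["clinical"]) if "clinical" in paths else None
    variants = hio.read_variants(paths["variants"]) if "variants" in paths else None
    cn = hio.read_cn_table(paths["cn"]) if "cn" in paths else None
    msi = hio.read_msi_table(paths["msi"]) if "msi" in paths else None
    expr = (hio.read_expression(paths["expression"])
            if "expression" in paths else None)
    return samples, variants, cn, msi, expr


def run(config: RunConfig, outdir) -> Path:
    """Execute the enabled stages; returns the output directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run start (seed=%s, config=%s)", config.seed, config.digest())
    samples, variants, cn_table, msi_table, expression = _load_inputs(config, outdir)
    report: dict = {"config_hash": config.digest(), "seed": config.seed,
                    "version": __version__, "stages": {}}

    tmb = None
    if "variant_stats" in config.stages:
        tmb = compute_tmb(variants, DEFAULT_PANEL,
                          samples=samples["sample_id"].tolist())
        tmb.to_csv(outdir / "tmb.tsv", sep="\t", index=False)
        msi = msi_table_scores(msi_table, threshold=config.msi_threshold) \
            if msi_table is not None else None
        if msi is not None:
            msi.to_csv(outdir / "msi.tsv", sep="\t", index=False)
        freq = mutation_frequency_table(variants, samples)
        freq.to_csv(outdir / "mutation_frequency.tsv", sep="\t")
        groups = samples.set_index("sample_id")["her2_class"]
        tmb_tests = group_mean_test(tmb.set_index("sample_id")["tmb"], groups)
        tmb_tests.pairs.to_csv(outdir / "tmb_group_tests.tsv", sep="\t",
                               index=False)
        catalog = build_96_catalog(variants)
        pd.Series(catalog, name="count").to_csv(outdir / "catalog96.tsv", sep="\t")
        if catalog.sum() > 0:
            fit = fit_signatures(catalog, synthetic_reference_signatures())
            fit.weights.to_csv(outdir / "signature_weights.tsv", sep="\t")
        report["stages"]["variant_stats"] = {
            "mean_tmb": float(tmb["tmb"].mean()),
            "n_samples": int(len(tmb)),
        }

    if "comparison" in config.stages:
        pool = generate_control_pool(config.pool_size, seed=config.seed + 1)
        spec = MatchSpec(target_size=config.match_target_size,
                         seed=config.seed + 2)
        matched = build_matched_cohort(pool, spec)
        matched.to_csv(outdir / "matched_cohort.tsv", sep="\t", index=False)
        genes = pool_gene_columns(pool)
        flags = oncoprint_matrix(variants, samples, genes=genes).T
        result = differential_mutation_test(flags, matched[genes],
                                            alpha=config.alpha)
        result.table.to_csv(outdir / "differential_mutation.tsv", sep="\t")
        raw, adj = result.spider_counts
        report["stages"]["comparison"] = {"spider_raw": raw, "spider_adj": adj}

    dge_result = None
    norm = None
    if "expression" in config.stages or "discovery" in config.stages:
        norm = normalize(expression, HOUSEKEEPING_GENES)

    if "expression" in config.stages:
        groups = samples.set_index("sample_id")["her2_class"]
        covs = samples.set_index("sample_id")[["er_status", "grade"]]
        dge_result = dge(norm, groups, target="HLBC-1", reference="HLBC-2E",
                         covariates=covs)
        dge_result.table.to_csv(outdir / "dge.tsv", sep="\t")
        # gene sets: planted metagene blocks when synthetic, else user GMT
        gene_sets = {}
        if "gene_sets" in config.inputs:
            gene_sets = hio.read_gene_sets(config.inputs["gene_sets"])
        else:
            for prefix in sorted({g.split("_")[0] for g in norm.genes
                                  if g.startswith("MG")}):
                gene_sets[prefix] = [g for g in norm.genes
                                     if g.startswith(prefix + "_")]
        if gene_sets:
            gss_table = gss(dge_result, gene_sets)
            gss_table.to_csv(outdir / "gss.tsv", sep="\t")
        report["stages"]["expression"] = {
            "n_significant": int((dge_result.table["p_adj"] < config.alpha).sum())
        }

    if "discovery" in config.stages:
        variable = select_variable_genes(norm)
        model = ConsensusNMF(variable,
                             k_range=range(config.nmf_k_min, config.nmf_k_max + 1),
                             n_runs=config.nmf_runs, random_state=config.seed)
        results = model.fit()
        results.summary().to_csv(outdir / "rank_summary.tsv", sep="\t")
        pam50 = samples.set_index("sample_id")["pam50"]
        try:
            selection = results.select_rank(
                pam50, overlap_threshold=config.overlap_ari_threshold)
            chosen = selection.chosen_k
            labels = results[chosen].labels
            labels.to_frame().to_csv(outdir / "cluster_labels.tsv", sep="\t")
            results[chosen].consensus.to_csv(outdir / "consensus.csv")
            selection.table.to_csv(outdir / "rank_selection.tsv", sep="\t")
            cluster_report = characterize_clusters(
                labels, samples, variants=variants, tmb=tmb, cn_table=cn_table)
            (outdir / "cluster_report.md").write_text(cluster_report.to_markdown())
            report["stages"]["discovery"] = {
                "chosen_k": chosen,
                "cophenetic": results[chosen].cophenetic,
            }
        except NoNovelClusteringError as err:
            report["stages"]["discovery"] = {"error": str(err)}

    if "actionability" in config.stages:
        cn_calls = cn_calls_from_fold_change(cn_table) \
            if cn_table is not None else None
        act = annotate(variants, cn_calls,
                       samples=samples["sample_id"].tolist())
        act.alterations.to_csv(outdir / "actionability.tsv", sep="\t",
                               index=False)
        msi = msi_table_scores(msi_table, threshold=config.msi_threshold)
        summary = summarize_cohort(act, tmb if tmb is not None
                                   else compute_tmb(variants, DEFAULT_PANEL,
                                                    samples["sample_id"].tolist()),
                                   msi,
                                   tmb_high_threshold=config.tmb_high_threshold)
        report["stages"]["actionability"] = summary

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("run complete: %s", outdir)
    return outdir
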