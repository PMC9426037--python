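"""Matched-control construction and multi-cohort mutation comparisons.

A control cohort is drawn from a large public-style pool so its ER /
grade composition matches the case series: 90% ER-positive overall, 55%
G3 within the ER-positive stratum and 80% G3 within the ER-negative
stratum (all configurable). Stratum sizes come from largest-remainder
rounding so the target total is hit exactly; sampling within strata is
without replacement and seeded.

Differential-mutation testing is per-gene two-sided Fisher's exact on
2x2 mutated/wild-type tables with BH adjustment across the tested genes;
the "spider" summary counts genes below alpha for both raw and adjusted
p-values. Variant-spectrum comparisons (variant type, classification,
pathogenicity) use Pearson's chi-square with Bonferroni correction over
the family of cohort pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import POOL_CLINICAL_COLUMNS, largest_remainder


@dataclass
class MatchSpec:
    """Target composition of the matched control cohort."""

    er_pos_fraction: float = 0.90
    g3_fraction_in_er_pos: float = 0.55
    g3_fraction_in_er_neg: float = 0.80
    target_size: int = 545
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("er_pos_fraction", "g3_fraction_in_er_pos",
                     "g3_fraction_in_er_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.target_size <= 0:
            raise ValueError(f"target_size must be positive, got {self.target_size}")


def _stratum_counts(spec: MatchSpec) -> dict[tuple[str, bool], int]:
    n_pos, n_neg = largest_remainder(
        spec.target_size, [spec.er_pos_fraction, 1 - spec.er_pos_fraction])
    pos_g3, pos_lo = largest_remainder(
        n_pos, [spec.g3_fraction_in_er_pos, 1 - spec.g3_fraction_in_er_pos])
    neg_g3, neg_lo = largest_remainder(
        n_neg, [spec.g3_fraction_in_er_neg, 1 - spec.g3_fraction_in_er_neg])
    return {("pos", True): pos_g3, ("pos", False): pos_lo,
            ("neg", True): neg_g3, ("neg", False): neg_lo}


def build_matched_cohort(pool: pd.DataFrame, spec: MatchSpec) -> pd.DataFrame:
    """Draw a composition-matched cohort from a pool, without replacement.

    Strata are ER status x (G3 vs lower grade); each stratum contributes
    its largest-remainder share of ``spec.target_size``. Raises when a
    stratum cannot supply its share, naming the stratum and the deficit.
    Deterministic for a given pool and seed.
    """
    for col in ("er_status", "grade"):
        if col not in pool.columns:
            raise ValueError(f"pool lacks required column {col!r}")
    counts = _stratum_counts(spec)
    rng = np.random.default_rng(spec.seed)
    chosen = []
    for (er, is_g3), want in sorted(counts.items()):
        mask = (pool["er_status"] == er) & ((pool["grade"] == "G3") == is_g3)
        stratum = pool.index[mask]
        if len(stratum) < want:
            label = f"ER-{er}/{'G3' if is_g3 else 'G1-G2'}"
            raise ValueError(
                f"stratum {label} has {len(stratum)} samples, needs {want} "
                f"(deficit {want - len(stratum)})"
            )
        chosen.extend(rng.choice(stratum, size=want, replace=False))
    return pool.loc[sorted(chosen)].reset_index(drop=True)


def pool_gene_columns(pool: pd.DataFrame) -> list[str]:
    """Columns of a pool table that are per-gene mutation flags."""
    return [c for c in pool.columns if c not in POOL_CLINICAL_COLUMNS]


@dataclass
class ComparisonResult:
    """Per-gene Fisher comparison between two cohorts plus spider counts."""

    table: pd.DataFrame                 # gene-indexed 2x2 counts, p, p_adj
    alpha: float = 0.05
    skipped_genes: list[str] = field(default_factory=list)

    @property
    def spider_counts(self) -> tuple[int, int]:
        raw = int((self.table["p"] < self.alpha).sum())
        adj = int((self.table["p_adj"] < self.alpha).sum())
        return raw, adj


def differential_mutation_test(ref_flags: pd.DataFrame, ctrl_flags: pd.DataFrame,
                               genes: list[str] | None = None,
                               alpha: float = 0.05) -> ComparisonResult:
    """Two-sided Fisher's exact test per gene between two cohorts.

    ``ref_flags`` / ``ctrl_flags`` are samples x genes 0/1 matrices. Genes
    unmutated in both cohorts have degenerate tables and are excluded from
    the BH family (reported in ``skipped_genes``).
    """
    if len(ref_flags) == 0 or len(ctrl_flags) == 0:
        raise ValueError("both cohorts must be nonempty")
    if genes is None:
        genes = [g for g in ref_flags.columns if g in ctrl_flags.columns]
    missing = [g for g in genes
               if g not in ref_flags.columns or g not in ctrl_flags.columns]
    if missing:
        raise ValueError(f"genes absent from a cohort's columns: {missing}")
    rows, skipped = [], []
    n_a, n_b = len(ref_flags), len(ctrl_flags)
    for gene in genes:
        a_mut = int(ref_flags[gene].sum())
        b_mut = int(ctrl_flags[gene].sum())
        if a_mut == 0 and b_mut == 0:
            skipped.append(gene)
            continue
        table = [[a_mut, n_a - a_mut], [b_mut, n_b - b_mut]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"gene": gene, "a_mut": a_mut, "a_wt": n_a - a_mut,
                     "b_mut": b_mut, "b_wt": n_b - b_mut, "p": float(p)})
    out = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["a_mut", "a_wt", "b_mut", "b_wt", "p", "p_adj"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return ComparisonResult(table=out, alpha=alpha, skipped_genes=skipped)


SPECTRUM_DIMENSIONS = {
    "VT": "variant_type",
    "VC": "variant_classification",
    "pathogenicity": "pathogenicity",
}


def compare_variant_spectra(variants_a: pd.DataFrame, variants_b: pd.DataFrame,
                            dimension: str = "VC",
                            n_comparisons: int = 1) -> dict[str, float]:
    """Pearson chi-square on the category x cohort contingency table.

    ``dimension`` selects variant type (VT), classification (VC) or
    pathogenicity. The Bonferroni factor ``n_comparisons`` is the number
    of cohort-pair comparisons in the family; the corrected p is capped
    at 1.
    """
    if dimension not in SPECTRUM_DIMENSIONS:
        raise ValueError(f"dimension must be one of {sorted(SPECTRUM_DIMENSIONS)}")
    if len(variants_a) == 0 or len(variants_b) == 0:
        raise ValueError("degenerate comparison: a cohort has zero variants")
    col = SPECTRUM_DIMENSIONS[dimension]
    counts = pd.concat([
        variants_a[col].value_counts().rename("a"),
        variants_b[col].value_counts().rename("b"),
    ], axis=1).fillna(0)
    counts = counts[(counts.sum(axis=1) > 0)]
    if len(counts) < 2:
        raise ValueError("need >= 2 categories with nonzero totals")
    if (counts["a"] == counts["b"]).all():
        chi2, p = 0.0, 1.0          # identical distributions, exact null
    else:
        chi2, p, _, _ = stats.chi2_contingency(counts.values, correction=False)
    return {"chi2": float(chi2), "p": float(p),
            "p_bonferroni": float(min(p * n_comparisons, 1.0)),
            "n_categories": int(len(counts))}


def cn_calls_from_fold_change(cn_table: pd.DataFrame, gain_threshold: float = 2.0,
                              loss_threshold: float = 0.5) -> pd.DataFrame:
    """Discretize log10 fold changes into {gain, loss, neutral} calls."""
    fc = np.power(10.0, cn_table["log10_fc"])
    call = np.where(fc >= gain_threshold, "gain",
                    np.where(fc <= loss_threshold, "loss", "neutral"))
    out = cn_table[["sample_id", "gene"]].copy()
    out["call"] = call
    return out


def compare_cn_rates(cn_calls_a: pd.DataFrame, cn_calls_b: pd.DataFrame,
                     gene: str, direction: str = "gain") -> dict[str, float]:
    """Two-sided Fisher on copy-number gain (or loss) prevalence for a gene."""
    if direction not in {"gain", "loss"}:
        raise ValueError("direction must be 'gain' or 'loss'")
    rows = []
    for name, calls in (("a", cn_calls_a), ("b", cn_calls_b)):
        sub = calls[calls["gene"] == gene]
        if len(sub) == 0:
            raise ValueError(f"gene {gene!r} not in cohort {name}'s CN panel")
        rows.append((int((sub["call"] == direction).sum()), len(sub)))
    (a_hit, a_n), (b_hit, b_n) = rows
    _, p = stats.fisher_exact([[a_hit, a_n - a_hit], [b_hit, b_n - b_hit]],
                              alternative="two-sided")
    return {"a_rate": a_hit / a_n, "b_rate": b_hit / b_n, "p": float(p),
            "a_n": a_n, "b_n": b_n}
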