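"""Per-sample and per-group mutation statistics from targeted-panel calls.

TMB is the number of somatic, non-synonymous variants with VAF strictly
above 0.05, divided by the panel's sequenced megabases. Samples with no
qualifying variant are reported with TMB 0, never dropped. The
non-synonymous set is {missense, nonsense, frameshift, inframe_indel,
splice}; whether panel software counts indels varies between vendors —
this implementation includes them.

MSI is the fraction of panel microsatellite loci scored unstable; a
sample is flagged MSI-high when that fraction reaches a configurable
threshold (default 0.20, inclusive — panels report no universal cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel import DEFAULT_PANEL, PanelSpec

NONSYNONYMOUS = {"missense", "nonsense", "frameshift", "inframe_indel", "splice"}
KNOWN_CLASSIFICATIONS = NONSYNONYMOUS | {"synonymous"}

DEFAULT_MSI_THRESHOLD = 0.20
DEFAULT_TMB_VAF_THRESHOLD = 0.05


def compute_tmb(variants: pd.DataFrame, panel: PanelSpec = DEFAULT_PANEL,
                samples: list[str] | None = None,
                vaf_threshold: float = DEFAULT_TMB_VAF_THRESHOLD) -> pd.DataFrame:
    """Tumor mutational burden per sample (mutations / megabase).

    Counts somatic non-synonymous variants with VAF > ``vaf_threshold``
    (strict). ``samples`` fixes the output universe so zero-variant samples
    appear with TMB 0; when omitted, the universe is the samples present in
    the variant table.
    """
    unknown = ~variants["variant_classification"].isin(KNOWN_CLASSIFICATIONS)
    if unknown.any():
        bad = variants.loc[unknown, ["sample_id", "gene", "variant_classification"]]
        raise ValueError(
            f"unknown variant_classification in rows:\n{bad.to_string()}"
        )
    qualifying = variants[
        (variants["origin"] == "somatic")
        & variants["variant_classification"].isin(NONSYNONYMOUS)
        & (variants["vaf"] > vaf_threshold)
    ]
    counts = qualifying.groupby("sample_id").size()
    universe = pd.Index(samples if samples is not None
                        else variants["sample_id"].unique(), name="sample_id")
    counts = counts.reindex(universe, fill_value=0).astype(int)
    return pd.DataFrame({
        "sample_id": universe,
        "n_qualifying_variants": counts.values,
        "tmb": counts.values / panel.panel_mb,
    }).reset_index(drop=True)


def msi_score(locus_calls, threshold: float = DEFAULT_MSI_THRESHOLD
              ) -> tuple[float, bool]:
    """Fraction of unstable microsatellite loci and the MSI-high flag.

    ``locus_calls`` is a sequence of {"stable", "unstable"} for one sample.
    The flag is inclusive: fraction >= threshold.
    """
    calls = list(locus_calls)
    if not calls:
        raise ValueError("empty microsatellite call set")
    bad = set(calls) - {"stable", "unstable"}
    if bad:
        raise ValueError(f"unknown MSI call values: {sorted(bad)}")
    fraction = sum(c == "unstable" for c in calls) / len(calls)
    return fraction, fraction >= threshold


def msi_table_scores(msi_table: pd.DataFrame,
                     threshold: float = DEFAULT_MSI_THRESHOLD) -> pd.DataFrame:
    """Per-sample MSI fraction/flag from a long (sample_id, locus, call) table."""
    rows = []
    for sample_id, sub in msi_table.groupby("sample_id", sort=True):
        fraction, flag = msi_score(sub["call"].tolist(), threshold=threshold)
        rows.append({"sample_id": sample_id, "msi_fraction": fraction,
                     "msi_high": flag})
    return pd.DataFrame(rows)


def mutation_frequency_table(variants: pd.DataFrame, samples: pd.DataFrame,
                             group_by: str = "her2_class",
                             genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene mutated-sample counts and fractions, overall and per group.

    A sample contributes once per gene regardless of how many variants it
    carries there (OncoPrint-style collapsing). Genes are ordered by
    overall frequency, ties broken alphabetically. ``genes`` fixes the row
    index (needed to report all-zero genes).
    """
    sample_index = samples.set_index("sample_id")
    orphans = set(variants["sample_id"]) - set(sample_index.index)
    if orphans:
        raise ValueError(f"variants reference unknown samples: {sorted(orphans)[:5]}")
    if genes is None:
        genes = sorted(variants["gene"].unique())
    pairs = variants[["sample_id", "gene"]].drop_duplicates()
    pairs = pairs.merge(sample_index[[group_by]], left_on="sample_id",
                        right_index=True)
    groups = sorted(sample_index[group_by].unique())
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    n_total = len(sample_index)
    overall = pairs.groupby("gene").size().reindex(genes, fill_value=0)
    out["n_mutated"] = overall.astype(int)
    out["frequency"] = overall / n_total
    for grp in groups:
        denom = int((sample_index[group_by] == grp).sum())
        cnt = (pairs[pairs[group_by] == grp].groupby("gene").size()
               .reindex(genes, fill_value=0))
        out[f"n_{grp}"] = cnt.astype(int)
        out[f"freq_{grp}"] = cnt / denom if denom else 0.0
    return out.sort_values(["frequency", "gene"], ascending=[False, True],
                           kind="mergesort")


def oncoprint_matrix(variants: pd.DataFrame, samples: pd.DataFrame,
                     genes: list[str] | None = None) -> pd.DataFrame:
    """Binary gene x sample mutation matrix (1 = at least one variant)."""
    if genes is None:
        genes = sorted(variants["gene"].unique())
    mat = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                       columns=samples["sample_id"], dtype=int)
    pairs = variants[["sample_id", "gene"]].drop_duplicates()
    for rec in pairs.itertuples(index=False):
        if rec.gene in mat.index:
            mat.loc[rec.gene, rec.sample_id] = 1
    return mat


@dataclass
class GroupMeanTestResult:
    """Welch t-tests between all group pairs plus per-group summaries."""

    group_summary: pd.DataFrame     # mean, sd, n, ci_low, ci_high per group
    pairs: pd.DataFrame             # group_a, group_b, t, p, p_adj per pair


def group_mean_test(values: pd.Series, groups: pd.Series,
                    conf_level: float = 0.95) -> GroupMeanTestResult:
    """Pairwise unequal-variance (Welch) t-tests of a per-sample scalar.

    Per-group 95% confidence intervals use the t distribution
    (mean +/- t_{0.975} * SE). Pairwise p-values are two-sided and
    BH-adjusted across pairs. Zero-variance groups collapse their CI to
    the mean.
    """
    values, groups = values.align(groups, join="inner")
    labels = sorted(groups.unique())
    summary_rows, by_group = [], {}
    for g in labels:
        x = values[groups == g].astype(float).values
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        by_group[g] = x
        se = x.std(ddof=1) / np.sqrt(len(x))
        tq = stats.t.ppf(0.5 + conf_level / 2, df=len(x) - 1)
        summary_rows.append({"group": g, "n": len(x), "mean": x.mean(),
                             "sd": x.std(ddof=1),
                             "ci_low": x.mean() - tq * se,
                             "ci_high": x.mean() + tq * se})
    pair_rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if np.ptp(by_group[a]) == 0 and np.ptp(by_group[b]) == 0 \
                    and by_group[a].mean() == by_group[b].mean():
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(by_group[a], by_group[b],
                                            equal_var=False)
            pair_rows.append({"group_a": a, "group_b": b,
                              "mean_a": by_group[a].mean(),
                              "mean_b": by_group[b].mean(),
                              "t": float(t_stat), "p": float(p)})
    pairs = pd.DataFrame(pair_rows)
    if len(pairs):
        pairs["p_adj"] = multipletests(pairs["p"], method="fdr_bh")[1]
    return GroupMeanTestResult(
        group_summary=pd.DataFrame(summary_rows).set_index("group"),
        pairs=pairs,
    )
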