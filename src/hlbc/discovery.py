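"""Consensus-NMF class discovery with cophenetic rank selection.

The model factorizes a nonnegative genes x samples matrix V ~ W H with
Kullback-Leibler multiplicative updates (Brunet-style, seeded uniform
random initialization) repeatedly under random restarts. Each run assigns
every sample to its dominant metagene (argmax of H); the consensus matrix
records the fraction of runs in which two samples co-cluster. Final
labels come from average-linkage hierarchical clustering of 1 - consensus
cut at K, and clustering stability is the cophenetic correlation between
those dissimilarities and the dendrogram's cophenetic distances.

Rank selection ranks candidate K by cophenetic coefficient but discards
candidates whose clustering reproduces an external subtype labelling
(adjusted Rand index above a threshold) — the point of the procedure is a
classification orthogonal to known intrinsic subtypes, not a restatement
of them.

Usage::

    model = ConsensusNMF(expr_values, k_range=range(2, 7), n_runs=30,
                         random_state=0)
    results = model.fit()
    selection = results.select_rank(external_labels=pam50, overlap_threshold=0.6)
    labels = results[selection.chosen_k].labels
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .expression import ExpressionMatrix

_EPS = np.finfo(float).tiny


def select_variable_genes(expr: ExpressionMatrix,
                          fraction: float = 0.33) -> ExpressionMatrix:
    """Keep the top floor(fraction x n_genes) genes by cross-sample variance.

    Ties in variance are broken lexicographically by gene symbol, making
    the selection deterministic even for constant matrices.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_genes = expr.shape[0]
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    n_keep = int(np.floor(fraction * n_genes))
    var = expr.values.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var, "gene": var.index}).sort_values(
        ["var", "gene"], ascending=[False, True], kind="mergesort")
    keep = order.index[:n_keep]
    return ExpressionMatrix(values=expr.values.loc[keep], state=expr.state)


def _kl_divergence(v: np.ndarray, wh: np.ndarray) -> float:
    wh = np.maximum(wh, _EPS)
    mask = v > 0
    return float((v[mask] * np.log(v[mask] / wh[mask])).sum() - v.sum() + wh.sum())


def nmf_factorize(v: np.ndarray, k: int, seed: int = 0, max_iter: int = 2000,
                  tol: float = 1e-6, track_objective: bool = False):
    """KL-divergence multiplicative-update NMF with seeded uniform init.

    Stops when the relative decrease of the KL objective over a 10-iteration
    window falls below ``tol`` (or the objective is numerically zero), never
    increasing it — multiplicative updates are monotone. Returns ``(W, H)``,
    plus the objective trajectory when ``track_objective``.
    """
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError("input matrix must be nonnegative")
    if not k < min(v.shape):
        raise ValueError(f"rank k={k} must be < min(matrix dims) {min(v.shape)}")
    zero_rows = np.where(~v.any(axis=1))[0]
    zero_cols = np.where(~v.any(axis=0))[0]
    if zero_rows.size or zero_cols.size:
        raise ValueError(
            f"all-zero rows {zero_rows.tolist()[:5]} / columns "
            f"{zero_cols.tolist()[:5]}; filter them before factorizing"
        )
    rng = np.random.default_rng(seed)
    n, m = v.shape
    w = rng.uniform(_EPS, 1.0, size=(n, k))
    h = rng.uniform(_EPS, 1.0, size=(k, m))
    history = []
    prev = _kl_divergence(v, w @ h)
    abs_floor = 1e-12 * max(v.sum(), 1.0)
    for it in range(1, max_iter + 1):
        wh = np.maximum(w @ h, _EPS)
        h *= (w.T @ (v / wh)) / np.maximum(w.sum(axis=0)[:, None], _EPS)
        wh = np.maximum(w @ h, _EPS)
        w *= ((v / wh) @ h.T) / np.maximum(h.sum(axis=1)[None, :], _EPS)
        if track_objective or it % 10 == 0 or it == max_iter:
            obj = _kl_divergence(v, w @ h)
            if track_objective:
                history.append(obj)
            if it % 10 == 0 or it == max_iter:
                if obj <= abs_floor or (prev - obj) <= tol * max(prev, _EPS):
                    break
                prev = obj
    if track_objective:
        return w, h, history
    return w, h


@dataclass
class ConsensusNMFResult:
    """Consensus factorization at one rank K."""

    k: int
    w: np.ndarray                   # genes x K, best-objective run
    h: np.ndarray                   # K x samples, best-objective run
    consensus: pd.DataFrame         # samples x samples co-clustering fractions
    cophenetic: float
    silhouette: float
    labels: pd.Series               # per-sample cluster id in 1..K
    best_objective: float

    def __post_init__(self) -> None:
        c = self.consensus.values
        assert np.allclose(c, c.T), "consensus must be symmetric"
        assert np.allclose(np.diag(c), 1.0), "consensus diagonal must be 1"
        assert c.min() >= 0 and c.max() <= 1 + 1e-12, "consensus entries in [0,1]"


def _consensus_labels(consensus: np.ndarray, k: int) -> tuple[np.ndarray, float, float]:
    """Cut the average-linkage tree of 1 - consensus at K clusters.

    Returns labels, the cophenetic correlation and the mean silhouette
    width on the consensus dissimilarities. A degenerate distance vector
    (all equal, e.g. a perfect one-block consensus) has undefined Pearson
    correlation; it is reported as cophenetic 1.0 — the tree reproduces
    the dissimilarities exactly.
    """
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = average(condensed)
    if np.ptp(condensed) == 0:
        coph = 1.0
    else:
        coph = float(cophenet(z, condensed)[0])
    labels = fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(labels)) > 1:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    else:
        sil = float("nan")
    return labels, coph, sil


class ConsensusNMF:
    """Consensus NMF class-discovery model over a range of ranks.

    Parameters
    ----------
    data : ExpressionMatrix or DataFrame
        Nonnegative genes x samples matrix (typically the most-variable
        genes of a normalized panel).
    k_range : iterable of int
        Candidate numbers of classes (default 2..6).
    n_runs : int
        Random restarts per rank (default 30).
    random_state : int
        Master seed; every restart derives its own child seed from it.
    """

    def __init__(self, data, k_range=range(2, 7), n_runs: int = 30,
                 max_iter: int = 2000, tol: float = 1e-6,
                 random_state: int = 0) -> None:
        values = data.values if isinstance(data, ExpressionMatrix) else data
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(np.asarray(values, dtype=float))
        if (values.values < 0).any():
            raise ValueError("NMF input must be nonnegative")
        self.data = values
        self.k_range = sorted(k_range)
        if n_runs < 2:
            raise ValueError("need n_runs >= 2 for a consensus")
        n_samples = values.shape[1]
        for k in self.k_range:
            if not 2 <= k < n_samples:
                raise ValueError(f"rank {k} outside valid range [2, {n_samples})")
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _run_seed(self, k: int, run: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.random_state, spawn_key=(k, run))

    def fit(self) -> "ConsensusNMFResults":
        v = self.data.values
        samples = self.data.columns
        n = len(samples)
        per_k: dict[int, ConsensusNMFResult] = {}
        for k in self.k_range:
            co_count = np.zeros((n, n))
            best_obj, best_wh = np.inf, None
            for run in range(self.n_runs):
                seed = int(self._run_seed(k, run).generate_state(1)[0] % (2**31))
                w, h = nmf_factorize(v, k, seed=seed, max_iter=self.max_iter,
                                     tol=self.tol)
                assign = h.argmax(axis=0)
                co_count += assign[:, None] == assign[None, :]
                obj = _kl_divergence(v, w @ h)
                if obj < best_obj:
                    best_obj, best_wh = obj, (w, h)
            consensus = co_count / self.n_runs
            np.fill_diagonal(consensus, 1.0)
            labels, coph, sil = _consensus_labels(consensus.copy(), k)
            per_k[k] = ConsensusNMFResult(
                k=k, w=best_wh[0], h=best_wh[1],
                consensus=pd.DataFrame(consensus, index=samples, columns=samples),
                cophenetic=coph, silhouette=sil,
                labels=pd.Series(labels, index=samples, name="cluster"),
                best_objective=best_obj,
            )
        return ConsensusNMFResults(model=self, per_k=per_k)


@dataclass
class RankSelection:
    """Outcome of cophenetic ranking with external-subtype exclusion."""

    table: pd.DataFrame             # k-indexed: cophenetic, overlap_ari, discarded
    chosen_k: int
    overlap_threshold: float


class NoNovelClusteringError(RuntimeError):
    """Every candidate clustering reproduces the external subtyping."""


@dataclass
class ConsensusNMFResults:
    """Fitted consensus factorizations for every candidate rank."""

    model: ConsensusNMF
    per_k: dict[int, ConsensusNMFResult]

    def __getitem__(self, k: int) -> ConsensusNMFResult:
        return self.per_k[k]

    @property
    def k_values(self) -> list[int]:
        return sorted(self.per_k)

    def summary(self) -> pd.DataFrame:
        """Rank-summary table: cophenetic, silhouette, dispersion per K."""
        rows = {}
        for k, res in self.per_k.items():
            c = res.consensus.values
            rows[k] = {
                "cophenetic": res.cophenetic,
                "silhouette": res.silhouette,
                # dispersion: how close consensus entries sit to {0, 1}
                "dispersion": float((4 * (c - 0.5) ** 2).mean()),
                "best_kl": res.best_objective,
            }
        out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        out.index.name = "k"
        return out

    def select_rank(self, external_labels: pd.Series,
                    overlap_threshold: float = 0.6,
                    min_k: int | None = None) -> RankSelection:
        """Choose K: best cophenetic among clusterings not overlapping
        the external labelling (ARI > threshold discards a candidate).

        ``min_k`` optionally also discards ranks below a floor.
        """
        rows = {}
        for k, res in self.per_k.items():
            ext = external_labels.reindex(res.labels.index)
            if ext.isna().any():
                missing = res.labels.index[ext.isna()].tolist()
                raise ValueError(f"external labels missing for {missing[:5]}")
            ari = adjusted_rand_score(ext.astype(str), res.labels)
            discarded = ari > overlap_threshold or (min_k is not None and k < min_k)
            rows[k] = {"cophenetic": res.cophenetic, "overlap_ari": float(ari),
                       "discarded": discarded}
        table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        table.index.name = "k"
        survivors = table[~table["discarded"]]
        if survivors.empty:
            raise NoNovelClusteringError(
                "no novel clustering: every candidate K overlaps the external "
                f"subtyping (ARI > {overlap_threshold})"
            )
        chosen = int(survivors["cophenetic"].idxmax())
        return RankSelection(table=table, chosen_k=chosen,
                             overlap_threshold=overlap_threshold)


# ---------------------------------------------------------------------------
# Downstream cluster characterization


@dataclass
class ClusterReport:
    """Per-cluster genotype/phenotype characterization tables."""

    cluster_sizes: pd.Series
    mutation_tests: pd.DataFrame | None     # cluster, gene, counts, p, p_adj
    scalar_tests: dict[str, pd.DataFrame]   # e.g. tmb / ki67 cluster-vs-rest
    composition: dict[str, pd.DataFrame]    # e.g. pam50 / grade cross-tabs
    erbb2_cn_means: pd.Series | None
    skipped_clusters: list = field(default_factory=list)

    def to_markdown(self) -> str:
        lines = ["# Cluster characterization", ""]
        lines.append("## Cluster sizes\n")
        lines.append(self.cluster_sizes.to_frame("n").to_markdown())
        for name, tab in self.composition.items():
            lines += ["", f"## Composition: {name}", "", tab.to_markdown()]
        for name, tab in self.scalar_tests.items():
            lines += ["", f"## {name}: cluster vs rest", "", tab.to_markdown()]
        if self.mutation_tests is not None and len(self.mutation_tests):
            sig = self.mutation_tests[self.mutation_tests["p_adj"] < 0.05]
            lines += ["", "## Mutation enrichment (BH-adjusted p < 0.05)", "",
                      (sig if len(sig) else self.mutation_tests.head(10)).to_markdown()]
        if self.erbb2_cn_means is not None:
            lines += ["", "## Mean ERBB2 CN fold change (log10)", "",
                      self.erbb2_cn_means.to_frame("mean_log10_fc").to_markdown()]
        if self.skipped_clusters:
            lines += ["", f"(singleton clusters skipped: {self.skipped_clusters})"]
        return "\n".join(lines)


def characterize_clusters(labels: pd.Series, clinical: pd.DataFrame,
                          variants: pd.DataFrame | None = None,
                          tmb: pd.DataFrame | None = None,
                          cn_table: pd.DataFrame | None = None,
                          genes: list[str] | None = None,
                          min_mutated: int = 3) -> ClusterReport:
    """Cluster-versus-rest characterization of a discovered classification.

    Per cluster: mutation-prevalence Fisher tests against the remaining
    samples (BH-adjusted within the report), Welch tests of TMB and Ki67,
    PAM50 / grade composition tables and mean ERBB2 copy-number fold
    change. Singleton clusters are skipped for the statistical tests, with
    a warning.
    """
    from scipy.stats import fisher_exact
    from statsmodels.stats.multitest import multipletests

    from .variant_stats import group_mean_test

    clin = clinical.set_index("sample_id").loc[labels.index]
    sizes = labels.value_counts().sort_index()
    singletons = sizes.index[sizes < 2].tolist()
    if singletons:
        warnings.warn(f"singleton clusters skipped for tests: {singletons}")
    testable = [c for c in sizes.index if c not in singletons]

    composition = {}
    for col in ("pam50", "grade"):
        if col in clin.columns:
            composition[col] = pd.crosstab(labels, clin[col])

    scalar_tests = {}
    cluster_of = labels.astype(str)
    for name, frame in (("tmb", tmb), ("ki67", None)):
        series = None
        if name == "tmb" and frame is not None:
            series = frame.set_index("sample_id")["tmb"].reindex(labels.index)
        elif name == "ki67" and "ki67_pct" in clin.columns:
            series = clin["ki67_pct"]
        if series is None:
            continue
        rows = []
        for c in testable:
            if (labels != c).sum() < 2:
                continue        # complement too small for a Welch test
            grp = pd.Series(np.where(labels == c, "cluster", "rest"),
                            index=labels.index)
            res = group_mean_test(series, grp)
            pair = res.pairs.iloc[0]
            rows.append({"cluster": c, "mean_cluster": pair["mean_a"],
                         "mean_rest": pair["mean_b"], "t": pair["t"],
                         "p": pair["p"]})
        tab = pd.DataFrame(rows)
        if len(tab):
            tab["p_adj"] = multipletests(tab["p"], method="fdr_bh")[1]
        scalar_tests[name] = tab

    mutation_tests = None
    if variants is not None and len(variants):
        pairs = variants[["sample_id", "gene"]].drop_duplicates()
        pairs = pairs[pairs["sample_id"].isin(labels.index)]
        if genes is None:
            freq = pairs.groupby("gene").size()
            genes = freq[freq >= min_mutated].index.tolist()
        rows = []
        for c in testable:
            in_c = labels.index[labels == c]
            n_c, n_r = len(in_c), len(labels) - len(in_c)
            for gene in genes:
                mutated = set(pairs.loc[pairs["gene"] == gene, "sample_id"])
                a = len(mutated & set(in_c))
                b = len(mutated) - a
                _, p = fisher_exact([[a, n_c - a], [b, n_r - b]],
                                    alternative="two-sided")
                rows.append({"cluster": c, "gene": gene, "mut_in": a,
                             "n_in": n_c, "mut_rest": b, "n_rest": n_r,
                             "p": float(p)})
        mutation_tests = pd.DataFrame(rows)
        if len(mutation_tests):
            mutation_tests["p_adj"] = multipletests(mutation_tests["p"],
                                                    method="fdr_bh")[1]

    erbb2 = None
    if cn_table is not None and (cn_table["gene"] == "ERBB2").any():
        sub = cn_table[cn_table["gene"] == "ERBB2"].set_index("sample_id")
        fc = sub["log10_fc"].reindex(labels.index)
        erbb2 = fc.groupby(labels).mean()
        erbb2.index.name = "cluster"

    return ClusterReport(cluster_sizes=sizes, mutation_tests=mutation_tests,
                         scalar_tests=scalar_tests, composition=composition,
                         erbb2_cn_means=erbb2, skipped_clusters=singletons)
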