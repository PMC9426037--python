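import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hlbc.synth import CohortConfig, generate_cohort, generate_control_pool

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def control_pool():
    return generate_control_pool(5000, seed=17)


@pytest.fixture
def small_variants():
    """Hand-written variant table with known TMB/catalog arithmetic."""
    rows = [
        # sample, gene, pchange, vtype, vclass, vaf, origin, patho, context
        ("S1", "PIK3CA", "p.H1047R", "SNV", "missense", 0.20, "somatic",
         "damaging", "A[C>T]G"),
        ("S1", "TP53", "p.R175H", "SNV", "missense", 0.30, "somatic",
         "damaging", "A[C>T]G"),
        ("S1", "GATA3", "p.M1I", "SNV", "missense", 0.25, "somatic",
         "damaging", "T[C>G]A"),
        ("S1", "CDH1", "p.Q23*", "SNV", "nonsense", 0.15, "somatic",
         "nonsense", "C[C>A]C"),
        ("S1", "AKT1", "p.E17K", "SNV", "missense", 0.12, "somatic",
         "potentially_damaging", "G[T>C]G"),
        ("S1", "ESR1", "p.Y537S", "SNV", "synonymous", 0.30, "somatic",
         "tolerated", "A[T>A]A"),
        ("S1", "NF1", "p.L5F", "SNV", "synonymous", 0.30, "somatic",
         "tolerated", "A[T>A]A"),
        ("S1", "KMT2C", "p.G10E", "SNV", "synonymous", 0.30, "somatic",
         "tolerated", "A[T>A]A"),
        ("S1", "MAP3K1", "p.S2P", "SNV", "missense", 0.03, "somatic",
         "tolerated", "A[C>G]T"),
        ("S1", "ERBB2", "p.V777L", "SNV", "missense", 0.04, "somatic",
         "damaging", "A[C>G]T"),
    ]
    return pd.DataFrame(rows, columns=[
        "sample_id", "gene", "protein_change", "variant_type",
        "variant_classification", "vaf", "origin", "pathogenicity", "context96",
    ])


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p.

    Sums the probabilities of every table with the observed margins whose
    point probability does not exceed the observed table's (the
    point-probability method, as in R's fisher.test).
    """
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    denom = comb(n, c1)
    probs = {x: comb(r1, x) * comb(n - r1, c1 - x) / denom
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def bh_stepdown_oracle(p: np.ndarray) -> np.ndarray:
    """Independent Benjamini-Hochberg adjustment with monotonicity."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj_sorted[i] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out
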