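"""96-context substitution catalogs and mutational-signature refitting.

Single-base substitutions are binned into the standard 96 trinucleotide
classes (6 pyrimidine-centered substitutions x 16 flanking contexts,
written ``A[C>T]G``). A per-cohort catalog is refit against a reference
signature matrix by non-negative least squares; weights are renormalized
to mix proportions.

The packaged reference (`synthetic_reference_signatures`) is a synthetic
stand-in for a COSMIC-style catalog: its columns are valid 96-long
probability vectors with recognisable shapes (flat clock-like, CpG
deamination, TpC-peaked APOBEC-like, ...) but they are generated in code,
not copied from the COSMIC release. Any user-supplied 96 x S matrix in the
same layout is accepted by `fit_signatures`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = "ACGT"

#: The 96 trinucleotide substitution classes in canonical order.
CONTEXTS_96: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]

_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}
_CONTEXT_RE = re.compile(r"^[ACGT]\[(C>[AGT]|T>[ACG])\][ACGT]$")


def validate_context(context: str) -> int:
    """Return the catalog index of a context string, or raise ValueError."""
    if not isinstance(context, str) or not _CONTEXT_RE.match(context):
        raise ValueError(f"malformed trinucleotide context: {context!r}")
    return _CONTEXT_INDEX[context]


def build_96_catalog(variants: pd.DataFrame, vaf_threshold: float = 0.1) -> np.ndarray:
    """Bin SNV trinucleotide contexts into a 96-long count vector.

    Only SNVs with VAF strictly above ``vaf_threshold`` enter the catalog;
    insertions/deletions and sub-threshold variants are ignored. The output
    sums to the number of qualifying SNVs.
    """
    catalog = np.zeros(96, dtype=float)
    if len(variants) == 0:
        return catalog
    snvs = variants[
        (variants["variant_type"] == "SNV") & (variants["vaf"] > vaf_threshold)
    ]
    for row_label, context in snvs["context96"].items():
        if pd.isna(context):
            raise ValueError(f"SNV without context96 at row {row_label}")
        try:
            idx = validate_context(context)
        except ValueError as err:
            raise ValueError(f"row {row_label}: {err}") from err
        catalog[idx] += 1
    return catalog


def _peaked_profile(rng: np.random.Generator, peak_indices: list[int],
                    peak_mass: float) -> np.ndarray:
    prof = rng.uniform(0.2, 1.0, size=96)
    prof /= prof.sum()
    prof *= 1.0 - peak_mass
    prof[peak_indices] += peak_mass / len(peak_indices)
    return prof / prof.sum()


def synthetic_reference_signatures(n_signatures: int = 6, seed: int = 7) -> pd.DataFrame:
    """A synthetic 96 x S reference signature matrix (column-normalized).

    Columns are named ``Signature_1 .. Signature_S``. The first columns have
    fixed, interpretable shapes; additional columns are random but seeded.
    This is a stand-in for a curated catalog, intended for simulation and
    testing; substantive analyses should refit against a curated reference.
    """
    rng = np.random.default_rng(seed)
    npcg = [_CONTEXT_INDEX[f"{f}[C>T]G"] for f in BASES]  # CpG deamination
    tpc = [_CONTEXT_INDEX[f"T[C>{alt}]{t}"] for alt in "GT" for t in "AT"]  # APOBEC-like
    profiles = [
        np.full(96, 1.0 / 96.0),              # flat clock-like
        _peaked_profile(rng, npcg, 0.6),      # CpG>TpG-dominated
        _peaked_profile(rng, tpc, 0.7),       # TpC-peaked
    ]
    while len(profiles) < n_signatures:
        peaks = rng.choice(96, size=4, replace=False).tolist()
        profiles.append(_peaked_profile(rng, peaks, 0.5))
    mat = np.column_stack(profiles[:n_signatures])
    cols = [f"Signature_{i + 1}" for i in range(n_signatures)]
    return pd.DataFrame(mat, index=CONTEXTS_96, columns=cols)


@dataclass
class SignatureFit:
    """Mixture weights of reference signatures refit to a catalog."""

    weights: pd.Series        # nonnegative, sums to 1
    residual: float           # L2 residual of the NNLS fit on frequencies
    catalog_n: int            # number of variants in the catalog

    def top_signatures(self, min_weight: float = 0.05) -> pd.Series:
        return self.weights[self.weights >= min_weight].sort_values(ascending=False)


def fit_signatures(catalog: np.ndarray, reference: pd.DataFrame) -> SignatureFit:
    """Non-negative least-squares refit of a 96-catalog on reference signatures.

    The catalog is normalized to frequencies, regressed on the reference
    columns under a nonnegativity constraint, and the solution renormalized
    to mixture proportions.
    """
    catalog = np.asarray(catalog, dtype=float)
    if catalog.shape != (96,):
        raise ValueError("catalog must be a 96-long vector")
    if reference.shape[0] != 96:
        raise ValueError("reference must have 96 rows (trinucleotide contexts)")
    if (reference.values < 0).any():
        raise ValueError("reference signatures must be nonnegative")
    total = catalog.sum()
    if total == 0:
        raise ValueError("empty catalog")
    freq = catalog / total
    coef, residual = nnls(reference.values, freq)
    weight_sum = coef.sum()
    weights = coef / weight_sum if weight_sum > 0 else coef
    return SignatureFit(
        weights=pd.Series(weights, index=reference.columns, name="weight"),
        residual=float(residual),
        catalog_n=int(total),
    )
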