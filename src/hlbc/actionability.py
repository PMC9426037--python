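"""Level-of-evidence annotation of variants and copy-number alterations.

Alterations are matched against a rule table of OncoKB-level / ESCAT-tier
records. A record's pattern is one of: an exact protein change
(``H1047R``), a residue-position range (``542-546``), or an alteration
class (``any_oncogenic_mutation``, ``amplification``, ``deletion``).
Match precedence is exact > range > class; unmatched alterations carry
level "none". A patient is "potentially actionable" when at least one of
their alterations carries any non-none OncoKB level or ESCAT tier.

The packaged default table (`default_loe_table`) is a small synthetic
stand-in for the live OncoKB / ESCAT knowledge bases — a curated handful
of breast-cancer rules sufficient for offline analysis and testing, not a
mirror of either database.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

ONCOKB_LEVELS = {"1", "2", "3A", "3B", "4", "none"}
ESCAT_TIERS = {"IA", "IB", "IC", "IIA", "IIB", "IIIA", "IV", "none"}
PATTERN_TYPES = {"exact", "range", "class"}
ALTERATION_CLASSES = {"any_oncogenic_mutation", "amplification", "deletion"}

_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")
_PROTEIN_POS_RE = re.compile(r"^p\.[A-Z*](\d+)")


def default_loe_table() -> pd.DataFrame:
    """Synthetic OncoKB/ESCAT-style rule table for offline annotation."""
    rows = [
        # gene, pattern, pattern_type, oncokb_level, escat_tier
        ("PIK3CA", "H1047R", "exact", "1", "IA"),
        ("PIK3CA", "E545K", "exact", "1", "IA"),
        ("PIK3CA", "E542K", "exact", "1", "IA"),
        ("PIK3CA", "542-546", "range", "2", "IB"),
        ("PIK3CA", "1043-1049", "range", "2", "IB"),
        ("PIK3CA", "any_oncogenic_mutation", "class", "2", "IIB"),
        ("AKT1", "E17K", "exact", "3A", "IIB"),
        ("ESR1", "any_oncogenic_mutation", "class", "3A", "IIA"),
        ("ERBB2", "310-312", "range", "3A", "IIB"),
        ("ERBB2", "755-781", "range", "3A", "IIB"),
        ("ERBB2", "amplification", "class", "1", "IA"),
        ("BRCA1", "any_oncogenic_mutation", "class", "1", "IA"),
        ("BRCA2", "any_oncogenic_mutation", "class", "1", "IA"),
        ("PALB2", "any_oncogenic_mutation", "class", "3A", "IIA"),
        ("PTEN", "any_oncogenic_mutation", "class", "4", "IIIA"),
        ("PTEN", "deletion", "class", "4", "IIIA"),
        ("FGFR1", "amplification", "class", "3B", "IIIA"),
        ("CCND1", "amplification", "class", "4", "IIIA"),
        ("NF1", "any_oncogenic_mutation", "class", "4", "none"),
    ]
    return pd.DataFrame(rows, columns=["gene", "pattern", "pattern_type",
                                       "oncokb_level", "escat_tier"])


def validate_loe_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a rule table at load time; raises naming the bad record."""
    required = {"gene", "pattern", "pattern_type", "oncokb_level", "escat_tier"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"LoE table missing columns: {sorted(missing)}")
    for idx, rec in table.iterrows():
        if rec["pattern_type"] not in PATTERN_TYPES:
            raise ValueError(f"record {idx}: unknown pattern_type "
                             f"{rec['pattern_type']!r}")
        if rec["pattern_type"] == "range" and not _RANGE_RE.match(rec["pattern"]):
            raise ValueError(f"record {idx}: malformed range pattern "
                             f"{rec['pattern']!r}")
        if rec["pattern_type"] == "class" and rec["pattern"] not in ALTERATION_CLASSES:
            raise ValueError(f"record {idx}: unknown alteration class "
                             f"{rec['pattern']!r}")
        if rec["oncokb_level"] not in ONCOKB_LEVELS:
            raise ValueError(f"record {idx}: unknown OncoKB level "
                             f"{rec['oncokb_level']!r}")
        if rec["escat_tier"] not in ESCAT_TIERS:
            raise ValueError(f"record {idx}: unknown ESCAT tier "
                             f"{rec['escat_tier']!r}")
        if rec["oncokb_level"] == "none" and rec["escat_tier"] == "none":
            raise ValueError(f"record {idx}: record assigns no level at all")
    return table


def _protein_position(protein_change: str) -> int | None:
    m = _PROTEIN_POS_RE.match(protein_change or "")
    return int(m.group(1)) if m else None


def _match_variant(gene: str, protein_change: str,
                   rules: pd.DataFrame) -> pd.Series | None:
    """Best-precedence rule for a variant: exact > range > class."""
    gene_rules = rules[rules["gene"] == gene]
    if gene_rules.empty:
        return None
    short = (protein_change or "").removeprefix("p.")
    exact = gene_rules[(gene_rules["pattern_type"] == "exact")
                       & (gene_rules["pattern"] == short)]
    if len(exact):
        return exact.iloc[0]
    pos = _protein_position(protein_change)
    if pos is not None:
        for _, rec in gene_rules[gene_rules["pattern_type"] == "range"].iterrows():
            lo, hi = map(int, _RANGE_RE.match(rec["pattern"]).groups())
            if lo <= pos <= hi:
                return rec
    cls = gene_rules[(gene_rules["pattern_type"] == "class")
                     & (gene_rules["pattern"] == "any_oncogenic_mutation")]
    if len(cls):
        return cls.iloc[0]
    return None


def _match_cn(gene: str, call: str, rules: pd.DataFrame) -> pd.Series | None:
    wanted = "amplification" if call == "gain" else "deletion"
    hit = rules[(rules["gene"] == gene) & (rules["pattern_type"] == "class")
                & (rules["pattern"] == wanted)]
    return hit.iloc[0] if len(hit) else None


@dataclass
class ActionabilityReport:
    """Per-alteration level assignments and per-patient actionability."""

    alterations: pd.DataFrame       # sample_id, gene, alteration, levels
    per_patient: pd.DataFrame       # sample_id, any_actionable

    @property
    def n_actionable(self) -> int:
        return int(self.per_patient["any_actionable"].sum())


def annotate(variants: pd.DataFrame, cn_calls: pd.DataFrame | None,
             loe_table: pd.DataFrame | None = None,
             samples: list[str] | None = None) -> ActionabilityReport:
    """Annotate somatic variants and CN gains/losses with evidence levels.

    Only somatic, non-synonymous variants are looked up. CN calls use the
    amplification / deletion alteration classes. The result is independent
    of input row order.
    """
    rules = validate_loe_table(loe_table if loe_table is not None
                               else default_loe_table())
    rows = []
    som = variants[(variants["origin"] == "somatic")
                   & (variants["variant_classification"] != "synonymous")]
    for rec in som.itertuples():
        hit = _match_variant(rec.gene, rec.protein_change, rules)
        rows.append({
            "sample_id": rec.sample_id, "gene": rec.gene,
            "alteration": rec.protein_change, "alteration_type": "mutation",
            "oncokb_level": hit["oncokb_level"] if hit is not None else "none",
            "escat_tier": hit["escat_tier"] if hit is not None else "none",
        })
    if cn_calls is not None:
        altered = cn_calls[cn_calls["call"].isin(["gain", "loss"])]
        for rec in altered.itertuples():
            hit = _match_cn(rec.gene, rec.call, rules)
            rows.append({
                "sample_id": rec.sample_id, "gene": rec.gene,
                "alteration": rec.call, "alteration_type": "cna",
                "oncokb_level": hit["oncokb_level"] if hit is not None else "none",
                "escat_tier": hit["escat_tier"] if hit is not None else "none",
            })
    alterations = pd.DataFrame(
        rows, columns=["sample_id", "gene", "alteration", "alteration_type",
                       "oncokb_level", "escat_tier"]
    ).sort_values(["sample_id", "gene", "alteration"]).reset_index(drop=True)
    actionable_flag = ((alterations["oncokb_level"] != "none")
                       | (alterations["escat_tier"] != "none"))
    by_sample = alterations.assign(actionable=actionable_flag) \
        .groupby("sample_id")["actionable"].any()
    universe = pd.Index(samples if samples is not None
                        else alterations["sample_id"].unique(), name="sample_id")
    per_patient = by_sample.reindex(universe, fill_value=False) \
        .rename("any_actionable").reset_index()
    return ActionabilityReport(alterations=alterations, per_patient=per_patient)


def summarize_cohort(report: ActionabilityReport, tmb_results: pd.DataFrame,
                     msi_results: pd.DataFrame,
                     tmb_high_threshold: float = 10.0) -> dict:
    """Cohort-level actionability / TMB-high / MSI-high counts and fractions."""
    ids = set(report.per_patient["sample_id"])
    for name, frame in (("tmb", tmb_results), ("msi", msi_results)):
        extra = set(frame["sample_id"]) - ids
        if extra or len(frame) != len(ids):
            raise ValueError(
                f"{name} results do not match report samples "
                f"(unexpected: {sorted(extra)[:5]})"
            )
    n = len(report.per_patient)
    n_act = report.n_actionable
    n_tmb = int((tmb_results["tmb"] >= tmb_high_threshold).sum())
    n_msi = int(msi_results["msi_high"].sum())
    return {
        "n_patients": n,
        "n_actionable": n_act,
        "fraction_actionable": n_act / n if n else 0.0,
        "n_tmb_high": n_tmb,
        "fraction_tmb_high": n_tmb / n if n else 0.0,
        "n_msi_high": n_msi,
        "fraction_msi_high": n_msi / n if n else 0.0,
        "tmb_high_threshold": tmb_high_threshold,
    }
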