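"""Targeted-panel description: gene content, footprint, MSI loci, CN genes.

The default panel mirrors a TSO500-class assay: 523 genes over 1.94 Mb of
sequenced footprint, 120 microsatellite loci and gene-level copy-number
calls for 59 genes. Real driver symbols cover the breast-cancer genes the
downstream statistics care about; the remainder of the 523 slots are
deterministic filler symbols so panel-wide tables have a full gene index.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Breast-cancer-relevant genes placed at the head of the default panel.
BC_DRIVER_GENES = [
    "PIK3CA", "GATA3", "TP53", "ERBB2", "CDH1", "MAP3K1", "AKT1", "ESR1",
    "KMT2C", "NCOR1", "PTEN", "ARID1A", "RUNX1", "SF3B1", "FOXA1", "CBFB",
    "ERBB3", "BRCA1", "BRCA2", "PALB2", "ATM", "CHEK2", "RB1", "NF1",
    "CCND1", "FGFR1", "FGF3", "FGF4", "FGF19", "MET", "KRAS", "NRG1",
    "MYC", "EGFR", "MDM2", "CDK4", "AURKA", "ZNF703", "PAK1", "RPS6KB1",
    "IGF1R", "FGFR2", "NOTCH1", "SMAD4", "STK11", "APC", "PIK3R1", "MAP2K4",
    "TBX3", "CTCF", "GPS2", "KMT2D", "SPEN", "NBN", "BARD1", "RAD51C",
    "RAD51D", "MLH1", "MSH2",
]

#: Genes with copy-number calls on the default panel (59 genes).
DEFAULT_CN_GENES = BC_DRIVER_GENES[:59]

#: Housekeeping genes used for expression normalization (stably expressed).
HOUSEKEEPING_GENES = [
    "ACTB", "GAPDH", "GUSB", "MRPL19", "PSMC4", "PUM1", "RPLP0", "SF3A1",
    "TBP", "TFRC",
]


def _filler_symbols(n: int, prefix: str = "PNL") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def default_gene_list(n_genes: int = 523) -> list[str]:
    """523 panel symbols: real drivers first, deterministic filler after."""
    core = BC_DRIVER_GENES[:n_genes]
    return core + _filler_symbols(n_genes - len(core))


@dataclass(frozen=True)
class PanelSpec:
    """Sequencing-panel description used by TMB, MSI and CN computations.

    Parameters
    ----------
    gene_list : list of str
        Symbols covered by the panel (default 523).
    panel_mb : float
        Sequenced footprint in megabases; TMB denominators use this.
    msi_loci : int
        Number of microsatellite loci scored for instability.
    cn_genes : list of str
        Subset of ``gene_list`` with gene-level copy-number calls.
    """

    gene_list: list[str] = field(default_factory=default_gene_list)
    panel_mb: float = 1.94
    msi_loci: int = 120
    cn_genes: list[str] = field(default_factory=lambda: list(DEFAULT_CN_GENES))

    def __post_init__(self) -> None:
        if self.panel_mb <= 0:
            raise ValueError("panel_mb must be positive")
        if self.msi_loci <= 0:
            raise ValueError("msi_loci must be positive")
        missing = set(self.cn_genes) - set(self.gene_list)
        if missing:
            raise ValueError(
                f"cn_genes must be a subset of gene_list; not covered: {sorted(missing)}"
            )


DEFAULT_PANEL = PanelSpec()
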