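"""Reference tagSNP panel and cohort margins used as simulation defaults.

The panel bundles 16 published tagSNPs (with their control genotype
counts) from an 18-gene candidate pathway, padded with synthetic null
tagSNPs to the full 184-SNP design. The demographics block carries the
published case/control category counts used to parameterize the default
covariate model of the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PanelSnp",
    "REFERENCE_SNPS",
    "PATHWAY_GENES",
    "N_PANEL_SNPS",
    "DEMOGRAPHICS",
    "N_CASES",
    "N_CONTROLS",
    "default_panel",
]


@dataclass(frozen=True)
class PanelSnp:
    snp_id: str
    gene: str
    control_counts: tuple[int, int, int] | None  # (n_AA, n_Aa, n_aa), None if synthetic
    control_maf: float


def _maf(counts: tuple[int, int, int]) -> float:
    n_aa_major, n_het, n_aa_minor = counts
    return (n_het + 2 * n_aa_minor) / (2 * sum(counts))


# (snp_id, gene, control genotype counts AA/Aa/aa)
_REFERENCE_ROWS: tuple[tuple[str, str, tuple[int, int, int]], ...] = (
    ("rs11757379", "BAK1", (642, 390, 54)),
    ("rs1058696", "IGF1R", (998, 90, 0)),
    ("rs12591122", "IGF1R", (824, 250, 14)),
    ("rs4966015", "IGF1R", (771, 276, 41)),
    ("rs702497", "IGF1R", (645, 366, 73)),
    ("rs7166348", "IGF1R", (670, 355, 62)),
    ("rs2604235", "TP53AIP1", (463, 473, 149)),
    ("rs1942919", "PMAIP1", (353, 509, 224)),
    ("rs7240884", "PMAIP1", (477, 471, 138)),
    ("rs1509476", "SERPINB5", (614, 405, 69)),
    ("rs1509478", "SERPINB5", (450, 493, 139)),
    ("rs6567355", "SERPINB5", (552, 435, 93)),
    ("rs12489753", "TP63", (934, 146, 7)),
    ("rs13321831", "TP63", (927, 155, 6)),
    ("rs6779677", "TP63", (347, 547, 194)),
    ("rs3765731", "TP73", (544, 446, 96)),
)

REFERENCE_SNPS: tuple[PanelSnp, ...] = tuple(
    PanelSnp(snp_id, gene, counts, _maf(counts))
    for snp_id, gene, counts in _REFERENCE_ROWS
)

PATHWAY_GENES: tuple[str, ...] = (
    "TP53",
    "TP63",
    "TP73",
    "BAK1",
    "BAX",
    "BBC3",
    "BIRC5",
    "CDKN1A",
    "FAS",
    "GADD45A",
    "IGF1R",
    "MDM2",
    "MYC",
    "PCNA",
    "PMAIP1",
    "SERPINB5",
    "SFN",
    "TP53AIP1",
)

N_PANEL_SNPS = 184

#: Cohort design sizes.
N_CASES = 1058
N_CONTROLS = 1138

#: Published case/control category counts (cases, controls) per level.
DEMOGRAPHICS: dict[str, dict[str, tuple[int, int]]] = {
    "gender": {
        "male": (920, 991),
        "female": (138, 147),
    },
    "age_group": {
        "<55": (149, 181),
        "55-64": (222, 278),
        "65-69": (241, 263),
        "70-74": (225, 222),
        "75+": (221, 194),
    },
    "region": {
        "barcelona": (214, 233),
        "valles": (173, 181),
        "elche": (83, 80),
        "tenerife": (195, 207),
        "asturias": (393, 437),
    },
    "smoking": {
        "never": (147, 334),
        "occasional": (43, 81),
        "former": (409, 429),
        "current": (454, 283),
    },
}

#: Samples with unreported smoking status (cases, controls).
SMOKING_MISSING: tuple[int, int] = (5, 11)

# MAFs cycled over the synthetic filler SNPs; spread over the common range.
_FILLER_MAFS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)


def default_panel(n_snps: int = N_PANEL_SNPS) -> list[PanelSnp]:
    """Reference SNPs padded with null filler tagSNPs to ``n_snps``.

    Filler SNPs are deterministic: ids ``tag017`` ... with genes cycled
    over the pathway and MAFs cycled over a fixed common-range grid.
    """
    if n_snps < len(REFERENCE_SNPS):
        return list(REFERENCE_SNPS[:n_snps])
    panel = list(REFERENCE_SNPS)
    for i in range(len(REFERENCE_SNPS), n_snps):
        panel.append(
            PanelSnp(
                snp_id=f"tag{i + 1:03d}",
                gene=PATHWAY_GENES[i % len(PATHWAY_GENES)],
                control_counts=None,
                control_maf=_FILLER_MAFS[i % len(_FILLER_MAFS)],
            )
        )
    return panel
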