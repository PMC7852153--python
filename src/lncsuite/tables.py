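"""Published worked examples: the DE-lncRNA table and the cis-target table.

These are the printed result tables of the porcine adipogenic-vs-myogenic
precursor comparison the pipeline reimplements, kept here as structured data
so the calling rules can be replayed against them: 24 differentially
expressed lncRNAs with fold change (Myo/Adi) and adjusted p, and the cis
target genes of the DE lncRNAs with genomic relationship and Pearson
correlation index. Fold changes ≥ 2 are the 'up' block, ≤ 0.5 the 'down'
block of the source table; exon sizes are in nt.
"""

from __future__ import annotations

import pandas as pd

from .diffexpr import call_de, de_summary

# id, fold change, adjusted p, chromosome, strand, exon count, exon sizes
_DE_LNCRNAS = [
    ("XLOC_021529", 6.29, 1.92e-09, "Chr1", "+", 2, (29, 202)),
    ("XLOC_012932", 2.42, 2.37e-06, "Chr9", "-", 1, (1077,)),
    ("XLOC_079751", 2.94, 0.000142, "Chr14", "-", 2, (190, 127)),
    ("XLOC_090236", 2.04, 0.009776, "Chr15", "+", 2, (17, 184)),
    ("XLOC_001307", 3.13, 0.010441, "Chr7", "+", 3, (156, 104, 1671)),
    ("XLOC_164011", 2.98, 0.015133, "Chr6", "+", 1, (259,)),
    ("XLOC_189646", 2.28, 0.025817, "Chr8", "+", 2, (361, 114)),
    ("XLOC_091324", 2.70, 0.028678, "Chr15", "-", 1, (304,)),
    ("XLOC_165070", 2.68, 0.035623, "Chr6", "-", 2, (21, 131)),
    ("XLOC_062039", 0.46, 0.000132, "Chr13", "+", 2, (592, 149)),
    ("XLOC_023175", 0.32, 0.001145, "Chr1", "-", 2, (229, 210)),
    ("XLOC_118825", 0.35, 0.003995, "Chr2", "-", 2, (164, 431)),
    ("XLOC_155509", 0.30, 0.010121, "Chr5", "-", 2, (1113, 182)),
    ("XLOC_021811", 0.36, 0.010917, "Chr1", "+", 2, (1110, 783)),
    ("XLOC_189950", 0.38, 0.014067, "Chr8", "+", 3, (114, 114, 295)),
    ("XLOC_108084", 0.42, 0.016205, "Chr17", "-", 1, (207,)),
    ("XLOC_189516", 0.32, 0.017106, "Chr8", "+", 2, (52, 194)),
    ("XLOC_190244", 0.35, 0.019752, "Chr8", "-", 2, (10531, 747)),
    ("XLOC_118028", 0.41, 0.019867, "Chr2", "+", 2, (20801, 239)),
    ("XLOC_119417", 0.45, 0.020062, "Chr2", "-", 3, (1785, 113, 121)),
    ("XLOC_154508", 0.36, 0.023445, "Chr5", "+", 2, (427, 144)),
    ("XLOC_155480", 0.36, 0.025117, "Chr5", "-", 2, (221, 42)),
    ("XLOC_178755", 0.43, 0.049905, "Chr7", "+", 2, (662, 136)),
    ("XLOC_190092", 0.41, 0.049938, "Chr8", "-", 2, (1858, 188)),
]

# lncRNA, lnc FC, gene, symbol, gene FC, relationship, correlation index
_CIS_TARGETS = [
    ("XLOC_021529", 6.29, "ENSSSCG00000005087", "SIX1", 1.94, "Downstream:23,747", 0.96),
    ("XLOC_079751", 2.94, "ENSSSCG00000009880", "SLC8B1", 1.12, "Overlap", 0.61),
    ("XLOC_164011", 2.98, "ENSSSCG00000003102", "PNMA8A", 0.60, "Upstream:22,659", -0.91),
    ("XLOC_189646", 2.28, "ENSSSCG00000021506", "", 3.21, "Downstream:72,987", 0.88),
    ("XLOC_165070", 2.68, "ENSSSCG00000026699", "ZNF180", 1.06, "Downstream:41,893", 0.72),
    ("XLOC_062039", 0.46, "ENSSSCG00000011496", "ADAMTS9", 0.45, "Overlap", 0.98),
    ("XLOC_023175", 0.32, "ENSSSCG00000005751", "COL5A1", 0.75, "Overlap", 0.64),
    ("XLOC_155509", 0.30, "ENSSSCG00000000837", "CHST11", 0.98, "Overlap", 0.78),
    ("XLOC_021811", 0.36, "ENSSSCG00000005491", "ATP6V1G1", 1.08, "Downstream:17,273", -0.88),
    ("XLOC_021811", 0.36, "ENSSSCG00000005492", "TMEM268", 0.88, "Overlap", 0.76),
    ("XLOC_189950", 0.38, "ENSSSCG00000009230", "WDFY3", 0.71, "Overlap", 0.91),
    ("XLOC_108084", 0.42, "ENSSSCG00000007391", "MATN4", 1.67, "Upstream:6245", -0.70),
    ("XLOC_189516", 0.32, "ENSSSCG00000008725", "CYTL1", 0.88, "Downstream:15,131", 0.90),
    ("XLOC_118028", 0.41, "ENSSSCG00000029992", "NAV2", 0.55, "Overlap", 0.98),
    ("XLOC_119417", 0.45, "ENSSSCG00000024043", "ADAMTS2", 0.80, "Intron", 0.83),
    ("XLOC_154508", 0.36, "ENSSSCG00000000191", "KMT2D", 0.56, "Downstream:27,338", 0.65),
    ("XLOC_155480", 0.36, "ENSSSCG00000030685", "ARID2", 0.77, "Intron", 0.64),
    ("XLOC_178755", 0.43, "ENSSSCG00000002526", "RCOR1", 0.67, "Overlap", 0.99),
]


def de_lncrna_table() -> pd.DataFrame:
    """The 24 published DE lncRNAs: fold change, adjusted p, structure."""
    df = pd.DataFrame(
        _DE_LNCRNAS,
        columns=["feature_id", "fold_change", "q", "chrom", "strand", "n_exons", "exon_sizes"],
    )
    return df.set_index("feature_id")


def cis_target_table() -> pd.DataFrame:
    """The published cis-target pairs of the DE lncRNAs."""
    return pd.DataFrame(
        _CIS_TARGETS,
        columns=[
            "lncrna_id", "lnc_fold_change", "gene_id", "gene_symbol",
            "gene_fold_change", "relationship", "correlation_index",
        ],
    )


def replay_de_calls(fc_up: float = 2.0, fc_down: float = 0.5, alpha: float = 0.05):
    """Run the DE calling rule over the published (fold change, q) pairs.

    Returns (called table, summary dict with n_up/n_down/n_total)."""
    called = call_de(de_lncrna_table(), fc_up=fc_up, fc_down=fc_down, alpha=alpha)
    return called, de_summary(called)


def replay_cis_rule(r_min: float = 0.6) -> pd.DataFrame:
    """Apply the strict |r| > r_min acceptance rule to the published
    correlation indices; adds an ``accepted`` column."""
    df = cis_target_table()
    df["accepted"] = df["correlation_index"].abs() > r_min
    return df
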