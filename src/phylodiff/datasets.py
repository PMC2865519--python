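"""Published summary tables of the validation cohorts.

These are the printed per-subtype sample counts, differential-expression
tallies, the adipogenesis gene panel with its fold changes, and the
transcribed liposarcoma consensus topology from the public leukemia,
breast-cancer and sarcoma expression compendia used to validate the
method (GEO series GSE1159, GSE9476, GSE1729, GSE12417, GSE7390, GSE2990,
GSE3494, GSE9574, GSE7332).  They serve as small worked-example inputs;
the raw expression data itself is not shipped.
"""

from __future__ import annotations

__all__ = [
    "ADIPOGENESIS_GENE_PANEL",
    "AML_SUBTYPE_SAMPLES",
    "BREAST_TUMOR_SUBGROUP_SAMPLES",
    "DE_PROBE_COUNTS",
    "LIPOSARCOMA_CONSENSUS_NEWICK",
    "LIPOSARCOMA_SUBTYPE_SAMPLES",
    "SARCOMA_SUBTYPE_SAMPLES",
    "published_sweep_grid",
    "total_samples",
]

#: AML subtypes in FAB order (M0..M6) with per-subtype sample counts.
AML_SUBTYPE_SAMPLES: dict[str, int] = {
    "M0 dedifferentiated": 14,
    "M1 myeloblastic": 78,
    "M2 myeloblastic with maturation": 78,
    "M3 promyelocytic": 29,
    "M4 myelomonocytic": 75,
    "M5 monocytic": 78,
    "M6 erythroleukemic": 10,
}

#: Breast tumor subgroups (ER status x Elston grade); normal tissue excluded.
BREAST_TUMOR_SUBGROUP_SAMPLES: dict[str, int] = {
    "ER- G3": 76,
    "ER- G2": 27,
    "ER- G1": 3,
    "ER+ G3": 84,
    "ER+ G2": 179,
    "ER+ G1": 114,
}

#: The five liposarcoma subtypes.
LIPOSARCOMA_SUBTYPE_SAMPLES: dict[str, int] = {
    "dedifferentiated": 61,
    "well-differentiated": 52,
    "pleomorphic": 26,
    "round-cell": 18,
    "myxoid": 23,
}

#: The full sarcoma cohort (liposarcomas plus lipoma, leiomyosarcoma,
#: malignant fibrous histiocytoma and myxofibrosarcoma).
SARCOMA_SUBTYPE_SAMPLES: dict[str, int] = {
    **LIPOSARCOMA_SUBTYPE_SAMPLES,
    "lipoma": 7,
    "leiomyosarcoma": 23,
    "MFH": 5,
    "myxofibrosarcoma": 36,
}

#: Published counts of differentially expressed probe sets per cohort and
#: correction (ANOVA, adjusted p < 0.01).
DE_PROBE_COUNTS: dict[str, int] = {
    "aml_bh_0.01": 11105,
    "aml_holm_0.01": 4051,
    "breast_bh_0.01": 17966,
    "liposarcoma_bh_0.01": 13429,
    "liposarcoma_holm_0.01": 7290,
}

#: Adipogenesis-related gene panel: (symbol, linear fold change between
#: mesenchymal stem cells and normal fat, log2 ratio), fold-ranked.
ADIPOGENESIS_GENE_PANEL: list[tuple[str, float, float]] = [
    ("FABP4", 352.1, 8.46),
    ("LPL", 164.3, 7.36),
    ("ADH1B", 150.1, 7.23),
    ("HBA/B", 147.0, 7.20),
    ("ADIPOQ", 137.2, 7.14),
    ("RBP4", 104.0, 6.70),
    ("GOS2", 85.6, 6.42),
    ("FOS", 78.3, 6.29),
    ("SORBS1", 72.0, 6.17),
    ("PLIN", 68.1, 6.09),
    ("PRKAR2B", 53.1, 5.73),
    ("CHRDL1", 52.0, 5.70),
    ("APOD", 49.9, 5.64),
    ("PPP1R1A", 41.4, 5.37),
    ("GHR", 41.4, 5.37),
    ("AOC3", 40.8, 5.35),
    ("CLEC3B", 38.1, 5.25),
    ("DPT", 37.0, 5.21),
    ("NTRK2", 36.5, 5.19),
    ("PALMD", 34.1, 5.09),
    ("ACACB", 32.2, 5.01),
    ("LEP", 28.8, 4.85),
    ("VWF", 28.1, 4.81),
    ("TIMP4", 26.7, 4.74),
    ("COL11A1", -11.7, -3.55),
]

#: Consensus topology of the liposarcoma phylogeny, rooted with human
#: mesenchymal stem cells (hMSC) and including normal fat as the
#: differentiated reference: a caterpillar in which dedifferentiated
#: liposarcoma branches first and well-differentiated last.
LIPOSARCOMA_CONSENSUS_NEWICK: str = (
    "(hMSC,(dedifferentiated,(pleomorphic,(myxoid,"
    "(round-cell,(well-differentiated,normal_fat))))));"
)


def total_samples(counts: dict[str, int]) -> int:
    """Total cohort size from a per-subtype count table."""
    return sum(counts.values())


def published_sweep_grid():
    """The parameter grid of the systematic methods comparison.

    Three DE tests, two corrections, two cutoffs, five tree methods (the
    four built-ins plus a balanced-minimum-evolution plugin slot) and two
    metrics: 120 configurations.
    """
    from .pipeline import SweepGrid

    return SweepGrid(
        tests=["anova", "kruskal_wallis", "welch"],
        corrections=["bh", "holm"],
        alphas=[0.01, 0.05],
        tree_methods=["wls", "me", "nj", "upgma"],
        metrics=["pearson", "euclidean"],
        plugin_methods={"balanced_me": None},
    )
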