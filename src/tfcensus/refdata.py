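"""Reference census numbers for the 19 prokaryotic TF families.

Printed summary values from the published 761-genome survey this package
reanalyzes.  They serve as default catalogs, fixed group memberships and
desk-check inputs; nothing here is computed at import time.
"""

from __future__ import annotations

#: The 19 DNA-binding TF families, in descending published correlation order.
FAMILIES: tuple[str, ...] = (
    "PhoB", "GerE", "GntR", "MarR", "SinR", "ArsR", "TetR/AcrR", "LysR",
    "AraC/XylS", "Crp", "Lrp", "LexA", "IclR", "GalR/LacI", "Fur", "Fis",
    "BirA", "ArgR", "TrmB",
)

#: Published total TF count per family over the 761-genome dataset.
FAMILY_TOTALS: dict[str, int] = {
    "PhoB": 4948,
    "GerE": 6074,
    "GntR": 6639,
    "MarR": 6305,
    "SinR": 5939,
    "ArsR": 3314,
    "TetR/AcrR": 12097,
    "LysR": 11610,
    "AraC/XylS": 6860,
    "Crp": 2264,
    "Lrp": 4119,
    "LexA": 611,
    "IclR": 1323,
    "GalR/LacI": 3504,
    "Fur": 1428,
    "Fis": 4143,
    "BirA": 1076,
    "ArgR": 485,
    "TrmB": 746,
}

#: Published grand total of TF proteins (equals sum(FAMILY_TOTALS.values())).
GRAND_TOTAL: int = 83485

#: Dataset bookkeeping: non-redundant genomes analyzed.
N_GENOMES: int = 761
N_BACTERIA: int = 672
N_ARCHAEA: int = 89

#: Genomes per lifestyle class in the published dataset.
LIFESTYLE_COUNTS: dict[str, int] = {
    "free-living": 368,
    "pathogen": 187,
    "extremophile": 158,
    "intracellular": 48,
}

#: Fixed default membership of the four published abundance groups.
ABUNDANCE_GROUPS: dict[int, frozenset[str]] = {
    1: frozenset({"LysR", "TetR/AcrR"}),
    2: frozenset({"AraC/XylS", "GntR", "MarR", "GerE", "PhoB", "SinR"}),
    3: frozenset({"Lrp", "Fis", "GalR/LacI", "ArsR"}),
    4: frozenset({"ArgR", "Fur", "LexA", "IclR", "Crp", "BirA", "TrmB"}),
}

#: Published number of distinct companion domains per family.
CD_COUNTS: dict[str, int] = {
    "PhoB": 72, "GerE": 96, "GntR": 76, "MarR": 126, "SinR": 133,
    "ArsR": 86, "TetR/AcrR": 70, "LysR": 24, "AraC/XylS": 106, "Crp": 53,
    "Lrp": 126, "LexA": 36, "IclR": 80, "GalR/LacI": 25, "Fur": 14,
    "Fis": 65, "BirA": 58, "ArgR": 22, "TrmB": 84,
}

#: Published distinct-CD total across all families (not the column sum).
DISTINCT_CDS_TOTAL: int = 457

#: Published mean companion-domain length (mean, sd) in amino acids.
CD_MEAN_LENGTHS: dict[str, tuple[float, float]] = {
    "PhoB": (136.08, 42.06), "GerE": (134.32, 43.21), "GntR": (188.69, 91.35),
    "MarR": (149.56, 72.11), "SinR": (126.99, 62.05), "ArsR": (138.97, 56.56),
    "TetR/AcrR": (111.91, 25.01), "LysR": (201.09, 15.79),
    "AraC/XylS": (136.78, 52.77), "Crp": (133.14, 31.75),
    "Lrp": (109.55, 51.13), "LexA": (119.99, 31.21), "IclR": (164.31, 44.13),
    "GalR/LacI": (258.52, 32.84), "Fur": (84.50, 71.21), "Fis": (192.78, 53.01),
    "BirA": (121.56, 62.46), "ArgR": (84.42, 38.25), "TrmB": (139.84, 69.73),
}

#: Published per-family enriched-CD counts (adjusted p <= 1e-10).
ENRICHED_CD_COUNTS: dict[str, int] = {
    "PhoB": 8, "GerE": 24, "GntR": 9, "MarR": 30, "SinR": 35, "ArsR": 21,
    "TetR/AcrR": 4, "LysR": 1, "AraC/XylS": 46, "Crp": 4, "Lrp": 30,
    "LexA": 6, "IclR": 11, "GalR/LacI": 1, "Fur": 1, "Fis": 20, "BirA": 9,
    "ArgR": 2, "TrmB": 19,
}

#: Published Pearson R between family abundance and genome size (ORFs).
PEARSON_R: dict[str, float] = {
    "PhoB": 0.73, "GerE": 0.71, "GntR": 0.71, "MarR": 0.69, "SinR": 0.65,
    "ArsR": 0.65, "TetR/AcrR": 0.65, "LysR": 0.62, "AraC/XylS": 0.61,
    "Crp": 0.61, "Lrp": 0.60, "LexA": 0.53, "IclR": 0.51, "GalR/LacI": 0.51,
    "Fur": 0.50, "Fis": 0.47, "BirA": 0.47, "ArgR": 0.17, "TrmB": 0.12,
}
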