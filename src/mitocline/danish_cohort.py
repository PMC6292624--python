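"""Published summary counts from a nationwide Danish birth cohort.

These are the printed haplogroup tallies of a registry-based survey of 24,216
mtDNA-haplotyped Danish newborns (birth years 1981-2005; 418 array-typed mtDNA
SNPs). The raw genotypes are registry-protected, so these aggregate tables are
the quantitative anchor of the package: they parameterize the default
synthetic-cohort model (:func:`mitocline.simulate.denmark_model`) and serve as
worked-example inputs for the frequency statistics.

All counts are sample tallies; percentages in the source tables are per-column
(region) or per-period and are recomputed here rather than stored.
"""

from __future__ import annotations

__all__ = [
    "MACRO_COUNTS",
    "R_HG_COUNTS",
    "SUBHG_COUNTS",
    "N_HG_COUNTS",
    "M_HG_COUNTS",
    "REGIONS",
    "REGIONAL_COUNTS",
    "REGIONAL_TOTALS",
    "PERIOD_COUNTS",
    "PERIOD_TOTALS",
    "PERIODS",
    "SUBHG_BINS",
    "N_COMPARISON_GROUPS",
]

# Macro-haplogroup distribution among the 24,216 haplotyped samples.
MACRO_COUNTS = {
    "L0": 26, "L1": 13, "L2": 54, "L3": 71, "L4": 16, "L5": 2, "L6": 0,
    "M": 394, "N": 1700, "R": 21940,
}

# Haplogroups within the R macro-haplogroup (21,836 resolved).
R_HG_COUNTS = {
    "H": 10912, "U": 3237, "T": 2323, "J": 2195, "K": 1754,
    "V": 785, "R": 570, "F": 50, "B": 10,
}

# Sub-haplogroup distributions (merged reporting bins as printed).
SUBHG_COUNTS = {
    "H": {
        "H": 3924, "H1-H30b-H79a": 4054, "H2": 1058, "H3": 699,
        "H4": 220, "H5-36": 828,
    },
    "U": {
        "U": 120, "U1": 66, "U2-U3": 596, "U4-9": 603, "U5a": 1113,
        "U5b": 471, "U6": 26, "U7": 87, "U8": 90,
    },
    "K": {"K": 1, "K1": 1385, "K2": 307, "K3": 1},
    "J": {"J": 2, "J1": 1686, "J2": 407},
    "T": {"T*": 9, "T1": 396, "T2": 1908},
}

# Haplogroups within the N and M macro-haplogroups.
N_HG_COUNTS = {
    "A": 119, "I": 655, "N": 55, "N1-5": 111, "N2": 11,
    "W": 319, "X": 394, "Y": 6,
}
M_HG_COUNTS = {
    "C": 40, "D4": 53, "D5": 4, "D6": 2, "E": 8, "G": 10, "M": 81,
    "M1": 30, "M2": 11, "M3": 24, "M30": 14, "M4": 3, "M5": 26,
    "M6": 9, "M7": 37, "M8a": 7, "M9": 4, "Z": 11,
}

# Regional distribution (five administrative regions; birth locations with
# >= 20 births). Rows mix reporting levels as printed: H..X are haplogroup
# bins, L and M are whole macro-haplogroups, "NA" is unassignable.
REGIONS = ("Capital", "Zealand", "Central", "South", "North")
REGIONAL_COUNTS = {
    "H": (2962, 1664, 2584, 2259, 1284),
    "I": (175, 89, 180, 148, 60),
    "J": (586, 313, 534, 464, 215),
    "K": (468, 224, 456, 364, 229),
    "L": (88, 17, 31, 20, 17),
    "M": (176, 45, 56, 79, 27),
    "N": (92, 43, 68, 61, 33),
    "R": (244, 74, 144, 119, 61),
    "T": (627, 354, 525, 434, 238),
    "U": (939, 491, 744, 666, 346),
    "V": (229, 116, 195, 175, 73),
    "W": (96, 57, 74, 67, 24),
    "X": (134, 60, 67, 101, 24),
    "NA": (2, 3, 2, 1, 1),
}
REGIONAL_TOTALS = {"Capital": 6818, "Zealand": 3550, "Central": 5660,
                   "South": 4957, "North": 2632}

# Temporal comparison: first (1981-1986) vs last (2000-2005) birth period.
PERIODS = ((1981, 1986), (2000, 2005))
PERIOD_COUNTS = {
    "H": (2162, 2454), "I": (130, 150), "J": (405, 511), "K": (359, 387),
    "L": (8, 67), "M": (44, 131), "N": (50, 73), "R": (102, 163),
    "T": (447, 468), "U": (579, 790), "V": (163, 169), "W": (56, 80),
    "X": (64, 89), "NA": (1, 3),
}
PERIOD_TOTALS = (4570, 5535)

# Number of simultaneously compared groups in the published tables
# (13 haplogroup bins + the NA column) — the Bonferroni denominator.
N_COMPARISON_GROUPS = 14

# Mapping from tree sub-haplogroup node names to the merged reporting bins
# used in the printed sub-haplogroup tables.
SUBHG_BINS = {
    "H1": "H1-H30b-H79a",
    "H5": "H5-36",
    "U2": "U2-U3",
    "U3": "U2-U3",
    "U4": "U4-9",
    "U9": "U4-9",
}
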