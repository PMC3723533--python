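"""Bundled reference values for the human Y palindrome P6 survey.

These are the published summary inputs of the P6 gene-conversion analysis of
378 HGDP Y chromosomes: conversion-event counts by direction and GC class,
the phylogeny generation-budget calibration and printed budget bounds,
interspecific arm/spacer divergence counts for the three great-ape pairwise
comparisons, and the lineage-polarised W<->S replacement tables before and
after hypermutable-dinucleotide removal.  They serve as ready-made inputs to
the statistics layer (the raw per-sample genotype tables are supplementary
material and are not redistributed here).
"""

from __future__ import annotations

from .model import Psv
from .stats import CalibrationConstants, GenerationBudget

#: direction and GC classification of the 146 converted SN-PSVs
CONVERSION_COUNTS = {
    "total": 146,
    "to_ancestral": 86,
    "to_derived": 60,
    "gc_informative": 79,
    "fixes_S": 59,
    "fixes_W": 20,
}

#: phased-window (PSV1-7) tallies from the 83 arm-phased chromosomes
PHASED_COUNTS = {
    "n_phased_samples": 83,
    "n_conversion_events": 56,
    "n_inversion_events": 3,
    "n_samples_with_inverted_phase": 5,
    "individual_conversions_in_window": 107,
    "conversions_explained_by_tracts": 49,
    "n_coconversion_tracts": 18,
}

#: number of PSV assays surveyed (per-PSV rates divide the total rate by this)
N_PSVS_SURVEYED = 10

CALIBRATION = CalibrationConstants()

#: printed generation budget for the 378-chromosome sample (from 323-935
#: total base substitutions at ~547.4 generations per substitution)
SUBSTITUTION_RANGE = (323, 935)
GENERATION_BUDGET = GenerationBudget(
    subs_lower=323, subs_upper=935, gen_lower=175_000, gen_upper=505_500
)

#: SYNTHETIC: generation budget of the 83-chromosome phased subset,
#: back-computed from the published per-generation rates in that subset
#: (3 inversions -> 1.36-1.72e-5; 56 conversions -> 2.54-3.21e-4); the true
#: per-branch bounds live in supplementary material not redistributed here.
PHASED_GENERATION_BUDGET = GenerationBudget(
    subs_lower=174_400 / CALIBRATION.generations_per_substitution,
    subs_upper=220_600 / CALIBRATION.generations_per_substitution,
    gen_lower=174_400,
    gen_upper=220_600,
)

#: interspecific divergence per region: (substitutions, ungapped bp)
DIVERGENCE_COUNTS = {
    ("human", "chimp"): {"arm": (1497, 104_230), "spacer": (919, 45_959)},
    ("human", "gorilla"): {"arm": (1726, 88_031), "spacer": (773, 31_206)},
    ("chimp", "gorilla"): {"arm": (1820, 84_096), "spacer": (828, 31_097)},
}

#: lineage-polarised replacement counts per region:
#: (total, W->S count, W denominator, S->W count, S denominator)
REPLACEMENT_COUNTS = {
    "before_dinucleotide_removal": {
        ("human", "arm"): (487, 235, 51_201, 161, 32_892),
        ("human", "spacer"): (238, 72, 19_687, 124, 11_404),
        ("chimp", "arm"): (659, 366, 51_201, 181, 32_892),
        ("chimp", "spacer"): (297, 110, 19_687, 137, 11_404),
    },
    "after_dinucleotide_removal": {
        ("human", "arm"): (180, 80, 38_071, 74, 19_215),
        ("human", "spacer"): (100, 24, 14_935, 56, 6_596),
        ("chimp", "arm"): (270, 135, 38_071, 88, 19_215),
        ("chimp", "spacer"): (134, 43, 14_935, 75, 6_596),
    },
}

#: GC content of P6 arms vs spacer on the human reference
GC_CONTENT = {"arm_pct": 38.8, "spacer_pct": 37.0}


def synthetic_psv_set() -> list[Psv]:
    """SYNTHETIC stand-in for the ten surveyed P6 SN-PSVs.

    The published per-PSV coordinate table is supplementary material and not
    redistributed; these coordinates are constructed to honour the published
    inter-PSV distances that the analyses depend on: PSV1-PSV2 = 81 bp,
    PSV1-PSV7 = 9023 bp (the longest minimum tract), with all ten inside a
    ~20 kb outer-arm window and PSV1-7 inside the ~18.9 kb phased fragment.
    Alleles are likewise constructed: six GC-informative PSVs (five with a
    strong ancestral base) and four S<->S / W<->W transversions, mirroring
    the published composition.
    """
    rows = [
        ("PSV1", 1_000, "G", "A"),
        ("PSV2", 1_081, "C", "T"),
        ("PSV3", 2_650, "A", "T"),
        ("PSV4", 4_120, "G", "T"),
        ("PSV5", 5_136, "C", "G"),
        ("PSV6", 7_410, "C", "A"),
        ("PSV7", 10_023, "A", "G"),
        ("PSV8", 13_480, "G", "C"),
        ("PSV9", 16_250, "G", "A"),
        ("PSV10", 19_300, "T", "A"),
    ]
    return [Psv(*row) for row in rows]


#: PSV ids covered by the arm-specific long-PCR phased window
PHASED_WINDOW = tuple(f"PSV{i}" for i in range(1, 8))
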