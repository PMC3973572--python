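"""Published survey constants for the Malebo forest-savannah mosaic study.

The bonobo population of the Malebo region (Lake Tumba landscape, western
DRC) was surveyed with line transects in 2011-2013 over three strata: the
Nkala and Mpelu forests (the presumed home ranges of two communities) and
the young *Uapaca* patches of Lokoso & Mankere.  The raw field data are not
public; what is public is the survey design (areas, yearly efforts), the
village census and questionnaire bookkeeping, and the headline detection
quantities.  Those printed values are collected here so that the in-report
arithmetic identities can be recomputed, and so the synthetic landscape
generator can default to the real study conditions.
"""

from __future__ import annotations

STRATA = ("Nkala", "Mpelu", "Lokoso&Mankere")

#: Stratum areas in km^2; they sum to the 93.84 km^2 global study area.
STRATUM_AREAS_KM2 = {
    "Nkala": 32.45,
    "Mpelu": 54.26,
    "Lokoso&Mankere": 7.13,
}

GLOBAL_AREA_KM2 = 93.84

#: Total transect effort (km) walked per stratum and year.
EFFORT_KM = {
    2011: {"Nkala": 49.9, "Mpelu": 72.7, "Lokoso&Mankere": 7.5},
    2012: {"Nkala": 61.9, "Mpelu": 109.7, "Lokoso&Mankere": 7.5},
    2013: {"Nkala": 61.9, "Mpelu": 106.1, "Lokoso&Mankere": 7.5},
}

#: Printed global efforts per year (km), for bookkeeping checks.
GLOBAL_EFFORT_KM = {2011: 130.1, 2012: 179.1, 2013: 175.5}

N_TRANSECTS = 114
TRANSECT_SPACING_KM = 0.5

# Headline detection quantities of the study fit (half-normal + cosine key,
# truncated where detection probability falls to 0.15).
TRUNCATION_M = 35.0
ESW_M = 19.1
MEAN_DETECTION_P = 0.55
DETECTION_P_THRESHOLD = 0.15
N_NESTS_TOTAL = 1411
N_NESTS_RETAINED = 1341

# Nest-to-individual conversion constants (literature values).
NEST_CONSTRUCTION_RATE = 1.37   # nests per builder per day
BUILDER_FRACTION = 0.75         # fraction of the population that builds
MEAN_DECAY_DAYS = 183.0         # estimated on site; bootstrap range 179-188
DECAY_CI_DAYS = (179.0, 188.0)

#: Village census and questionnaire bookkeeping.  One row per settlement:
#: (name, households, men, women, children, interviewed_total,
#:  interviewed_men, interviewed_women, hunters_m, fishers_w, fishers_m,
#:  ntpc_w, ntpc_m).  "ntpc" = non-timber product collection.
VILLAGE_TABLE = [
    ("Nkoo",               168, 169, 202, 540, 50, 35, 15, 16, 13, 20,  7,  9),
    ("Mpelu",               43,  50,  58, 153, 50, 30, 20, 19, 20, 23, 20, 19),
    ("Lebomo",              37,  37,  34, 141, 26, 14, 12,  7,  9,  8,  3,  2),
    ("Nkala",               34,  36,  49, 110, 39, 21, 18,  7, 18, 14, 16, 10),
    ("Malebo",              10,   9,  11,  38,  6,  3,  3,  1,  3,  2,  3,  2),
    ("Mavula",              10,  10,  12,  25,  6,  3,  3,  3,  3,  2,  3,  1),
    ("Bosatore",             7,   5,   7,  22,  2,  1,  1,  1,  1,  1,  1,  1),
    ("Mokoabuo",             6,   5,   8,  17,  4,  2,  2,  1,  2,  1,  2,  1),
    ("Dispensaire de Nkoo",  4,   4,   4,  19,  2,  1,  1,  0,  0,  0,  0,  0),
    ("Lensiana",             4,   4,   3,  18,  0,  0,  0,  0,  0,  0,  0,  0),
    ("Biomengele",           3,   3,   3,  13,  3,  2,  1,  2,  1,  1,  1,  1),
    ("Ngandjele",            3,   3,   6,   7,  2,  1,  1,  0,  1,  0,  1,  0),
    ("Motsuemontore",        2,   2,   4,   9,  2,  1,  1,  1,  1,  0,  0,  0),
    ("Ezano",                3,   2,   2,   8,  1,  1,  0,  1,  0,  1,  0,  1),
    ("Mayi Monene",          2,   2,   3,   5,  2,  1,  1,  0,  1,  1,  0,  0),
    ("Mbou-Mon-Tour",        4,   4,   4,   2,  2,  1,  1,  0,  1,  0,  0,  0),
    ("Moza",                 1,   1,   1,   6,  2,  1,  1,  0,  1,  0,  1,  0),
    ("Bosieli",              1,   1,   1,   5,  2,  1,  1,  1,  1,  1,  1,  0),
]

VILLAGE_COLUMNS = [
    "village", "households", "men", "women", "children",
    "interviewed_total", "interviewed_men", "interviewed_women",
    "hunters_m", "fishers_w", "fishers_m", "ntpc_w", "ntpc_m",
]

TOTAL_INTERVIEWED = 201

#: Tree abundance survey size used as the denominator of the nesting-tree
#: preference test (stems >=10 cm DBH over 27 ha of plots).
N_ABUNDANCE_TREES = 9730
ABUNDANCE_PLOT_HA = 27.0


def village_frame():
    """Return the census/questionnaire table as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(VILLAGE_TABLE, columns=VILLAGE_COLUMNS)
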