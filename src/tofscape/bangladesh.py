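"""Published national accounting figures for Bangladesh.

These tables are the inputs to the reporting layer when no raster is in
hand: division areas and mapped trees-outside-forests (TOF) areas with
their 95% confidence intervals, the national patch-size tallies, the
division areas of two comparison products (a canopy-cover map converted to
extent, and a radar forest/non-forest map), the national population and
the prior mapped forest area.  All areas are hectares.
"""

from __future__ import annotations

__all__ = [
    "DIVISIONS",
    "TOF_AREA_HA",
    "TOF_CI95_HA",
    "DIVISION_AREA_HA",
    "PATCH_COUNTS",
    "TOF_AREA_ABOVE_5M_HA",
    "COVER_MAP_AREA_HA",
    "FNF_AREA_HA",
    "POPULATION",
    "PRIOR_FOREST_AREA_HA",
]

DIVISIONS = (
    "Barisal", "Chittagong", "Dhaka", "Khulna",
    "Mymensingh", "Rajshahi", "Rangpur", "Sylhet",
)

# Mapped TOF area and its 95% confidence interval, per division
TOF_AREA_HA = {
    "Barisal": 303_220, "Chittagong": 399_331, "Dhaka": 415_544,
    "Khulna": 293_262, "Mymensingh": 178_410, "Rajshahi": 267_266,
    "Rangpur": 233_180, "Sylhet": 143_365,
}
TOF_CI95_HA = {
    "Barisal": 25_123, "Chittagong": 37_392, "Dhaka": 29_102,
    "Khulna": 37_441, "Mymensingh": 15_544, "Rajshahi": 36_763,
    "Rangpur": 28_632, "Sylhet": 19_365,
}
DIVISION_AREA_HA = {
    "Barisal": 1_329_700, "Chittagong": 3_377_100, "Dhaka": 2_059_300,
    "Khulna": 2_227_200, "Mymensingh": 1_058_400, "Rajshahi": 1_819_700,
    "Rangpur": 1_631_700, "Sylhet": 1_259_600,
}

# National patch tallies per connected-area class (4-connected stands)
PATCH_COUNTS = {
    "<=1 ha": 454_846,
    "1-5 ha": 177_909,
    "5-10 ha": 29_928,
    "10-100 ha": 29_154,
    "100-1000 ha": 1_904,
    "1000-10000 ha": 119,
    "10000-100000 ha": 8,
}

# TOF area restricted to canopy heights above 5 m, per division
TOF_AREA_ABOVE_5M_HA = {
    "Barisal": 213_075, "Chittagong": 277_181, "Dhaka": 265_083,
    "Khulna": 194_372, "Mymensingh": 143_529, "Rajshahi": 183_087,
    "Rangpur": 134_708, "Sylhet": 66_532,
}

# Comparison products: 30 m global canopy-cover map converted to extent
# (cover > 0%), and the 50 m radar forest/non-forest (FNF) map
COVER_MAP_AREA_HA = {
    "Barisal": 158_773, "Chittagong": 224_110, "Dhaka": 128_682,
    "Khulna": 149_802, "Mymensingh": 73_514, "Rajshahi": 51_583,
    "Rangpur": 61_654, "Sylhet": 104_426,
}
FNF_AREA_HA = {
    "Barisal": 331_797, "Chittagong": 463_168, "Dhaka": 327_624,
    "Khulna": 419_290, "Mymensingh": 202_110, "Rajshahi": 246_310,
    "Rangpur": 362_804, "Sylhet": 113_985,
}

POPULATION = 161_356_039

# Prior remotely sensed national forest-area estimate
PRIOR_FOREST_AREA_HA = 1_464_000
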