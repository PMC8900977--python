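"""Shared demographic constants: provinces, regions, age bands, food-source categories.

The modelled provinces are the twelve covered by the China Health and
Nutrition Survey waves used for exposure estimation, grouped into three
dietary-culture regions.  The three megacities joined the survey only in
2011, so their sodium exposure is held constant at the 2011 level rather
than trend-projected.
"""

from __future__ import annotations

NORTH = ("Beijing", "Heilongjiang", "Liaoning")
CENTRAL = ("Henan", "Jiangsu", "Shandong")
SOUTH = ("Chongqing", "Hunan", "Hubei", "Guizhou", "Guangxi", "Shanghai")

PROVINCES = NORTH + CENTRAL + SOUTH

REGION_OF = {p: "north" for p in NORTH}
REGION_OF.update({p: "central" for p in CENTRAL})
REGION_OF.update({p: "south" for p in SOUTH})

REGIONS = ("north", "central", "south")

#: Provinces with no pre-2011 survey waves; exposure held at the 2011 level.
MEGACITIES = frozenset({"Beijing", "Chongqing", "Shanghai"})

SEXES = ("male", "female")

#: Census age bands: 0-1, 1-4, then 5-year increments up to 85+.
AGE_BANDS = (
    "0-1",
    "1-4",
    "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74",
    "75-79", "80-84",
    "85+",
)

#: Half-open [lo, hi) integer-age bounds per band; 85+ is capped at 100.
AGE_BAND_BOUNDS = {
    "0-1": (0, 1),
    "1-4": (1, 5),
    **{f"{lo}-{lo + 4}": (lo, lo + 5) for lo in range(5, 85, 5)},
    "85+": (85, 100),
}

#: Dietary sodium source categories.  The first five are the high-sodium
#: categories a salt substitute can replace; "other" is everything else
#: (intrinsic food sodium, packaged foods).
SOURCE_CATEGORIES = ("added_salt", "soy_sauce", "msg", "fermented", "pickled", "other")
SUBSTITUTABLE_CATEGORIES = SOURCE_CATEGORIES[:5]

#: Dietary survey waves providing 24-h recalls.
SURVEY_YEARS = (2004, 2006, 2009, 2011)

#: Sodium mass fraction of NaCl; a 2-gram salt spoon holds ~788 mg sodium.
SODIUM_FRACTION_OF_SALT = 0.394


def age_to_band(age: int) -> str:
    """Map an integer age in years to its census band label."""
    if age < 0:
        raise ValueError(f"age must be nonnegative, got {age}")
    if age < 1:
        return "0-1"
    if age < 5:
        return "1-4"
    if age >= 85:
        return "85+"
    lo = (age // 5) * 5
    return f"{lo}-{lo + 4}"


def band_index(band: str) -> int:
    try:
        return AGE_BANDS.index(band)
    except ValueError:
        raise KeyError(f"unknown age band {band!r}") from None
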