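"""Published regional summary estimates used as worked-example inputs.

Education distributions (percent low / medium / high, ISCED 0-2 / 3-4 / 5-6)
and age-standardized prevalences (ASP, percent) of self-reported hearing loss
by European region and gender, for adults aged 50+ in the pooled harmonized
SHARE cross-sections. These printed summary numbers are inputs to the
relative-index-of-inequality worked examples; nothing here is an output of
this package.
"""

from __future__ import annotations

REGIONS = ("Northern", "Western", "Southern", "Eastern")
GENDERS = ("man", "woman")

# (region, gender) -> education shares in percent, ordered low, medium, high.
EDUCATION_SHARES_PCT: dict[tuple[str, str], tuple[float, float, float]] = {
    ("Northern", "man"): (29.7, 38.3, 31.9),
    ("Western", "man"): (27.6, 42.8, 29.6),
    ("Southern", "man"): (68.2, 19.0, 12.8),
    ("Eastern", "man"): (32.5, 49.6, 17.9),
    ("Northern", "woman"): (32.5, 31.3, 36.2),
    ("Western", "woman"): (39.9, 38.7, 21.4),
    ("Southern", "woman"): (74.6, 16.7, 8.7),
    ("Eastern", "woman"): (38.4, 45.9, 15.7),
}

# (region, gender) -> age-standardized hearing-loss prevalence in percent for
# the full 50+ range ("Total" column), ordered low, medium, high education.
HL_ASP_TOTAL_PCT: dict[tuple[str, str], tuple[float, float, float]] = {
    ("Northern", "man"): (19.4, 19.4, 16.9),
    ("Western", "man"): (27.2, 24.7, 20.5),
    ("Southern", "man"): (25.1, 18.9, 17.4),
    ("Eastern", "man"): (26.7, 22.5, 19.7),
    ("Northern", "woman"): (13.4, 12.5, 10.9),
    ("Western", "woman"): (19.2, 17.4, 16.1),
    ("Southern", "woman"): (21.0, 13.3, 17.1),
    ("Eastern", "woman"): (21.7, 17.2, 13.8),
}

# Published RII (Total column), for cross-checking the reproduction.
HL_RII_TOTAL: dict[tuple[str, str], float] = {
    ("Northern", "man"): 1.2,
    ("Western", "man"): 1.5,
    ("Southern", "man"): 1.8,
    ("Eastern", "man"): 1.5,
    ("Northern", "woman"): 1.4,
    ("Western", "woman"): 1.3,
    ("Southern", "woman"): 1.6,
    ("Eastern", "woman"): 1.8,
}
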