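"""Age-band / sex stratification shared by every module.

The population is stratified into 5-year age bands from age 2 to 100 (the
first band, 2-4, is three years wide) crossed with sex.  Strata are
identified by strings such as ``"35-39F"``.
"""

from __future__ import annotations

import numpy as np

SEXES = ("F", "M")

# (lower, upper) with upper exclusive: [2,5), [5,10), ..., [95,100)
AGE_BANDS: tuple[tuple[int, int], ...] = ((2, 5),) + tuple(
    (lo, lo + 5) for lo in range(5, 100, 5)
)

N_BANDS = len(AGE_BANDS)


def stratum_id(band: tuple[int, int], sex: str) -> str:
    lo, hi = band
    return f"{lo:02d}-{hi - 1:02d}{sex}"


STRATUM_IDS: tuple[str, ...] = tuple(
    stratum_id(band, sex) for sex in SEXES for band in AGE_BANDS
)

N_STRATA = len(STRATUM_IDS)


def band_index_of_age(age: float) -> int:
    """Index of the band containing ``age``; ages beyond 100 use the last band."""
    if age < AGE_BANDS[0][0]:
        raise ValueError(f"age {age} below modelled range (starts at 2)")
    for i, (lo, hi) in enumerate(AGE_BANDS):
        if lo <= age < hi:
            return i
    return N_BANDS - 1


def band_midpoint(band: tuple[int, int]) -> int:
    lo, hi = band
    return (lo + hi) // 2


def parse_stratum_id(sid: str) -> tuple[tuple[int, int], str]:
    """Inverse of :func:`stratum_id`."""
    sex = sid[-1]
    lo, hi = sid[:-1].split("-")
    band = (int(lo), int(hi) + 1)
    if sex not in SEXES or band not in AGE_BANDS:
        raise ValueError(f"unrecognised stratum id {sid!r}")
    return band, sex


def stratum_frame() -> "np.recarray":
    """Structured array of (stratum_id, age_lo, age_hi, sex, start_age)."""
    rows = []
    for sex in SEXES:
        for band in AGE_BANDS:
            rows.append((stratum_id(band, sex), band[0], band[1], sex,
                         band_midpoint(band)))
    return np.rec.fromrecords(
        rows, names=["stratum_id", "age_lo", "age_hi", "sex", "start_age"]
    )
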