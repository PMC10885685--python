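"""Detailed-domain definitions shared by every stage.

A detailed domain is one state x age-group x sex cell. With 8 states and
territories, 7 adult age groups and 2 sexes there are exactly 112 detailed
domains, and over the 21 calendar years 2001-2021 there are 112 x 21 = 2352
domain-year cells. Domains are totally ordered by (state, age group, sex) so
the domain index ``d`` in {0..111} is reproducible everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Ordered levels. The first level of each factor is the fixed-effect
# reference category used by the model: ACT, 18-24, female.
STATES: tuple[str, ...] = ("ACT", "NSW", "VIC", "QLD", "SA", "WA", "TAS", "NT")
AGE_GROUPS: tuple[str, ...] = ("18-24", "25-29", "30-39", "40-49", "50-59", "60-69", "70+")
SEXES: tuple[str, ...] = ("female", "male")

YEAR_START = 2001
YEAR_END = 2021
YEARS: tuple[int, ...] = tuple(range(YEAR_START, YEAR_END + 1))

N_STATES = len(STATES)
N_AGES = len(AGE_GROUPS)
N_SEXES = len(SEXES)
N_DOMAINS = N_STATES * N_AGES * N_SEXES  # 112
N_YEARS = len(YEARS)  # 21
N_CELLS = N_DOMAINS * N_YEARS  # 2352

#: The 14 sex-by-age cells indexing the RW1 temporal random-effect series.
SEX_AGE_CELLS: tuple[tuple[str, str], ...] = tuple(
    (sex, age) for sex in SEXES for age in AGE_GROUPS
)

_DOMAIN_COLS = ["state", "age_group", "sex"]


def domain_table() -> pd.DataFrame:
    """Return the 112 detailed domains in canonical order.

    Columns: ``d`` (0-based domain index), ``state``, ``age_group``, ``sex``
    and ``sex_age`` (0-based index of the sex-by-age cell carrying the RW1
    series).
    """
    rows = []
    d = 0
    for state in STATES:
        for age in AGE_GROUPS:
            for sex in SEXES:
                rows.append(
                    {
                        "d": d,
                        "state": state,
                        "age_group": age,
                        "sex": sex,
                        "sex_age": SEX_AGE_CELLS.index((sex, age)),
                    }
                )
                d += 1
    return pd.DataFrame(rows)


def domain_index(df: pd.DataFrame) -> np.ndarray:
    """Map rows carrying state/age_group/sex columns to domain indices."""
    for col, levels in (("state", STATES), ("age_group", AGE_GROUPS), ("sex", SEXES)):
        bad = set(df[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} level(s): {sorted(bad)}")
    s = np.asarray([STATES.index(v) for v in df["state"]])
    a = np.asarray([AGE_GROUPS.index(v) for v in df["age_group"]])
    x = np.asarray([SEXES.index(v) for v in df["sex"]])
    return s * (N_AGES * N_SEXES) + a * N_SEXES + x


def cell_table() -> pd.DataFrame:
    """Return all 2352 domain-year cells (domain_table crossed with YEARS)."""
    dom = domain_table()
    years = pd.DataFrame({"year": YEARS})
    return dom.merge(years, how="cross")


def standardize_year(year):
    """Standardize calendar years over the fixed 2001-2021 window.

    ``z_t = (t - mean(2001..2021)) / sd(2001..2021)`` with the sample
    standard deviation (denominator n-1, matching R's ``sd``). The mean year
    2011 maps to 0 and the transform is antisymmetric about it.
    """
    year_arr = np.asarray(year)
    if np.any((year_arr < YEAR_START) | (year_arr > YEAR_END)):
        raise ValueError(f"year out of range {YEAR_START}..{YEAR_END}: {year!r}")
    yrs = np.asarray(YEARS, dtype=float)
    z = (year_arr - yrs.mean()) / yrs.std(ddof=1)
    return float(z) if np.isscalar(year) else z


def check_survey_years(years) -> list[int]:
    """Validate a collection of survey-wave years and return them sorted."""
    out = sorted(int(y) for y in years)
    if not out:
        raise ValueError("at least one survey year is required")
    for y in out:
        if y < YEAR_START or y > YEAR_END:
            raise ValueError(f"survey year {y} outside {YEAR_START}..{YEAR_END}")
    if len(set(out)) != len(out):
        raise ValueError("duplicate survey years")
    return out


#: Survey-wave calendar years used by default: seven waves on a roughly
#: three-year cycle, mirroring the national health survey rounds.
DEFAULT_SURVEY_YEARS: tuple[int, ...] = (2001, 2005, 2008, 2012, 2015, 2018, 2021)
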