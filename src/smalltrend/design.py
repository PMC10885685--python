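"""Fixed-effect design matrix shared by the generator and the model.

The linear predictor for domain ``d`` (state s, age a, sex x) in year ``t``
is ``eta_dt = beta' x_dt + v_d + z_t * v_d^yr + u_t^(sex-age)`` where the
fixed part has 22 columns: intercept, standardized year ``z_t``, a male
indicator, 6 age contrasts, 7 state contrasts, and 6 male-by-age interaction
contrasts. Reference levels are female / 18-24 / ACT, so the reference row
at ``z_t = 0`` is the intercept alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from smalltrend.domains import AGE_GROUPS, SEXES, STATES, standardize_year


def design_columns() -> list[str]:
    """Names of the 22 fixed-effect columns, in design order."""
    cols = ["intercept", "year_std", "male"]
    cols += [f"age:{a}" for a in AGE_GROUPS[1:]]
    cols += [f"state:{s}" for s in STATES[1:]]
    cols += [f"male:age:{a}" for a in AGE_GROUPS[1:]]
    return cols


def build_design(cells: pd.DataFrame) -> pd.DataFrame:
    """Build the fixed-effect design matrix for domain-year rows.

    Parameters
    ----------
    cells
        DataFrame with columns ``state``, ``age_group``, ``sex``, ``year``.

    Returns
    -------
    DataFrame with one row per input row and the 22 design columns.
    """
    for col, levels in (("state", STATES), ("age_group", AGE_GROUPS), ("sex", SEXES)):
        bad = set(cells[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} level(s): {sorted(bad)}")
    n = len(cells)
    X = pd.DataFrame(index=cells.index)
    X["intercept"] = 1.0
    X["year_std"] = standardize_year(cells["year"].to_numpy())
    male = (cells["sex"] == "male").to_numpy(dtype=float)
    X["male"] = male
    for a in AGE_GROUPS[1:]:
        X[f"age:{a}"] = (cells["age_group"] == a).to_numpy(dtype=float)
    for s in STATES[1:]:
        X[f"state:{s}"] = (cells["state"] == s).to_numpy(dtype=float)
    for a in AGE_GROUPS[1:]:
        X[f"male:age:{a}"] = male * X[f"age:{a}"].to_numpy()
    assert X.shape == (n, 22)
    return X


def beta_vector(beta: dict[str, float]) -> np.ndarray:
    """Arrange a name->value coefficient mapping into design order.

    Missing names default to 0; unknown names raise.
    """
    cols = design_columns()
    unknown = set(beta) - set(cols)
    if unknown:
        raise ValueError(f"unknown coefficient name(s): {sorted(unknown)}")
    return np.array([float(beta.get(c, 0.0)) for c in cols])
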