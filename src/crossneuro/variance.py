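"""Sex differences in the dispersion of brain volumes (Levene-type tests).

Volumes are first residualized for the nuisance covariates (TTV, age, and
Euler number in humans; TTV, age, and background strain in mice -- sex is
deliberately excluded so that sex-linked dispersion differences survive), then
each region is tested for unequal spread between the sexes with a Levene-type
test. The default centering is the group median (the Brown-Forsythe variant);
mean-centering is available as an option.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .volumetrics import _covariate_design, _single_species, bh_fdr

__all__ = ["residualize", "levene_by_sex"]


def residualize(subjects: pd.DataFrame, volumes: pd.DataFrame,
                include_ttv: bool = True) -> pd.DataFrame:
    """Per-region OLS residuals after regressing out the nuisance covariates.

    Sex is never included in the design. Returns a matrix aligned with the
    input, with its state flag set to ``residualized``.
    """
    species = _single_species(subjects)
    X, names, _ = _covariate_design(subjects, species, include_ttv, include_sex=False)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate (collinear) covariate design")
    Y = volumes.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    out = pd.DataFrame(resid, index=volumes.index, columns=volumes.columns)
    out.attrs.update(volumes.attrs)
    out.attrs["state"] = "residualized"
    out.attrs["design_columns"] = names
    return out


def levene_by_sex(residuals: pd.DataFrame, subjects: pd.DataFrame,
                  center: Literal["median", "mean"] = "median") -> pd.DataFrame:
    """Levene/Brown-Forsythe test of equal spread between sexes, per region.

    Returns one row per region with the F statistic, its p-value, the BH-FDR
    q-value across regions, and the direction call from comparing the sexes'
    mean absolute deviations (reported regardless of significance).
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    sex = subjects["sex"].to_numpy()
    is_m = sex == "M"
    if is_m.sum() < 2 or (~is_m).sum() < 2:
        raise ValueError("need at least 2 subjects per sex")
    Y = residuals.to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("residual matrix contains non-finite values")
    center_fn = np.median if center == "median" else np.mean

    rows = []
    for j, region in enumerate(residuals.columns):
        m, f = Y[is_m, j], Y[~is_m, j]
        stat, p = stats.levene(m, f, center=center)
        dev_m = np.abs(m - center_fn(m)).mean()
        dev_f = np.abs(f - center_fn(f)).mean()
        direction = "male_more_variable" if dev_m > dev_f else "female_more_variable"
        rows.append((region, stat, p, direction))
    out = pd.DataFrame(rows, columns=["region", "f_value", "p_value", "direction"])
    out.insert(3, "q_value", bh_fdr(out["p_value"].to_numpy()))
    out["sig_uncorrected"] = out["p_value"] < 0.05
    out["sig_fdr"] = out["q_value"] < 0.05
    out.attrs["center"] = center
    return out
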