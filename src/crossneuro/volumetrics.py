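"""Quality filtering, volume standardization, and per-region sex effect sizes.

The central operation fits, for every region, the linear model

    z(volume) ~ intercept + sex + (age - mean age) + TTV + Euler     (human)
    z(volume) ~ intercept + sex + (age - mean age) + TTV + strain    (mouse)

by ordinary least squares, where z() denotes z-scoring the volume across the
included subjects. The coefficient on the male indicator (F=0, M=1) is the
*standardized effect size* of sex, in SD units with positive = male-larger.
P-values across regions are adjusted with the Benjamini-Hochberg step-up
procedure at the conventional q < 0.05 threshold.

Sex coding is F=0 / M=1 throughout the package; TTV and Euler number enter
mean-centered (this only shifts the intercept but conditions the solve).
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["qc_filter", "fit_sex_effects", "bh_fdr", "EULER_EXCLUSION_THRESHOLD"]

#: Subjects whose cortical-surface Euler number is strictly below this value
#: are excluded (more negative = worse reconstruction quality).
EULER_EXCLUSION_THRESHOLD = -200


def qc_filter(subjects: pd.DataFrame, volumes: pd.DataFrame):
    """Remove low-quality human subjects (Euler number < -200).

    Mouse rows pass through unchanged. Returns ``(subjects, volumes, report)``
    with both outputs row-aligned; the report lists excluded subject ids.
    """
    if len(subjects) != len(volumes):
        raise ValueError(
            f"subject table ({len(subjects)}) and volume matrix ({len(volumes)}) "
            "have different row counts"
        )
    if len(subjects) == 0:
        return subjects.copy(), volumes.copy(), {"excluded": [], "n_before": 0, "n_after": 0}
    is_human = subjects["species"].to_numpy() == "human"
    if is_human.any() and "euler" not in subjects.columns:
        raise ValueError("human rows must carry an euler value")
    keep = np.ones(len(subjects), dtype=bool)
    if is_human.any():
        keep &= ~is_human | (subjects["euler"].to_numpy() >= EULER_EXCLUSION_THRESHOLD)
    excluded = subjects.loc[~keep, "subject_id"].tolist()
    out_subj = subjects.loc[keep].reset_index(drop=True)
    out_vol = volumes.loc[keep]
    out_vol.attrs.update(volumes.attrs)
    report = {"excluded": excluded, "n_before": int(len(subjects)), "n_after": int(keep.sum())}
    return out_subj, out_vol, report


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _covariate_design(subjects: pd.DataFrame, species: str, include_ttv: bool,
                      include_sex: bool = True):
    """Design matrix [intercept, (male), age_c, (ttv_c), euler_c | strain].

    Returns (X, column names, index of the sex column or None).
    """
    n = len(subjects)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    sex_idx = None
    if include_sex:
        cols.append((subjects["sex"].to_numpy() == "M").astype(float))
        names.append("sex_male")
        sex_idx = 1
    age = subjects["age"].to_numpy(dtype=float)
    cols.append(age - age.mean())
    names.append("age_c")
    if include_ttv:
        ttv = subjects["ttv"].to_numpy(dtype=float)
        cols.append(ttv - ttv.mean())
        names.append("ttv_c")
    if species == "human":
        euler = subjects["euler"].to_numpy(dtype=float)
        cols.append(euler - euler.mean())
        names.append("euler_c")
    else:
        strains = pd.unique(subjects["strain"])
        for s in strains[1:]:  # first strain is the reference level
            cols.append((subjects["strain"].to_numpy() == s).astype(float))
            names.append(f"strain_{s}")
    X = np.column_stack(cols)
    return X, names, sex_idx


def fit_sex_effects(
    subjects: pd.DataFrame,
    volumes: pd.DataFrame,
    covariate_set: Literal["with_ttv", "without_ttv"] = "with_ttv",
    target: Literal["regional", "global"] = "regional",
) -> pd.DataFrame:
    """Standardized sex effect size per region via OLS on z-scored volumes.

    ``covariate_set='without_ttv'`` drops the TTV covariate; ``target='global'``
    also drops it (global outcomes such as TTV itself cannot covary for TTV).
    Zero-variance regions yield rows flagged in the ``note`` column with NaN
    statistics instead of aborting the fit. Returns one row per region with
    ``beta_sex``, ``t_value``, ``p_value``, ``q_value``, ``n_f``, ``n_m``.
    """
    species = _single_species(subjects)
    n_f = int((subjects["sex"] == "F").sum())
    n_m = int((subjects["sex"] == "M").sum())
    if n_f < 2 or n_m < 2:
        raise ValueError("need at least 2 subjects per sex")
    include_ttv = covariate_set == "with_ttv" and target != "global"
    X, names, sex_idx = _covariate_design(subjects, species, include_ttv)
    n, k = X.shape
    if n <= k:
        raise ValueError("more model parameters than subjects")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("degenerate (collinear) covariate design")

    Y = volumes.to_numpy(dtype=float)
    sd = Y.std(axis=0, ddof=1)
    ok = sd > 0
    Z = np.full_like(Y, np.nan)
    Z[:, ok] = (Y[:, ok] - Y[:, ok].mean(axis=0)) / sd[ok]

    xtx_inv = np.linalg.inv(X.T @ X)
    beta_all = xtx_inv @ X.T @ Z[:, ok]
    resid = Z[:, ok] - X @ beta_all
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[sex_idx, sex_idx])
    beta_sex = beta_all[sex_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_sex / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)

    regions = list(volumes.columns)
    out = pd.DataFrame(
        {
            "region": regions,
            "beta_sex": np.nan,
            "t_value": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
            "n_f": n_f,
            "n_m": n_m,
            "note": "",
        }
    )
    out.loc[ok, "beta_sex"] = beta_sex
    out.loc[ok, "t_value"] = t
    out.loc[ok, "p_value"] = p
    out.loc[ok, "q_value"] = bh_fdr(p) if ok.any() else np.nan
    out.loc[~ok, "note"] = "zero-variance region"
    out.attrs.update(
        species=species,
        covariate_set=covariate_set,
        target=target,
        design_columns=names,
        sex_coding="F=0, M=1",
    )
    return out


def _single_species(subjects: pd.DataFrame) -> str:
    species = pd.unique(subjects["species"])
    if len(species) != 1:
        raise ValueError("subject table must contain exactly one species")
    return str(species[0])
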