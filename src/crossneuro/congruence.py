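"""Cross-species congruence of sex effects: robust correlation and scores.

The headline statistic is the percentage-bend correlation (Wilcox), a robust
alternative to Pearson's r. For each variable, a percentage-bend measure of
location and scale is computed -- the scale omega is the m-th order statistic
of the absolute deviations from the median, with m = floor((1 - bend) * n +
0.5) -- deviations are standardized and winsorized through psi(u) =
max(-1, min(1, u)), and the normalized cross-product of the winsorized scores
gives r. Significance uses the usual t transform with n - 2 degrees of
freedom.

The module also provides the anatomical sex-effect similarity score (the
product of the two species' standardized sex effect sizes -- positive when a
region is sex-biased in the same direction in both species), quadrant
classification of paired effects, and Cook's-distance influence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PbcorResult",
    "pbcor",
    "anatomical_similarity",
    "quadrant_classify",
    "cooks_influence",
]


@dataclass(frozen=True)
class PbcorResult:
    r: float
    t_stat: float
    p_value: float
    n: int
    bend: float


def _pb_scale(x: np.ndarray, bend: float) -> float:
    """Percentage-bend measure of scale: the m-th smallest |x - median|."""
    n = x.size
    w = np.sort(np.abs(x - np.median(x)))
    m = int(np.floor((1.0 - bend) * n + 0.5))
    return float(w[m - 1])


def _pb_location(x: np.ndarray, bend: float, omega: float) -> float:
    """Percentage-bend measure of location (one-step M-estimate)."""
    med = np.median(x)
    psi = (x - med) / omega
    i1 = int(np.sum(psi < -1.0))
    i2 = int(np.sum(psi > 1.0))
    core = np.where(np.abs(psi) <= 1.0, x, 0.0).sum()
    return float((core + omega * (i2 - i1)) / (x.size - i1 - i2))


def pbcor(x, y, bend: float = 0.2) -> PbcorResult:
    """Percentage-bend correlation between two equal-length vectors.

    ``bend`` is the bend constant in (0, 0.5]; 0.2 is the conventional
    default. Raises on constant input (the bend scale is zero there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if not 0.0 < bend <= 0.5:
        raise ValueError("bend constant must lie in (0, 0.5]")
    om_x, om_y = _pb_scale(x, bend), _pb_scale(y, bend)
    if om_x == 0.0 or om_y == 0.0:
        raise ValueError("constant (zero-spread) input vector")
    a = np.clip((x - _pb_location(x, bend, om_x)) / om_x, -1.0, 1.0)
    b = np.clip((y - _pb_location(y, bend, om_y)) / om_y, -1.0, 1.0)
    r = float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:  # exact linear dependence after winsorizing
        return PbcorResult(r=r, t_stat=np.inf if r > 0 else -np.inf,
                           p_value=0.0, n=n, bend=bend)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return PbcorResult(r=r, t_stat=float(t), p_value=float(p), n=n, bend=bend)


def anatomical_similarity(paired: pd.DataFrame) -> pd.DataFrame:
    """Anatomical sex-effect similarity score per region.

    ``S_r = beta_human * beta_mouse`` (SD^2 units): positive where the sexes
    bias volume in the same direction in both species, negative where the
    bias is inverted. The compartment label is carried through for subsequent
    cortical / non-cortical splits.
    """
    if len(paired) == 0:
        raise ValueError("paired effect table is empty")
    for col in ("beta_human", "beta_mouse"):
        if paired[col].isna().any():
            raise ValueError(f"missing values in {col}")
    out = paired[["region", "label", "hemisphere"]].copy() if "label" in paired.columns \
        else paired[["region"]].copy()
    out["anat_similarity"] = paired["beta_human"].to_numpy() * paired["beta_mouse"].to_numpy()
    if "compartment" in paired.columns:
        out["compartment"] = paired["compartment"].to_numpy()
    return out


def quadrant_classify(paired: pd.DataFrame) -> pd.DataFrame:
    """Sign-quadrant category for each paired region.

    Categories: ``both_male``, ``both_female``, ``human_male_mouse_female``,
    ``human_female_mouse_male``; an exact zero in either beta yields
    ``unbiased``. ``starred`` marks regions significant in both species.
    """
    bh = paired["beta_human"].to_numpy(dtype=float)
    bm = paired["beta_mouse"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(bh)) and np.all(np.isfinite(bm))):
        raise ValueError("betas must be finite")
    cats = np.select(
        [
            (bh == 0) | (bm == 0),
            (bh > 0) & (bm > 0),
            (bh < 0) & (bm < 0),
            (bh > 0) & (bm < 0),
        ],
        ["unbiased", "both_male", "both_female", "human_male_mouse_female"],
        default="human_female_mouse_male",
    )
    out = paired.copy()
    out["quadrant"] = cats
    if {"sig_human", "sig_mouse"}.issubset(paired.columns):
        out["starred"] = paired["sig_human"].astype(bool) & paired["sig_mouse"].astype(bool)
    return out


def cooks_influence(x, y) -> pd.DataFrame:
    """Cook's distance for each point of the simple OLS regression of y on x.

    Points with d > 4/n are flagged as influential (the common rule of
    thumb).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("constant x")
    X = np.column_stack([np.ones(n), x])
    fit = sm.OLS(y, X).fit()
    d = fit.get_influence().cooks_distance[0]
    return pd.DataFrame({"cooks_d": d, "influential": d > 4.0 / n})
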