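"""Anatomy-transcription coupling and gene-subset resampling nulls.

The observed quantity is the robust (percentage-bend) correlation, across
homologous regions, between the anatomical sex-effect similarity score and the
per-region transcriptional similarity. To calibrate gene-subset analyses
(X-linked, hormone-signaling, ...), the same correlation is recomputed over
many random gene subsets of matched size drawn without replacement from the
shared homologous pool, and the observed value is referred to that null
distribution with an add-one empirical p-value
``p = (1 + #{draws >= observed}) / (1 + n_draws)`` (one-sided; two-sided
doubles the smaller tail). The add-one correction keeps p strictly positive.

The subset sizes used for the standard panels are exposed as
:data:`SUBSET_SIZES`: 91 X-linked genes, 34 hormone-signaling genes, of which
11 androgen and 23 estrogen/progesterone genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .congruence import pbcor

__all__ = [
    "NullDistribution",
    "SUBSET_SIZES",
    "correlate_anatomy_transcription",
    "build_null",
    "permutation_pvalue",
]

#: Gene-subset sizes of the standard sensitivity panels.
SUBSET_SIZES = {
    "x_linked": 91,
    "hormone": 34,
    "androgen": 11,
    "estrogen_progesterone": 23,
}


@dataclass
class NullDistribution:
    draws: np.ndarray
    subset_size: int
    seed: int
    statistic: str = "pbcor"
    bend: float = 0.2
    region_subset: str = "all"

    @property
    def n_draws(self) -> int:
        return int(len(self.draws))


def _select_regions(anat: pd.DataFrame, regions, region_subset: str) -> pd.Series:
    """Anatomical scores aligned to the given region order, optionally
    restricted to one compartment."""
    a = anat.set_index("region")
    if region_subset != "all":
        if "compartment" not in anat.columns:
            raise ValueError("anatomical score table lacks a compartment column")
        a = a[a["compartment"] == region_subset]
    shared = [r for r in regions if r in a.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 overlapping regions after subsetting")
    return a.loc[shared, "anat_similarity"]


def correlate_anatomy_transcription(
    anat: pd.DataFrame,
    transcr: pd.DataFrame,
    region_subset: str = "all",
    bend: float = 0.2,
):
    """Robust correlation of anatomical similarity scores with transcriptional
    similarity across regions (optionally one compartment only)."""
    t = transcr.set_index("region")["similarity"]
    scores = _select_regions(anat, list(t.index), region_subset)
    return pbcor(scores.to_numpy(), t.loc[scores.index].to_numpy(), bend=bend)


def build_null(
    mat_h: pd.DataFrame,
    mat_m: pd.DataFrame,
    anat: pd.DataFrame,
    k: int,
    n_draws: int = 10_000,
    seed: int = 0,
    region_subset: str = "all",
    bend: float = 0.2,
) -> NullDistribution:
    """Null distribution of anatomy-transcription correlations over random
    gene subsets of size ``k``.

    Each draw samples ``k`` genes without replacement from the shared pool,
    recomputes the per-region similarity on that subset, and correlates it
    with the anatomical scores using the same robust statistic as the
    observed value. Reproducible given ``seed``.
    """
    G = mat_h.shape[0]
    if k < 3:
        raise ValueError("subset size k must be at least 3")
    if k > G:
        raise ValueError(f"subset size k={k} exceeds gene count {G}")
    if n_draws < 1:
        raise ValueError("need at least one draw")
    regions = list(mat_h.columns)
    scores = _select_regions(anat, regions, region_subset)
    col_idx = np.array([regions.index(r) for r in scores.index])
    s = scores.to_numpy()

    rng = np.random.default_rng(seed)
    H = mat_h.to_numpy(dtype=float)[:, col_idx]
    M = mat_m.to_numpy(dtype=float)[:, col_idx]
    draws = np.empty(n_draws)
    chunk = max(1, min(n_draws, 2_000_000 // max(1, k * len(col_idx))))
    done = 0
    while done < n_draws:
        c = min(chunk, n_draws - done)
        idx = np.stack([rng.choice(G, size=k, replace=False) for _ in range(c)])
        Hs, Ms = H[idx], M[idx]  # (c, k, R)
        Hc = Hs - Hs.mean(axis=1, keepdims=True)
        Mc = Ms - Ms.mean(axis=1, keepdims=True)
        denom = np.sqrt((Hc**2).sum(axis=1) * (Mc**2).sum(axis=1))
        sims = (Hc * Mc).sum(axis=1) / denom  # (c, R)
        for i in range(c):
            draws[done + i] = pbcor(s, sims[i], bend=bend).r
        done += c
    return NullDistribution(
        draws=draws, subset_size=k, seed=seed, bend=bend, region_subset=region_subset
    )


def permutation_pvalue(observed: float, null: NullDistribution,
                       direction: str = "two_sided") -> float:
    """Add-one empirical p-value of an observed correlation under a null."""
    draws = np.asarray(null.draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty null distribution")
    n = draws.size
    p_greater = (1.0 + np.sum(draws >= observed)) / (1.0 + n)
    p_less = (1.0 + np.sum(draws <= observed)) / (1.0 + n)
    if direction == "greater":
        return float(p_greater)
    if direction == "less":
        return float(p_less)
    if direction == "two_sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError("direction must be 'greater', 'less', or 'two_sided'")
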