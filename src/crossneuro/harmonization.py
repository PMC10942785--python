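"""Empirical-Bayes batch harmonization of regional volumes (ComBat).

Parametric ComBat removes additive (location) and multiplicative (scale)
batch effects from a subject-by-region matrix while preserving the variance
attributable to biological covariates (by default sex and age). Per region,
the data are standardized with covariate effects retained in the grand mean,
per-batch location/scale estimates are shrunk toward priors fitted across
regions (normal prior for locations, inverse-gamma for scales, moment-matched
and refined by the standard iterative EB update), the shrunken effects are
removed, and the covariate structure is restored.

Harmonization is performed strictly *within* each level of an optional outer
grouping (background strain in the mouse cohort); batches never span groups.
A group with a single batch is returned untouched -- there is nothing to
remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["combat", "HarmonizationModel"]


@dataclass
class HarmonizationModel:
    """Fitted ComBat parameters, one entry per outer group (e.g. strain).

    ``gamma_star[group]`` / ``delta2_star[group]`` are batch-by-region frames
    of the shrunken additive effects and squared scale factors.
    """

    gamma_star: dict = field(default_factory=dict)
    delta2_star: dict = field(default_factory=dict)
    gamma_hat: dict = field(default_factory=dict)
    delta2_hat: dict = field(default_factory=dict)
    prior_location: dict = field(default_factory=dict)
    batch_sizes: dict = field(default_factory=dict)
    n_iterations: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def frames(d):
            return {g: v.to_dict() if isinstance(v, pd.DataFrame) else v for g, v in d.items()}

        return {
            "gamma_star": frames(self.gamma_star),
            "delta2_star": frames(self.delta2_star),
            "prior_location": self.prior_location,
            "batch_sizes": self.batch_sizes,
            "n_iterations": self.n_iterations,
        }


def _eb_iterate(gamma_hat, delta2_hat, z, batch_masks, tol=1e-4, max_iter=100):
    """Iterative EB update of batch location/scale effects (one group).

    gamma_hat, delta2_hat: (B, G); z: (n, G) standardized data.
    Returns gamma_star, delta2_star, iteration counts per batch.
    """
    B, G = gamma_hat.shape
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    n_iters = []
    for b in range(B):
        g_hat, d2_hat = gamma_hat[b], delta2_hat[b]
        zb = z[batch_masks[b]]
        n_b = zb.shape[0]
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d2_hat.mean(), d2_hat.var(ddof=1)
        # moment-matched inverse-gamma hyperparameters
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        g_old, d2_old = g_hat.copy(), d2_hat.copy()
        count = 0
        while count < max_iter:
            g_new = (n_b * t2 * g_hat + d2_old * g_bar) / (n_b * t2 + d2_old)
            sum2 = ((zb - g_new[None, :]) ** 2).sum(axis=0)
            d2_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d2_new - d2_old) / np.maximum(np.abs(d2_old), 1e-12)),
            )
            g_old, d2_old = g_new, d2_new
            count += 1
            if change < tol:
                break
        gamma_star[b], delta2_star[b] = g_old, d2_old
        n_iters.append(count)
    return gamma_star, delta2_star, n_iters


def _combat_one_group(Y, batch, design_cov):
    """Parametric ComBat on one outer group. Y: (n, G); batch: array of labels."""
    n, G = Y.shape
    batches = list(pd.unique(batch))
    masks = [batch == b for b in batches]
    sizes = np.array([m.sum() for m in masks])
    if np.any(sizes < 2):
        small = [b for b, s in zip(batches, sizes) if s < 2]
        raise ValueError(f"singleton batch(es): {small}")

    # design: batch indicators (no global intercept) + covariates
    Xb = np.column_stack([m.astype(float) for m in masks])
    X = np.column_stack([Xb, design_cov]) if design_cov is not None else Xb
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate harmonization design (collinear covariates)")
    B_hat = np.linalg.solve(X.T @ X, X.T @ Y)

    grand = (sizes / n) @ B_hat[: len(batches)]
    stand_mean = np.tile(grand, (n, 1))
    if design_cov is not None:
        stand_mean = stand_mean + design_cov @ B_hat[len(batches):]
    var_pooled = ((Y - X @ B_hat) ** 2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise ValueError("zero pooled variance in at least one region")
    sd = np.sqrt(var_pooled)

    Z = (Y - stand_mean) / sd[None, :]
    gamma_hat = np.vstack([Z[m].mean(axis=0) for m in masks])
    delta2_hat = np.vstack([Z[m].var(axis=0, ddof=1) for m in masks])

    gamma_star, delta2_star, iters = _eb_iterate(gamma_hat, delta2_hat, Z, masks)

    adj = Z.copy()
    for b, m in enumerate(masks):
        adj[m] = (Z[m] - gamma_star[b][None, :]) / np.sqrt(delta2_star[b])[None, :]
    Y_adj = adj * sd[None, :] + stand_mean
    return Y_adj, batches, sizes, gamma_hat, delta2_hat, gamma_star, delta2_star, iters


def combat(
    volumes: pd.DataFrame,
    subjects: pd.DataFrame,
    preserve: Sequence[str] = ("sex", "age"),
    batch_col: str = "cohort",
    within_col: str | None = "strain",
):
    """Harmonize a subject-by-region volume matrix across batches.

    Parameters
    ----------
    volumes : subject-by-region matrix, rows aligned with ``subjects``.
    subjects : covariate table; must carry ``batch_col`` (and ``within_col``
        if given).
    preserve : biological covariates whose effects are retained. ``sex`` is
        dummy-coded F=0/M=1; numeric covariates are mean-centered.
    within_col : optional outer grouping (e.g. background strain); batches are
        harmonized independently within each group and must not span groups.

    Returns ``(harmonized volumes, HarmonizationModel)``.
    """
    if len(subjects) != len(volumes):
        raise ValueError("subject table and volume matrix are misaligned")
    if batch_col not in subjects.columns:
        raise ValueError(f"every subject needs a {batch_col!r} assignment")
    batch = subjects[batch_col].to_numpy()
    if within_col is not None and within_col in subjects.columns:
        group = subjects[within_col].to_numpy()
        span = pd.DataFrame({"b": batch, "g": group}).groupby("b")["g"].nunique()
        bad = span[span > 1].index.tolist()
        if bad:
            raise ValueError(f"batch(es) spanning multiple {within_col} groups: {bad}")
    else:
        group = np.array(["all"] * len(subjects))

    cov_cols = []
    for name in preserve:
        if name == "sex":
            cov_cols.append((subjects["sex"].to_numpy() == "M").astype(float))
        else:
            v = subjects[name].to_numpy(dtype=float)
            cov_cols.append(v - v.mean())
    design_cov = np.column_stack(cov_cols) if cov_cols else None

    Y = volumes.to_numpy(dtype=float)
    out = Y.copy()
    model = HarmonizationModel()
    regions = list(volumes.columns)
    for g in pd.unique(group):
        gm = group == g
        g_batches = pd.unique(batch[gm])
        if len(g_batches) < 2:
            model.batch_sizes[str(g)] = {str(b): int((batch[gm] == b).sum()) for b in g_batches}
            model.n_iterations[str(g)] = []
            continue  # single batch: nothing to remove
        cov_g = design_cov[gm] if design_cov is not None else None
        (Y_adj, batches, sizes, gh, d2h, gs, d2s, iters) = _combat_one_group(
            Y[gm], batch[gm], cov_g
        )
        out[gm] = Y_adj
        bindex = pd.Index([str(b) for b in batches], name=batch_col)
        model.gamma_hat[str(g)] = pd.DataFrame(gh, index=bindex, columns=regions)
        model.delta2_hat[str(g)] = pd.DataFrame(d2h, index=bindex, columns=regions)
        model.gamma_star[str(g)] = pd.DataFrame(gs, index=bindex, columns=regions)
        model.delta2_star[str(g)] = pd.DataFrame(d2s, index=bindex, columns=regions)
        model.prior_location[str(g)] = model.gamma_hat[str(g)].mean(axis=1).to_dict()
        model.batch_sizes[str(g)] = dict(zip(bindex, (int(s) for s in sizes)))
        model.n_iterations[str(g)] = iters

    harmonized = pd.DataFrame(out, index=volumes.index, columns=volumes.columns)
    harmonized.attrs.update(volumes.attrs)
    harmonized.attrs["harmonized"] = True
    return harmonized, model
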