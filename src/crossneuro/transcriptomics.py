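"""Gene-by-region expression matrices and cross-species transcriptional similarity.

The pipeline order is fixed: aggregate unit-level expression into regions,
reflect hemispheres to fill one-sided gaps, intersect to the shared homologous
gene set, z-score each gene across regions, then correlate the two species'
z-scored profiles per region. Z-scoring happens *after* the gene intersection
so that genes dropped for zero regional variance are always dropped from both
species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_expression",
    "reflect_hemisphere",
    "intersect_homologous_genes",
    "zscore_across_regions",
    "zscore_pair",
    "transcriptional_similarity",
]


def aggregate_expression(unit_matrix: pd.DataFrame, unit_labels: pd.Series,
                         unit_weights: pd.Series | None = None):
    """Aggregate a gene-by-unit matrix into a gene-by-region matrix.

    ``unit_labels`` maps each unit (column) to a region id; unlabeled units
    (NaN) are ignored and counted in the report. If ``unit_weights`` is given
    (human component volumes), regions are weighted means of their units;
    otherwise plain means (the mouse voxel case). Returns ``(matrix, report)``.
    """
    labels = unit_labels.reindex(unit_matrix.columns)
    mapped = labels.notna()
    if not mapped.any():
        raise ValueError("no units map to any region")
    if unit_weights is not None:
        w = unit_weights.reindex(unit_matrix.columns).astype(float)
        if (w[mapped] <= 0).any() or w[mapped].isna().any():
            raise ValueError("unit weights must be positive for mapped units")
    else:
        w = pd.Series(1.0, index=unit_matrix.columns)

    out = {}
    for region, cols in labels[mapped].groupby(labels[mapped]).groups.items():
        ww = w[cols].to_numpy()
        vals = unit_matrix[cols].to_numpy(dtype=float)
        out[region] = vals @ (ww / ww.sum())
    mat = pd.DataFrame(out, index=unit_matrix.index)
    mat.attrs.update(unit_matrix.attrs)
    mat.attrs["provenance"] = (
        "sample_aggregated" if unit_weights is not None else "voxel_aggregated"
    )
    report = {"n_units_ignored": int((~mapped).sum()), "n_regions": mat.shape[1]}
    return mat, report


def reflect_hemisphere(matrix: pd.DataFrame, registry: pd.DataFrame):
    """Fill a missing hemisphere of a bilateral region from its counterpart.

    A region column counts as missing if absent or entirely NaN. Midline
    regions have no counterpart; regions missing on both sides stay missing.
    Returns ``(matrix, report)`` where the report lists reflected and
    still-missing region ids.
    """
    mat = matrix.copy()
    mat.attrs.update(matrix.attrs)

    def missing(rid: str) -> bool:
        return rid not in mat.columns or mat[rid].isna().all()

    reflected, still_missing = [], []
    for label, grp in registry.groupby("label", sort=False):
        hemis = set(grp["hemisphere"])
        if hemis == {"L", "R"}:
            left, right = f"{label}|L", f"{label}|R"
            for a, b in ((left, right), (right, left)):
                if missing(a) and not missing(b):
                    mat[a] = mat[b].to_numpy()
                    reflected.append(a)
            if missing(left) and missing(right):
                still_missing.extend([left, right])
        else:
            for h in hemis:
                rid = f"{label}|{h}"
                if missing(rid):
                    still_missing.append(rid)
    report = {"reflected": reflected, "missing": still_missing}
    return mat, report


def intersect_homologous_genes(mat_h: pd.DataFrame, mat_m: pd.DataFrame,
                               homology_map: pd.DataFrame):
    """Restrict both matrices to the shared homologous gene set.

    ``homology_map`` needs ``human_gene`` and ``mouse_gene`` columns forming
    unique one-to-one pairs. Both outputs are row-ordered identically and
    indexed by the human symbol, so the gene lists are exchangeable downstream.
    """
    for col in ("human_gene", "mouse_gene"):
        if homology_map[col].duplicated().any():
            dups = homology_map[col][homology_map[col].duplicated()].tolist()
            raise ValueError(f"homology map has duplicate {col} entries: {dups[:5]}")
    keep = homology_map[
        homology_map["human_gene"].isin(mat_h.index)
        & homology_map["mouse_gene"].isin(mat_m.index)
    ]
    if len(keep) == 0:
        raise ValueError("empty homologous-gene intersection")
    out_h = mat_h.loc[keep["human_gene"]].copy()
    out_m = mat_m.loc[keep["mouse_gene"]].copy()
    out_m.index = keep["human_gene"].to_numpy()  # shared symbol space
    out_h.index.name = out_m.index.name = "gene"
    out_h.attrs.update(mat_h.attrs)
    out_m.attrs.update(mat_m.attrs)
    return out_h, out_m


def zscore_across_regions(matrix: pd.DataFrame):
    """Z-score every gene across regions; drop zero-variance genes.

    Returns ``(zscored matrix, list of dropped genes)``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 regions to z-score across regions")
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    ok = sd > 0
    z = (vals[ok] - vals[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    out = pd.DataFrame(z, index=matrix.index[ok], columns=matrix.columns)
    out.attrs.update(matrix.attrs)
    out.attrs["zscored"] = True
    return out, list(matrix.index[~ok])


def zscore_pair(mat_h: pd.DataFrame, mat_m: pd.DataFrame):
    """Z-score both species' matrices, dropping degenerate genes pairwise.

    A gene constant across regions in *either* species is removed from both,
    so the shared gene list stays identical. Returns
    ``(z_human, z_mouse, dropped)``.
    """
    zh, drop_h = zscore_across_regions(mat_h)
    zm, drop_m = zscore_across_regions(mat_m)
    dropped = sorted(set(drop_h) | set(drop_m))
    keep = [g for g in zh.index if g in set(zm.index) and g not in set(dropped)]
    out_h, out_m = zh.loc[keep], zm.loc[keep]
    out_h.attrs.update(zh.attrs)
    out_m.attrs.update(zm.attrs)
    return out_h, out_m, dropped


def transcriptional_similarity(mat_h: pd.DataFrame, mat_m: pd.DataFrame,
                               gene_subset=None, subset_tag: str = "all") -> pd.DataFrame:
    """Per-region Pearson correlation of the two species' expression profiles.

    Matrices must already be aligned on genes and regions (z-scored across
    regions). With ``gene_subset``, the correlation uses only those genes
    (at least 3, all present in both matrices). Symmetric in species order.
    """
    if list(mat_h.index) != list(mat_m.index):
        raise ValueError("matrices are not aligned on genes")
    if list(mat_h.columns) != list(mat_m.columns):
        raise ValueError("matrices are not aligned on regions")
    if gene_subset is not None:
        subset = list(gene_subset)
        missing = set(subset) - set(mat_h.index)
        if missing:
            raise ValueError(f"gene subset outside shared genes: {sorted(missing)[:5]}")
        if len(subset) < 3:
            raise ValueError("gene subset must have at least 3 genes")
        mat_h, mat_m = mat_h.loc[subset], mat_m.loc[subset]
    H = mat_h.to_numpy(dtype=float)
    M = mat_m.to_numpy(dtype=float)
    Hc = H - H.mean(axis=0)
    Mc = M - M.mean(axis=0)
    denom = np.sqrt((Hc**2).sum(axis=0) * (Mc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Hc * Mc).sum(axis=0) / denom
    return pd.DataFrame(
        {
            "region": list(mat_h.columns),
            "similarity": r,
            "n_genes": H.shape[0],
            "gene_subset": subset_tag,
        }
    )
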