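"""Synthetic two-species cohorts and paired expression matrices.

The generators in this module produce data with the statistical structure the
downstream analysis assumes: per-subject covariate tables plus subject-by-region
volume matrices for a human-like and a mouse-like cohort, and paired
gene-by-region expression matrices with a controllable per-region cross-species
correlation. Every generative coefficient is recorded in a truth record so that
estimator-recovery tests can compare fitted values against ground truth.

Volumes are generated on a unit-SD latent scale

    y*_ir = beta_ttv * ttvz_i + beta_age * agez_i + beta_sex_r * male_i
            + batch_b(i),r + eps_ir

and mapped affinely to positive mm^3 values per region. ``true_sex_beta`` is
interpreted as the *standardized* effect size the analysis estimates (an OLS
coefficient for the male indicator fitted on z-scored volumes). Because
z-scoring divides by the marginal SD of the volume -- which itself grows with
the planted sex effect and the covariate effects -- the generator solves the
self-consistency

    sd_y^2 = V_rest / (1 - beta^2 * p * (1 - p)),   beta_raw = beta * sd_y

(with ``p`` the male fraction and ``V_rest`` the variance contributed by
covariates, batch offsets, and noise) so that the requested beta is exactly the
coefficient an OLS fit on z-scored volumes recovers in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "ExpressionSpec",
    "simulate_cohort",
    "simulate_expression_pair",
    "default_human_spec",
    "default_mouse_spec",
    "default_expression_spec",
    "default_gene_homology_map",
    "MOUSE_COHORT_DESIGN",
    "save_cohort",
]

#: Per-cohort (cohort, strain, n_female, n_male) design of the multi-lab mouse
#: sample: 12 C57BL6J cohorts (134 F / 141 M) and 6 C57BL6N cohorts
#: (79 F / 75 M), 213 F / 216 M in total.
MOUSE_COHORT_DESIGN: tuple[tuple[str, str, int, int], ...] = (
    ("A", "C57BL6J", 10, 12), ("B", "C57BL6J", 15, 15), ("C", "C57BL6J", 27, 29),
    ("D", "C57BL6J", 13, 7), ("E", "C57BL6J", 8, 11), ("F", "C57BL6J", 9, 10),
    ("G", "C57BL6J", 7, 9), ("H", "C57BL6J", 10, 10), ("I", "C57BL6J", 7, 9),
    ("J", "C57BL6J", 10, 6), ("K", "C57BL6J", 9, 8), ("L", "C57BL6J", 9, 15),
    ("M", "C57BL6N", 13, 19), ("N", "C57BL6N", 10, 8), ("O", "C57BL6N", 25, 14),
    ("P", "C57BL6N", 9, 9), ("Q", "C57BL6N", 9, 13), ("R", "C57BL6N", 13, 12),
)

_TTV_PARAMS = {"human": (1_200_000.0, 100_000.0), "mouse": (450.0, 20.0)}
_MU_RANGE = {"human": (200.0, 20_000.0), "mouse": (0.5, 30.0)}


@dataclass
class CohortSpec:
    """Generative specification for one species' cohort.

    ``true_sex_beta`` may be a scalar (broadcast to all regions) or a
    per-region sequence/mapping, in SD units with positive = male-larger.
    ``ttv_sex_shift`` is the male-minus-female gap of total tissue volume in
    SD units. ``batch_shift`` gives additive per-batch offsets on the latent
    (unit-SD) scale; batch membership is assigned deterministically and never
    consumes random numbers, so zero shifts reproduce a single-batch run
    bit-for-bit. ``sex_variance_ratio`` scales the male residual SD relative
    to the female one.
    """

    n_female: int
    n_male: int
    region_labels: Sequence[str]
    true_sex_beta: float | Sequence[float] | Mapping[str, float] = 0.0
    ttv_sex_shift: float = 0.0
    age_range: tuple[float, float] = (22.0, 36.0)
    batch_labels: Sequence[str] | None = None
    batch_shift: Mapping[str, float] | None = None
    cohort_design: Sequence[tuple[str, str, int, int]] | None = None
    sex_variance_ratio: float | Sequence[float] = 1.0
    noise_sd: float = 1.0
    beta_ttv: float = 0.5
    beta_age: float = -0.1
    euler_range: tuple[int, int] = (-136, -16)
    euler_outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 2 or self.n_male < 2:
            raise ValueError("need at least 2 subjects per sex")
        labels = list(self.region_labels)
        if len(labels) != len(set(labels)):
            raise ValueError("region labels must be unique")
        ratio = np.atleast_1d(np.asarray(self.sex_variance_ratio, dtype=float))
        if np.any(ratio <= 0):
            raise ValueError("sex_variance_ratio must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.cohort_design is not None:
            nf = sum(d[2] for d in self.cohort_design)
            nm = sum(d[3] for d in self.cohort_design)
            if (nf, nm) != (self.n_female, self.n_male):
                raise ValueError("cohort_design totals disagree with n_female/n_male")

    def beta_vector(self) -> np.ndarray:
        labels = list(self.region_labels)
        if isinstance(self.true_sex_beta, Mapping):
            return np.array([float(self.true_sex_beta.get(r, 0.0)) for r in labels])
        arr = np.atleast_1d(np.asarray(self.true_sex_beta, dtype=float))
        if arr.size == 1:
            return np.full(len(labels), arr.item())
        if arr.size != len(labels):
            raise ValueError("true_sex_beta length does not match region_labels")
        return arr.astype(float)


@dataclass
class ExpressionSpec:
    """Specification for a paired human/mouse gene-by-region expression draw.

    ``target_similarity`` is the intended per-region cross-species correlation
    rho_r of the gene vectors before downstream z-scoring (scalar or
    per-region).
    """

    n_genes: int
    region_labels: Sequence[str]
    target_similarity: float | Sequence[float] = 0.0
    gene_subset_tags: Mapping[str, Sequence[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("need at least 3 genes")
        rho = np.atleast_1d(np.asarray(self.target_similarity, dtype=float))
        if np.any(np.abs(rho) > 1):
            raise ValueError("|target_similarity| must be <= 1")

    def rho_vector(self) -> np.ndarray:
        labels = list(self.region_labels)
        arr = np.atleast_1d(np.asarray(self.target_similarity, dtype=float))
        if arr.size == 1:
            return np.full(len(labels), arr.item())
        if arr.size != len(labels):
            raise ValueError("target_similarity length does not match region_labels")
        return arr.astype(float)


def _batch_assignment(spec: CohortSpec, species: str):
    """Deterministic batch/strain labels per subject (females first, then males)."""
    n = spec.n_female + spec.n_male
    if species == "mouse" and spec.cohort_design is not None:
        cohorts, strains = [], []
        for sex_col in (2, 3):  # female block first, then male block
            for d in spec.cohort_design:
                cohorts.extend([d[0]] * d[sex_col])
                strains.extend([d[1]] * d[sex_col])
        return np.array(cohorts), np.array(strains)
    if spec.batch_labels:
        labs = list(spec.batch_labels)
        cohorts = np.array([labs[i % len(labs)] for i in range(n)])
    else:
        cohorts = np.array(["batch0"] * n)
    strains = np.array(["C57BL6J"] * n) if species == "mouse" else None
    return cohorts, strains


def simulate_cohort(spec: CohortSpec, species: str):
    """Draw a cohort for one species.

    Returns ``(subjects, volumes, truth)``: the per-subject covariate table,
    the aligned subject-by-region volume matrix (mm^3), and a truth record
    holding every generative coefficient. Deterministic given ``spec.seed``.
    """
    if species not in ("human", "mouse"):
        raise ValueError(f"unknown species tag: {species!r}")
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.region_labels)
    n_f, n_m = spec.n_female, spec.n_male
    n, n_regions = n_f + n_m, len(labels)
    male = np.concatenate([np.zeros(n_f), np.ones(n_m)])
    p = n_m / n

    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, n)
    ttv_z = rng.standard_normal(n)
    euler = None
    if species == "human":
        e_lo, e_hi = spec.euler_range
        euler = rng.integers(e_lo, e_hi + 1, n).astype(float)
        if spec.euler_outlier_fraction > 0:
            is_out = rng.random(n) < spec.euler_outlier_fraction
            euler[is_out] = rng.integers(-300, -201, n)[is_out]
    noise = rng.standard_normal((n, n_regions))

    ttv_mean, ttv_sd = _TTV_PARAMS[species]
    ttvz = ttv_z + spec.ttv_sex_shift * male  # standardized TTV incl. sex gap
    ttv = ttv_mean + ttv_sd * ttvz

    age_sd = (hi - lo) / np.sqrt(12.0) if hi > lo else 1.0
    agez = (age - (lo + hi) / 2.0) / age_sd

    cohorts, strains = _batch_assignment(spec, species)
    shift_map = dict(spec.batch_shift or {})
    batch_off = np.array([shift_map.get(c, 0.0) for c in cohorts])

    ratio = np.atleast_1d(np.asarray(spec.sex_variance_ratio, dtype=float))
    ratio = np.full(n_regions, ratio.item()) if ratio.size == 1 else ratio
    eps_scale = np.where(male[:, None] > 0, ratio[None, :], 1.0) * spec.noise_sd

    beta = spec.beta_vector()
    if np.any(beta**2 * p * (1 - p) >= 1.0):
        raise ValueError("true_sex_beta too large for a unit-variance outcome")

    # batch-free rest-variance; the planted beta refers to the batch-free data
    var_ttvz = 1.0 + spec.ttv_sex_shift**2 * p * (1 - p)
    var_eps = spec.noise_sd**2 * (p * ratio**2 + (1 - p))
    v_rest = spec.beta_ttv**2 * var_ttvz + spec.beta_age**2 + var_eps
    sd_y = np.sqrt(v_rest / (1.0 - beta**2 * p * (1 - p)))
    beta_raw = beta * sd_y

    latent = (
        spec.beta_ttv * ttvz[:, None]
        + spec.beta_age * agez[:, None]
        + male[:, None] * beta_raw[None, :]
        + batch_off[:, None]
        + noise * eps_scale
    )

    mu = np.geomspace(*_MU_RANGE[species], n_regions)
    latent_scale = 0.1 * mu / sd_y
    volumes = mu[None, :] + latent_scale[None, :] * latent

    prefix = "H" if species == "human" else "M"
    ids = [f"{prefix}{i:05d}" for i in range(n)]
    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "species": species,
            "sex": np.where(male > 0, "M", "F"),
            "age": age,
            "ttv": ttv,
        }
    )
    if species == "human":
        subjects["euler"] = euler.astype(int)
    else:
        subjects["cohort"] = cohorts
        subjects["strain"] = strains
    vol = pd.DataFrame(volumes, index=pd.Index(ids, name="subject_id"), columns=labels)
    vol.attrs["state"] = "raw"

    truth = {
        "species": species,
        "seed": spec.seed,
        "true_sex_beta": dict(zip(labels, beta.tolist())),
        "beta_raw_latent": dict(zip(labels, beta_raw.tolist())),
        "sd_latent": dict(zip(labels, sd_y.tolist())),
        "latent_offset": dict(zip(labels, mu.tolist())),
        "latent_scale": dict(zip(labels, latent_scale.tolist())),
        "beta_ttv": spec.beta_ttv,
        "beta_age": spec.beta_age,
        "ttv_sex_shift": spec.ttv_sex_shift,
        "ttv_mean": ttv_mean,
        "ttv_sd": ttv_sd,
        "noise_sd": spec.noise_sd,
        "sex_variance_ratio": dict(zip(labels, ratio.tolist())),
        "batch_shift": shift_map,
    }
    return subjects, vol, truth


def simulate_expression_pair(spec: ExpressionSpec):
    """Draw paired human/mouse gene-by-region expression matrices.

    For each region r the mouse gene vector is ``rho_r * human + sqrt(1 -
    rho_r^2) * noise`` so the intended cross-species correlation over genes is
    ``rho_r`` before downstream z-scoring. Both matrices share the gene index.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.region_labels)
    rho = spec.rho_vector()
    G, R = spec.n_genes, len(labels)
    human = rng.standard_normal((G, R))
    indep = rng.standard_normal((G, R))
    mouse = rho[None, :] * human + np.sqrt(1.0 - rho[None, :] ** 2) * indep
    genes = pd.Index([f"G{i:04d}" for i in range(G)], name="gene")
    mat_h = pd.DataFrame(human, index=genes, columns=labels)
    mat_m = pd.DataFrame(mouse, index=genes, columns=labels)
    for mat, sp in ((mat_h, "human"), (mat_m, "mouse")):
        mat.attrs.update(species=sp, provenance="synthetic", zscored=False)
    truth = {
        "seed": spec.seed,
        "target_similarity": dict(zip(labels, rho.tolist())),
        "n_genes": G,
        "gene_subset_tags": {g: list(t) for g, t in (spec.gene_subset_tags or {}).items()},
    }
    return mat_h, mat_m, truth


def default_human_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Human-like cohort: 597 F / 496 M pre-QC, male TTV shift of 1.28 SD,
    ages 22-36 y, surface-quality (Euler) numbers in the observed [-136, -16]
    range with no quality outliers unless requested."""
    kw = dict(
        n_female=597,
        n_male=496,
        region_labels=[f"region{i:03d}" for i in range(100)],
        ttv_sex_shift=1.28,
        age_range=(22.0, 36.0),
        euler_range=(-136, -16),
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def default_mouse_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Mouse-like cohort: 213 F / 216 M over 18 cohorts in 2 background
    strains, no TTV sex shift, ages 56-90 postnatal days."""
    kw = dict(
        n_female=213,
        n_male=216,
        region_labels=[f"region{i:03d}" for i in range(100)],
        ttv_sex_shift=0.0,
        age_range=(56.0, 90.0),
        cohort_design=MOUSE_COHORT_DESIGN,
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def default_expression_spec(
    region_labels: Sequence[str], seed: int = 0, **overrides
) -> ExpressionSpec:
    """2835 homologous genes with the field's gene-subset sizes: 91 X-linked,
    11 androgen and 23 estrogen/progesterone signaling genes (34 hormone genes
    in total); remaining genes untagged."""
    n_genes = int(overrides.pop("n_genes", 2835))
    tags: dict[str, list[str]] = {}
    genes = [f"G{i:04d}" for i in range(n_genes)]
    for g in genes[:91]:
        tags[g] = ["x_linked"]
    for g in genes[91:102]:
        tags[g] = ["hormone", "androgen"]
    for g in genes[102:125]:
        tags[g] = ["hormone", "estrogen_progesterone"]
    kw = dict(
        n_genes=n_genes,
        region_labels=list(region_labels),
        gene_subset_tags=tags,
        seed=seed,
    )
    kw.update(overrides)
    return ExpressionSpec(**kw)


def default_gene_homology_map(n_genes: int = 2835) -> pd.DataFrame:
    """One-to-one synthetic human<->mouse gene symbol map (Gnnnn <-> gnnnn)."""
    human = [f"G{i:04d}" for i in range(n_genes)]
    mouse = [g.lower() for g in human]
    return pd.DataFrame({"human_gene": human, "mouse_gene": mouse})


def save_cohort(out_dir, subjects: pd.DataFrame, volumes: pd.DataFrame, truth: dict,
                stem: str = "cohort") -> None:
    """Write a simulated cohort as TSVs plus a sidecar JSON truth record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(out / f"{stem}_subjects.tsv", sep="\t", index=False)
    volumes.to_csv(out / f"{stem}_volumes.tsv", sep="\t")
    (out / f"{stem}_truth.json").write_text(json.dumps(truth, indent=1))
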