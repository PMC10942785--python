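"""Registry of homologous human-mouse brain regions and effect pairing.

The packaged registry lists 60 region instances with well-established
human-mouse homology: 28 bilateral pairs plus 4 midline structures. Each
instance carries the atlas components it aggregates in either species, a
cortical / non-cortical compartment label, and a flag for whether regional
expression data exist (false only for the bilateral medial amygdalar nucleus
and medial preoptic area, leaving 56 expression-bearing instances).

Regions are identified throughout the package by the id ``"label|hemisphere"``
(hemisphere L, R, or M for midline). A packaged fixture encodes the two
species' standardized sex effect sizes for all 60 instances, with positive
values meaning larger in males.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import pandas as pd

from .congruence import quadrant_classify

__all__ = [
    "load_homology_registry",
    "load_reference_effects",
    "reference_effect_tables",
    "pair_effects",
    "region_id",
]

_HEMIS = {"L", "R", "M"}


def region_id(label: str, hemisphere: str) -> str:
    return f"{label}|{hemisphere}"


def _packaged(name: str):
    return resources.files("crossneuro.data").joinpath(name)


def load_homology_registry(path: str | Path | None = None) -> pd.DataFrame:
    """Load and validate the homologous-region registry.

    With no argument, the packaged default is loaded and its documented counts
    (60 instances, 56 with expression data) are enforced. A user-supplied TSV
    must provide the same columns but may define any region set.
    """
    if path is None:
        with resources.as_file(_packaged("homologous_regions.tsv")) as f:
            reg = pd.read_csv(f, sep="\t", dtype=str)
    else:
        reg = pd.read_csv(Path(path), sep="\t", dtype=str)
    required = {"label", "hemisphere", "human_components", "mouse_components",
                "compartment", "has_expression"}
    missing = required - set(reg.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    if len(reg) == 0:
        raise ValueError("empty registry file")
    bad_hemi = set(reg["hemisphere"]) - _HEMIS
    if bad_hemi:
        raise ValueError(f"unknown hemisphere code(s): {sorted(bad_hemi)}")
    flag_map = {"1": True, "0": False, "true": True, "false": False,
                "True": True, "False": False}
    reg["has_expression"] = reg["has_expression"].map(flag_map)
    if reg["has_expression"].isna().any():
        raise ValueError("has_expression must be boolean-coded (0/1)")
    reg["region"] = [region_id(l, h) for l, h in zip(reg["label"], reg["hemisphere"])]
    dup = reg["region"][reg["region"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate label/hemisphere entries: {sorted(set(dup))}")
    bad_comp = set(reg["compartment"]) - {"cortical", "non_cortical"}
    if bad_comp:
        raise ValueError(f"unknown compartment value(s): {sorted(bad_comp)}")
    if path is None:
        # packaged defaults carry documented invariants
        assert len(reg) == 60 and int(reg["has_expression"].sum()) == 56
    return reg


def load_reference_effects(path: str | Path | None = None) -> pd.DataFrame:
    """Packaged per-region sex effect sizes for both species (60 rows)."""
    if path is None:
        with resources.as_file(_packaged("reference_sex_effects.tsv")) as f:
            fix = pd.read_csv(f, sep="\t")
    else:
        fix = pd.read_csv(Path(path), sep="\t")
    fix["region"] = [region_id(l, h) for l, h in zip(fix["label"], fix["hemisphere"])]
    fix["sig_human"] = fix["sig_human"].astype(bool)
    fix["sig_mouse"] = fix["sig_mouse"].astype(bool)
    return fix


def reference_effect_tables(path: str | Path | None = None):
    """The fixture split into per-species effect tables (region, beta_sex, sig)."""
    fix = load_reference_effects(path)
    human = pd.DataFrame(
        {"region": fix["region"], "beta_sex": fix["beta_human"], "sig": fix["sig_human"]}
    )
    mouse = pd.DataFrame(
        {"region": fix["region"], "beta_sex": fix["beta_mouse"], "sig": fix["sig_mouse"]}
    )
    return human, mouse


def _sig_flags(effects: pd.DataFrame) -> pd.Series:
    if "q_value" in effects.columns:
        return effects["q_value"] < 0.05
    if "sig" in effects.columns:
        return effects["sig"].astype(bool)
    raise ValueError("effect table needs a q_value or sig column")


def pair_effects(
    effects_human: pd.DataFrame,
    effects_mouse: pd.DataFrame,
    registry: pd.DataFrame,
) -> pd.DataFrame:
    """Join the two species' effect tables over the homology registry.

    Effect tables are matched on the ``region`` id. Registry regions missing
    from either table are dropped with a warning; fewer than 3 resolvable
    regions is an error because every downstream correlation is undefined.
    Returns one row per resolved region with both betas, significance flags,
    the compartment, and the sign-quadrant category.
    """
    if len(effects_human) == 0 or len(effects_mouse) == 0:
        raise ValueError("empty effect table")
    h = effects_human.set_index("region")
    m = effects_mouse.set_index("region")
    sig_h = _sig_flags(effects_human).to_numpy()
    sig_m = _sig_flags(effects_mouse).to_numpy()
    h = h.assign(_sig=sig_h)
    m = m.assign(_sig=sig_m)

    rows, unresolved = [], []
    for _, reg in registry.iterrows():
        rid = reg["region"]
        if rid not in h.index or rid not in m.index:
            unresolved.append(rid)
            continue
        rows.append(
            {
                "region": rid,
                "label": reg["label"],
                "hemisphere": reg["hemisphere"],
                "beta_human": float(h.at[rid, "beta_sex"]),
                "beta_mouse": float(m.at[rid, "beta_sex"]),
                "sig_human": bool(h.at[rid, "_sig"]),
                "sig_mouse": bool(m.at[rid, "_sig"]),
                "compartment": reg["compartment"],
            }
        )
    if unresolved:
        warnings.warn(
            f"{len(unresolved)} registry region(s) unresolved and dropped: {unresolved}",
            stacklevel=2,
        )
    if len(rows) < 3:
        raise ValueError("fewer than 3 resolvable regions; pairing undefined")
    paired = pd.DataFrame(rows)
    return quadrant_classify(paired)
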