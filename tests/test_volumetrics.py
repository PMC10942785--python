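"""QC filtering, standardized sex effects, and BH-FDR against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossneuro.synthetic import CohortSpec, simulate_cohort
from crossneuro.volumetrics import bh_fdr, fit_sex_effects, qc_filter


def _human_table(eulers):
    n = len(eulers)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "species": "human",
            "sex": ["F", "M"] * (n // 2) + ["F"] * (n % 2),
            "age": np.linspace(22, 36, n),
            "ttv": np.linspace(1.1e6, 1.3e6, n),
            "euler": eulers,
        }
    )


class TestQcFilter:
    def test_threshold_is_strict(self):
        subj = _human_table([-250, -200, -100, -16])
        vol = pd.DataFrame(np.arange(8.0).reshape(4, 2), columns=["a", "b"])
        out_s, out_v, report = qc_filter(subj, vol)
        assert report["excluded"] == ["s0"]  # -250 out, -200 retained
        assert len(out_s) == len(out_v) == 3
        assert out_s["subject_id"].tolist() == ["s1", "s2", "s3"]

    def test_typical_range_passes_untouched(self):
        subj = _human_table(list(np.linspace(-136, -16, 10).astype(int)))
        vol = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        _, out_v, report = qc_filter(subj, vol)
        assert report["excluded"] == [] and len(out_v) == 10

    def test_empty_input(self):
        subj = _human_table([]).iloc[:0]
        vol = pd.DataFrame(columns=["a"])
        out_s, out_v, report = qc_filter(subj, vol)
        assert len(out_s) == 0 and len(out_v) == 0 and report["excluded"] == []

    def test_misaligned_rows_rejected(self):
        subj = _human_table([-50, -50])
        vol = pd.DataFrame(np.ones((3, 1)), columns=["a"])
        with pytest.raises(ValueError, match="row counts"):
            qc_filter(subj, vol)

    def test_mouse_rows_pass_through(self):
        subj = pd.DataFrame(
            {
                "subject_id": ["m0", "m1"],
                "species": "mouse",
                "sex": ["F", "M"],
                "age": [60.0, 61.0],
                "ttv": [450.0, 455.0],
                "cohort": ["A", "A"],
                "strain": ["C57BL6J", "C57BL6J"],
            }
        )
        vol = pd.DataFrame(np.ones((2, 1)), columns=["a"])
        _, _, report = qc_filter(subj, vol)
        assert report["excluded"] == []


def _bh_reference(p):
    """Explicit step-up loop, independent of the implementation under test."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestBhFdr:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_identities(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_agrees_with_stepup_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), _bh_reference(p), atol=1e-12)


class TestFitSexEffects:
    def test_recovers_planted_beta(self):
        spec = CohortSpec(
            n_female=200, n_male=200, region_labels=[f"r{i}" for i in range(20)],
            true_sex_beta=0.5, seed=42,
        )
        subj, vol, _ = simulate_cohort(spec, "human")
        eff = fit_sex_effects(subj, vol)
        assert 0.4 < eff["beta_sex"].mean() < 0.6
        assert eff["beta_sex"].between(0.2, 0.8).all()  # per-region, 3-4 SE slack
        assert (np.sign(eff["beta_sex"]) == np.sign(eff["t_value"])).all()
        assert (eff["q_value"] >= eff["p_value"] - 1e-15).all()

    def test_sign_symmetry_under_label_swap(self, small_human_cohort):
        subj, vol, _ = small_human_cohort
        eff = fit_sex_effects(subj, vol)
        swapped = subj.assign(sex=subj["sex"].map({"F": "M", "M": "F"}))
        eff_sw = fit_sex_effects(swapped, vol)
        np.testing.assert_allclose(eff_sw["beta_sex"], -eff["beta_sex"], atol=1e-10)
        np.testing.assert_allclose(eff_sw["p_value"], eff["p_value"], atol=1e-10)

    def test_scale_invariance(self, small_human_cohort):
        subj, vol, _ = small_human_cohort
        eff = fit_sex_effects(subj, vol)
        scaled = vol * 37.5
        eff_sc = fit_sex_effects(subj, scaled)
        for col in ("beta_sex", "t_value", "p_value"):
            np.testing.assert_allclose(eff_sc[col], eff[col], atol=1e-10)

    def test_identical_sex_groups_give_zero_beta(self):
        """Mirror-image male/female groups with balanced covariates."""
        base = np.array([3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        subj = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(12)],
                "species": "human",
                "sex": ["F"] * 6 + ["M"] * 6,
                "age": np.tile([22.0, 30.0, 25.0, 36.0, 28.0, 33.0], 2),
                "ttv": np.tile([1.1e6, 1.15e6, 1.3e6, 1.2e6, 1.28e6, 1.18e6], 2),
                "euler": np.tile([-60, -50, -40, -70, -55, -45], 2),
            }
        )
        vol = pd.DataFrame({"roi": np.tile(base, 2)})
        eff = fit_sex_effects(subj, vol)
        assert eff["beta_sex"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_region_flagged(self, small_human_cohort):
        subj, vol, _ = small_human_cohort
        vol = vol.copy()
        vol["flat"] = 1.0
        eff = fit_sex_effects(subj, vol)
        row = eff.set_index("region").loc["flat"]
        assert row["note"] == "zero-variance region" and np.isnan(row["beta_sex"])
        assert eff.set_index("region")["beta_sex"].drop("flat").notna().all()

    def test_single_sex_rejected(self, small_human_cohort):
        subj, vol, _ = small_human_cohort
        only_f = subj["sex"] == "F"
        with pytest.raises(ValueError, match="per sex"):
            fit_sex_effects(subj[only_f], vol.loc[only_f.to_numpy()])

    def test_dropping_ttv_shifts_betas_maleward(self):
        """With a male TTV advantage, omitting the TTV covariate makes every
        region look more male-biased."""
        spec = CohortSpec(
            n_female=200, n_male=200, region_labels=[f"r{i}" for i in range(30)],
            true_sex_beta=0.0, ttv_sex_shift=1.28, seed=9,
        )
        subj, vol, _ = simulate_cohort(spec, "human")
        with_ttv = fit_sex_effects(subj, vol, covariate_set="with_ttv")
        without = fit_sex_effects(subj, vol, covariate_set="without_ttv")
        assert (without["beta_sex"].to_numpy() > with_ttv["beta_sex"].to_numpy()).all()

    def test_global_target_drops_ttv_covariate(self, small_human_cohort):
        subj, _, _ = small_human_cohort
        glob = pd.DataFrame({"ttv": subj["ttv"].to_numpy()})
        eff = fit_sex_effects(subj, glob, target="global")
        assert "ttv_c" not in eff.attrs["design_columns"]
        assert np.isfinite(eff["beta_sex"].iloc[0])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_type_one_error_is_nominal_property(seed):
    """Under the null generator, region p-values are uniform (spot check)."""
    spec = CohortSpec(
        n_female=40, n_male=40, region_labels=[f"r{i}" for i in range(5)],
        true_sex_beta=0.0, seed=seed,
    )
    subj, vol, _ = simulate_cohort(spec, "human")
    eff = fit_sex_effects(subj, vol)
    assert (eff["p_value"] > 0).all() and (eff["p_value"] <= 1).all()
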