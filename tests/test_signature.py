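"""Signature derivation: association statistics, filters, ranking, hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irdr.signature import (
    SelectionConfig,
    associate_disease,
    associate_treatment,
    combine_and_rank,
    derive_disease_signature,
    filter_treatment_candidates,
    meta_correlation,
    rank_by_hub_connectivity,
)
from irdr.synthetic import CohortSpec, generate_cohort_study, generate_intervention_study
from irdr.types import ExpressionStudy

# printed 8-sample worked fixture for the partial-correlation oracle
_FIXTURE_EXPR = [2.1, 3.4, 1.9, 4.2, 3.8, 2.6, 4.9, 3.1]
_FIXTURE_IR = [1.2, 2.5, 0.9, 3.1, 2.8, 1.6, 3.9, 2.2]
_FIXTURE_AGE = [41.0, 52.0, 38.0, 60.0, 55.0, 47.0, 63.0, 50.0]


def _study_from_vectors(expr_rows: dict[str, list[float]], ir, age) -> ExpressionStudy:
    samples = [f"s{i}" for i in range(len(ir))]
    return ExpressionStudy(
        study_id="fix",
        tissue="muscle",
        design="cross_sectional",
        expression=pd.DataFrame(expr_rows, index=samples).T,
        phenotype=pd.DataFrame(
            {"homa2_ir": ir, "age": age}, index=pd.Index(samples, name="sample_id")
        ),
    )


class TestAssociateDisease:
    def test_expression_equal_to_logir_gives_cc_one(self):
        rng = np.random.default_rng(0)
        ir = np.exp(np.linspace(0, 1.5, 12))
        age = list(40 + 20 * rng.random(12))  # not collinear with log-IR
        study = _study_from_vectors(
            {"gA": list(np.log(ir)), "gB": list(rng.normal(size=12))},
            ir, age,
        )
        res = associate_disease(study).set_index("gene_id")
        assert res.loc["gA", "cc"] == pytest.approx(1.0, abs=1e-9)
        assert res.loc["gA", "p_value"] == pytest.approx(0.0, abs=1e-12)

    def test_partial_cc_equals_two_stage_residual_oracle(self):
        """Worked 8-sample fixture: the age-adjusted partial correlation
        equals the correlation of residuals from regressing both expression
        and log-IR on age."""
        # associate_disease requires >=10 samples: extend the printed
        # 8-sample fixture by two points, shared by both routes
        ir = _FIXTURE_IR + [1.0, 2.0]
        age = _FIXTURE_AGE + [45.0, 58.0]
        expr = _FIXTURE_EXPR + [2.4, 3.6]
        study = _study_from_vectors({"g": expr}, ir, age)
        res = associate_disease(study).set_index("gene_id")

        x = np.log(np.asarray(ir))
        a = np.asarray(age)
        e = np.asarray(expr)
        slope_e = np.polyfit(a, e, 1)
        slope_x = np.polyfit(a, x, 1)
        r_oracle = np.corrcoef(e - np.polyval(slope_e, a), x - np.polyval(slope_x, a))[0, 1]
        assert res.loc["g", "cc"] == pytest.approx(r_oracle, abs=1e-12)

    def test_type_one_error_at_nominal_level(self):
        """1000 null genes at n=200: rejection rate at p<0.05 within 3 s.e."""
        spec = CohortSpec(n_samples=200, n_genes=1000, n_ir_genes=0, seed=42)
        study = generate_cohort_study(spec, "muscle")
        res = associate_disease(study)
        rate = (res["p_value"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < 3 * se

    def test_zero_variance_gene_reported_missing(self):
        rng = np.random.default_rng(8)
        ir = list(np.exp(rng.normal(0.3, 0.5, 12)))
        study = _study_from_vectors(
            {"flat": [5.0] * 12, "ok": list(rng.normal(size=12))},
            ir, list(40 + 20 * rng.random(12)),
        )
        res = associate_disease(study).set_index("gene_id")
        assert np.isnan(res.loc["flat", "cc"])
        assert np.isnan(res.loc["flat", "q_value"])
        assert np.isfinite(res.loc["ok", "q_value"])

    def test_bh_matches_direct_step_up(self):
        spec = CohortSpec(n_samples=50, n_genes=120, n_ir_genes=20, seed=9)
        res = associate_disease(generate_cohort_study(spec, "muscle"))
        p = res["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q_direct = np.empty(m)
        prev = 1.0
        for rank_from_end, i in enumerate(order[::-1]):
            rank = m - rank_from_end
            prev = min(prev, p[i] * m / rank)
            q_direct[i] = prev
        np.testing.assert_allclose(res["q_value"], q_direct, rtol=1e-12)


class TestTreatmentFilter:
    def _frames(self, qs, signs, adipose_sign=1.0):
        frames = []
        for i, (q, s) in enumerate(zip(qs, signs)):
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": ["g"],
                        "cc": [0.4 * s],
                        "p_value": [q / 2],
                        "q_value": [q],
                        "n": [50],
                        "study_id": [f"m{i}"],
                        "tissue": ["muscle"],
                    }
                )
            )
        adipose = [
            pd.DataFrame(
                {
                    "gene_id": ["g"],
                    "cc": [0.3 * adipose_sign],
                    "p_value": [0.2],
                    "q_value": [0.2],
                    "n": [50],
                    "study_id": ["a0"],
                    "tissue": ["adipose"],
                }
            )
        ]
        return frames, adipose

    def test_three_of_four_consistent_and_mean_q_below_threshold_retained(self):
        # mean q = 0.065 < 0.08, signs (+,+,+,-): 3/4 consistent -> retained
        frames, adipose = self._frames(
            [0.02, 0.05, 0.10, 0.09], [1, 1, 1, -1]
        )
        out = filter_treatment_candidates(frames, adipose)
        assert list(out["gene_id"]) == ["g"]
        assert out["mean_q"].iloc[0] == pytest.approx(0.065)
        assert out["frac_consistent"].iloc[0] == pytest.approx(0.75)

    def test_two_of_four_consistent_excluded(self):
        frames, adipose = self._frames([0.01, 0.01, 0.01, 0.01], [1, 1, -1, -1])
        out = filter_treatment_candidates(frames, adipose)
        assert out.empty

    def test_adipose_sign_mismatch_excluded(self):
        frames, adipose = self._frames(
            [0.02, 0.05, 0.10, 0.09], [1, 1, 1, -1], adipose_sign=-1.0
        )
        out = filter_treatment_candidates(frames, adipose)
        assert out.empty

    def test_mean_q_above_threshold_excluded(self):
        frames, adipose = self._frames([0.2, 0.2, 0.01, 0.01], [1, 1, 1, 1])
        assert filter_treatment_candidates(frames, adipose).empty


class TestAssociateTreatment:
    def test_noiseless_theta_recovered(self):
        spec = CohortSpec(n_samples=20, n_genes=4, n_ir_genes=0, noise_sd=1e-12, seed=6)
        genes = [f"G{i:04d}" for i in range(4)]
        thetas = pd.Series([0, -2.0, 1.5, 0], index=genes)
        study = generate_intervention_study(spec, thetas=thetas)
        res = associate_treatment(study).set_index("gene_id")
        assert res.loc["G0001", "cc"] == pytest.approx(-1.0, abs=1e-6)
        assert res.loc["G0002", "cc"] == pytest.approx(1.0, abs=1e-6)

    def test_unpaired_design_rejected(self):
        spec = CohortSpec(n_samples=20, n_genes=4, n_ir_genes=0, seed=6)
        study = generate_cohort_study(spec, "muscle")
        with pytest.raises(ValueError):
            associate_treatment(study)


class TestDiseaseSelection:
    def test_planted_genes_retained_with_correct_signs_low_noise(self):
        spec = CohortSpec(
            n_samples=60, n_genes=120, n_ir_genes=20, noise_sd=1e-6,
            age_effect_sd=1e-6, seed=31,
        )
        from irdr.synthetic import plant_ir_effects

        betas = plant_ir_effects(spec)
        muscle = generate_cohort_study(spec, "muscle", betas=betas)
        adipose = generate_cohort_study(spec, "adipose", betas=betas)
        out = derive_disease_signature([muscle], [adipose])
        planted = set(betas[betas != 0].index)
        assert planted <= set(out["gene_id"])
        merged = out.set_index("gene_id")
        for g in planted:
            assert np.sign(merged.loc[g, "meta_cc"]) == np.sign(betas[g])

    def test_opposite_adipose_sign_excluded(self):
        """A gene significant in muscle but opposite-signed in adipose is
        dropped by the cross-tissue consistency requirement."""
        rng = np.random.default_rng(3)
        n = 100
        ir = np.exp(rng.normal(0.3, 0.6, n))
        age = rng.normal(50, 8, n)
        x = np.log(ir)
        noise = rng.normal(0, 0.3, (2, n))
        muscle = _study_from_vectors(
            {"flip": list(2 * x + noise[0]), "stable": list(2 * x + noise[1])},
            list(ir), list(age),
        )
        adipose = _study_from_vectors(
            {"flip": list(-2 * x + noise[1]), "stable": list(2 * x + noise[0])},
            list(ir), list(age),
        )
        out = derive_disease_signature([muscle], [adipose])
        assert "stable" in set(out["gene_id"])
        assert "flip" not in set(out["gene_id"])

    def test_retained_set_equals_brute_force_filter(self):
        spec = CohortSpec(n_samples=80, n_genes=150, n_ir_genes=30, seed=77)
        from irdr.synthetic import plant_ir_effects

        betas = plant_ir_effects(spec)
        muscle = generate_cohort_study(spec, "muscle", betas=betas)
        adipose = generate_cohort_study(spec, "adipose", betas=betas)
        cfg = SelectionConfig()
        out = set(derive_disease_signature([muscle], [adipose], cfg)["gene_id"])

        m = meta_correlation([associate_disease(muscle)]).set_index("gene_id")
        a = meta_correlation([associate_disease(adipose)]).set_index("gene_id")
        brute = {
            g
            for g in m.index
            if m.loc[g, "q_value"] < cfg.disease_fdr_max
            and abs(m.loc[g, "meta_cc"]) > cfg.disease_min_abs_cc
            and np.sign(a.loc[g, "meta_cc"]) == np.sign(m.loc[g, "meta_cc"])
        }
        assert out == brute


class TestCombineAndRank:
    def _mk(self, genes, zs):
        return pd.DataFrame({"gene_id": genes, "meta_z": zs, "meta_cc": np.tanh(zs)})

    def test_default_sizes_give_120_genes(self):
        genes = [f"g{i:03d}" for i in range(200)]
        z = np.concatenate([np.linspace(3, 8, 100), np.linspace(-8, -3, 100)])
        sig = combine_and_rank(self._mk(genes, z), self._mk([], []))
        assert len(sig.up_genes) == 60 and len(sig.down_genes) == 60
        assert len(sig) == 120
        assert not set(sig.up_genes) & set(sig.down_genes)

    def test_opposite_signs_attenuate_toward_zero(self):
        disease = self._mk(["conflict", "agree"], [4.0, 4.0])
        treatment = self._mk(["conflict", "agree"], [-4.0, 4.0])
        sig = combine_and_rank(disease, treatment, SelectionConfig(n_up=1, n_down=1))
        st = sig.stats.set_index("gene_id")
        # 'agree' keeps full magnitude (scaled by sqrt2), 'conflict' cancels
        assert abs(st.loc["agree", "combined_z"]) == pytest.approx(8 / np.sqrt(2))
        assert "conflict" not in st.index or abs(st.loc["conflict", "combined_z"]) < 1e-9

    def test_ranking_equals_brute_force_sort_on_ten_gene_fixture(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(10)]
        zd = rng.normal(0, 3, 10)
        zt = rng.normal(0, 3, 10)
        sig = combine_and_rank(
            self._mk(genes, zd), self._mk(genes, zt), SelectionConfig(n_up=3, n_down=3)
        )
        combined = -(zd + zt) / np.sqrt(2)
        order = sorted(zip(genes, combined), key=lambda t: (-t[1], t[0]))
        expect_up = [g for g, c in order if c > 0][:3]
        order_neg = sorted(zip(genes, combined), key=lambda t: (t[1], t[0]))
        expect_down = [g for g, c in order_neg if c < 0][:3]
        assert sig.up_genes == expect_up
        assert sig.down_genes == expect_down

    def test_exhausted_candidates_flagged(self):
        with pytest.warns(UserWarning, match="exhausted"):
            sig = combine_and_rank(
                self._mk(["a", "b"], [2.0, -2.0]), self._mk([], []),
            )
        assert sig.truncated
        assert sig.up_genes == ["b"] and sig.down_genes == ["a"]

    def test_up_set_is_upregulated_by_ir_lowering_intervention(self):
        """Sign convention: an exercise-like intervention that lowers IR
        up-regulates the signature's up set."""
        spec = CohortSpec(
            n_samples=80, n_genes=60, n_ir_genes=20, noise_sd=0.05,
            age_effect_sd=1e-6, seed=55,
        )
        from irdr.synthetic import plant_ir_effects

        betas = plant_ir_effects(spec)
        muscle = generate_cohort_study(spec, "muscle", betas=betas)
        adipose = generate_cohort_study(spec, "adipose", betas=betas)
        disease = derive_disease_signature([muscle], [adipose])
        sig = combine_and_rank(
            disease, pd.DataFrame(columns=["gene_id", "meta_z"]),
            SelectionConfig(n_up=5, n_down=5),
        )
        interv = generate_intervention_study(spec, thetas=betas * 3.0)
        d_ir = interv.truth["delta_log_ir"]
        pheno = interv.phenotype
        pre_cols = pheno[pheno.timepoint == "pre"].index
        post_cols = pheno[pheno.timepoint == "post"].index
        mean_delta = (
            interv.expression[post_cols].to_numpy()
            - interv.expression[pre_cols].to_numpy()
        ).mean(axis=1)
        mean_delta = pd.Series(mean_delta, index=interv.genes)
        assert d_ir.mean() < 0  # the intervention lowers IR
        assert (mean_delta[sig.up_genes] > 0).all()
        assert (mean_delta[sig.down_genes] < 0).all()


class TestHubConnectivity:
    def test_three_gene_hand_calculation(self):
        # fixed expression giving known pairwise correlations
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        expr = pd.DataFrame(
            {
                "a": x,
                "b": 0.8 * x + 0.2 * rng.normal(size=30),
                "c": rng.normal(size=30),
            }
        ).T
        expr.columns = [f"s{i}" for i in range(30)]
        k = rank_by_hub_connectivity(expr, ["a", "b", "c"], soft_power=6)
        cor = np.corrcoef(expr.to_numpy())
        adj = np.abs(cor) ** 6
        np.fill_diagonal(adj, 0)
        expect = adj.sum(axis=1)
        for i, g in enumerate(["a", "b", "c"]):
            assert k[g] == pytest.approx(expect[i], rel=1e-12)
        assert list(k.index[:2]) == sorted(["a", "b"], key=lambda g: -k[g])

    def test_uncorrelated_gene_has_minimum_connectivity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        expr = pd.DataFrame(
            {
                "hub1": x,
                "hub2": x + 0.1 * rng.normal(size=200),
                "hub3": x + 0.1 * rng.normal(size=200),
                "lone": rng.normal(size=200),
            }
        ).T
        expr.columns = [f"s{i}" for i in range(200)]
        k = rank_by_hub_connectivity(expr, ["hub1", "hub2", "hub3", "lone"])
        assert k.index[-1] == "lone"

    def test_soft_power_zero_degenerates_to_equal_connectivity(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(4, 20)), index=list("abcd"))
        k = rank_by_hub_connectivity(expr, list("abcd"), soft_power=0)
        np.testing.assert_allclose(k.to_numpy(), 3.0)

    def test_fewer_than_three_genes_rejected(self):
        expr = pd.DataFrame(np.ones((2, 5)), index=["a", "b"])
        with pytest.raises(ValueError):
            rank_by_hub_connectivity(expr, ["a", "b"])


def test_parameter_recovery_of_planted_cross_tissue_genes():
    """>=90% of planted cross-tissue IR genes appear among disease
    candidates at default synthetic settings (fixed seed)."""
    from irdr.synthetic import plant_ir_effects

    spec = CohortSpec(seed=2024)
    betas = plant_ir_effects(spec)
    muscle = generate_cohort_study(spec, "muscle", betas=betas)
    adipose = generate_cohort_study(spec, "adipose", betas=betas)
    out = derive_disease_signature([muscle], [adipose])
    planted = set(betas[betas != 0].index)
    recovered = planted & set(out["gene_id"])
    assert len(recovered) / len(planted) >= 0.90
    # and non-planted genes pass at no more than the nominal FDR
    false = set(out["gene_id"]) - planted
    assert len(false) <= max(3, 0.05 * len(out))
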