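import numpy as np
import pandas as pd
import pytest

from regucircuit.diffcount import (
    CountMatrix,
    DiffConfig,
    estimate_dispersion,
    nb_test,
    nb_test_two_factor,
    size_factors,
    working_dispersion,
)
from _oracles import size_factor_oracle
from conftest import nb_count_matrix


def two_group(counts, n=3):
    cols = [f"c{i}" for i in range(n)] + [f"m{i}" for i in range(n)]
    cond = pd.Series(["control"] * n + ["mutant"] * n, index=cols)
    frame = pd.DataFrame(counts, columns=cols)
    return CountMatrix(frame, cond)


class TestCountMatrix:
    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            two_group([[1, 2, 3, -1, 2, 3]])
        with pytest.raises(ValueError, match="integer"):
            two_group([[1.5, 2, 3, 1, 2, 3]])

    def test_rejects_unknown_condition_labels(self):
        cols = ["a", "b"]
        with pytest.raises(ValueError, match="condition"):
            CountMatrix(
                pd.DataFrame([[1, 2]], columns=cols),
                pd.Series(["ctrl", "mut"], index=cols),
            )

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        cm = nb_count_matrix(rng, n_features=10, times=("4wk", "6wk"))
        cm.counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        sheet = pd.DataFrame({"condition": cm.condition, "time": cm.time})
        sheet.index.name = "sample_id"
        sheet.to_csv(tmp_path / "samples.tsv", sep="\t")
        back = CountMatrix.from_tsv(tmp_path / "counts.tsv", tmp_path / "samples.tsv")
        assert back.counts.equals(cm.counts)
        assert back.subset_time("4wk").sample_ids == [
            s for s in cm.sample_ids if cm.time[s] == "4wk"
        ]


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = two_group(np.tile([[10], [50], [200]], (1, 6)))
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_sample_closed_form(self):
        """s2 = 2*s1 exactly -> factors (1/sqrt 2, sqrt 2) with a geometric-mean reference."""
        base = np.array([[10], [50], [200], [7]])
        counts = np.hstack([base, 2 * base])
        cols = ["c0", "m0"]
        cm = CountMatrix(
            pd.DataFrame(counts, columns=cols),
            pd.Series(["control", "mutant"], index=cols),
        )
        f = size_factors(cm)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_matches_literal_definition_oracle(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 500, size=(50, 4))
        counts[:5] += 1  # guarantee some all-positive features
        cols = [f"c{i}" for i in range(2)] + [f"m{i}" for i in range(2)]
        cm = CountMatrix(
            pd.DataFrame(counts, columns=cols),
            pd.Series(["control", "control", "mutant", "mutant"], index=cols),
        )
        assert np.allclose(size_factors(cm), size_factor_oracle(counts), atol=1e-12)

    def test_no_all_positive_feature_raises(self):
        cm = two_group([[0, 1, 1, 1, 1, 1], [1, 0, 1, 1, 1, 1]])
        with pytest.raises(ValueError, match="positive"):
            size_factors(cm)

    def test_rescaling_one_sample_scales_factor_ratios(self):
        """Scaling sample j by c multiplies every factor ratio f_j/f_i by c."""
        rng = np.random.default_rng(1)
        cm = nb_count_matrix(rng, n_features=100)
        f = size_factors(cm).to_numpy()
        scaled = cm.counts.copy()
        scaled.iloc[:, 0] *= 3
        cm2 = CountMatrix(scaled, cm.condition)
        f2 = size_factors(cm2).to_numpy()
        assert np.allclose(f2[0] / f2[1:], 3.0 * f[0] / f[1:], rtol=1e-9)


class TestDispersion:
    def test_poisson_counts_mostly_hit_the_floor(self):
        rng = np.random.default_rng(0)
        cm = nb_count_matrix(rng, n_features=2000, dispersion=0.0)
        d = estimate_dispersion(cm, size_factors(cm))
        assert (d <= 1e-8).mean() > 0.5
        assert np.median(d) <= 1e-8

    def test_recovers_planted_dispersion_with_many_replicates(self):
        rng = np.random.default_rng(1)
        cm = nb_count_matrix(rng, n_features=2000, dispersion=0.2, n_per_group=20)
        d = estimate_dispersion(cm, size_factors(cm))
        assert 0.1 <= np.median(d) <= 0.3

    def test_constant_feature_floors(self):
        cm = two_group(np.vstack([np.full((1, 6), 7), np.array([[5, 9, 6, 12, 4, 8]])]))
        d = estimate_dispersion(cm, pd.Series(np.ones(6), index=cm.sample_ids))
        assert d.iloc[0] <= 1e-8

    def test_working_dispersion_tracks_truth(self):
        rng = np.random.default_rng(2)
        cm = nb_count_matrix(rng, n_features=1000, dispersion=0.1)
        d = working_dispersion(cm, size_factors(cm))
        assert 0.05 <= np.median(d) <= 0.2


class TestNbTestBasics:
    def test_constant_feature_is_ns_with_zero_lfc(self):
        # equal library depths (identical columns) so size factors are 1
        rng = np.random.default_rng(3)
        col = rng.integers(1, 500, size=50)
        counts = np.tile(col[:, None], (1, 6))
        res = nb_test(two_group(counts))
        assert (res["status"] == "ns").all()
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)

    def test_all_zero_feature_excluded_and_reported_ns(self):
        rng = np.random.default_rng(4)
        cm = nb_count_matrix(rng, n_features=50)
        counts = cm.counts.copy()
        counts.iloc[7] = 0
        res = nb_test(CountMatrix(counts, cm.condition))
        row = res.iloc[7]
        assert (row["status"], row["p_value"], row["p_adjusted"]) == ("ns", 1.0, 1.0)

    def test_requires_two_replicates_per_condition(self):
        cols = ["c0", "c1", "m0"]
        cm = CountMatrix(
            pd.DataFrame([[5, 6, 7]], columns=cols),
            pd.Series(["control", "control", "mutant"], index=cols),
        )
        with pytest.raises(ValueError, match="replicates"):
            nb_test(cm)

    def test_label_swap_flips_lfc_and_preserves_p(self):
        rng = np.random.default_rng(5)
        cm = nb_count_matrix(rng, n_features=200, lfc_index=np.arange(20))
        res = nb_test(cm)
        swapped = CountMatrix(
            cm.counts,
            cm.condition.map({"control": "mutant", "mutant": "control"}),
        )
        res2 = nb_test(swapped)
        assert np.allclose(res2["log2fc"], -res["log2fc"], atol=1e-6)
        assert np.allclose(res2["p_value"], res["p_value"], atol=1e-9)

    def test_sample_rescaling_leaves_lfc_invariant(self):
        rng = np.random.default_rng(6)
        cm = nb_count_matrix(rng, n_features=150, lfc_index=np.arange(10))
        res = nb_test(cm)
        scaled = cm.counts.copy()
        scaled.iloc[:, 2] *= 4
        res2 = nb_test(CountMatrix(scaled, cm.condition))
        # invariant up to the re-estimated dispersion weights
        assert np.allclose(res2["log2fc"], res["log2fc"], atol=0.05)

    def test_bh_adjustment_monotone_in_p_rank(self):
        rng = np.random.default_rng(7)
        cm = nb_count_matrix(rng, n_features=300, lfc_index=np.arange(30))
        res = nb_test(cm).sort_values("p_value")
        assert (res["p_adjusted"].diff().dropna() >= -1e-12).all()
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()

    def test_status_consistent_with_call_and_sign(self):
        rng = np.random.default_rng(8)
        cm = nb_count_matrix(rng, n_features=300, lfc_index=np.arange(30))
        cfg = DiffConfig(alpha=0.05, use_adjusted=True)
        res = nb_test(cm, cfg)
        sig = res["p_adjusted"] < cfg.alpha
        assert ((res["status"] == "up") == (sig & (res["log2fc"] > 0))).all()
        assert ((res["status"] == "down") == (sig & (res["log2fc"] < 0))).all()

    def test_zero_group_mean_reported_with_pseudocount(self):
        counts = np.vstack([[0, 0, 0, 40, 50, 45]])
        cm = two_group(np.vstack([counts, np.full((30, 6), 100)]))
        res = nb_test(cm)
        assert np.isfinite(res.iloc[0]["log2fc"])
        assert res.iloc[0]["log2fc"] > 4  # ~log2((45+.5)/.5)

    def test_agrees_with_statsmodels_glm(self):
        """Per-feature coefficients/SEs match an independent NB GLM fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        cm = nb_count_matrix(rng, n_features=20, lfc_index=np.arange(5), lfc=1.0)
        f = size_factors(cm)
        disp = working_dispersion(cm, f)
        from regucircuit.diffcount import _fit_nb_glm

        y = cm.counts.to_numpy(float)
        X = np.column_stack([np.ones(6), (cm.condition == "mutant").to_numpy(float)])
        beta, se = _fit_nb_glm(y, X, np.log(f.to_numpy()), disp.to_numpy())
        for i in range(20):
            model = sm.GLM(
                y[i],
                X,
                family=sm.families.NegativeBinomial(alpha=float(disp.iloc[i])),
                offset=np.log(f.to_numpy()),
            )
            fit = model.fit()
            assert np.allclose(beta[i], fit.params, atol=1e-5)
            assert np.allclose(se[i], fit.bse, rtol=1e-3)


class TestCalibration:
    def test_null_type_i_error_near_nominal(self):
        """Null NB data (3v3, alpha=0.1): raw p<0.05 fraction within MC band."""
        rng = np.random.default_rng(0)
        cm = nb_count_matrix(rng, n_features=2000)
        res = nb_test(cm)
        frac = (res["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_fourfold_effects(self):
        """4-fold changes in 10% of features are mostly recovered at BH 0.05."""
        rng = np.random.default_rng(1)
        idx = np.arange(200)
        cm = nb_count_matrix(rng, n_features=2000, lfc_index=idx)
        res = nb_test(cm)
        sensitivity = (res["p_adjusted"].to_numpy()[idx] < 0.05).mean()
        false_rate = (res["status"].to_numpy()[200:] != "ns").mean()
        assert sensitivity >= 0.70
        assert false_rate <= 0.10


class TestTwoFactor:
    def test_requires_time_labels_and_full_cells(self):
        rng = np.random.default_rng(10)
        cm = nb_count_matrix(rng, n_features=10)
        with pytest.raises(ValueError, match="time"):
            nb_test_two_factor(cm)
        cm2 = nb_count_matrix(rng, n_features=10, times=("t1", "t2"))
        # removing control_t1 replicates below 2 must raise
        keep = [s for s in cm2.sample_ids if not s.startswith("control_t1")] + ["control_t1_r0"]
        with pytest.raises(ValueError, match="cell"):
            nb_test_two_factor(cm2.subset_samples(keep))

    def test_genotype_null_with_time_effect_only(self):
        """Planted 2-fold time shift, no genotype effect: near-nominal level."""
        rng = np.random.default_rng(2)
        cm = nb_count_matrix(rng, n_features=2000, times=("t1", "t2"))
        counts = cm.counts.copy()
        t2 = [s for s in cm.sample_ids if cm.time[s] == "t2"]
        mu = np.full((2000, len(cm.sample_ids)), 100.0)
        mu[:, [s in t2 for s in cm.sample_ids]] *= 2.0
        y = rng.poisson(rng.gamma(10.0, 0.1 * mu))
        cm = CountMatrix(pd.DataFrame(y, index=counts.index, columns=counts.columns),
                         cm.condition, cm.time)
        res = nb_test_two_factor(cm)
        frac = (res["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_shared_genotype_effect_gains_power_over_single_time(self):
        """A genotype effect present at both times: pooling beats per-time tests."""
        rng = np.random.default_rng(11)
        idx = np.arange(100)
        cm = nb_count_matrix(rng, n_features=800, times=("t1", "t2"), lfc_index=idx, lfc=1.0)
        res_two = nb_test_two_factor(cm)
        res_one = nb_test(cm.subset_time("t1"))
        planted_two = res_two["p_value"].to_numpy()[idx]
        planted_one = res_one["p_value"].to_numpy()[idx]
        assert np.median(planted_two) < np.median(planted_one)

    def test_all_zero_feature_reported_ns(self):
        rng = np.random.default_rng(12)
        cm = nb_count_matrix(rng, n_features=20, times=("t1", "t2"))
        counts = cm.counts.copy()
        counts.iloc[3] = 0
        res = nb_test_two_factor(CountMatrix(counts, cm.condition, cm.time))
        assert res.iloc[3]["status"] == "ns" and res.iloc[3]["p_value"] == 1.0
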