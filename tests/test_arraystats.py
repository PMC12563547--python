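import numpy as np
import pandas as pd
import pytest
from scipy import stats

import asymlung as al
from asymlung.arraystats import (METHODS_THRESHOLDS, RESULTS_THRESHOLDS,
                                 Thresholds, aggregate_experiment)
from asymlung.synthdata import ArrayConfig, simulate_array


def make_experiment(m_truth: np.ndarray, a_level: float = 10.0,
                    seed: int = 0) -> al.ArrayExperiment:
    """Noiseless dual-channel experiment with prescribed M values
    (antibody x sample) and a common reference level."""
    rng = np.random.default_rng(seed)
    n_ab, n_s = m_truth.shape
    ref_log2 = rng.normal(a_level, 1.0, n_ab)
    rows = []
    for j in range(n_s):
        for chan, log2 in (("sample", ref_log2 + m_truth[:, j]),
                           ("reference", ref_log2)):
            for rep in (1, 2):
                rows.append(pd.DataFrame({
                    "sample_id": f"s{j}", "antibody_id":
                        [f"ab{i:03d}" for i in range(n_ab)],
                    "replicate": rep, "channel": chan,
                    "intensity": 2.0 ** log2}))
    samples = pd.DataFrame({"sample_id": [f"s{j}" for j in range(n_s)],
                            "group": ["g"] * n_s, "timepoint": ["t6"] * n_s})
    return al.ArrayExperiment(pd.concat(rows, ignore_index=True), samples)


class TestAggregation:
    def test_constant_spots(self):
        assert al.aggregate_replicates([100, 100, 100, 100])[0] == 100.0

    def test_median_of_skewed_replicates(self):
        assert al.aggregate_replicates([1, 2, 3, 100])[0] == 2.5

    def test_background_floor(self):
        inten, _ = al.aggregate_replicates([50], background=[60], epsilon=1)
        assert inten == 1.0

    def test_all_missing_flagged(self):
        with pytest.raises(ValueError, match="missing"):
            al.aggregate_replicates([np.nan, np.nan])

    def test_cv_reported(self):
        _, cv = al.aggregate_replicates([90, 100, 110, 100])
        assert cv == pytest.approx(np.std([90, 100, 110, 100]) / 100)


class TestNormalize:
    def test_identical_channels_all_m_zero(self):
        exp = make_experiment(np.zeros((50, 3)))
        norm = al.normalize(exp)
        assert np.allclose(norm.m_values.to_numpy(), 0.0, atol=1e-9)

    def test_planted_linear_bias_removed(self):
        # null antibodies with dye bias M = 0.3 + 0.1*A
        rng = np.random.default_rng(4)
        n = 300
        exp = make_experiment(np.zeros((n, 4)), seed=4)
        agg = aggregate_experiment(exp)
        # rebuild spots with the bias applied to the sample channel
        spots = exp.spots.copy()
        is_sample = spots["channel"] == "sample"
        a = np.log2(spots["intensity"].to_numpy())
        spots.loc[is_sample, "intensity"] = 2.0 ** (
            a[is_sample] + 0.3 + 0.1 * a[is_sample])
        biased = al.ArrayExperiment(spots, exp.samples)
        norm = al.normalize(biased)
        assert float(norm.m_values.abs().median().median()) < 0.02

    def test_planted_effects_preserved_through_normalization(self):
        cfg = ArrayConfig(n_antibodies=300, groups={"g1": 5, "g2": 5},
                          timepoints=("t6",), effect_fraction=0.05,
                          effect_lfc=1.0, residual_sd=0.0, spot_noise_sd=0.02,
                          effect_conditions=(("g2", "t6"),))
        spots, samples, truth = simulate_array(cfg, 5)
        norm = al.normalize(al.ArrayExperiment(spots, samples))
        planted = truth.set_index("antibody_id")["planted"]
        g2 = [s for s in norm.m_values.columns if s.startswith("g2")]
        g1 = [s for s in norm.m_values.columns if s.startswith("g1")]
        lfc = (norm.m_values[g2].mean(axis=1)
               - norm.m_values[g1].mean(axis=1))
        assert np.all(np.abs(lfc[planted] - 1.0) < 0.1)

    def test_small_invariant_set_falls_back_to_median(self):
        # anti-correlated channels: no antibody is rank-invariant
        rng = np.random.default_rng(6)
        n = 60
        ref = np.sort(rng.normal(10, 1.5, n))
        smp = ref[::-1].copy()
        rows = []
        for chan, log2 in (("sample", smp), ("reference", ref)):
            rows.append(pd.DataFrame({
                "sample_id": "s0",
                "antibody_id": [f"ab{i:03d}" for i in range(n)],
                "replicate": 1, "channel": chan, "intensity": 2.0 ** log2}))
        exp = al.ArrayExperiment(
            pd.concat(rows, ignore_index=True),
            pd.DataFrame({"sample_id": ["s0"], "group": ["g"],
                          "timepoint": ["t6"]}))
        with pytest.warns(UserWarning, match="invariant set too small"):
            norm = al.normalize(exp)
        assert abs(float(norm.m_values["s0"].median())) < 1e-9


class TestModeratedContrast:
    def run_contrast(self, m, labels, **kw):
        df = pd.DataFrame(m, index=[f"ab{i}" for i in range(m.shape[0])],
                          columns=[f"s{j}" for j in range(m.shape[1])])
        norm = al.NormalizedMatrix(df, df * 0,
                                   pd.DataFrame({"sample_id": df.columns}))
        cond = dict(zip(df.columns, labels))
        return al.moderated_contrast(norm, cond, {"b": 1.0, "a": -1.0}, **kw)

    def test_identical_group_means_null(self):
        rng = np.random.default_rng(8)
        noise = rng.normal(0, 1, (30, 3))
        m = np.hstack([noise, noise])  # both groups see the same values
        res = self.run_contrast(m, ["a"] * 3 + ["b"] * 3)
        assert np.allclose(res["log_fc"], 0.0)
        assert (res["p_raw"] > 0.999).all()

    def test_moderation_disabled_equals_ordinary_t(self):
        rng = np.random.default_rng(9)
        m = rng.normal(0, 1, (40, 10))
        labels = ["a"] * 5 + ["b"] * 5
        res = self.run_contrast(m, labels, d0=0.0, s0_2=1.0)
        for i in range(40):
            t, p = stats.ttest_ind(m[i, 5:], m[i, :5])
            assert res["t"].iloc[i] == pytest.approx(t)
            assert res["p_raw"].iloc[i] == pytest.approx(p)

    def test_infinite_prior_pools_all_variances(self):
        rng = np.random.default_rng(10)
        m = rng.normal(0, 1, (40, 10))
        labels = ["a"] * 5 + ["b"] * 5
        s0_2 = 0.7
        res = self.run_contrast(m, labels, d0=np.inf, s0_2=s0_2)
        lfc = res["log_fc"].to_numpy()
        se = np.sqrt(s0_2) * np.sqrt(2 / 5)
        assert np.allclose(res["t"], lfc / se)

    def test_prior_estimated_from_data(self):
        rng = np.random.default_rng(12)
        m = rng.normal(0, 0.5, (200, 10))
        res = self.run_contrast(m, ["a"] * 5 + ["b"] * 5)
        assert res.attrs["d0"] > 0
        assert res.attrs["s0_2"] == pytest.approx(0.25, rel=0.4)

    def test_too_few_samples_rejected(self):
        m = np.zeros((5, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            self.run_contrast(m, ["a", "b"])


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert al.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_step_up_example(self):
        adj = al.bh_adjust([0.01, 0.04, 0.03, 0.05])
        assert np.allclose(adj, [0.04, 0.05, 0.05, 0.05])

    def test_equal_inputs_unchanged(self):
        assert np.allclose(al.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(1e-6, 1, 50)
        adj = al.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_constant_vectors_are_fixed_points(self):
        adj = al.bh_adjust([0.2] * 5)
        assert np.allclose(al.bh_adjust(adj), adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            al.bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            al.bh_adjust([1.5])


class TestClassify:
    @pytest.mark.parametrize("lfc, p, expected", [
        (0.6, 0.01, "differential"),
        (0.6, 0.5, "noteworthy"),
        (0.6, 0.95, "nonsignificant"),
        (0.0, 0.001, "nonsignificant"),
        (-0.8, 0.02, "differential"),
        (0.5, 0.01, "nonsignificant"),   # strict inequality on |logFC|
    ])
    def test_default_thresholds(self, lfc, p, expected):
        assert al.classify(lfc, p) == expected

    def test_methods_variant_uses_lfc_band(self):
        assert al.classify(0.4, 0.5, METHODS_THRESHOLDS) == "noteworthy"
        assert al.classify(0.6, 0.01, METHODS_THRESHOLDS) == "nonsignificant"
        assert al.classify(0.6, 0.004, METHODS_THRESHOLDS) == "differential"

    def test_vectorized(self):
        out = al.classify([0.6, 0.0], [0.01, 0.01])
        assert list(out) == ["differential", "nonsignificant"]


class TestClusterOrder:
    def test_identical_samples_adjacent(self):
        rng = np.random.default_rng(15)
        m = rng.normal(0, 1, (10, 3))
        df = pd.DataFrame(np.hstack([m, m[:, [0]]]),
                          index=[f"ab{i}" for i in range(10)],
                          columns=["s0", "s1", "s2", "s0dup"])
        _, cols = al.cluster_order(df)
        i, j = cols.index("s0"), cols.index("s0dup")
        assert abs(i - j) == 1

    def test_two_block_structure_separated(self):
        rng = np.random.default_rng(16)
        n_ab, n_s = 20, 8
        block = np.array([1.0] * 4 + [-1.0] * 4)
        m = np.outer(np.sign(rng.normal(size=n_ab)), block)
        m += rng.normal(0, 0.05, m.shape)
        df = pd.DataFrame(m, index=[f"ab{i}" for i in range(n_ab)],
                          columns=[f"s{j}" for j in range(n_s)])
        _, cols = al.cluster_order(df)
        first_half = {f"s{j}" for j in range(4)}
        got = [c in first_half for c in cols]
        assert got == sorted(got) or got == sorted(got, reverse=True)

    def test_zero_variance_row_warns(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0],
                           [2.0, 1.0, 0.0]],
                          index=["flat", "up", "down"],
                          columns=["s0", "s1", "s2"])
        with pytest.warns(UserWarning, match="zero-variance"):
            al.cluster_order(df)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            al.cluster_order(pd.DataFrame([[1.0, 2.0]]))
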