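"""Factor summaries: moments, contributions, dispersion tests, clustering."""

import numpy as np
import pytest

import fcharm as f
from fcharm.data import BiasDecomposition, ValidationError

from conftest import make_dataset


def simple_decomposition(blocks, n_edges):
    """Decomposition with given measurement biases and empty other blocks."""
    zeros = np.zeros(n_edges)
    return BiasDecomposition(
        measurement_bias=blocks, sampling_bias_hc={}, sampling_bias_mdd={},
        sampling_bias_scz={}, disorder_factor={}, participant_factor={},
        intercept=zeros, residual_variance=zeros, lam=0.0)


class TestMagnitudeMoments:
    def test_symmetric_two_point_distribution(self):
        c = 0.3
        v = np.array([c] * 50 + [-c] * 50)
        dec = simple_decomposition({"A": v, "B": -v}, 100)
        df = f.magnitude_moments(dec, "measurement")
        assert df.loc["A", "mean"] == pytest.approx(0.0)
        assert df.loc["A", "sd"] == pytest.approx(c)
        assert df.loc["A", "third_moment_cbrt"] == pytest.approx(0.0)

    def test_zero_bias_zero_moments(self):
        dec = simple_decomposition({"A": np.zeros(10)}, 10)
        assert (f.magnitude_moments(dec, "measurement").loc["A"] == 0).all()

    def test_gaussian_sd_recovered(self, rng):
        sd = 0.04
        dec = simple_decomposition({"A": rng.normal(0, sd, 35778)}, 35778)
        assert f.magnitude_moments(dec, "measurement").loc["A", "sd"] == \
            pytest.approx(sd, abs=5e-4)

    def test_sd_invariant_to_sign_flip(self, decomposition):
        flipped = simple_decomposition(
            {k: -v for k, v in decomposition.measurement_bias.items()},
            decomposition.n_edges())
        assert f.factor_sd(flipped, "measurement") == \
            pytest.approx(f.factor_sd(decomposition, "measurement"))

    def test_empty_factor_rejected(self):
        dec = simple_decomposition({"A": np.zeros(3)}, 3)
        with pytest.raises(ValidationError):
            f.magnitude_moments(dec, "participant")


class TestContributionSizes:
    def test_shares_sum_to_one(self, study, decomposition):
        rep = f.contribution_sizes(study["combined"], decomposition)
        assert rep.conservation_error() < 1e-8

    def test_pure_measurement_signal_share(self, rng):
        # 12 single-HC sites, data exactly equal to the measurement bias:
        # the one nonzero squared term takes the whole share, and the
        # contribution size divides it by the 12 measurement levels
        sites = [f"S{i:02d}" for i in range(12)]
        m = {s: rng.normal(size=4) for s in sites}
        m = {s: v - np.mean(list(m.values()), axis=0) for s, v in m.items()}
        values = np.array([m[s] for s in sites])
        ds = make_dataset(values, site=sites, diagnosis=["HC"] * 12,
                          kind=["multisite"] * 12)
        dec = BiasDecomposition(
            measurement_bias=m,
            sampling_bias_hc={s: np.zeros(4) for s in sites},
            sampling_bias_mdd={}, sampling_bias_scz={}, disorder_factor={},
            participant_factor={}, intercept=np.zeros(4),
            residual_variance=np.zeros(4), lam=0.0)
        rep = f.contribution_sizes(ds, dec)
        assert rep.contribution["measurement"] == pytest.approx(1 / 12)
        assert rep.noise_share == pytest.approx(0.0, abs=1e-12)

    def test_generating_order_recovered(self, study, decomposition):
        # generating SDs: participant > measurement > disorder > sampling
        rep = f.contribution_sizes(study["combined"], decomposition)
        c = rep.contribution
        assert c["participant"] > c["measurement"] > c["disorder"]
        assert c["disorder"] > c["sampling_mdd"]
        assert c["disorder"] > c["sampling_scz"]


class TestVarianceComparisons:
    def test_identical_vectors_not_significant(self, rng):
        v = rng.normal(size=500)
        dec = simple_decomposition({"A": v}, 500)
        dec.participant_factor = {"p1": v.copy()}
        table = f.variance_comparisons(dec)
        assert table["p"].iloc[0] > 0.5

    def test_threefold_scale_detected(self, rng):
        v = rng.normal(size=35778)
        dec = simple_decomposition({"A": v}, 35778)
        dec.participant_factor = {"p1": 3 * v}
        table = f.variance_comparisons(dec)
        assert table["p_bonferroni"].iloc[0] < 0.05

    def test_full_grid_has_108_pairs(self, decomposition):
        table = f.variance_comparisons(decomposition)
        assert len(table) == 9 * 12 == 108


class TestBiasDisorderCorrelation:
    def test_identical_pattern_r_one(self, rng):
        v = rng.normal(size=200)
        dec = simple_decomposition({"A": v}, 200)
        dec.disorder_factor = {"MDD": v.copy()}
        table, _ = f.bias_disorder_correlation(dec)
        assert table.loc["A", "MDD"] == pytest.approx(1.0)

    def test_orthogonal_vectors_near_zero(self, rng):
        dec = simple_decomposition({"A": rng.normal(size=20000)}, 20000)
        dec.disorder_factor = {"MDD": rng.normal(size=20000)}
        table, _ = f.bias_disorder_correlation(dec)
        assert abs(table.loc["A", "MDD"]) < 0.03

    def test_full_grid_36_pairs_df_35(self, decomposition):
        table, test = f.bias_disorder_correlation(decomposition)
        assert table.size == 36 and test["df"] == 35


class TestRoiProjection:
    def make_three_node(self, a, b, c):
        # edge order for 3 nodes: (1,0), (2,0), (2,1) -> effects a, b, c
        idx = f.build_edge_index(3)
        dec = simple_decomposition({"A": np.array([a, b, c])}, 3)
        return idx, dec

    def test_node_average_formula(self):
        idx, dec = self.make_three_node(0.2, 0.4, 0.6)
        out = f.roi_projection(dec, "measurement", idx)
        assert out["effect"].tolist() == pytest.approx(
            [(0.2 + 0.4) / 2, (0.2 + 0.6) / 2, (0.4 + 0.6) / 2])

    def test_uniform_effects_zero_zscores(self):
        idx, dec = self.make_three_node(0.5, 0.5, 0.5)
        out = f.roi_projection(dec, "measurement", idx, z_score=True)
        assert np.allclose(out["z"], 0)

    def test_concentration_ranks_top(self, rng):
        idx = f.build_edge_index(6)
        v = np.full(idx.n_edges, 0.01)
        hot = [e for e, (i, j) in enumerate(idx.pairs) if 2 in (i, j)]
        v[hot] = 1.0
        dec = simple_decomposition({"A": v}, idx.n_edges)
        out = f.roi_projection(dec, "measurement", idx)
        assert out["effect"].idxmax() == 2

    def test_commutes_with_node_relabeling(self, rng):
        k = 5
        idx = f.build_edge_index(k)
        v = rng.normal(size=idx.n_edges)
        dec = simple_decomposition({"A": v}, idx.n_edges)
        base = f.roi_projection(dec, "measurement", idx)["effect"].to_numpy()
        perm = rng.permutation(k)
        mat = f.devectorize(np.abs(v), idx)[np.ix_(perm, perm)]
        v_perm = mat[idx.pairs[:, 0], idx.pairs[:, 1]]
        dec_perm = simple_decomposition({"A": v_perm}, idx.n_edges)
        out = f.roi_projection(dec_perm, "measurement", idx)["effect"].to_numpy()
        np.testing.assert_allclose(out, base[perm], atol=1e-12)


class TestClustering:
    def test_identical_vectors_merge_at_zero(self, rng):
        v = rng.normal(size=100)
        dec = simple_decomposition(
            {"A": v, "B": v.copy(), "C": rng.normal(size=100)}, 100)
        dend = f.cluster_measurement_bias(dec)
        assert dend.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self, rng):
        v = rng.normal(size=100)
        dec = simple_decomposition({"A": v, "B": -v}, 100)
        dend = f.cluster_measurement_bias(dec)
        assert dend.linkage[-1, 2] == pytest.approx(2.0)

    def test_heights_within_bounds(self, decomposition):
        dend = f.cluster_measurement_bias(decomposition)
        assert (dend.linkage[:, 2] >= -1e-12).all()
        assert (dend.linkage[:, 2] <= 2 + 1e-12).all()

    def test_group_structure_recovered(self, rng):
        """Two scanner-family groups split into three vendor subgroups."""
        from scipy.cluster.hierarchy import fcluster
        n = 400
        group_a = rng.normal(size=n)   # e.g. phase-encoding direction offset
        group_b = rng.normal(size=n)
        vendors = {v: rng.normal(size=n) for v in "uvwxyz"}
        biases, labels = {}, {}
        for s in range(12):
            top = "A" if s < 6 else "B"
            vendor = "uvwxyz"[s // 2]
            biases[f"S{s:02d}"] = (2.0 * (group_a if top == "A" else group_b)
                                   + 1.0 * vendors[vendor]
                                   + 0.2 * rng.normal(size=n))
            labels[f"S{s:02d}"] = top
        dec = simple_decomposition(biases, n)
        dend = f.cluster_measurement_bias(dec)
        sites = sorted(biases)
        cut = fcluster(dend.linkage, t=2, criterion="maxclust")
        groups = {lab: {labels[s] for s, c in zip(sites, cut) if c == lab}
                  for lab in set(cut)}
        assert all(len(g) == 1 for g in groups.values())

    def test_constant_vector_rejected(self):
        dec = simple_decomposition({"A": np.ones(10), "B": np.zeros(10)}, 10)
        with pytest.raises(ValidationError, match="A"):
            f.cluster_measurement_bias(dec)


class TestSiteAnova:
    def test_null_fraction_near_zero(self, rng):
        vals = rng.normal(size=(120, 400))
        sites = ["A"] * 40 + ["B"] * 40 + ["C"] * 40
        ds = make_dataset(vals, site=sites, diagnosis=["HC"] * 120,
                          kind=["multisite"] * 120)
        out = f.site_effect_anova(ds)
        assert out["significant_fraction"] < 0.01

    def test_injected_offsets_all_detected(self, rng):
        vals = rng.normal(size=(120, 50), scale=0.1)
        vals[40:80] += 1.0
        sites = ["A"] * 40 + ["B"] * 40 + ["C"] * 40
        ds = make_dataset(vals, site=sites, diagnosis=["HC"] * 120,
                          kind=["multisite"] * 120)
        out = f.site_effect_anova(ds)
        assert out["significant_fraction"] == pytest.approx(1.0)

    def test_equal_group_means_f_zero(self):
        vals = np.array([[1.0], [3.0], [1.0], [3.0]])
        ds = make_dataset(vals, site=["A", "A", "B", "B"],
                          diagnosis=["HC"] * 4, kind=["multisite"] * 4)
        out = f.site_effect_anova(ds)
        assert out["f"][0] == pytest.approx(0.0)
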