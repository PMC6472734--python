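"""The four harmonization methods and their apply semantics."""

import numpy as np
import pytest

import fcharm as f
from fcharm.data import ValidationError

from conftest import make_dataset


def two_site_dataset(rng, means=(1.0, 3.0), n_per_site=20, n_edges=4, sds=(1, 1),
                     diagnosis=None):
    vals, sites = [], []
    for mean, sd, site in zip(means, sds, ["A", "B"]):
        vals.append(rng.normal(mean, sd, size=(n_per_site, n_edges)))
        sites += [site] * n_per_site
    diagnosis = diagnosis or ["HC"] * (2 * n_per_site)
    return make_dataset(np.vstack(vals), site=sites, diagnosis=diagnosis,
                        kind=["multisite"] * (2 * n_per_site))


class TestGLM:
    def test_site_means_equalized(self, rng):
        ds = two_site_dataset(rng)
        model = f.GLMHarmonizer().fit(ds)
        out = model.transform(ds)
        a = out.values[(out.meta["site_id"] == "A").to_numpy()].mean(axis=0)
        b = out.values[(out.meta["site_id"] == "B").to_numpy()].mean(axis=0)
        np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(a, model.intercept_, atol=1e-12)

    def test_single_site_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(5, 3)), site=["A"] * 5,
                          diagnosis=["HC"] * 5, kind=["multisite"] * 5)
        with pytest.raises(ValidationError):
            f.GLMHarmonizer().fit(ds)

    def test_confounded_disorder_signal_removed(self, rng):
        """A site sampling only patients loses its disorder signal under GLM
        but keeps it under the adjusted GLM — the motivating contrast."""
        n = 30
        d_effect = 1.0
        vals = np.vstack([
            rng.normal(0, 0.1, (n, 4)),              # site A, all HC
            rng.normal(d_effect, 0.1, (n, 4)),       # site B, all MDD
        ])
        ds = make_dataset(vals, site=["A"] * n + ["B"] * n,
                          diagnosis=["HC"] * n + ["MDD"] * n,
                          kind=["multisite"] * (2 * n))
        glm_out = f.GLMHarmonizer().fit(ds).transform(ds)
        hc = glm_out.values[:n].mean()
        mdd = glm_out.values[n:].mean()
        assert abs(mdd - hc) < 0.05  # disorder contrast destroyed with site


class TestAdjustedGLM:
    def test_balanced_design_round_trip(self, rng):
        n = 40
        site_terms = {"A": 0.5, "B": -0.5}
        d_mdd = 0.8
        vals, sites, diags = [], [], []
        for site in "AB":
            for diag, off in (("HC", 0.0), ("MDD", d_mdd)):
                vals.append(rng.normal(site_terms[site] + off, 0.01, (n, 3)))
                sites += [site] * n
                diags += [diag] * n
        ds = make_dataset(np.vstack(vals), site=sites, diagnosis=diags,
                          kind=["multisite"] * len(sites))
        model = f.AdjustedGLMHarmonizer().fit(ds)
        assert model.site_terms_["A"].mean() == pytest.approx(0.5, abs=0.01)
        assert model.covariate_terms_["MDD"].mean() == pytest.approx(d_mdd, abs=0.01)
        out = model.transform(ds)
        mdd = out.values[np.array(diags) == "MDD"].mean()
        hc = out.values[np.array(diags) == "HC"].mean()
        assert mdd - hc == pytest.approx(d_mdd, abs=0.01)  # biology retained

    def test_reduces_to_glm_without_diagnosis_variation(self, rng):
        ds = two_site_dataset(rng)
        adj = f.AdjustedGLMHarmonizer().fit(ds)
        glm = f.GLMHarmonizer().fit(ds)
        for s in ("A", "B"):
            np.testing.assert_allclose(adj.site_terms_[s], glm.site_terms_[s],
                                       atol=1e-10)

    def test_perfect_confounding_warns(self, rng):
        n = 10
        ds = make_dataset(rng.normal(size=(2 * n, 3)),
                          site=["A"] * n + ["B"] * n,
                          diagnosis=["HC"] * n + ["MDD"] * n,
                          kind=["multisite"] * (2 * n))
        with pytest.warns(UserWarning, match="confounded"):
            f.AdjustedGLMHarmonizer().fit(ds)

    def test_disorder_contrast_preserved_on_study(self, study):
        ms = study["multisite"]
        model = f.AdjustedGLMHarmonizer().fit(ms)
        out = model.transform(ms)
        post = f.AdjustedGLMHarmonizer().fit(out)
        for d in model.covariate_terms_:
            r = np.corrcoef(model.covariate_terms_[d],
                            post.covariate_terms_[d])[0, 1]
            assert r > 0.99


class TestComBat:
    def test_large_sample_moments_equalized(self, rng):
        # systematic (across-edge average) site differences vanish; per-edge
        # sample moments still carry O(1/sqrt(n)) sampling noise
        ds = two_site_dataset(rng, means=(0.0, 1.0), sds=(1.0, 2.0),
                              n_per_site=600, n_edges=60)
        out = f.CombatHarmonizer(use_covariates=False).fit(ds).transform(ds)
        a = (ds.meta["site_id"] == "A").to_numpy()
        mean_gap = out.values[a].mean(axis=0) - out.values[~a].mean(axis=0)
        pooled_sd = out.values.std(axis=0)
        assert abs((mean_gap / pooled_sd).mean()) < 0.02
        var_ratio = out.values[a].var(axis=0) / out.values[~a].var(axis=0)
        assert abs(var_ratio.mean() - 1) < 0.02
        # and the raw data fail both checks by an order of magnitude
        raw_gap = ds.values[a].mean(axis=0) - ds.values[~a].mean(axis=0)
        assert abs((raw_gap / ds.values.std(axis=0)).mean()) > 0.2
        raw_ratio = ds.values[a].var(axis=0) / ds.values[~a].var(axis=0)
        assert abs(raw_ratio.mean() - 1) > 0.5

    def test_scale_terms_strictly_positive(self, rng):
        ds = two_site_dataset(rng, sds=(0.5, 2.0))
        model = f.CombatHarmonizer().fit(ds)
        for v in model.scale_terms_.values():
            assert (v > 0).all()

    def test_identical_sites_near_identity(self, rng):
        base = rng.normal(0, 1, size=(40, 1))
        ds = make_dataset(np.vstack([base, base]),
                          site=["A"] * 40 + ["B"] * 40,
                          diagnosis=["HC"] * 80, kind=["multisite"] * 80)
        model = f.CombatHarmonizer(use_covariates=False).fit(ds)
        assert np.abs(model.site_terms_["A"]).max() < 0.05
        assert model.scale_terms_["A"][0] == pytest.approx(1.0, abs=0.1)

    def test_requires_two_subjects_per_site(self, rng):
        ds = make_dataset(rng.normal(size=(3, 3)), site=["A", "A", "B"],
                          diagnosis=["HC"] * 3, kind=["multisite"] * 3)
        with pytest.raises(ValidationError):
            f.CombatHarmonizer().fit(ds)


class TestTravelingSubject:
    def test_noiseless_round_trip(self):
        cfg = f.paper_scale_config(n_edges=60)
        cfg.scan_noise_sd = 0.0
        cfg.xi = 0.0
        ms, tr, truth = f.generate_study(cfg, seed=7)
        combined = f.concat_datasets(ms, tr)
        model = f.TravelingSubjectHarmonizer(lam=1e-8).fit(combined)
        out = model.transform(combined)
        refit = f.TravelingSubjectHarmonizer(lam=1e-8).fit(out)
        assert max(np.abs(v).max() for v in refit.site_terms_.values()) < 1e-6

    def test_sampling_bias_untouched(self, study):
        # tiny ridge weight: with lam > 0 the penalty couples blocks at
        # O(lam * m / n), so exact invariance holds only in the lam -> 0 limit
        combined = study["combined"]
        model = f.TravelingSubjectHarmonizer(lam=1e-8).fit(combined)
        out = model.transform(combined)
        refit = f.SiteBiasModel(lam=1e-8).fit(out)
        before = model.bias_model_.sampling_bias_hc_
        after = refit.sampling_bias_hc_
        for k in before:
            np.testing.assert_allclose(after[k], before[k], atol=1e-8)

    def test_apply_is_linear_shift(self, study):
        combined = study["combined"]
        model = f.TravelingSubjectHarmonizer(lam=1.0).fit(combined)
        once = model.transform(combined)
        twice = model.transform(once)
        site0 = combined.meta["site_id"].iloc[0]
        shift = combined.values[0] - once.values[0]
        np.testing.assert_allclose(shift, model.site_terms_[site0], atol=1e-12)
        np.testing.assert_allclose(once.values[0] - twice.values[0], shift,
                                   atol=1e-12)

    def test_refuses_uncovered_sites(self, study):
        ms = study["multisite"]
        tr = study["traveling"]
        drop = tr.subset((tr.meta["site_id"] != "MS03").to_numpy())
        with pytest.raises(ValidationError, match="MS03"):
            f.TravelingSubjectHarmonizer().fit(f.concat_datasets(ms, drop))


class TestApply:
    def test_zero_model_is_identity(self, rng):
        ds = two_site_dataset(rng)
        model = f.GLMHarmonizer().fit(ds)
        for k in model.site_terms_:
            model.site_terms_[k] = np.zeros(ds.n_edges)
        out = f.apply_harmonization(ds, model)
        np.testing.assert_allclose(out.values, ds.values)

    def test_unknown_site_listed(self, rng):
        ds = two_site_dataset(rng)
        model = f.GLMHarmonizer().fit(ds)
        other = make_dataset(rng.normal(size=(2, 4)), site=["C", "C"],
                             diagnosis=["HC"] * 2, kind=["multisite"] * 2)
        with pytest.raises(ValidationError, match="C"):
            model.transform(other)

    def test_fit_harmonizer_dispatch(self, rng):
        ds = two_site_dataset(rng)
        assert isinstance(f.fit_harmonizer("glm", ds), f.GLMHarmonizer)
        with pytest.raises(ValueError):
            f.fit_harmonizer("nope", ds)
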