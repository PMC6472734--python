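"""Four site-harmonization methods for connectivity matrices.

* Traveling-subject: subtract the measurement bias estimated by the joint
  constrained-ridge decomposition (needs traveling data covering every
  target site).  Removes engineering bias only; sampling bias is left in the
  data because it is biology.
* GLM: subtract per-site mean offsets fitted without covariates — removes
  the whole site difference, biological or not.
* Adjusted GLM: per-site offsets fitted while adjusting for diagnosis
  (healthy-control baseline); only the site offsets are subtracted.
* ComBat: location-and-scale model with parametric empirical-Bayes shrinkage
  of the per-site additive and multiplicative effects, diagnosis retained as
  covariates.

Site terms in the GLM-family models use sum-to-zero site coding so the
intercept is the (unweighted) grand mean across sites, mirroring the bias
decomposition's convention and making the fitted site terms directly
comparable to measurement-bias estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .bias import SiteBiasModel
from .data import ConnectivityDataset, ValidationError

DIAG_COVARIATES = ("MDD", "SCZ", "ASD", "OTHER")


class BaseHarmonizer(BaseEstimator, TransformerMixin):
    """Shared apply logic: subtract per-site additive terms row-wise.

    Fitted attributes: ``site_terms_`` (site -> edge vector),
    ``covariate_terms_`` (diagnosis -> edge vector, possibly empty),
    ``scale_terms_`` (site -> multiplicative edge vector; identity unless the
    method models scale), ``intercept_``.
    """

    def _check_sites(self, dataset: ConnectivityDataset):
        unknown = sorted(set(dataset.meta["site_id"]) - set(self.site_terms_))
        if unknown:
            raise ValidationError(
                f"no fitted site terms for sites {unknown}; "
                f"known sites: {sorted(self.site_terms_)}"
            )

    def transform(self, dataset: ConnectivityDataset) -> ConnectivityDataset:
        self._check_sites(dataset)
        out = dataset.values.copy()
        for site, term in self.site_terms_.items():
            rows = (dataset.meta["site_id"] == site).to_numpy()
            out[rows] -= term
        return ConnectivityDataset(values=out, meta=dataset.meta.copy(),
                                   edge_index=dataset.edge_index)


class TravelingSubjectHarmonizer(BaseHarmonizer):
    """Subtract jointly estimated measurement bias.

    Fit on the combined multisite + traveling dataset; refuses to run when
    the traveling sessions do not cover every multisite site (no
    extrapolation of measurement bias).
    """

    def __init__(self, lam: float = 1.0):
        self.lam = lam

    def fit(self, dataset: ConnectivityDataset, y=None):
        meta = dataset.meta
        multi_sites = set(meta.loc[meta["dataset_kind"] == "multisite", "site_id"])
        trav_sites = set(meta.loc[meta["dataset_kind"] == "traveling", "site_id"])
        uncovered = sorted(multi_sites - trav_sites)
        if uncovered:
            raise ValidationError(
                f"traveling data do not cover sites {uncovered}; measurement "
                "bias cannot be estimated there"
            )
        model = SiteBiasModel(lam=self.lam).fit(dataset)
        self.bias_model_ = model
        self.site_terms_ = {k: v.copy()
                            for k, v in model.measurement_bias_.items()}
        self.covariate_terms_ = {}
        self.scale_terms_ = {k: np.ones(dataset.n_edges) for k in self.site_terms_}
        self.intercept_ = model.intercept_.copy()
        return self


def _site_design(meta: pd.DataFrame):
    sites = sorted(meta["site_id"].unique())
    counts = meta["site_id"].value_counts()
    empty = [s for s in sites if counts.get(s, 0) == 0]
    if empty:  # pragma: no cover - unique() cannot return empty levels
        warnings.warn(f"sites with no rows dropped: {empty}")
        sites = [s for s in sites if s not in empty]
    if len(sites) < 2:
        raise ValidationError("need >= 2 sites to harmonize")
    ind = np.column_stack([(meta["site_id"] == s).to_numpy(float) for s in sites])
    return sites, ind


class GLMHarmonizer(BaseHarmonizer):
    """Per-site mean removal without covariate adjustment.

    Ordinary least squares of each edge on site indicators with the
    sum-to-zero constraint reduces to: intercept = unweighted mean of site
    means, site term = site mean - intercept.  After applying, every site's
    mean equals the intercept exactly (up to float error) — including any
    disorder signal that is confounded with site.
    """

    def fit(self, dataset: ConnectivityDataset, y=None):
        sites, ind = _site_design(dataset.meta)
        site_means = {s: dataset.values[ind[:, i].astype(bool)].mean(axis=0)
                      for i, s in enumerate(sites)}
        grand = np.mean(list(site_means.values()), axis=0)
        self.site_terms_ = {s: site_means[s] - grand for s in sites}
        self.covariate_terms_ = {}
        self.scale_terms_ = {s: np.ones(dataset.n_edges) for s in sites}
        self.intercept_ = grand
        return self


class AdjustedGLMHarmonizer(BaseHarmonizer):
    """Per-site offsets estimated while adjusting for diagnosis.

    Per-edge OLS on sum-to-zero site indicators plus diagnosis indicators
    (healthy-control baseline); only the site terms are subtracted on apply,
    so disorder contrasts are preserved.  Perfect site-diagnosis confounding
    leaves the system rank-deficient; a minimum-norm (pseudo-inverse) fit is
    used with a prominent warning.
    """

    def fit(self, dataset: ConnectivityDataset, y=None):
        meta = dataset.meta
        sites, site_ind = _site_design(meta)
        diags = [d for d in DIAG_COVARIATES if (meta["diagnosis"] == d).any()]
        diag_ind = np.column_stack(
            [(meta["diagnosis"] == d).to_numpy(float) for d in diags]
        ) if diags else np.zeros((len(meta), 0))
        k = len(sites)
        # sum-to-zero site coding: drop last indicator, expressed vs the rest
        x = np.column_stack([
            np.ones(len(meta)),
            site_ind[:, :-1] - site_ind[:, -1:],
            diag_ind,
        ])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            warnings.warn(
                "site and diagnosis are (near-)perfectly confounded; using a "
                "minimum-norm fit — site terms may absorb disorder signal",
                stacklevel=2,
            )
        beta, *_ = np.linalg.lstsq(x, dataset.values, rcond=None)
        s_free = beta[1:k]                      # first k-1 site terms
        s_last = -s_free.sum(axis=0)
        site_terms = {s: s_free[i] for i, s in enumerate(sites[:-1])}
        site_terms[sites[-1]] = s_last
        self.site_terms_ = site_terms
        self.covariate_terms_ = {d: beta[k + i] for i, d in enumerate(diags)}
        self.scale_terms_ = {s: np.ones(dataset.n_edges) for s in sites}
        self.intercept_ = beta[0]
        return self


class CombatHarmonizer(BaseHarmonizer):
    """Parametric empirical-Bayes location-and-scale harmonization.

    Each edge y for a subject at site k is modelled as
    ``const + covariates + s_k + delta_k * e``; per-site additive effects get
    a normal prior and multiplicative effects an inverse-gamma prior, with
    hyperparameters moment-matched across edges and conditional posterior
    means iterated to convergence.  Diagnosis is kept as a covariate so
    biological trends survive the adjustment.  Apply:
    ``(y - const - covariates - s_k) / delta_k + const + covariates``.
    """

    def __init__(self, use_covariates: bool = True, tol: float = 1e-4,
                 max_iter: int = 100):
        self.use_covariates = use_covariates
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, dataset: ConnectivityDataset, y=None):
        meta = dataset.meta
        sites, site_ind = _site_design(meta)
        counts = np.array([(meta["site_id"] == s).sum() for s in sites])
        if (counts < 2).any():
            small = [s for s, c in zip(sites, counts) if c < 2]
            raise ValidationError(f"ComBat needs >= 2 subjects per site: {small}")
        n = len(meta)
        diags = [d for d in DIAG_COVARIATES if (meta["diagnosis"] == d).any()] \
            if self.use_covariates else []
        cov_ind = np.column_stack(
            [(meta["diagnosis"] == d).to_numpy(float) for d in diags]
        ) if diags else np.zeros((n, 0))

        # location fit with full site indicators (no intercept; the grand
        # mean is the subject-weighted combination of site effects)
        x = np.hstack([site_ind, cov_ind])
        beta, *_ = np.linalg.lstsq(x, dataset.values, rcond=None)
        gamma_hat_ols = beta[:len(sites)]
        beta_cov = beta[len(sites):]
        alpha = (counts / n) @ gamma_hat_ols          # weighted grand mean
        stand_mean = alpha + cov_ind @ beta_cov
        resid = dataset.values - x @ beta
        var_pooled = (resid ** 2).mean(axis=0)
        if (var_pooled <= 0).any():
            var_pooled = np.maximum(var_pooled, 1e-12)
        sd_pooled = np.sqrt(var_pooled)

        z = (dataset.values - stand_mean) / sd_pooled
        gamma_hat = np.array([z[site_ind[:, i].astype(bool)].mean(axis=0)
                              for i in range(len(sites))])
        delta2_hat = np.array([z[site_ind[:, i].astype(bool)].var(axis=0, ddof=1)
                               for i in range(len(sites))])

        # moment-matched hyperpriors (per site, across edges)
        gbar = gamma_hat.mean(axis=1)
        t2 = gamma_hat.var(axis=1)
        dbar = delta2_hat.mean(axis=1)
        dvar = delta2_hat.var(axis=1)
        a_prior = (2 * dvar + dbar ** 2) / dvar
        b_prior = (dbar * dvar + dbar ** 3) / dvar

        gamma_star = gamma_hat.copy()
        delta2_star = delta2_hat.copy()
        self.n_iter_ = np.zeros(len(sites), dtype=int)
        for i, nk in enumerate(counts):
            if not (np.isfinite(a_prior[i]) and np.isfinite(b_prior[i])) \
                    or dvar[i] <= 0:
                # degenerate hyperprior (e.g., a single edge, or identical
                # per-edge scales): fall back to the direct estimates
                gamma_star[i] = gamma_hat[i]
                delta2_star[i] = delta2_hat[i]
                continue
            zi = z[site_ind[:, i].astype(bool)]
            g, d2 = gamma_hat[i], delta2_hat[i]
            for it in range(self.max_iter):
                g_new = (nk * t2[i] * gamma_hat[i] + d2 * gbar[i]) / \
                        (nk * t2[i] + d2)
                ss = ((zi - g_new) ** 2).sum(axis=0)
                d2_new = (b_prior[i] + 0.5 * ss) / (nk / 2 + a_prior[i] - 1)
                change = max(np.abs(g_new - g).max() / max(np.abs(g).max(), 1e-12),
                             np.abs(d2_new - d2).max() / max(d2.max(), 1e-12))
                g, d2 = g_new, d2_new
                if change < self.tol:
                    break
            else:
                raise RuntimeError(
                    f"ComBat EB did not converge for site {sites[i]!r} after "
                    f"{self.max_iter} iterations (last relative change "
                    f"{change:.2e}); inspect per-edge variances"
                )
            self.n_iter_[i] = it + 1
            gamma_star[i] = g
            delta2_star[i] = d2

        self.sites_ = sites
        self.intercept_ = alpha
        self.covariate_terms_ = {d: beta_cov[i] for i, d in enumerate(diags)}
        self.sd_pooled_ = sd_pooled
        # data-scale additive and multiplicative site effects
        self.site_terms_ = {s: gamma_star[i] * sd_pooled
                            for i, s in enumerate(sites)}
        self.scale_terms_ = {s: np.sqrt(np.maximum(delta2_star[i], 1e-12))
                             for i, s in enumerate(sites)}
        return self

    def transform(self, dataset: ConnectivityDataset) -> ConnectivityDataset:
        self._check_sites(dataset)
        meta = dataset.meta
        cov = np.zeros_like(dataset.values)
        for d, term in self.covariate_terms_.items():
            rows = (meta["diagnosis"] == d).to_numpy()
            cov[rows] += term
        base = self.intercept_ + cov
        out = dataset.values.copy()
        for i, site in enumerate(self.sites_):
            rows = (meta["site_id"] == site).to_numpy()
            if not rows.any():
                continue
            out[rows] = (out[rows] - base[rows] - self.site_terms_[site]) \
                / self.scale_terms_[site] + base[rows]
        return ConnectivityDataset(values=out, meta=meta.copy(),
                                   edge_index=dataset.edge_index)


METHODS = {
    "traveling": TravelingSubjectHarmonizer,
    "glm": GLMHarmonizer,
    "adjglm": AdjustedGLMHarmonizer,
    "combat": CombatHarmonizer,
}


def fit_harmonizer(method: str, dataset: ConnectivityDataset, **kwargs):
    """Fit one of the four harmonizers by name."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    return METHODS[method](**kwargs).fit(dataset)


def apply_harmonization(dataset: ConnectivityDataset, model) -> ConnectivityDataset:
    """Apply a fitted harmonizer to a dataset (metadata unchanged)."""
    return model.transform(dataset)
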