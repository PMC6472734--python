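"""Generative models for sampling-bias variance versus site sample size.

A site's sampling bias is the across-edge vector of its subject-mean
deviation from the grand mean.  If all sites recruit from one population
with per-subject edge SD xi, the expected across-edge variance of that
vector is xi^2 / N_k (pure finite-sample noise); if each site recruits from
its own subpopulation whose mean is itself dispersed with SD sigma, the
expectation gains a floor: xi^2 / N_k + sigma^2.  On log10 axes
(x_k = log10 N_k, y_k = log10 v_k):

    single population:      y_k = -x_k + 2 log10 xi
    different subpopulation: y_k = -log10(xi^2 10^-x_k + sigma^2)

The two models are compared by small-sample AICc and BIC on the
variance-scale residuals phi_k = v_k - v_hat_k, and by leave-one-site-out
predictive error.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .data import BiasDecomposition, ConnectivityDataset, ValidationError

_CLASS_BLOCKS = {"HC": "sampling_bias_hc", "MDD": "sampling_bias_mdd",
                 "SCZ": "sampling_bias_scz"}


def compute_site_variance_points(decomp: BiasDecomposition,
                                 dataset: ConnectivityDataset,
                                 klass: str = "HC") -> pd.DataFrame:
    """Per-site (N_k, V_k) points for one participant class.

    ``V_k`` is the across-edge variance of the fitted sampling-bias vector
    (these vectors are already centred: they sum to zero over sites per the
    model constraints); ``N_k`` is the subject count from the metadata.
    """
    if klass not in _CLASS_BLOCKS:
        raise ValidationError(f"unknown class {klass!r}")
    block = decomp.block(_CLASS_BLOCKS[klass])
    if len(block) < 3:
        raise ValidationError(
            f"sampling bias for {klass} fitted at {len(block)} sites; need >= 3"
        )
    meta = dataset.meta
    multi = (meta["dataset_kind"] == "multisite") & (meta["diagnosis"] == klass)
    recs = []
    for site in sorted(block):
        n_k = int((multi & (meta["site_id"] == site)).sum())
        if n_k < 1:
            raise ValidationError(f"no {klass} rows at site {site!r}")
        v = float(block[site].var())
        recs.append({"site_id": site, "n_subjects": n_k, "variance": v,
                     "x": np.log10(n_k),
                     "y": np.log10(v) if v > 0 else -np.inf})
    return pd.DataFrame(recs)


def _predict_variance(n_subjects, xi, sigma):
    n = np.asarray(n_subjects, dtype=float)
    return xi ** 2 / n + sigma ** 2


def information_criteria(residuals: np.ndarray, q: int):
    """Small-sample AICc and BIC from variance-scale residuals.

    AICc = sum ln phi_k^2 + 2q + 2q(q+1)/(K - q - 1);
    BIC  = sum ln phi_k^2 + q ln K.  A zero residual means a perfect fit and
    makes both criteria -inf (flagged with a warning).
    """
    phi = np.asarray(residuals, dtype=float)
    k = phi.size
    if k - q - 1 <= 0:
        raise ValidationError(f"AICc undefined: K={k} points for q={q} parameters")
    if np.any(phi == 0):
        warnings.warn("zero residual: criteria degenerate (-inf, perfect fit)")
        return -np.inf, -np.inf
    ll = float(np.sum(np.log(phi ** 2)))
    aicc = ll + 2 * q + 2 * q * (q + 1) / (k - q - 1)
    bic = ll + q * np.log(k)
    return aicc, bic


class PopulationVarianceModel(BaseEstimator):
    """Fit one of the two sampling-bias variance laws to site points.

    Parameters
    ----------
    model : {"single", "different"}
        Single-population law (sigma fixed at 0, q = 1) or
        different-subpopulation law (free sigma, q = 2).
    loss_scale : {"log", "variance"}
        Scale of the least-squares loss.  The log10 scale matches the axes
        on which the laws are written and plotted and is the default; the
        information criteria always use variance-scale residuals.

    Attributes
    ----------
    xi_, sigma_ : float
    residuals_ : ndarray           phi_k = v_k - v_hat_k (variance scale)
    aicc_, bic_ : float
    q_ : int
    """

    def __init__(self, model: str = "single", loss_scale: str = "log"):
        self.model = model
        self.loss_scale = loss_scale

    @property
    def _q(self) -> int:
        return 1 if self.model == "single" else 2

    def fit(self, points: pd.DataFrame, y=None):
        if self.model not in ("single", "different"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.loss_scale not in ("log", "variance"):
            raise ValueError(f"unknown loss_scale {self.loss_scale!r}")
        n = points["n_subjects"].to_numpy(dtype=float)
        v = points["variance"].to_numpy(dtype=float)
        if len(points) < self._q + 1:
            raise ValidationError(
                f"need at least {self._q + 1} sites for the {self.model} model"
            )
        if (n < 1).any():
            raise ValidationError("every site needs N_k >= 1")

        if self.model == "single":
            xi, sigma = self._fit_single(n, v)
        else:
            xi, sigma = self._fit_different(n, v)
        self.xi_ = float(xi)
        self.sigma_ = float(sigma)
        self.residuals_ = v - _predict_variance(n, self.xi_, self.sigma_)
        self.aicc_, self.bic_ = information_criteria(self.residuals_, self._q)
        self.q_ = self._q
        return self

    def _fit_single(self, n, v):
        if self.loss_scale == "log":
            # y = -x + 2 log10 xi  =>  closed form on the log scale
            y, x = np.log10(v), np.log10(n)
            return 10 ** (np.mean(y + x) / 2.0), 0.0
        # normal equation for: minimize sum (v - xi^2/n)^2
        xi2 = np.sum(v / n) / np.sum(1.0 / n ** 2)
        return np.sqrt(max(xi2, 0.0)), 0.0

    def _fit_different(self, n, v):
        # optimize on (log xi, log sigma) so positivity is smooth
        single_xi = self._fit_single(n, v)[0]
        floor = max(v.min(), 1e-12)
        theta0 = np.log([max(single_xi, 1e-6), np.sqrt(floor)])

        def loss(theta):
            xi, sigma = np.exp(theta)
            pred = _predict_variance(n, xi, sigma)
            if self.loss_scale == "log":
                return np.sum((np.log10(v) - np.log10(pred)) ** 2)
            return np.sum((v - pred) ** 2)

        res = optimize.minimize(loss, theta0, method="BFGS")
        # the single model is nested (sigma -> 0); never do worse than it
        nested = np.array([np.log(max(single_xi, 1e-12)), np.log(1e-9)])
        candidates = [res.x] if np.isfinite(res.fun) else []
        res2 = optimize.minimize(loss, nested, method="BFGS")
        if np.isfinite(res2.fun):
            candidates.append(res2.x)
        candidates.append(nested)
        best = min(candidates, key=loss)
        if not np.isfinite(loss(best)):
            raise RuntimeError(f"population-model fit failed: {res}")
        xi, sigma = np.exp(best)
        return xi, sigma

    def predict(self, n_subjects):
        """Predicted across-edge variance at the given site sizes."""
        return _predict_variance(n_subjects, self.xi_, self.sigma_)


def fit_population_model(points: pd.DataFrame, model: str,
                         loss_scale: str = "log") -> PopulationVarianceModel:
    return PopulationVarianceModel(model=model, loss_scale=loss_scale).fit(points)


def loso_cv_predict(points: pd.DataFrame, models=("single", "different"),
                    loss_scale: str = "log"):
    """Leave-one-site-out predictive comparison of the variance laws.

    Each site in turn is held out, the parameters are fitted on the rest, and
    the held-out variance is predicted from its N_k.  Returns
    ``(errors, comparison)``: per-site absolute errors per model and, when
    both laws are requested, a one-tailed Wilcoxon signed-rank test of
    whether the different-subpopulation model has smaller absolute error.
    """
    if len(points) < 3:
        raise ValidationError("need >= 3 sites for leave-one-site-out")
    recs = []
    for i in range(len(points)):
        rest = points.drop(points.index[i])
        held = points.iloc[i]
        row = {"site_id": held["site_id"], "actual": held["variance"]}
        for model in models:
            try:
                fit = fit_population_model(rest, model, loss_scale)
                pred = float(fit.predict(held["n_subjects"]))
                row[f"pred_{model}"] = pred
                row[f"abs_err_{model}"] = abs(pred - held["variance"])
            except (ValidationError, RuntimeError) as err:
                warnings.warn(f"fold {held['site_id']}: {model} fit failed "
                              f"({err}); excluded")
                row[f"pred_{model}"] = np.nan
                row[f"abs_err_{model}"] = np.nan
        recs.append(row)
    errors = pd.DataFrame(recs)
    comparison = None
    if set(models) >= {"single", "different"}:
        ok = errors[["abs_err_single", "abs_err_different"]].dropna()
        if len(ok) >= 3:
            res = stats.wilcoxon(ok["abs_err_single"], ok["abs_err_different"],
                                 alternative="greater")
            comparison = {"statistic": float(res.statistic),
                          "p": float(res.pvalue), "n": len(ok),
                          "direction": "different model has smaller error"}
    return errors, comparison
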