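"""PCA projection for visualizing site and disorder structure.

Thin wrapper over a centered principal-component decomposition: no per-edge
scaling, since every edge shares Fisher-z units.  Group means (healthy
controls per site, and per diagnosis) summarize where sites and disorders
sit in the leading component plane — a large measurement bias shows up as a
site mean far from the origin, and collapses after harmonization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .data import ConnectivityDataset, ValidationError


class ConnectivityPCA(BaseEstimator):
    """Centered PCA of a connectivity dataset with group-mean overlays.

    Attributes (after fit): ``loadings_`` (edges x components),
    ``scores_`` (rows x components), ``explained_variance_ratio_``,
    ``group_means_`` (DataFrame of score means for HC-per-site and
    per-diagnosis groups).  Components are sign-fixed so each one's
    largest-magnitude loading is positive.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, dataset: ConnectivityDataset, y=None):
        if dataset.n_rows <= self.n_components:
            raise ValidationError("need more rows than components")
        if np.allclose(dataset.values.std(axis=0), 0):
            warnings.warn("constant dataset: components are degenerate")
        pca = PCA(n_components=self.n_components)
        scores = pca.fit_transform(dataset.values)
        flip = np.sign(
            pca.components_[np.arange(self.n_components),
                            np.abs(pca.components_).argmax(axis=1)]
        )
        flip[flip == 0] = 1.0
        self.loadings_ = (pca.components_ * flip[:, None]).T
        self.scores_ = scores * flip
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.mean_ = pca.mean_

        meta = dataset.meta
        cols = [f"pc{i + 1}" for i in range(self.n_components)]
        recs = []
        hc = meta["diagnosis"] == "HC"
        for site in sorted(meta.loc[hc, "site_id"].unique()):
            rows = (hc & (meta["site_id"] == site)).to_numpy()
            recs.append({"group": f"HC@{site}", "kind": "site_hc", "n": rows.sum(),
                         **dict(zip(cols, self.scores_[rows].mean(axis=0)))})
        for diag in sorted(meta.loc[~hc, "diagnosis"].unique()):
            rows = (meta["diagnosis"] == diag).to_numpy()
            recs.append({"group": diag, "kind": "diagnosis", "n": rows.sum(),
                         **dict(zip(cols, self.scores_[rows].mean(axis=0)))})
        self.group_means_ = pd.DataFrame(recs)
        return self

    def transform(self, dataset: ConnectivityDataset) -> np.ndarray:
        return (dataset.values - self.mean_) @ self.loadings_


def project_pca(dataset: ConnectivityDataset, n_components: int = 2) -> ConnectivityPCA:
    """Fit a :class:`ConnectivityPCA`; convenience wrapper."""
    return ConnectivityPCA(n_components=n_components).fit(dataset)
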