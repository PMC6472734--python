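"""Joint decomposition of site differences into measurement and sampling bias.

The model regresses each connectivity edge, over the pooled multisite patient
rows and traveling-subject rows, on 1-of-K indicator blocks:

    y = x_m' m + x_shc' s_hc + x_smdd' s_mdd + x_sscz' s_scz
        + x_d' d + x_p' p + const + e,        e ~ N(0, gamma^-1)

where ``m`` is per-site measurement bias (every site visited by the traveling
subjects), ``s_*`` are per-site sampling biases for healthy controls and for
each patient class sampled at more than one site, ``d`` are disorder factors
(healthy-control baseline, so d(HC) = 0), and ``p`` are traveling-participant
factors.  Multisite rows carry no participant block (individual differences
are noise there); traveling rows carry no sampling or disorder blocks.  Each
constrained block is forced to sum to zero across its levels so the intercept
is the grand mean; patient classes observed at a single site get no sampling
block — their site deviation is absorbed by the disorder factor.

Estimation is equality-constrained ridge: minimize
``||y - Xw||^2 + lambda * ||w_pen||^2`` subject to ``Cw = 0``, solved by
null-space elimination (substitute ``w = Z u`` with ``Z`` an orthonormal
basis of the null space of ``C`` and solve the reduced normal equations).
One factorization is shared by all edges.  The intercept is excluded from the
penalty by default: it estimates the grand mean and should not shrink.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .data import BiasDecomposition, ConnectivityDataset

DISORDER_LEVELS = ("MDD", "SCZ", "ASD")
SAMPLING_CLASSES = ("HC", "MDD", "SCZ")


class RankDeficiencyError(np.linalg.LinAlgError):
    """Constrained least squares is singular at lambda = 0; use lambda > 0."""


@dataclass
class DesignMatrix:
    """Indicator design with named column blocks (order: m, s_hc, s_mdd,
    s_scz, d, p, const)."""

    x: np.ndarray
    blocks: dict[str, list[str]]  # block name -> level labels, in column order

    def columns(self) -> list[tuple[str, str]]:
        return [(b, lvl) for b, levels in self.blocks.items() for lvl in levels]

    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, levels in self.blocks.items():
            out[name] = slice(start, start + len(levels))
            start += len(levels)
        return out

    @property
    def n_columns(self) -> int:
        return self.x.shape[1]


@dataclass
class ConstraintSet:
    """Equality constraints ``C w = 0`` (sum-to-zero rows per block)."""

    c: np.ndarray
    names: list[str]


#: blocks whose coefficients must average to zero across levels
_CONSTRAINED = ("m", "s_hc", "s_mdd", "s_scz", "p")


def assemble_design(dataset: ConnectivityDataset):
    """Build the indicator design matrix and its constraint set.

    Sampling-bias blocks exist only for classes observed at >= 2 multisite
    sites (a single-site class is confounded with its disorder factor and is
    deliberately folded into it).
    """
    meta = dataset.meta
    multi = meta["dataset_kind"] == "multisite"
    trav = meta["dataset_kind"] == "traveling"
    m_levels = sorted(meta["site_id"].unique())
    missing = set(meta.loc[multi, "site_id"]) - set(meta.loc[trav, "site_id"])
    if trav.any() and missing:
        warnings.warn(
            f"multisite sites without traveling coverage: {sorted(missing)}; "
            "their measurement bias is identified from patient rows only"
        )

    blocks: dict[str, list[str]] = {"m": m_levels}
    for cls in SAMPLING_CLASSES:
        sites = sorted(meta.loc[multi & (meta["diagnosis"] == cls), "site_id"].unique())
        key = f"s_{cls.lower()}"
        if len(sites) >= 2:
            blocks[key] = sites
        else:
            blocks[key] = []
            if len(sites) == 1:
                warnings.warn(
                    f"{cls} sampled at a single site; its sampling bias is "
                    "folded into the disorder factor"
                )
    d_levels = [d for d in DISORDER_LEVELS
                if (multi & (meta["diagnosis"] == d)).any()]
    blocks["d"] = d_levels
    blocks["p"] = sorted(meta.loc[trav, "participant_id"].unique())
    blocks["const"] = ["const"]

    col_of = {}
    start = 0
    for name, levels in blocks.items():
        for i, lvl in enumerate(levels):
            col_of[(name, lvl)] = start + i
        start += len(levels)
    p_cols = start

    x = np.zeros((len(meta), p_cols))
    x[:, col_of[("const", "const")]] = 1.0
    site = meta["site_id"].to_numpy()
    diag = meta["diagnosis"].to_numpy()
    part = meta["participant_id"].to_numpy()
    for i in range(len(meta)):
        x[i, col_of[("m", site[i])]] = 1.0
        if multi.iloc[i]:
            dx = diag[i]
            if dx in SAMPLING_CLASSES and (f"s_{dx.lower()}", site[i]) in col_of:
                x[i, col_of[(f"s_{dx.lower()}", site[i])]] = 1.0
            if (("d", dx)) in col_of:
                x[i, col_of[("d", dx)]] = 1.0
        else:
            x[i, col_of[("p", part[i])]] = 1.0

    design = DesignMatrix(x=x, blocks=blocks)
    rows, names = [], []
    sl = design.slices()
    for name in _CONSTRAINED:
        if len(blocks[name]) >= 2:
            row = np.zeros(p_cols)
            row[sl[name]] = 1.0
            rows.append(row)
            names.append(f"sum({name})=0")
    c = np.array(rows) if rows else np.zeros((0, p_cols))
    return design, ConstraintSet(c=c, names=names)


def fit_constrained_ridge(y: np.ndarray, x: np.ndarray, c: np.ndarray,
                          lam: float, penalize_intercept: bool = False,
                          intercept_col: int | None = None):
    """Equality-constrained ridge via null-space elimination.

    ``y`` may be a vector or a rows-by-edges matrix; the reduced system is
    factorized once and solved for every edge.  Returns ``(w, resid_var)``
    with ``w`` of shape (n_columns, n_edges) and residual variance RSS/n
    (degrees of freedom are ill-defined under constraints plus ridge, so the
    plain 1/n estimator is used).

    Raises :class:`RankDeficiencyError` when ``lam = 0`` and the constrained
    design is singular.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    yy = y[:, None] if squeeze else y
    n, p = x.shape
    if yy.shape[0] != n:
        raise ValueError("y row count does not match design")

    if c.size:
        if np.linalg.matrix_rank(c) < c.shape[0]:
            raise ValueError("constraint rows are redundant or infeasible")
        z = linalg.null_space(c)
    else:
        z = np.eye(p)
    pen = np.ones(p)
    if not penalize_intercept and intercept_col is not None:
        pen[intercept_col] = 0.0
    xz = x @ z
    a = xz.T @ xz + lam * (z.T @ (pen[:, None] * z))
    if lam == 0 and np.linalg.matrix_rank(a, hermitian=True) < a.shape[0]:
        raise RankDeficiencyError(
            "design is rank-deficient under the constraints at lambda = 0; "
            "set lambda > 0"
        )
    b = xz.T @ yy
    try:
        cf = linalg.cho_factor(a)
        u = linalg.cho_solve(cf, b)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise RankDeficiencyError(str(err)) from err
    w = z @ u
    resid = yy - x @ w
    resid_var = (resid ** 2).mean(axis=0)
    if squeeze:
        return w[:, 0], float(resid_var[0])
    return w, resid_var


def _decomposition_from_coef(design: DesignMatrix, w: np.ndarray,
                             resid_var: np.ndarray, lam: float) -> BiasDecomposition:
    sl = design.slices()

    def blk(name):
        return {lvl: w[sl[name]][i].copy()
                for i, lvl in enumerate(design.blocks[name])}

    return BiasDecomposition(
        measurement_bias=blk("m"),
        sampling_bias_hc=blk("s_hc"),
        sampling_bias_mdd=blk("s_mdd"),
        sampling_bias_scz=blk("s_scz"),
        disorder_factor=blk("d"),
        participant_factor=blk("p"),
        intercept=w[sl["const"]][0].copy(),
        residual_variance=np.atleast_1d(resid_var).astype(float),
        lam=lam,
    )


class SiteBiasModel(BaseEstimator):
    """Constrained-ridge estimator of the site-difference decomposition.

    Parameters
    ----------
    lam : float
        Ridge weight on all non-intercept coefficients.  Zero is allowed
        only when the constrained design has full rank (it does when the
        traveling data cover every multisite site); see
        :func:`select_lambda` for the data-driven choice.
    penalize_intercept : bool
        Include the grand-mean intercept in the penalty (off by default).

    Attributes
    ----------
    decomposition_ : BiasDecomposition
    design_ : DesignMatrix
    constraints_ : ConstraintSet
    measurement_bias_, sampling_bias_hc_, sampling_bias_mdd_,
    sampling_bias_scz_, disorder_factor_, participant_factor_ : dict
        Level -> edge-vector views into the decomposition.
    intercept_, residual_variance_ : ndarray
    """

    def __init__(self, lam: float = 1.0, penalize_intercept: bool = False):
        self.lam = lam
        self.penalize_intercept = penalize_intercept

    def fit(self, dataset: ConnectivityDataset, y=None):
        design, constraints = assemble_design(dataset)
        icol = design.slices()["const"].start
        w, resid_var = fit_constrained_ridge(
            dataset.values, design.x, constraints.c, self.lam,
            penalize_intercept=self.penalize_intercept, intercept_col=icol,
        )
        self.design_ = design
        self.constraints_ = constraints
        self.coef_ = w
        self.decomposition_ = _decomposition_from_coef(
            design, w, resid_var, self.lam
        )
        d = self.decomposition_
        self.measurement_bias_ = d.measurement_bias
        self.sampling_bias_hc_ = d.sampling_bias_hc
        self.sampling_bias_mdd_ = d.sampling_bias_mdd
        self.sampling_bias_scz_ = d.sampling_bias_scz
        self.disorder_factor_ = d.disorder_factor
        self.participant_factor_ = d.participant_factor
        self.intercept_ = d.intercept
        self.residual_variance_ = d.residual_variance
        return self


def fit_all_edges(dataset: ConnectivityDataset, lam: float = 1.0,
                  penalize_intercept: bool = False) -> BiasDecomposition:
    """Fit every edge jointly (shared factorization) and return the result."""
    return SiteBiasModel(lam=lam, penalize_intercept=penalize_intercept).fit(
        dataset
    ).decomposition_


# ---------------------------------------------------------------------------
# ridge-weight selection
# ---------------------------------------------------------------------------

def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def spurious_bias_correlations(decomp: BiasDecomposition) -> dict[str, list[float]]:
    """Matched-site correlations between bias families.

    Under the generating model measurement and sampling bias are independent,
    so any systematic correlation between the fitted vectors at the same site
    is an estimation artifact; shrinkage is tuned to suppress it.
    """
    fams: dict[str, list[float]] = {}
    m, shc = decomp.measurement_bias, decomp.sampling_bias_hc
    fams["m_vs_s_hc"] = [
        _safe_corr(m[k], shc[k]) for k in shc if k in m
    ]
    for name, blk in (("s_hc_vs_s_mdd", decomp.sampling_bias_mdd),
                      ("s_hc_vs_s_scz", decomp.sampling_bias_scz)):
        fams[name] = [_safe_corr(shc[k], blk[k]) for k in blk if k in shc]
    return {k: v for k, v in fams.items() if v}


def bias_correlation_criterion(decomp: BiasDecomposition) -> float:
    """Absolute mean over the between-family mean correlations."""
    fams = spurious_bias_correlations(decomp)
    if not fams:
        raise ValueError("no overlapping bias families to correlate")
    return float(abs(np.mean([np.nanmean(v) for v in fams.values()])))


@dataclass
class LambdaSearchResult:
    grid: np.ndarray
    criterion: np.ndarray
    lambda_: float
    permutation_criterion: np.ndarray | None = None
    families: list[dict] = field(default_factory=list)


def select_lambda(dataset: ConnectivityDataset, grid=None,
                  with_permutation: bool = False, seed: int | None = None,
                  penalize_intercept: bool = False) -> LambdaSearchResult:
    """Pick the ridge weight minimizing the spurious between-bias correlation.

    For each grid value the model is refitted and the absolute mean of the
    matched-site correlations (measurement vs HC sampling bias, HC vs MDD
    sampling bias, HC vs SCZ sampling bias) is recorded; the grid argmin is
    returned.  Grid points where the solver refuses (lambda = 0 on a
    rank-deficient design) score NaN.  Optionally the same curve is computed
    on site-permuted data as a null reference.
    """
    grid = np.arange(0.0, 21.0) if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if (grid < 0).any():
        raise ValueError("lambda values must be non-negative")

    def curve(ds):
        crit, fams = [], []
        for lam in grid:
            try:
                dec = fit_all_edges(ds, lam=lam,
                                    penalize_intercept=penalize_intercept)
                crit.append(bias_correlation_criterion(dec))
                fams.append(spurious_bias_correlations(dec))
            except RankDeficiencyError:
                warnings.warn(f"lambda={lam}: rank-deficient; skipped")
                crit.append(np.nan)
                fams.append({})
        return np.array(crit), fams

    criterion, families = curve(dataset)
    if np.all(np.isnan(criterion)):
        raise RankDeficiencyError("no lambda on the grid gave a solvable fit")
    chosen = float(grid[np.nanargmin(criterion)])

    perm_criterion = None
    if with_permutation:
        rng = np.random.default_rng(seed)
        meta = dataset.meta.copy()
        multi = meta["dataset_kind"] == "multisite"
        sites = meta.loc[multi, "site_id"].to_numpy()
        meta.loc[multi, "site_id"] = rng.permutation(sites)
        shuffled = ConnectivityDataset(values=dataset.values.copy(), meta=meta,
                                       edge_index=dataset.edge_index)
        perm_criterion, _ = curve(shuffled)

    return LambdaSearchResult(grid=grid, criterion=criterion, lambda_=chosen,
                              permutation_criterion=perm_criterion,
                              families=families)
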