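"""Summaries of fitted bias/factor vectors.

Magnitude-distribution moments, contribution sizes, dispersion comparisons,
bias-disorder pattern correlations, projection of edge effects onto ROIs,
hierarchical clustering of measurement biases, and the per-edge site ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .bias import assemble_design
from .data import BiasDecomposition, ConnectivityDataset, EdgeIndex, ValidationError

#: decomposition block behind each factor name
FACTOR_BLOCKS = {
    "measurement": "measurement_bias",
    "sampling_hc": "sampling_bias_hc",
    "sampling_mdd": "sampling_bias_mdd",
    "sampling_scz": "sampling_bias_scz",
    "disorder": "disorder_factor",
    "participant": "participant_factor",
}


def _get_block(decomp: BiasDecomposition, factor: str) -> dict[str, np.ndarray]:
    if factor not in FACTOR_BLOCKS:
        raise ValidationError(
            f"unknown factor {factor!r}; choose from {sorted(FACTOR_BLOCKS)}"
        )
    block = decomp.block(FACTOR_BLOCKS[factor])
    if not block:
        raise ValidationError(f"factor {factor!r} is empty in this decomposition")
    return block


def magnitude_moments(decomp: BiasDecomposition, factor: str) -> pd.DataFrame:
    """First three moments of each level's magnitude distribution.

    Per level (site or participant): mean, population SD, and the signed cube
    root of the third central moment of the edge-wise values.  The row
    ``__summary__`` averages the per-level statistics, which is the
    factor-level magnitude usually quoted.
    """
    block = _get_block(decomp, factor)
    rows = {}
    for level, v in block.items():
        mu = v.mean()
        rows[level] = {
            "mean": mu,
            "sd": v.std(),                       # population SD over ~N edges
            "third_moment_cbrt": float(np.cbrt(((v - mu) ** 3).mean())),
        }
    df = pd.DataFrame(rows).T.sort_index()
    df.loc["__summary__"] = df.mean(axis=0)
    df.index.name = "level"
    return df


def factor_sd(decomp: BiasDecomposition, factor: str) -> float:
    """Mean across levels of the per-level magnitude SD."""
    block = _get_block(decomp, factor)
    return float(np.mean([v.std() for v in block.values()]))


@dataclass
class ContributionReport:
    """Per-factor contribution sizes plus the residual (noise) share.

    ``contribution[f] * n_levels[f]`` summed over factors, plus
    ``noise_share``, equals 1: the squared-term shares are a partition of
    each (subject, edge) cell.
    """

    contribution: dict[str, float]
    noise_share: float
    n_levels: dict[str, int]

    def conservation_error(self) -> float:
        total = sum(self.contribution[f] * self.n_levels[f]
                    for f in self.contribution) + self.noise_share
        return abs(total - 1.0)


def contribution_sizes(dataset: ConnectivityDataset,
                       decomp: BiasDecomposition) -> ContributionReport:
    """Share of squared signal each model term explains, per level count.

    For every (subject, edge) cell the squared values of the six factor terms
    and the residual are normalized by their sum; the contribution size of a
    factor is the average share divided by its number of levels.
    """
    design, _ = assemble_design(dataset)
    sl = design.slices()
    w = _coef_matrix(design, decomp)
    fitted = design.x @ w
    resid = dataset.values - fitted

    factor_names = [n for n in ("m", "s_hc", "s_mdd", "s_scz", "d", "p")
                    if design.blocks[n]]
    terms = {n: (design.x[:, sl[n]] @ w[sl[n]]) ** 2 for n in factor_names}
    terms["__noise__"] = resid ** 2
    denom = sum(terms.values())
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} (subject, edge) cells have all-zero "
                      "terms; their shares are set to zero")
        denom = np.where(zero, 1.0, denom)
    shares = {n: np.where(zero, 0.0, t / denom).mean() for n, t in terms.items()}

    name_map = {"m": "measurement", "s_hc": "sampling_hc",
                "s_mdd": "sampling_mdd", "s_scz": "sampling_scz",
                "d": "disorder", "p": "participant"}
    n_levels = {name_map[n]: len(design.blocks[n]) for n in factor_names}
    contribution = {name_map[n]: float(shares[n]) / len(design.blocks[n])
                    for n in factor_names}
    return ContributionReport(contribution=contribution,
                              noise_share=float(shares["__noise__"]),
                              n_levels=n_levels)


def _coef_matrix(design, decomp: BiasDecomposition) -> np.ndarray:
    """Stack decomposition blocks back into design-column order."""
    blocks = {"m": decomp.measurement_bias, "s_hc": decomp.sampling_bias_hc,
              "s_mdd": decomp.sampling_bias_mdd, "s_scz": decomp.sampling_bias_scz,
              "d": decomp.disorder_factor, "p": decomp.participant_factor,
              "const": {"const": decomp.intercept}}
    cols = []
    for name, levels in design.blocks.items():
        for lvl in levels:
            if lvl not in blocks[name]:
                raise ValidationError(
                    f"decomposition lacks level {lvl!r} of block {name!r}; "
                    "was it fitted on this dataset?"
                )
            cols.append(blocks[name][lvl])
    return np.array(cols)


def variance_comparisons(decomp: BiasDecomposition,
                         factor_a: str = "participant",
                         factor_b: str = "measurement") -> pd.DataFrame:
    """Ansari-Bradley dispersion tests between all level pairs of two factors.

    With the default factors and the full study design this is the 9
    participants x 12 sites = 108-pair grid; p-values are
    Bonferroni-corrected by the number of pairs.
    """
    a = _get_block(decomp, factor_a)
    b = _get_block(decomp, factor_b)
    lengths = {v.shape[0] for v in list(a.values()) + list(b.values())}
    if len(lengths) != 1:
        raise ValidationError("factor vectors have unequal lengths")
    recs = []
    n_pairs = len(a) * len(b)
    for la, va in sorted(a.items()):
        for lb, vb in sorted(b.items()):
            res = stats.ansari(va, vb)
            recs.append({
                f"{factor_a}_level": la, f"{factor_b}_level": lb,
                "statistic": res.statistic, "p": res.pvalue,
                "p_bonferroni": min(1.0, res.pvalue * n_pairs),
            })
    return pd.DataFrame(recs)


def bias_disorder_correlation(decomp: BiasDecomposition):
    """Pattern correlations between measurement biases and disorder factors.

    Returns ``(table, test)``: the site x disorder Pearson-r table and a
    one-sample t test of the absolute correlations against zero with
    ``df = pairs - 1``.  Constant vectors yield NaN cells and are excluded
    from the test with a warning.
    """
    m = _get_block(decomp, "measurement")
    d = _get_block(decomp, "disorder")
    table = pd.DataFrame(index=sorted(m), columns=sorted(d), dtype=float)
    for site, mv in m.items():
        for dis, dv in d.items():
            if mv.std() == 0 or dv.std() == 0:
                table.loc[site, dis] = np.nan
            else:
                table.loc[site, dis] = np.corrcoef(mv, dv)[0, 1]
    vals = table.to_numpy(dtype=float).ravel()
    if np.isnan(vals).any():
        warnings.warn("constant vectors produced undefined correlations; "
                      "flagged as NaN and excluded from the t test")
    finite = vals[np.isfinite(vals)]
    if len(finite) >= 2:
        t = stats.ttest_1samp(np.abs(finite), 0.0)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
    else:  # a single pair leaves no degrees of freedom
        t_stat, t_p = np.nan, np.nan
    test = {"mean_r": float(np.nanmean(vals)), "sd_r": float(np.nanstd(vals)),
            "t": t_stat, "p": t_p,
            "df": len(finite) - 1, "n_pairs": len(finite)}
    return table, test


def roi_projection(decomp: BiasDecomposition, factor: str,
                   edge_index: EdgeIndex, z_score: bool = False) -> pd.DataFrame:
    """Project per-edge effects onto ROIs.

    The per-edge effect is the median absolute value across levels (biases
    and the participant factor) or the absolute value of a single disorder
    vector (``factor="disorder:MDD"`` etc.); an ROI's value is the mean over
    its incident edges.  ``z_score=True`` standardizes across ROIs within
    the factor.
    """
    if factor.startswith("disorder:"):
        level = factor.split(":", 1)[1]
        block = _get_block(decomp, "disorder")
        if level not in block:
            raise ValidationError(f"disorder level {level!r} absent")
        edge_effect = np.abs(block[level])
    else:
        block = _get_block(decomp, factor)
        edge_effect = np.median(np.abs(np.array(list(block.values()))), axis=0)
    if edge_effect.shape[0] != edge_index.n_edges:
        raise ValidationError("edge index inconsistent with decomposition")

    k = edge_index.n_nodes
    sums = np.zeros(k)
    counts = np.zeros(k)
    for (i, j), e in zip(edge_index.pairs, edge_effect):
        sums[i] += e
        sums[j] += e
        counts[i] += 1
        counts[j] += 1
    with np.errstate(invalid="ignore"):
        effect = sums / counts
    out = pd.DataFrame({"roi": np.arange(1, k + 1), "effect": effect})
    if z_score:
        sd = np.nanstd(effect)
        out["z"] = np.zeros(k) if sd == 0 else (effect - np.nanmean(effect)) / sd
    return out


@dataclass
class BiasDendrogram:
    """Correlation structure of per-site measurement biases.

    ``linkage`` is a scipy linkage matrix on the 1 - r distance with optimal
    leaf ordering applied; merge heights therefore live in [0, 2].
    """

    correlation: pd.DataFrame
    linkage: np.ndarray
    leaves: list[str]


def cluster_measurement_bias(decomp: BiasDecomposition,
                             linkage_method: str = "average") -> BiasDendrogram:
    """Hierarchical clustering of measurement-bias vectors on 1 - r distance."""
    block = _get_block(decomp, "measurement")
    if len(block) < 2:
        raise ValidationError("need at least 2 sites to cluster")
    for site, v in block.items():
        if v.std() == 0:
            raise ValidationError(f"constant measurement bias at site {site!r}")
    sites = sorted(block)
    mat = np.array([block[s] for s in sites])
    corr = np.corrcoef(mat)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = hierarchy.linkage(condensed, method=linkage_method)
    z = hierarchy.optimal_leaf_ordering(z, condensed)
    leaves = [sites[i] for i in hierarchy.leaves_list(z)]
    return BiasDendrogram(
        correlation=pd.DataFrame(corr, index=sites, columns=sites),
        linkage=z, leaves=leaves,
    )


def site_effect_anova(dataset: ConnectivityDataset, alpha: float = 0.05):
    """Per-edge one-way ANOVA across sites with a Bonferroni threshold.

    Returns a dict with per-edge F and p arrays, the Bonferroni significance
    mask, and the significant fraction.  Sites with fewer than 2 rows are
    dropped with a warning.
    """
    multi = dataset.meta["dataset_kind"] == "multisite"
    ds = dataset.subset(multi.to_numpy()) if not multi.all() else dataset
    groups = []
    for site in ds.sites():
        vals = ds.values[(ds.meta["site_id"] == site).to_numpy()]
        if vals.shape[0] < 2:
            warnings.warn(f"site {site!r} has < 2 rows; dropped from ANOVA")
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValidationError("need >= 2 sites with >= 2 rows each")
    f, p = stats.f_oneway(*groups, axis=0)
    n_edges = ds.n_edges
    mask = p < alpha / n_edges
    return {"f": f, "p": p, "significant": mask,
            "significant_fraction": float(mask.mean()),
            "threshold": alpha / n_edges}
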