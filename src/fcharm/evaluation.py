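"""Two-fold cross-validated harmonization benchmark.

The multisite dataset is split into two site-stratified halves; the
traveling dataset is split into two halves stratified by site and
participant, so measurement bias is shared between folds while the sampled
participants differ.  For each fold direction a harmonizer is fitted on the
estimating half (plus its traveling half for the traveling-subject method),
applied to the testing half, and the bias decomposition is refitted on the
harmonized testing data.  A method that removed measurement bias leaves a
smaller refitted measurement-bias SD; a method that also removed biology
degrades the participant/disorder signal, which the two signal-to-noise
ratios (measurement SD over participant-factor SD and over disorder-factor
SD) expose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias import SiteBiasModel
from .data import ConnectivityDataset, ValidationError, concat_datasets
from .harmonize import METHODS, TravelingSubjectHarmonizer
from .metrics import factor_sd

ALL_METHODS = ("raw", "traveling", "glm", "adjglm", "combat")


@dataclass
class CvSplit:
    """Fold-1 membership masks for the multisite and traveling rows."""

    multisite_fold1: np.ndarray
    traveling_fold1: np.ndarray
    seed: int | None


def _stratified_half(index_groups, rng):
    """Assign ~half of each group to fold 1 (odd counts round to fold 1)."""
    n_total = sum(len(g) for g in index_groups)
    fold1 = np.zeros(n_total, dtype=bool)
    for idx in index_groups:
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        take = (len(idx) + 1) // 2
        fold1[idx[perm[:take]]] = True
    return fold1


def make_split(multisite: ConnectivityDataset, traveling: ConnectivityDataset,
               seed: int | None = None) -> CvSplit:
    """Deterministic site-stratified 2-fold split.

    Multisite rows are halved within each site; traveling rows within each
    (site, participant) cell.  A cell with a single row goes whole to fold 1
    with a warning.
    """
    rng = np.random.default_rng(seed)
    m_groups, singletons = [], []
    for site, grp in multisite.meta.groupby("site_id"):
        if len(grp) == 1:
            singletons.append(site)
        m_groups.append(grp.index.to_numpy())
    if singletons:
        warnings.warn(f"sites with a single multisite row assigned whole to "
                      f"fold 1: {singletons}")
    t_groups, lone = [], 0
    for (_site, _pid), grp in traveling.meta.groupby(["site_id", "participant_id"]):
        if len(grp) == 1:
            lone += 1
        t_groups.append(grp.index.to_numpy())
    if lone:
        warnings.warn(f"{lone} traveling (site, participant) cells have a "
                      "single session; assigned whole to fold 1")
    return CvSplit(
        multisite_fold1=_stratified_half(m_groups, rng),
        traveling_fold1=_stratified_half(t_groups, rng),
        seed=seed,
    )


def _summaries(testing: ConnectivityDataset, lam: float) -> dict[str, float]:
    model = SiteBiasModel(lam=lam).fit(testing)
    d = model.decomposition_
    sd_m = factor_sd(d, "measurement")
    sd_p = factor_sd(d, "participant")
    disorder_sds = [v.std() for v in d.disorder_factor.values()]
    sd_d = float(np.mean(disorder_sds)) if disorder_sds else np.nan
    return {"sd_measurement": sd_m, "sd_participant": sd_p,
            "sd_disorder": sd_d,
            "ratio_measurement_participant": sd_m / sd_p,
            "ratio_measurement_disorder": sd_m / sd_d if sd_d else np.nan}


def run_cv_evaluation(multisite: ConnectivityDataset,
                      traveling: ConnectivityDataset,
                      methods=ALL_METHODS, lam: float = 1.0,
                      seed: int | None = None) -> pd.DataFrame:
    """Per-(method, fold) measurement-bias SD and signal-to-noise ratios.

    The traveling-subject method fits on the estimating multisite half plus
    its traveling half and is applied to the whole testing dataset; the
    GLM-family methods fit on the estimating multisite half alone and are
    applied to the testing multisite half (traveling-only sites have no
    fitted term).  Failures mark the (method, fold) cell and do not abort
    the remaining cells.
    """
    bad = sorted(set(methods) - set(ALL_METHODS))
    if bad:
        raise ValidationError(f"unknown methods {bad}; choose from {ALL_METHODS}")
    split = make_split(multisite, traveling, seed)
    rows = []
    for fold, (m_est_mask, t_est_mask) in enumerate(
        [(split.multisite_fold1, split.traveling_fold1),
         (~split.multisite_fold1, ~split.traveling_fold1)], start=1
    ):
        m_est = multisite.subset(m_est_mask)
        m_test = multisite.subset(~m_est_mask)
        t_est = traveling.subset(t_est_mask)
        t_test = traveling.subset(~t_est_mask)
        testing = concat_datasets(m_test, t_test)
        for method in methods:
            rec = {"method": method, "fold": fold, "failed": False}
            try:
                if method == "raw":
                    harmonized = testing
                elif method == "traveling":
                    est = concat_datasets(m_est, t_est)
                    model = TravelingSubjectHarmonizer(lam=lam).fit(est)
                    harmonized = model.transform(testing)
                else:
                    model = METHODS[method]().fit(m_est)
                    harmonized = concat_datasets(model.transform(m_test), t_test)
                rec.update(_summaries(harmonized, lam))
            except Exception as err:  # keep other cells alive
                warnings.warn(f"{method} fold {fold} failed: {err}")
                rec["failed"] = True
            rows.append(rec)
    return pd.DataFrame(rows)


def reduction_and_snr(report: pd.DataFrame) -> pd.DataFrame:
    """Percent reductions versus the raw baseline, averaged over folds.

    reduction% = 100 (SD_raw - SD_method) / SD_raw on the measurement-bias
    SD; the signal-to-noise improvements are the same percentage computed on
    the measurement/participant and measurement/disorder SD ratios (a lower
    ratio is better).  Raw scores 0 by definition.
    """
    if "raw" not in set(report["method"]):
        raise ValidationError("report lacks the raw baseline")
    ok = report[~report["failed"]]
    folds = sorted(ok["fold"].unique())
    out = []
    for method in ok["method"].unique():
        reds, snr_p, snr_d = [], [], []
        for fold in folds:
            raw = ok[(ok["method"] == "raw") & (ok["fold"] == fold)]
            cur = ok[(ok["method"] == method) & (ok["fold"] == fold)]
            if raw.empty or cur.empty:
                continue
            raw, cur = raw.iloc[0], cur.iloc[0]
            if raw["sd_measurement"] == 0:
                warnings.warn("raw measurement-bias SD is zero; percentages "
                              "undefined for this fold")
                continue
            reds.append(100 * (raw["sd_measurement"] - cur["sd_measurement"])
                        / raw["sd_measurement"])
            for key, acc in (("ratio_measurement_participant", snr_p),
                             ("ratio_measurement_disorder", snr_d)):
                if raw[key] and np.isfinite(raw[key]) and np.isfinite(cur[key]):
                    acc.append(100 * (raw[key] - cur[key]) / raw[key])
        out.append({
            "method": method,
            "bias_reduction_pct": float(np.mean(reds)) if reds else np.nan,
            "snr_participant_improvement_pct":
                float(np.mean(snr_p)) if snr_p else np.nan,
            "snr_disorder_improvement_pct":
                float(np.mean(snr_d)) if snr_d else np.nan,
        })
    return pd.DataFrame(out)
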