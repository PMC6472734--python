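"""Synthetic multisite + traveling-subject study generator with ground truth.

The generator draws data from the same linear structure the estimator fits:
each multisite patient row is grand mean + per-site measurement bias +
per-site/per-class sampling bias + disorder factor + subject deviation +
scan noise; each traveling-subject session is grand mean + measurement bias +
participant factor + scan noise.  Edges are generated independently (the
decomposition model treats them independently; spatial correlation among
edges is out of scope).

The default configuration mirrors the study design this model was built for:
six unified-protocol multisite sites with realistic per-class counts
(335 healthy controls, 81 major depression, 48 schizophrenia, 49 autism-
spectrum rows — autism at a single site, so its site deviation is folded
into the disorder factor), twelve traveling sites visited by nine healthy
participants on a 411-session schedule (three sessions at nine sites, two at
two sites, five three-session cycles at one home site, with one participant
one cycle short).  Default effect scales put each factor's across-edge SD at
the magnitude observed for that factor class in multisite resting-state
connectivity work: participant 0.0662, measurement 0.0411, disorder
0.030-0.038, between-subpopulation sampling 0.021-0.027 (Fisher-z units).
The scan-to-scan noise SD (0.03) is a synthetic calibration: real studies do
not publish it.

Under the different-subpopulation sampling model the per-class site means
beta_k are drawn N(0, sigma^2) per edge and subjects scatter N(beta_k, xi^2)
around them; the single-population model is the sigma = 0 special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ConnectivityDataset, EdgeIndex, build_edge_index
from .preprocess import RoiTimeSeries

#: multisite per-site class counts for the default (unified-protocol) design
DEFAULT_SITE_CLASSES: dict[str, dict[str, int]] = {
    "MS01": {"HC": 31},
    "MS02": {"HC": 77},
    "MS03": {"HC": 10, "MDD": 38},
    "MS04": {"HC": 35, "MDD": 9, "SCZ": 22},
    "MS05": {"HC": 40, "SCZ": 12, "ASD": 49},
    "MS06": {"HC": 142, "MDD": 34, "SCZ": 14},
}

DEFAULT_PARTICIPANTS = tuple(f"TS{i:02d}" for i in range(1, 10))


@dataclass(frozen=True)
class TravelingSchedule:
    """Session counts per (participant, site)."""

    counts: pd.DataFrame  # participants x sites

    @property
    def participants(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sites(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_sessions(self) -> int:
        return int(self.counts.to_numpy().sum())


def default_schedule() -> TravelingSchedule:
    """The 411-session traveling design.

    Twelve sites: the six multisite sites plus six traveling-only/extra sites.
    Nine participants do 3 sessions at nine sites, 2 sessions at two sites
    (EX01, EX02), and five 3-session cycles at the home site MS01; the last
    participant misses one home-site cycle.
    """
    sites = [f"MS{i:02d}" for i in range(1, 7)] + [f"EX{i:02d}" for i in range(1, 7)]
    counts = pd.DataFrame(3, index=list(DEFAULT_PARTICIPANTS), columns=sites)
    counts["EX01"] = 2
    counts["EX02"] = 2
    counts["MS01"] = 15
    counts.loc["TS09", "MS01"] = 12
    return TravelingSchedule(counts=counts)


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic study."""

    site_classes: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SITE_CLASSES.items()}
    )
    schedule: TravelingSchedule = field(default_factory=default_schedule)
    n_edges: int = 2000
    sd_m: float = 0.0411            # measurement-bias SD per site, per edge
    sd_p: float = 0.0662            # traveling-participant factor SD
    sd_d: dict[str, float] = field(
        default_factory=lambda: {"MDD": 0.0328, "SCZ": 0.0377, "ASD": 0.0297}
    )
    sigma_s: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.0267, "MDD": 0.0214, "SCZ": 0.0217}
    )                               # between-subpopulation SD per class
    xi: float = 0.0662              # within-population subject SD
    scan_noise_sd: float = 0.03     # session-to-session noise
    const_mean: float = 0.15        # grand-mean connectivity (Fisher z)
    const_sd: float = 0.30
    model: str = "different"        # "different" or "single" subpopulation law


def paper_scale_config(n_edges: int = 2000, model: str = "different") -> SimulationConfig:
    """The default study-scale configuration (see module docstring)."""
    return SimulationConfig(n_edges=n_edges, model=model)


@dataclass
class GroundTruth:
    """Generating parameters, for recovery tests against fitted estimates.

    All constrained blocks are re-centred to sum to zero across their levels,
    matching the estimator's conventions, so recovery is unbiased rather than
    alias-shifted.
    """

    const: np.ndarray
    measurement_bias: dict[str, np.ndarray]
    sampling_bias: dict[str, dict[str, np.ndarray]]   # class -> site -> vector
    disorder_factor: dict[str, np.ndarray]
    participant_factor: dict[str, np.ndarray]
    xi: float
    sigma: dict[str, float]
    scan_noise_sd: float
    seed: int | None


def _recenter(block: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if not block:
        return block
    mean = np.mean(list(block.values()), axis=0)
    return {k: v - mean for k, v in block.items()}


def _centered_draws(rng, levels, sd, n) -> dict[str, np.ndarray]:
    """Sum-to-zero draws whose per-level SD equals ``sd`` after centering.

    Centering K i.i.d. draws shrinks each one's SD by sqrt(1 - 1/K); the raw
    draws are inflated accordingly so the configured scale is the scale of
    the centred (estimable) vectors.
    """
    k = len(levels)
    if k == 0 or sd == 0:
        return {lvl: np.zeros(n) for lvl in levels}
    raw_sd = sd / np.sqrt(1 - 1 / k) if k > 1 else sd
    return _recenter({lvl: rng.normal(0, raw_sd, n) for lvl in levels})


def make_ground_truth(config: SimulationConfig, seed=None) -> GroundTruth:
    rng = np.random.default_rng(seed)
    n = config.n_edges
    sites = sorted(set(config.schedule.sites) | set(config.site_classes))
    const = rng.normal(config.const_mean, config.const_sd, n)
    m = _centered_draws(rng, sites, config.sd_m, n)

    sampling: dict[str, dict[str, np.ndarray]] = {}
    for cls, sigma in config.sigma_s.items():
        cls_sites = sorted(s for s, cc in config.site_classes.items()
                           if cc.get(cls, 0) > 0)
        if len(cls_sites) < 2:
            continue
        eff_sigma = 0.0 if config.model == "single" else sigma
        sampling[cls] = _centered_draws(rng, cls_sites, eff_sigma, n)
    disorders = sorted({c for cc in config.site_classes.values() for c in cc
                        if c in config.sd_d})
    d = {cls: rng.normal(0, config.sd_d[cls], n) for cls in disorders}
    p = _centered_draws(rng, list(config.schedule.participants), config.sd_p, n)
    return GroundTruth(
        const=const, measurement_bias=m, sampling_bias=sampling,
        disorder_factor=d, participant_factor=p, xi=config.xi,
        sigma={k: (0.0 if config.model == "single" else v)
               for k, v in config.sigma_s.items()},
        scan_noise_sd=config.scan_noise_sd,
        seed=None if seed is None else int(np.random.SeedSequence(seed).entropy),
    )


def _edge_index_for(n_edges: int) -> EdgeIndex:
    """Smallest edge index with >= n_edges pairs, truncated to n_edges."""
    k = 2
    while k * (k - 1) // 2 < n_edges:
        k += 1
    full = build_edge_index(k)
    return EdgeIndex(n_nodes=k, pairs=full.pairs[:n_edges])


def generate_multisite(config: SimulationConfig | None = None, seed=None,
                       truth: GroundTruth | None = None):
    """Synthesize the multisite patient dataset.

    Returns ``(dataset, truth)``.  Each subject row is
    const + m_site + s_class,site + d_class + xi*z_subject + scan noise.
    """
    config = config or SimulationConfig()
    if not any(c > 0 for cc in config.site_classes.values() for c in cc.values()):
        raise ValueError("all per-site class counts are zero")
    rng = np.random.default_rng(None if seed is None else np.random.SeedSequence([1, seed]))
    if truth is None:
        truth = make_ground_truth(config, seed)
    n = config.n_edges
    rows, meta = [], []
    for site in sorted(config.site_classes):
        for cls in sorted(config.site_classes[site]):
            count = config.site_classes[site][cls]
            for i in range(count):
                base = truth.const + truth.measurement_bias[site]
                if cls in truth.sampling_bias and site in truth.sampling_bias[cls]:
                    base = base + truth.sampling_bias[cls][site]
                if cls in truth.disorder_factor:
                    base = base + truth.disorder_factor[cls]
                subj = rng.normal(0, truth.xi, n)
                noise = rng.normal(0, truth.scan_noise_sd, n)
                rows.append(base + subj + noise)
                pid = f"{site}_{cls}_{i:03d}"
                meta.append((pid, pid, site, cls, "multisite", "1"))
    meta = pd.DataFrame(meta, columns=["row_id", "participant_id", "site_id",
                                       "diagnosis", "dataset_kind", "session_id"])
    dataset = ConnectivityDataset(values=np.array(rows), meta=meta,
                                  edge_index=_edge_index_for(n))
    return dataset, truth


def generate_traveling(schedule: TravelingSchedule, truth: GroundTruth,
                       n_edges: int, seed=None) -> ConnectivityDataset:
    """Synthesize the traveling-subject dataset for a given ground truth.

    Each session row is const + m_site + p_participant + scan noise.
    """
    if schedule.total_sessions == 0:
        raise ValueError("schedule has no sessions")
    missing = set(schedule.participants) - set(truth.participant_factor)
    if missing:
        raise ValueError(f"participants absent from ground truth: {sorted(missing)}")
    rng = np.random.default_rng(None if seed is None else np.random.SeedSequence([2, seed]))
    rows, meta = [], []
    for pid in schedule.participants:
        for site in schedule.sites:
            for sess in range(int(schedule.counts.loc[pid, site])):
                noise = rng.normal(0, truth.scan_noise_sd, n_edges)
                rows.append(truth.const + truth.measurement_bias[site]
                            + truth.participant_factor[pid] + noise)
                meta.append((f"{pid}_{site}_s{sess + 1}", pid, site, "HC",
                             "traveling", str(sess + 1)))
    meta = pd.DataFrame(meta, columns=["row_id", "participant_id", "site_id",
                                       "diagnosis", "dataset_kind", "session_id"])
    return ConnectivityDataset(values=np.array(rows), meta=meta,
                               edge_index=_edge_index_for(n_edges))


def generate_study(config: SimulationConfig | None = None, seed=None):
    """Matched multisite + traveling datasets sharing one ground truth.

    Returns ``(multisite, traveling, truth)``.
    """
    config = config or SimulationConfig()
    truth = make_ground_truth(config, seed)
    multisite, _ = generate_multisite(config, seed=seed, truth=truth)
    traveling = generate_traveling(config.schedule, truth, config.n_edges,
                                   seed=seed)
    return multisite, traveling, truth


def generate_population_points(xi: float, sigma: float, site_sizes: dict[str, int],
                               n_edges: int, model: str = "different",
                               seed=None) -> pd.DataFrame:
    """Simulate per-site sampling-bias variance points.

    Subjects at site k are drawn N(beta_k, xi^2 I) per edge with
    beta_k ~ N(0, sigma^2 I) (``model="different"``) or beta_k = 0
    (``model="single"``); the point for site k is the across-edge variance of
    the site-mean vector, whose expectation is xi^2 / N_k + sigma^2.
    """
    if xi < 0 or sigma < 0:
        raise ValueError("xi and sigma must be non-negative")
    if any(n < 1 for n in site_sizes.values()):
        raise ValueError("every site needs at least one subject")
    rng = np.random.default_rng(seed)
    recs = []
    for site, n_k in sorted(site_sizes.items()):
        beta = rng.normal(0, sigma, n_edges) if model == "different" else np.zeros(n_edges)
        subjects = rng.normal(beta, xi, size=(n_k, n_edges))
        mean_vec = subjects.mean(axis=0)
        v = float(mean_vec.var())
        recs.append({"site_id": site, "n_subjects": n_k, "variance": v,
                     "x": np.log10(n_k), "y": np.log10(v) if v > 0 else -np.inf})
    return pd.DataFrame(recs)


def generate_roi_timeseries(n_nodes: int, t: int, tr_seconds: float = 2.5,
                            target_corr: np.ndarray | None = None,
                            motion_spike_prob: float = 0.05,
                            motion_spike_mm: float = 0.8,
                            seed=None):
    """Gaussian latent-factor ROI series plus motion traces with spikes.

    The population correlation matrix of the generated series equals
    ``target_corr`` (identity by default).  Motion is a smooth random walk
    with occasional translation spikes, so framewise displacement
    occasionally crosses the usual scrubbing threshold.  Returns
    ``(RoiTimeSeries, motion)``.
    """
    if t < 50:
        raise ValueError("need at least 50 volumes")
    rng = np.random.default_rng(seed)
    if target_corr is None:
        target_corr = np.eye(n_nodes)
    target_corr = np.asarray(target_corr, dtype=float)
    eigvals = np.linalg.eigvalsh(target_corr)
    if eigvals.min() < -1e-10:
        raise ValueError(
            "target correlation matrix is not positive semidefinite; project "
            "it to the nearest PSD matrix (clip negative eigenvalues) first"
        )
    chol = np.linalg.cholesky(target_corr + 1e-12 * np.eye(n_nodes))
    values = rng.standard_normal((t, n_nodes)) @ chol.T
    steps = rng.normal(0, 0.02, (t, 6))
    spikes = rng.random(t) < motion_spike_prob
    steps[spikes, 0] += motion_spike_mm * rng.choice([-1, 1], spikes.sum())
    motion = np.cumsum(steps, axis=0)
    return RoiTimeSeries(values=values, tr_seconds=tr_seconds), motion
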