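"""ROI time series to Fisher-z connectivity.

Implements the standard resting-state pipeline from extracted ROI signals
onward: framewise-displacement scrubbing, 36-parameter nuisance regression
(6 motion + global/white-matter/CSF signals, each with a temporal derivative,
plus squares of all 18), zero-phase first-order Butterworth band-pass
(0.01-0.08 Hz by default), and pairwise Pearson correlation with the Fisher z
transform.  Stage order is fixed: scrub -> regress -> band-pass -> correlate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import EdgeIndex, ValidationError

#: Fisher-z cap keeping degenerate r = +/-1 finite
MAX_Z = float(np.arctanh(1 - 1e-7))


@dataclass(frozen=True)
class RoiTimeSeries:
    """T-by-K BOLD matrix with its repetition time in seconds."""

    values: np.ndarray
    tr_seconds: float

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValidationError("time series needs >= 2 volumes")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")


def compute_fd(motion: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement in mm per volume.

    ``motion`` is T x 6: three translations (mm) and three rotations
    (radians).  FD[t] is the sum of absolute backward differences, rotations
    converted to arc length on a sphere of ``head_radius_mm`` (the radius is
    a convention the preprocessing literature leaves to the implementation;
    50 mm is the common choice).  FD[0] = 0 by definition.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValidationError("motion must be T x 6")
    if not np.isfinite(m).all():
        raise ValidationError("motion parameters contain non-finite values")
    d = np.abs(np.diff(m, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub_volumes(fd: np.ndarray, threshold_mm: float = 0.5):
    """Retained-volume mask: False exactly where FD exceeds the threshold.

    Returns ``(mask, n_removed)``.
    """
    if threshold_mm <= 0:
        raise ValidationError("FD threshold must be positive")
    fd = np.asarray(fd, dtype=float)
    mask = fd <= threshold_mm
    return mask, int((~mask).sum())


def build_nuisance_design(motion: np.ndarray, global_signal: np.ndarray,
                          wm_signal: np.ndarray, csf_signal: np.ndarray):
    """36-regressor nuisance design.

    9 base columns (6 motion + 3 tissue means), their backward-difference
    derivatives (first row zero), and the squares of all 18.  Returns
    ``(design, labels)`` with ``design`` T x 36.
    """
    motion = np.asarray(motion, dtype=float)
    tissues = [np.asarray(v, dtype=float).ravel()
               for v in (global_signal, wm_signal, csf_signal)]
    t = motion.shape[0]
    if motion.shape != (t, 6) or any(v.shape != (t,) for v in tissues):
        raise ValidationError("motion must be T x 6 and tissue signals length T")
    base = np.column_stack([motion] + tissues)
    deriv = np.vstack([np.zeros((1, 9)), np.diff(base, axis=0)])
    eighteen = np.hstack([base, deriv])
    design = np.hstack([eighteen, eighteen ** 2])
    names = [f"mot{i + 1}" for i in range(6)] + ["gs", "wm", "csf"]
    labels = names + [f"d_{n}" for n in names]
    labels += [f"{n}_sq" for n in labels[:18]]
    return design, labels


def regress_nuisance(series: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residualize each ROI series against the design plus an intercept."""
    y = np.asarray(series, dtype=float)
    x = np.asarray(design, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValidationError("series and design row counts differ")
    if y.shape[0] <= x.shape[1] + 1:
        raise ValidationError("need more volumes than regressors + intercept")
    xi = np.column_stack([np.ones(x.shape[0]), x])
    if np.linalg.matrix_rank(xi) < xi.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudo-inverse")
    beta, *_ = np.linalg.lstsq(xi, y, rcond=None)
    return y - xi @ beta


def bandpass_filter(series: np.ndarray, tr_seconds: float,
                    low_hz: float = 0.01, high_hz: float = 0.08) -> np.ndarray:
    """Zero-phase (forward-backward) first-order Butterworth band-pass."""
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 < low_hz < high_hz < nyquist:
        raise ValidationError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyquist:.4g})"
        )
    b, a = signal.butter(1, [low_hz, high_hz], btype="bandpass",
                         fs=1.0 / tr_seconds)
    return signal.filtfilt(b, a, np.asarray(series, dtype=float), axis=0)


def compute_connectivity(series: np.ndarray, edge_index: EdgeIndex,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Fisher-z Pearson correlations over retained volumes.

    Zero-variance ROIs make every incident edge NaN (flagged by a warning);
    perfect correlations are capped at :data:`MAX_Z`.
    """
    y = np.asarray(series, dtype=float)
    if mask is not None:
        y = y[np.asarray(mask, dtype=bool)]
    if y.shape[0] < 3:
        raise ValidationError("need >= 3 retained volumes")
    if y.shape[1] != edge_index.n_nodes:
        raise ValidationError("ROI count does not match edge index")
    sd = y.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(y, rowvar=False)
    if len(dead):
        warnings.warn(f"zero-variance ROI(s) {dead.tolist()}: edges set to NaN")
        r[dead, :] = np.nan
        r[:, dead] = np.nan
    vec = r[edge_index.pairs[:, 0], edge_index.pairs[:, 1]]
    return np.clip(np.arctanh(np.clip(vec, -1 + 1e-7, 1 - 1e-7)), -MAX_Z, MAX_Z)


def exclusion_check(removed_counts, n_sd: float = 3.0,
                    direction: str = "removed_high") -> np.ndarray:
    """Motion-based participant exclusion.

    Flags subjects whose removed-volume count exceeds ``mean + n_sd * SD``
    of the removed counts (``direction="removed_high"``, the default reading)
    or whose retained count falls below ``mean - n_sd * SD`` of the retained
    counts (``direction="retained_low"``).  Returns flagged indices.
    """
    c = np.asarray(removed_counts, dtype=float)
    if c.size < 2:
        raise ValidationError("need at least 2 subjects")
    if direction == "removed_high":
        return np.flatnonzero(c > c.mean() + n_sd * c.std())
    if direction == "retained_low":
        r = -c
        return np.flatnonzero(r < r.mean() - n_sd * r.std())
    raise ValidationError(f"unknown direction {direction!r}")


def timeseries_to_connectivity(ts: RoiTimeSeries, motion: np.ndarray,
                               edge_index: EdgeIndex,
                               fd_threshold_mm: float = 0.5,
                               head_radius_mm: float = 50.0,
                               low_hz: float = 0.01,
                               high_hz: float = 0.08):
    """Full pipeline for one session: scrub, regress, band-pass, correlate.

    Tissue signals are proxied by the ROI-mean signal when only ROI series
    are available (global mean used for all three compartments is a
    fixture-level simplification; pass real compartment means when you have
    them).  Returns ``(edge_vector, n_removed)``.
    """
    fd = compute_fd(motion, head_radius_mm)
    mask, n_removed = scrub_volumes(fd, fd_threshold_mm)
    y = ts.values[mask]
    m = np.asarray(motion)[mask]
    gs = y.mean(axis=1)
    design, _ = build_nuisance_design(m, gs, gs, gs)
    resid = regress_nuisance(y, design)
    filtered = bandpass_filter(resid, ts.tr_seconds, low_hz, high_hz)
    return compute_connectivity(filtered, edge_index), n_removed
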