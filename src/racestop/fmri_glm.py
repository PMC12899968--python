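"""Scaled-down event-related GLM on ROI time series, plus sphere-ROI geometry.

Each trial maps to one of eight event types — {food, neutral} x {gocor,
goincor, stopcor, stopincor} — with zero duration, time-locked to stimulus
onset. The design matrix convolves each event train with the canonical
double-gamma hemodynamic response function and its first-order temporal
derivative (via nilearn), appends six head-motion nuisance columns and an
intercept (8 x 2 + 6 + 1 = 23 columns), and contrasts are estimated by
ordinary least squares on an ROI-mean time series. The group stage
(flexible factorial: group x stimulus with covariates) delegates to
:mod:`racestop.group_stats`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from nilearn.glm.first_level import compute_regressor

from . import group_stats
from .group_stats import AncovaSpec, AncovaResult

EVENT_TYPES = (
    "food_gocor",
    "food_stopcor",
    "neutral_gocor",
    "neutral_stopcor",
    "food_goincor",
    "food_stopincor",
    "neutral_goincor",
    "neutral_stopincor",
)

CONTRAST_NAMES = ("stopcor_gt_gocor", "stopcor_gt_baseline", "stopincor_gt_gocor")

# Recorded for documentation of the original whole-brain thresholds; no
# voxelwise inference is implemented here.
VOXEL_P_UNCORRECTED = 0.005
CLUSTER_P_FWE = 0.05
MIN_CLUSTER_VOXELS = 20


class EventClassificationError(ValueError):
    pass


def events_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Map a trial log to a BIDS-events-style table (onset s, duration 0,
    one of the eight event types).

    Classification: go trials are gocor when a correct response was made,
    goincor otherwise (wrong key or omission); stop trials are stopcor
    when inhibited, stopincor when a response escaped.
    """
    if "onset_ms" not in trials:
        raise EventClassificationError("trial log lacks onset_ms timing column")
    rows = []
    for rec in trials.to_dict("records"):
        cond, ttype = rec["condition"], rec["trial_type"]
        responded = bool(rec["responded"])
        if ttype == "go":
            sub = "gocor" if (responded and bool(rec["correct"])) else "goincor"
        elif ttype == "stop":
            sub = "stopincor" if responded else "stopcor"
        else:
            raise EventClassificationError(f"unclassifiable trial: {rec}")
        name = f"{cond}_{sub}"
        if name not in EVENT_TYPES:
            raise EventClassificationError(f"unclassifiable trial: {rec}")
        rows.append(
            {"onset": rec["onset_ms"] / 1000.0, "duration": 0.0, "trial_type": name}
        )
    ev = pd.DataFrame(rows)
    if (ev["onset"].diff().dropna() <= 0).any():
        raise EventClassificationError("onsets must be strictly increasing")
    return ev


@dataclass
class DesignMatrixBundle:
    """First-level design: 8 event types x {HRF, derivative} + 6 motion
    nuisance columns + intercept, sampled at scan times."""

    matrix: pd.DataFrame
    tr: float
    n_scans: int

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)


def build_design_matrix(
    events: pd.DataFrame,
    motion: np.ndarray,
    tr: float = 2.0,
    n_scans: int | None = None,
) -> DesignMatrixBundle:
    """Convolve zero-duration event trains with the canonical (SPM
    double-gamma) HRF and its temporal derivative, sampled at scan onsets.

    Event types with no occurrences keep an all-zero column (with a
    warning) so contrast weights stay aligned across runs.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (n_scans, 6), got {motion.shape}")
    if n_scans is None:
        n_scans = motion.shape[0]
    if motion.shape[0] != n_scans:
        raise ValueError("motion rows must equal n_scans")
    if len(events) and events["onset"].max() >= n_scans * tr:
        raise ValueError("event onset beyond the end of the run")

    frame_times = np.arange(n_scans) * tr
    cols: dict[str, np.ndarray] = {}
    for etype in EVENT_TYPES:
        sel = events[events["trial_type"] == etype] if len(events) else events
        if len(sel) == 0:
            warnings.warn(
                f"event type {etype!r} has no occurrences; keeping zero columns",
                stacklevel=2,
            )
            cols[etype] = np.zeros(n_scans)
            cols[f"{etype}_derivative"] = np.zeros(n_scans)
            continue
        exp_condition = (
            sel["onset"].to_numpy(),
            np.zeros(len(sel)),
            np.ones(len(sel)),
        )
        reg, _ = compute_regressor(
            exp_condition, hrf_model="spm + derivative", frame_times=frame_times
        )
        cols[etype] = reg[:, 0]
        cols[f"{etype}_derivative"] = reg[:, 1]
    for j in range(6):
        cols[f"motion_{j + 1}"] = motion[:, j]
    cols["intercept"] = np.ones(n_scans)
    matrix = pd.DataFrame(cols)
    return DesignMatrixBundle(matrix=matrix, tr=tr, n_scans=n_scans)


@dataclass
class ContrastSpec:
    """Named weight vector over design columns. Derivative and nuisance
    columns carry zero weight; between-condition contrasts sum to zero
    over the task HRF columns, while stopcor > baseline weights the
    stopcor HRF column(s) alone."""

    name: str
    weights: pd.Series


def contrast_spec(
    name: str, bundle: DesignMatrixBundle, condition: str | None = None
) -> ContrastSpec:
    """Build one of the three named contrasts, optionally restricted to a
    single stimulus condition (needed for the per-condition values the
    group model consumes)."""
    if name not in CONTRAST_NAMES:
        raise ValueError(f"unknown contrast {name!r}; choose from {CONTRAST_NAMES}")
    conds = (condition,) if condition else ("food", "neutral")
    w = pd.Series(0.0, index=bundle.columns)
    share = 1.0 / len(conds)
    for c in conds:
        if name == "stopcor_gt_gocor":
            w[f"{c}_stopcor"] += share
            w[f"{c}_gocor"] -= share
        elif name == "stopcor_gt_baseline":
            w[f"{c}_stopcor"] += share
        elif name == "stopincor_gt_gocor":
            w[f"{c}_stopincor"] += share
            w[f"{c}_gocor"] -= share
    return ContrastSpec(name=name, weights=w)


@dataclass
class ContrastEstimate:
    value: float
    se: float
    dof: int
    betas: pd.Series


def fit_and_contrast(
    ts: np.ndarray, bundle: DesignMatrixBundle, contrast: ContrastSpec
) -> ContrastEstimate:
    """OLS fit of the ROI time series on the design; contrast value is
    w'beta with its standard error from the residual variance."""
    y = np.asarray(ts, dtype=float)
    X = bundle.matrix.to_numpy()
    if y.shape[0] != X.shape[0]:
        raise ValueError(f"time series length {y.shape[0]} != n_scans {X.shape[0]}")
    # zero columns (empty event types) are excluded from estimation but kept
    # in the weight alignment; a nonzero weight on an empty column is an error
    nz = X.any(axis=0)
    w = contrast.weights.to_numpy()
    if np.any(w[~nz] != 0):
        empty = [c for c, keep, wt in zip(bundle.columns, nz, w) if not keep and wt]
        raise ValueError(f"contrast weights nonzero on empty columns: {empty}")
    Xe, we = X[:, nz], w[nz]
    rank = np.linalg.matrix_rank(Xe)
    if rank < Xe.shape[1]:
        names = [c for c, keep in zip(bundle.columns, nz) if keep]
        bad = [
            names[j]
            for j in range(Xe.shape[1])
            if np.linalg.matrix_rank(np.delete(Xe, j, axis=1)) == rank
        ]
        raise group_stats.RankDeficientError(f"collinear design columns: {bad}")
    XtX_inv = np.linalg.inv(Xe.T @ Xe)
    beta = XtX_inv @ Xe.T @ y
    resid = y - Xe @ beta
    dof = len(y) - Xe.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    value = float(we @ beta)
    se = float(np.sqrt(sigma2 * we @ XtX_inv @ we))
    betas = pd.Series(0.0, index=bundle.columns)
    betas[np.asarray(bundle.columns)[nz]] = beta
    return ContrastEstimate(value=value, se=se, dof=dof, betas=betas)


def flexible_factorial(
    contrast_values: pd.DataFrame,
    participants: pd.DataFrame,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[list[AncovaResult], pd.DataFrame]:
    """Group-level model on per-participant, per-stimulus contrast values:
    group (between) x stimulus type (within) with covariates, delegated to
    the repeated-measures ANCOVA, plus a simple-effects decomposition of
    the interaction (group comparison per stimulus, stimulus comparison
    per group, Bonferroni over the four tests).

    ``contrast_values`` needs participant_id, condition, value columns.
    """
    covs = DEFAULT_GROUP_COVARIATES if covariates is None else covariates
    long = contrast_values.merge(
        participants[["participant_id", "group"] + covs], on="participant_id"
    )
    spec = AncovaSpec(dv="value", covariates=list(covs), alpha=alpha)
    results, posthoc = group_stats.rm_ancova(long, spec, return_posthoc=True)

    # simple effects: add per-group paired stimulus comparisons
    rows = [dict(r, kind="group_within_stimulus") for r in posthoc.to_dict("records")]
    wide = contrast_values.pivot_table(
        index="participant_id", columns="condition", values="value", aggfunc="first"
    ).join(participants.set_index("participant_id")["group"])
    levels = [c for c in wide.columns if c != "group"]
    if len(levels) == 2:
        for grp, sub in wide.groupby("group"):
            d = (sub[levels[1]] - sub[levels[0]]).dropna()
            t, p = stats.ttest_1samp(d, 0.0)
            rows.append(
                {
                    "level": grp,
                    "comparison": f"{levels[1]} - {levels[0]}",
                    "mean_diff": float(d.mean()),
                    "F": float(t**2),
                    "p_raw": float(p),
                    "p_bonferroni": group_stats.bonferroni(float(p), 4),
                    "kind": "stimulus_within_group",
                }
            )
    simple = pd.DataFrame(rows)
    return results, simple


DEFAULT_GROUP_COVARIATES = ["age", "sex", "bmi", "bdi_ii", "composite_appetite"]


# ---------------------------------------------------------------------------
# Sphere ROI geometry


@dataclass
class SphereRoi:
    """Sphere ROI on an axis-aligned voxel grid: member voxels are grid
    points whose centers lie within (inclusive) the radius of the snapped
    center."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    voxel_size_mm: float
    voxels: np.ndarray = field(repr=False)  # (n, 3) voxel-center mm coords

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def sphere_roi(
    center: tuple[float, float, float],
    radius: float = 8.0,
    voxel_size: float = 3.0,
) -> SphereRoi:
    """Enumerate sphere-member voxels on a voxel_size-spaced grid.

    The center is snapped to the nearest grid point; membership uses voxel
    centers with an inclusive boundary. The canonical inferior-frontal ROI
    (8 mm sphere at MNI (51, 16, 18) on a 3 mm grid) has 81 voxels.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    snapped = np.round(np.asarray(center, dtype=float) / voxel_size) * voxel_size
    reach = int(np.floor(radius / voxel_size))
    offsets = np.arange(-reach, reach + 1) * voxel_size
    pts = []
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                if dx * dx + dy * dy + dz * dz <= radius**2 + 1e-9:
                    pts.append(snapped + np.array([dx, dy, dz]))
    if not pts:
        raise ValueError("empty ROI: radius too small for the voxel grid")
    return SphereRoi(
        center_mm=tuple(snapped),
        radius_mm=float(radius),
        voxel_size_mm=float(voxel_size),
        voxels=np.asarray(pts),
    )


def roi_mean_signal(voxel_values: np.ndarray) -> np.ndarray:
    """Mean over member voxels; accepts (n_voxels,) or (n_scans, n_voxels)."""
    v = np.asarray(voxel_values, dtype=float)
    return v.mean(axis=-1)
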