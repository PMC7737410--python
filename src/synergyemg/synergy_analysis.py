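"""Posture-robust synergy modules, cosine tuning and preferred directions.

Synergy vectors extracted from the Elbow-0, Elbow-90 and Total datasets
are clustered into modules by their mutual scalar product (normalized
inner product) with UPGMA average linkage, merging only while the
average inter-cluster similarity exceeds 0.75. Each synergy's direction
tuning is fitted as m(theta) = a0 + a1 cos(theta) + a2 sin(theta); the
preferred direction is atan2(a2, a1) and the tuning weight
W = sqrt(a1^2 + a2^2) measures modulation depth. Elbow-90 preferred
directions are compensated by a 90 degree clockwise shift before
within-module consistency (mean absolute circular deviation) is
computed. Modules are typed *parallel* (footprint elongated along the
forearm, the superficial signature) or *local* (spread around the
cross-section, the deep signature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from synergyemg.emg_synth import Montage
from synergyemg.synergy_nmf import SynergySet, hals_nmf

logger = logging.getLogger(__name__)

__all__ = [
    "TuningResult",
    "ModuleGrouping",
    "scalar_product",
    "sp_matrix",
    "upgma_cluster",
    "condition_synergies",
    "direction_means",
    "cosine_tune",
    "pd_error",
    "classify_module_type",
    "compare_tuning_weights",
]

DIRECTION_ANGLES_DEG = np.arange(8) * 45.0


@dataclass
class TuningResult:
    """Cosine-tuning fit of one synergy or channel."""

    a0: float
    a1: float
    a2: float
    pd_deg: float
    w: float
    r_squared: float
    defined: bool  # PD meaningful only when W exceeds the floor


@dataclass
class ModuleGrouping:
    members: list  # (condition, synergy index) per clustered vector
    sp_matrix: np.ndarray
    assignments: np.ndarray
    threshold: float = 0.75

    @property
    def n_modules(self) -> int:
        return int(self.assignments.max()) + 1 if self.assignments.size else 0

    def module_members(self, module_id: int) -> list:
        return [m for m, a in zip(self.members, self.assignments)
                if a == module_id]


def scalar_product(e_i: np.ndarray, e_j: np.ndarray) -> float:
    """Normalized inner product of two non-negative synergy vectors,
    in [0, 1]."""
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    if e_i.shape != e_j.shape:
        raise ValueError("vectors must have equal length")
    if np.min(e_i) < 0 or np.min(e_j) < 0:
        raise ValueError("synergy vectors must be non-negative")
    ni, nj = np.linalg.norm(e_i), np.linalg.norm(e_j)
    if ni == 0 or nj == 0:
        raise ValueError("zero vector has no direction")
    return float(e_i @ e_j / (ni * nj))


def sp_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise scalar products of stacked synergy vectors (k x n)."""
    V = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vector has no direction")
    G = (V / norms[:, None]) @ (V / norms[:, None]).T
    return np.clip(G, 0.0, 1.0)


def upgma_cluster(sp: np.ndarray, threshold: float = 0.75) -> np.ndarray:
    """Flat UPGMA clustering of a similarity matrix.

    Average-linkage agglomeration on dissimilarity 1 - SP, merging the
    closest pair (lowest-index pair on ties) while the average
    inter-cluster similarity remains strictly above ``threshold``.
    Returns integer module assignments ordered by first appearance.
    """
    sp = np.asarray(sp, dtype=float)
    if sp.ndim != 2 or sp.shape[0] != sp.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(sp, sp.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    k = sp.shape[0]
    D = 1.0 - sp
    clusters: list[list[int]] = [[i] for i in range(k)]
    dist = D.copy()
    np.fill_diagonal(dist, np.inf)
    cutoff = 1.0 - threshold
    while len(clusters) > 1:
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if i > j:
            i, j = j, i
        if not dist[i, j] < cutoff:  # merge only while SP > threshold
            break
        ni, nj = len(clusters[i]), len(clusters[j])
        new_row = (ni * dist[i] + nj * dist[j]) / (ni + nj)
        dist[i] = new_row
        dist[:, i] = new_row
        dist[i, i] = np.inf
        clusters[i] = clusters[i] + clusters[j]
        dist = np.delete(np.delete(dist, j, axis=0), j, axis=1)
        del clusters[j]
    assignments = np.empty(k, dtype=int)
    for mod_id, members in enumerate(clusters):
        assignments[members] = mod_id
    # renumber by first appearance for determinism
    order = {}
    out = np.empty(k, dtype=int)
    for idx, a in enumerate(assignments):
        if a not in order:
            order[a] = len(order)
        out[idx] = order[a]
    return out


def condition_synergies(
    E: np.ndarray,
    sample_mask: np.ndarray,
    rank: int,
    seed: int = 0,
    n_seeds: int = 5,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> SynergySet:
    """Factorize one condition's rows of the envelope matrix at a fixed
    rank (the rank selected on the Total dataset), keeping the best of
    ``n_seeds`` restarts."""
    rows = np.asarray(sample_mask, dtype=bool)
    if not rows.any():
        raise ValueError("condition selects no samples")
    sub = E[rows]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_seeds):
        cand = hals_nmf(sub, rank, seed=int(rng.integers(2**31)),
                        max_iter=max_iter, tol=tol)
        if best is None or cand.vaf > best.vaf:
            best = cand
    return best


def direction_means(values: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Mean per-trial amplitude for each of the 8 directions (1..8).

    ``values`` holds one scalar amplitude per trial (typically the mean
    envelope or activation over the trial window).
    """
    values = np.asarray(values, dtype=float)
    direction = np.asarray(direction)
    out = np.empty(8)
    for d in range(1, 9):
        sel = direction == d
        if not sel.any():
            raise ValueError(f"no trials for direction {d}")
        out[d - 1] = values[sel].mean()
    return out


def cosine_tune(
    m: np.ndarray,
    theta_deg: np.ndarray | None = None,
    normalize: str | None = "max",
    w_floor: float = 1e-3,
) -> TuningResult:
    """Fit m(theta) = a0 + a1 cos(theta) + a2 sin(theta) by OLS.

    On 8 equally spaced directions the design is orthogonal, so the
    coefficients equal the discrete Fourier terms and the fit is exact
    for any true cosine tuning. ``normalize='max'`` divides m by its
    maximum first, making W a dimensionless modulation ratio
    (``'mean'`` and ``None`` are alternatives). PD is undefined when W
    falls below ``w_floor``.
    """
    m = np.asarray(m, dtype=float)
    theta_deg = DIRECTION_ANGLES_DEG if theta_deg is None else \
        np.asarray(theta_deg, dtype=float)
    if np.unique(theta_deg).size < 3:
        raise ValueError("need at least 3 distinct angles")
    if normalize == "max":
        peak = m.max()
        if peak <= 0:
            raise ValueError("cannot normalize a non-positive tuning curve")
        m = m / peak
    elif normalize == "mean":
        mu = m.mean()
        if mu <= 0:
            raise ValueError("cannot normalize a non-positive tuning curve")
        m = m / mu
    elif normalize is not None:
        raise ValueError(f"unknown normalization {normalize!r}")
    th = np.deg2rad(theta_deg)
    X = np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])
    coef, *_ = np.linalg.lstsq(X, m, rcond=None)
    a0, a1, a2 = (float(c) for c in coef)
    resid = m - X @ coef
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    w = float(np.hypot(a1, a2))
    defined = w > w_floor
    pd = float(np.rad2deg(np.arctan2(a2, a1)) % 360.0) if defined else np.nan
    return TuningResult(a0=a0, a1=a1, a2=a2, pd_deg=pd, w=w,
                        r_squared=r2, defined=defined)


def _wrap_deg(a: np.ndarray | float) -> np.ndarray:
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.rad2deg(np.arctan2(np.mean(np.sin(a)),
                                       np.mean(np.cos(a)))) % 360.0)


def pd_error(
    pds_deg: np.ndarray,
    postures: np.ndarray,
    compensation_deg: float = -90.0,
) -> float:
    """Within-module preferred-direction consistency.

    Elbow-90 PDs are compensated by a 90 degree clockwise shift (the
    sign is configurable); the result is the mean absolute circular
    deviation of the compensated PDs from their circular mean.
    """
    pds = np.asarray(pds_deg, dtype=float)
    postures = np.asarray(postures, dtype=float)
    ok = np.isfinite(pds)
    if not ok.all():
        logger.warning("excluding %d undefined PDs", int((~ok).sum()))
    pds, postures = pds[ok], postures[ok]
    if pds.size < 2:
        return np.nan
    comp = pds + np.where(postures != 0, compensation_deg, 0.0)
    mu = circular_mean_deg(comp)
    dev = np.abs(_wrap_deg(comp - mu))
    return float(dev.mean())


def classify_module_type(
    channel_weights: np.ndarray,
    montage: Montage,
) -> str:
    """Type a module footprint as parallel (along the forearm) or local
    (around the cross-section).

    Compares the weight-weighted standard deviation of the axial
    electrode positions (normalized by the grid's axial extent) with
    that of the circumferential positions (deviations taken around the
    weighted circular mean, normalized by 360 degrees). Greater-or-equal
    axial spread means parallel (the tie is broken as parallel).
    """
    w = np.asarray(channel_weights, dtype=float)
    grid = montage.grid_mask()
    if w.size == montage.n_channels:
        w = w[grid]
    ax = montage.axial_mm[grid]
    circ = montage.circ_deg[grid]
    if w.size != ax.size:
        raise ValueError("weights do not match the montage grid")
    if not np.any(w > 0):
        raise ValueError("all-zero module weights")
    w = w / w.sum()
    ax_extent = ax.max() - ax.min()
    mu_ax = float(w @ ax)
    sd_ax = np.sqrt(float(w @ (ax - mu_ax) ** 2)) / ax_extent
    rad = np.deg2rad(circ)
    mu_circ = np.rad2deg(np.arctan2(w @ np.sin(rad), w @ np.cos(rad)))
    dev = _wrap_deg(circ - mu_circ)
    sd_circ = np.sqrt(float(w @ dev**2)) / 360.0
    if np.isclose(sd_ax, sd_circ):
        logger.info("axial and circumferential spreads tie; typing as "
                    "parallel")
        return "parallel"
    return "parallel" if sd_ax >= sd_circ else "local"


def compare_tuning_weights(group_a: np.ndarray, group_b: np.ndarray) -> dict:
    """Welch two-sample t-test between two sets of tuning weights."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "n_a": int(a.size),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "n_b": int(b.size),
        "t": float(t_stat), "p": float(p),
    }
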