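"""Muscle-synergy extraction: E = TM by HALS non-negative factorization.

Signals (EMG channels or retained ICs) are converted to pseudo-joint-
torque envelopes (mean-activation normalization, rectification, 2nd
order 5 Hz Butterworth low-pass), factorized with hierarchical
alternating least squares, and the synergy count is chosen as the
smallest rank with Variance Accounted For above 0.9 whose VAF-vs-rank
plateau is linear (regression MSE below 1e-4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "EnvelopeMatrix",
    "SynergySet",
    "RankSelection",
    "to_pseudo_torque",
    "hals_nmf",
    "vaf",
    "select_rank",
]

_EPS = 1e-12


@dataclass
class EnvelopeMatrix:
    """Non-negative pseudo-joint-torque envelopes, time x signals."""

    E: np.ndarray
    fs: float
    signal_kind: str = "EMG"  # EMG | IC
    norm_consts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.min(self.E) < 0:
            raise ValueError("envelope matrix must be non-negative")


@dataclass
class SynergySet:
    """One NMF solution: activations T (time x s), synergy vectors M
    (s x signals, rows scaled to unit maximum with the scale absorbed
    into T)."""

    T: np.ndarray
    M: np.ndarray
    rank: int
    vaf: float
    converged: bool
    objective_trace: np.ndarray


@dataclass
class RankSelection:
    selected_rank: int
    ranks: np.ndarray
    vaf_curve: np.ndarray
    slope_mse_curve: np.ndarray
    best: SynergySet
    per_rank: dict = field(default_factory=dict)


def to_pseudo_torque(signals: np.ndarray, fs: float,
                     cutoff_hz: float = 5.0,
                     signal_kind: str = "EMG") -> EnvelopeMatrix:
    """Convert raw signals (signals x samples) to smooth activation
    envelopes.

    Per signal: divide by its mean rectified amplitude over the whole
    recording, rectify, zero-phase 2nd-order Butterworth low-pass at
    5 Hz, and clip the tiny negative filter ringing to zero.
    """
    if fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate too low for the envelope filter")
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    norm = np.mean(np.abs(signals), axis=-1)
    if np.any(norm <= 0):
        bad = np.nonzero(norm <= 0)[0]
        raise ValueError(f"zero-amplitude signal(s) {bad.tolist()}: cannot "
                         "normalize by mean activation")
    rect = np.abs(signals) / norm[:, None]
    sos = signal.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, rect, axis=-1)
    env = np.clip(env, 0.0, None)
    return EnvelopeMatrix(E=env.T, fs=fs, signal_kind=signal_kind,
                          norm_consts=norm)


def _objective(E_sq: float, T: np.ndarray, EMt: np.ndarray,
               MMt: np.ndarray) -> float:
    """||E - TM||_F^2 via the trace identity (EMt = E @ M.T must match
    the current M)."""
    return E_sq - 2.0 * float(np.einsum("ij,ij->", T, EMt)) \
        + float(np.einsum("ij,ij->", T.T @ T, MMt))


def hals_nmf(
    E: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> SynergySet:
    """Factorize a non-negative matrix E (m x n) as T (m x s) M (s x n).

    Hierarchical alternating least squares: each column of T and row of
    M is updated by its exact non-negative least-squares minimizer given
    the others, so the Euclidean objective is non-increasing across
    iterations. Stops when the relative objective change drops below
    ``tol``. Rows of M that collapse to zero are re-initialized once and
    then allowed to die.
    """
    E = np.asarray(E, dtype=float)
    if np.min(E) < 0:
        raise ValueError("E must be non-negative")
    m, n = E.shape
    if not 1 <= rank <= min(m, n):
        raise ValueError(f"rank {rank} outside [1, {min(m, n)}]")
    rng = np.random.default_rng(seed)
    if init is None:
        scale = np.sqrt(max(E.mean(), _EPS) / rank)
        T = rng.uniform(0, 1, (m, rank)) * scale
        M = rng.uniform(0, 1, (rank, n)) * scale
    else:
        T, M = (np.ascontiguousarray(a, dtype=float) for a in init)

    E_sq = float(np.einsum("ij,ij->", E, E))
    trace = []
    reinit_used = np.zeros(rank, dtype=bool)
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        # update rows of M given T
        A = T.T @ E
        B = T.T @ T
        for j in range(rank):
            if B[j, j] < _EPS:
                continue
            M[j] = np.maximum(0.0, M[j] + (A[j] - B[j] @ M) / B[j, j])
            if not M[j].any():
                if reinit_used[j]:
                    continue
                reinit_used[j] = True
                M[j] = rng.uniform(0, 1, n) * np.sqrt(max(E.mean(), _EPS) / rank)
                # re-apply the exact update so the objective stays monotone
                M[j] = np.maximum(0.0, M[j] + (A[j] - B[j] @ M) / B[j, j])
        # update columns of T given M
        C = E @ M.T
        D = M @ M.T
        for j in range(rank):
            if D[j, j] < _EPS:
                continue
            T[:, j] = np.maximum(0.0, T[:, j] + (C[:, j] - T @ D[:, j]) / D[j, j])
        obj = _objective(E_sq, T, C, D)
        trace.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(prev, _EPS):
            converged = True
            break
        prev = obj

    # unit-maximum synergy rows, scale absorbed into activations
    peaks = M.max(axis=1)
    live = peaks > 0
    M[live] /= peaks[live, None]
    T[:, live] *= peaks[live][None, :]
    v = vaf(E, T, M)
    return SynergySet(T=T, M=M, rank=rank, vaf=v, converged=converged,
                      objective_trace=np.asarray(trace))


def vaf(E: np.ndarray, T: np.ndarray, M: np.ndarray,
        per_signal: bool = False) -> float:
    """Uncentered Variance Accounted For of the reconstruction TM.

    Global form: 1 - ||E - TM||_F^2 / ||E||_F^2. Per-signal form:
    the same ratio computed per column (signal) and averaged — this
    penalizes signals whose own envelope structure is left unmodelled
    even when their share of the total energy is small.
    """
    resid = E - T @ M
    if per_signal:
        denom = np.einsum("ij,ij->j", E, E)
        if np.any(denom == 0):
            raise ValueError("VAF undefined for an all-zero signal")
        return float(np.mean(1.0 - np.einsum("ij,ij->j", resid, resid)
                             / denom))
    denom = float(np.einsum("ij,ij->", E, E))
    if denom == 0:
        raise ValueError("VAF undefined for an all-zero matrix")
    return 1.0 - float(np.einsum("ij,ij->", resid, resid)) / denom


def _slope_mse(ranks: np.ndarray, vafs: np.ndarray) -> float:
    """MSE of the ordinary-least-squares line through (rank, VAF)."""
    if ranks.size < 2:
        return 0.0
    coef = np.polyfit(ranks, vafs, 1)
    resid = vafs - np.polyval(coef, ranks)
    return float(np.mean(resid**2))


def select_rank(
    E: np.ndarray,
    s_min: int = 3,
    s_max: int = 15,
    n_seeds: int = 5,
    seed: int = 0,
    vaf_min: float = 0.9,
    slope_mse_max: float = 1e-4,
    max_iter: int = 300,
    tol: float = 1e-6,
    vaf_mode: str = "global",
) -> RankSelection:
    """Choose the synergy count by the dual VAF criterion.

    For each candidate rank the best of ``n_seeds`` random restarts plus
    a warm start grown from the best lower-rank solution is kept (the
    warm start makes the global VAF curve non-decreasing by
    construction). The selected rank is the smallest s with
    VAF(s) > ``vaf_min`` whose plateau {(r, VAF(r)) : r >= s} fits a
    line with MSE below ``slope_mse_max``. ``vaf_mode`` selects the VAF
    form used for the criterion: ``"global"`` (matrix-wide ratio) or
    ``"per_signal"`` (per-signal ratios averaged; sensitive to signals
    whose own structure stays unmodelled).
    """
    if vaf_mode not in ("global", "per_signal"):
        raise ValueError(f"unknown vaf_mode {vaf_mode!r}")
    E = np.asarray(E, dtype=float)
    s_max = min(s_max, min(E.shape))
    if s_min > s_max:
        raise ValueError("s_min exceeds the largest admissible rank")
    ranks = np.arange(s_min, s_max + 1)
    rng = np.random.default_rng(seed)
    best_sets: dict[int, SynergySet] = {}
    prev_best: SynergySet | None = None
    for s in ranks:
        candidates = []
        for _ in range(n_seeds):
            candidates.append(hals_nmf(E, s, seed=int(rng.integers(2**31)),
                                       max_iter=max_iter, tol=tol))
        if prev_best is not None:
            T0 = np.column_stack([
                prev_best.T,
                rng.uniform(0, 1, E.shape[0]) * np.sqrt(E.mean() / s)])
            M0 = np.vstack([
                prev_best.M,
                rng.uniform(0, 1, E.shape[1]) * np.sqrt(E.mean() / s)])
            candidates.append(hals_nmf(E, s, seed=int(rng.integers(2**31)),
                                       max_iter=max_iter, tol=tol,
                                       init=(T0, M0)))
        def crit_vaf(c):
            if vaf_mode == "per_signal":
                return vaf(E, c.T, c.M, per_signal=True)
            return c.vaf

        best = max(candidates, key=crit_vaf)
        best_sets[int(s)] = best
        prev_best = best

    vaf_curve = np.array([
        vaf(E, best_sets[int(s)].T, best_sets[int(s)].M,
            per_signal=(vaf_mode == "per_signal"))
        for s in ranks])
    slope_curve = np.array([
        _slope_mse(ranks[i:].astype(float), vaf_curve[i:])
        for i in range(ranks.size)
    ])
    ok = (vaf_curve > vaf_min) & (slope_curve < slope_mse_max)
    if not ok.any():
        lines = [
            f"  s={s}: VAF={v:.4f} ({'ok' if v > vaf_min else 'fail'}), "
            f"slope-MSE={e:.2e} ({'ok' if e < slope_mse_max else 'fail'})"
            for s, v, e in zip(ranks, vaf_curve, slope_curve)
        ]
        raise ValueError("no rank satisfies the dual VAF criterion:\n"
                         + "\n".join(lines))
    sel = int(ranks[np.argmax(ok)])
    logger.info("selected rank %d (VAF %.4f)", sel, best_sets[sel].vaf)
    return RankSelection(
        selected_rank=sel,
        ranks=ranks,
        vaf_curve=vaf_curve,
        slope_mse_curve=slope_curve,
        best=best_sets[sel],
        per_rank=best_sets,
    )
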