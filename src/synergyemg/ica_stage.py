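"""Blind source separation of multi-channel EMG (X = AS).

A non-Gaussianity-maximizing ICA (symmetric FastICA, log-cosh contrast)
decomposes the ground-rejected EMG into independent components; ICs with
white-noise characteristics (near-flat power spectrum and no slow
envelope structure) are excluded before synergy extraction and
classification. The unmixing can be fitted on a temporal subsample and
applied to the full recording.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

__all__ = [
    "Decomposition",
    "ICAConvergenceError",
    "whiten",
    "fit_ica",
    "component_metrics",
    "select_components",
]


class ICAConvergenceError(RuntimeError):
    """FastICA failed to converge after all restarts; carries the
    per-restart iteration counts in ``diagnostics``."""

    def __init__(self, msg: str, diagnostics: dict | None = None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


@dataclass
class Decomposition:
    """ICA result: X ~= A @ S + mean, S = W_u @ (X - mean)."""

    A: np.ndarray  # channels x components mixing
    W_u: np.ndarray  # components x channels unmixing
    S: np.ndarray  # components x samples source time courses
    mean: np.ndarray  # per-channel mean removed before unmixing
    retained_mask: np.ndarray | None = None
    metrics: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.A.shape[1]

    def retained_sources(self) -> np.ndarray:
        if self.retained_mask is None:
            return self.S
        return self.S[self.retained_mask]


def numerical_rank(X: np.ndarray, tol_factor: float = 1e-8) -> int:
    """Rank of the channel covariance with tolerance 1e-8 x largest
    singular value."""
    Xc = X - X.mean(axis=-1, keepdims=True)
    s = np.linalg.svd(Xc, compute_uv=False)
    return int(np.sum(s > tol_factor * s[0]))


def suggest_n_components(X: np.ndarray, eig_factor: float = 1.5,
                         cap: int | None = None) -> int:
    """Signal-subspace dimension: covariance eigenvalues above
    ``eig_factor`` times the median eigenvalue (the white-noise floor).

    With broadband sensor noise the data are numerically full rank, so
    the component count is set by the knee of the eigenspectrum rather
    than the rank; the number of ICs then emerges from the data.
    """
    Xc = X - X.mean(axis=-1, keepdims=True)
    ev = np.linalg.eigvalsh((Xc @ Xc.T) / (X.shape[-1] - 1))
    floor = np.median(ev)
    n = int(np.sum(ev > eig_factor * floor))
    n = max(n, 2)
    if cap is not None:
        n = min(n, cap)
    return n


def whiten(X: np.ndarray, rank_tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Sphere the data: returns (Z, K) with Z = K @ (X - mean) and
    cov(Z) = I. Rank-deficient input is reduced to its numerical rank
    rather than rejected."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    Xc = X - X.mean(axis=-1, keepdims=True)
    n = X.shape[-1]
    cov = (Xc @ Xc.T) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rank_tol * evals[0]
    K = (evecs[:, keep] / np.sqrt(evals[keep])).T
    return K @ Xc, K


def _fix_signs(A: np.ndarray, W_u: np.ndarray, S: np.ndarray) -> None:
    """Deterministic sign convention: the largest-|weight| mixing entry
    of each component is positive."""
    for k in range(A.shape[1]):
        j = int(np.argmax(np.abs(A[:, k])))
        if A[j, k] < 0:
            A[:, k] *= -1
            W_u[k] *= -1
            S[k] *= -1


def fit_ica(
    X: np.ndarray,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_restarts: int = 4,
    sample_stride: int = 1,
) -> Decomposition:
    """Symmetric FastICA with log-cosh contrast on channels x samples.

    Restarts with an incremented seed on non-convergence and raises
    :class:`ICAConvergenceError` with iteration diagnostics if all
    restarts fail. ``sample_stride`` fits the unmixing on every k-th
    sample (the sources are then computed for all samples), which keeps
    long recordings tractable without changing the model.
    """
    X = np.asarray(X, dtype=float)
    rank = numerical_rank(X)
    if rank < X.shape[0]:
        logger.warning("rank-deficient input (%d < %d channels); "
                       "reducing component count", rank, X.shape[0])
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds numerical "
                         f"rank {rank}")
    X_fit = X[:, ::sample_stride] if sample_stride > 1 else X
    diagnostics: dict[int, int] = {}
    for attempt in range(n_restarts):
        ica = FastICA(
            n_components=n_components,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica.fit(X_fit.T)
        diagnostics[seed + attempt] = int(ica.n_iter_)
        converged = not any(issubclass(w.category, ConvergenceWarning)
                            for w in caught)
        if converged:
            break
    else:
        raise ICAConvergenceError(
            f"FastICA did not converge in {n_restarts} restarts "
            f"(max_iter={max_iter}, tol={tol})", diagnostics)

    W_u = ica.components_  # components x channels, includes whitening
    mean = ica.mean_
    A = ica.mixing_
    S = W_u @ (X - mean[:, None])
    _fix_signs(A, W_u, S)
    return Decomposition(A=A, W_u=W_u, S=S, mean=mean)


def spectral_flatness(x: np.ndarray, fs: float) -> float:
    """Wiener entropy of the PSD: geometric / arithmetic mean. Near 1
    for white noise, near 0 for band-limited or line signals."""
    f, psd = sps.welch(x, fs=fs, nperseg=min(1024, x.size))
    psd = psd[1:]  # drop DC bin
    psd = np.maximum(psd, 1e-300)
    return float(np.exp(np.mean(np.log(psd))) / np.mean(psd))


def envelope_autocorr(x: np.ndarray, fs: float, lag_s: float = 0.02) -> float:
    """Autocorrelation of the rectified signal at a 20 ms lag.

    White noise has none; envelope-modulated activity keeps its slow
    amplitude structure across the lag.
    """
    lag = max(1, int(round(lag_s * fs)))
    r = np.abs(x)
    a, b = r[:-lag], r[lag:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def component_metrics(decomp: Decomposition, fs: float) -> dict:
    flat = np.array([spectral_flatness(s, fs) for s in decomp.S])
    ac = np.array([envelope_autocorr(s, fs) for s in decomp.S])
    kurt = stats.kurtosis(decomp.S, axis=-1, fisher=True)
    return {"spectral_flatness": flat, "envelope_autocorr": ac,
            "kurtosis": kurt}


def select_components(
    decomp: Decomposition,
    fs: float,
    flatness_max: float = 0.6,
    autocorr_min: float = 0.2,
) -> np.ndarray:
    """Flag white-noise-like ICs for exclusion.

    A component is excluded when its spectral flatness exceeds
    ``flatness_max`` AND its rectified-envelope lag autocorrelation is
    below ``autocorr_min`` — i.e. it looks spectrally white and carries
    no slow amplitude modulation. The automated criterion stands in for
    unavailable expert screening and its thresholds are configurable.
    """
    m = component_metrics(decomp, fs)
    excluded = (m["spectral_flatness"] > flatness_max) & \
               (m["envelope_autocorr"] < autocorr_min)
    retained = ~excluded
    if not retained.any():
        raise ValueError(
            "all components classified as white noise; review the "
            f"thresholds (flatness_max={flatness_max}, "
            f"autocorr_min={autocorr_min})")
    decomp.retained_mask = retained
    decomp.metrics = m
    logger.info("retained %d / %d components", int(retained.sum()),
                retained.size)
    return retained
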