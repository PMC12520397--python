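"""Negentropy FastICA for 2-D log-difference data.

Centering, eigendecomposition whitening, and the deflationary fixed-point
iteration with the ln cosh contrast.  Convergence is tracked explicitly per
component — the convergence-rate experiments count runs in which every
unmixing vector converges within the iteration budget, so non-convergence is
reported, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WhitenedData",
    "SeparationResult",
    "DegenerateInputError",
    "center",
    "whiten",
    "fastica_unmix",
    "coefficient_matrix",
]

_COND_LIMIT = 1e12


class DegenerateInputError(ValueError):
    """The two log-difference channels are too similar to whiten.

    This is the failure mode that sub-block selection exists to prevent:
    near-gray regions make the sample covariance numerically singular.
    """


@dataclass
class WhitenedData:
    Z: np.ndarray  # n×2, identity sample covariance
    whitening_matrix: np.ndarray  # 2×2, λ^{-1/2} Uᵀ
    dewhitening_matrix: np.ndarray  # 2×2 inverse
    mean_vector: np.ndarray  # length-2 subtracted mean


@dataclass
class SeparationResult:
    W: np.ndarray  # 2×2 separation matrix, rows orthonormal in whitened space
    V: np.ndarray  # 2×2 nonnegative pigment coefficient matrix, unit columns
    converged: bool
    iterations_per_component: tuple[int, ...]
    seed: int | None


def center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the column means; returns (centered samples, mean vector)."""
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to center")
    mean = X.mean(axis=0)
    return X - mean, mean


def whiten(Xc: np.ndarray, mean_vector: np.ndarray | None = None) -> WhitenedData:
    """Whiten centered samples via eigendecomposition of the covariance.

    Z = λ^{-1/2} Uᵀ X̃, where U, λ are the eigenvectors/eigenvalues of
    E{X̃X̃ᵀ}.  Each eigenvector's sign is fixed by making its
    largest-magnitude entry positive, so whitening is deterministic.
    """
    n = Xc.shape[0]
    cov = (Xc.T @ Xc) / n
    if not np.all(np.isfinite(cov)):
        raise DegenerateInputError("non-finite covariance")
    evals, evecs = np.linalg.eigh(cov)
    cond = evals[-1] / evals[0] if evals[0] > 0 else np.inf
    if cond > _COND_LIMIT:
        raise DegenerateInputError(
            "channels too similar: covariance condition number "
            f"{cond:.3e} exceeds {_COND_LIMIT:.0e}"
        )
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    wh = (evecs / np.sqrt(evals)).T  # diag(λ^{-1/2}) @ Uᵀ
    dewh = evecs * np.sqrt(evals)  # U @ diag(λ^{1/2})
    Z = Xc @ wh.T
    if mean_vector is None:
        mean_vector = np.zeros(Xc.shape[1])
    return WhitenedData(Z=Z, whitening_matrix=wh, dewhitening_matrix=dewh, mean_vector=mean_vector)


def _g(u: np.ndarray) -> np.ndarray:
    return np.tanh(u)


def _g_prime(u: np.ndarray) -> np.ndarray:
    t = np.tanh(u)
    return 1.0 - t * t


def fastica_unmix(
    Z: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int | None = None,
) -> tuple[np.ndarray, bool, tuple[int, ...]]:
    """Deflationary fixed-point iteration on whitened samples.

    Each unmixing vector follows w ← E{Z g(wᵀZ)} − E{g′(wᵀZ)} w with
    g = tanh, is Gram–Schmidt-orthogonalized against previously extracted
    vectors and renormalized every iteration.  A component converges when
    |1 − |w_new·w_old|| < tol.  Returns (W, all_converged, iteration counts);
    non-convergence is reported in the flag, not raised.
    """
    rng = np.random.default_rng(seed)
    dim = Z.shape[1]
    rows: list[np.ndarray] = []
    iters: list[int] = []
    all_converged = True
    for _ in range(dim):
        w = rng.normal(size=dim)
        w = _orthonormalize(w, rows, rng)
        converged = False
        n_it = 0
        for n_it in range(1, max_iter + 1):
            u = Z @ w
            w_new = (Z * _g(u)[:, None]).mean(axis=0) - _g_prime(u).mean() * w
            w_new = _orthonormalize(w_new, rows, rng)
            if abs(1.0 - abs(w_new @ w)) < tol:
                w = w_new
                converged = True
                break
            w = w_new
        rows.append(w)
        iters.append(n_it)
        all_converged &= converged
    return np.vstack(rows), all_converged, tuple(iters)


def _orthonormalize(w: np.ndarray, rows: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    for prev in rows:
        w = w - (w @ prev) * prev
    nrm = np.linalg.norm(w)
    while nrm < 1e-12:  # degenerate direction; re-draw (practically unreachable in 2-D)
        w = rng.normal(size=w.shape)
        for prev in rows:
            w = w - (w @ prev) * prev
        nrm = np.linalg.norm(w)
    return w / nrm


def coefficient_matrix(W: np.ndarray, whitened: WhitenedData) -> np.ndarray:
    """Pigment coefficient matrix V = |(λ^{-1/2}Uᵀ)^{-1} W^{-1}|, unit columns.

    The estimated mixing matrix in the original log-difference space is the
    dewhitening matrix times W⁻¹; entries are taken in absolute value and each
    column is scaled to unit Euclidean norm (the permutation matrix of the
    scale/order ambiguity is taken as the identity; column ordering is decided
    later from the ratio thresholds).
    """
    if abs(np.linalg.det(W)) < 1e-12:
        raise np.linalg.LinAlgError("separation matrix W is singular")
    M = whitened.dewhitening_matrix @ np.linalg.inv(W)
    V = np.abs(M)
    return V / np.linalg.norm(V, axis=0, keepdims=True)
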