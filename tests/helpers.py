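"""Independent oracles and metrics used by the tests.

Everything here deliberately avoids the package's own FastICA code paths so
the checks stay dual-route.
"""

from functools import lru_cache

import numpy as np
from scipy.integrate import quad


@lru_cache(maxsize=1)
def gauss_lncosh() -> float:
    """E{ln cosh(nu)} for a standard Gaussian nu, by quadrature."""
    val, _ = quad(
        lambda u: np.log(np.cosh(u)) * np.exp(-u * u / 2.0) / np.sqrt(2.0 * np.pi),
        -10.0,
        10.0,
    )
    return val


def negentropy_objective(Z: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Sum of squared negentropy contrasts of the two orthogonal directions
    (theta, theta + 90°) for each candidate rotation angle."""
    eg = gauss_lncosh()
    w = np.stack([np.cos(thetas), np.sin(thetas)])  # 2 × T
    j1 = (np.log(np.cosh(Z @ w)).mean(axis=0) - eg) ** 2
    w_perp = np.stack([-np.sin(thetas), np.cos(thetas)])
    j2 = (np.log(np.cosh(Z @ w_perp)).mean(axis=0) - eg) ** 2
    return j1 + j2


def grid_search_angle(Z: np.ndarray, coarse: int = 1800, refine_steps: int = 2) -> float:
    """Exhaustive rotation search maximizing the negentropy objective.

    Returns the best unmixing angle in [0, pi/2); the objective has period
    pi/2 because the two orthogonal components swap.
    """
    lo, hi = 0.0, np.pi / 2
    thetas = np.linspace(lo, hi, coarse, endpoint=False)
    for _ in range(refine_steps + 1):
        obj = negentropy_objective(Z, thetas)
        best = thetas[np.argmax(obj)]
        step = thetas[1] - thetas[0]
        thetas = np.linspace(best - step, best + step, 201)
    return float(best % (np.pi / 2))


def unmix_angle(W: np.ndarray) -> float:
    """Angle of the first unmixing vector, mod 90 degrees."""
    return float(np.arctan2(W[0, 1], W[0, 0]) % (np.pi / 2))


def angle_gap_deg(a: float, b: float) -> float:
    """Angular distance between two angles defined mod 90 degrees."""
    d = abs(a - b) % (np.pi / 2)
    return float(np.degrees(min(d, np.pi / 2 - d)))


def paired_cosines(V: np.ndarray, V_true: np.ndarray) -> tuple[float, float]:
    """|cos angle| per column after the better of the two column pairings.

    Both matrices are column-normalized first; sign is ignored (the scale /
    sign ambiguity of blind separation).
    """
    A = V / np.linalg.norm(V, axis=0, keepdims=True)
    B = V_true / np.linalg.norm(V_true, axis=0, keepdims=True)
    c = np.abs(A.T @ B)
    if c[0, 0] + c[1, 1] >= c[0, 1] + c[1, 0]:
        return float(c[0, 0]), float(c[1, 1])
    return float(c[0, 1]), float(c[1, 0])
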