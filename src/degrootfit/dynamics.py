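"""Opinion dynamics: the DeGroot model and its bounded-confidence and decay
extensions.

Plain DeGroot updates opinions as X(t+1) = W X(t) with W row-stochastic and
constrained to the links of a symmetric adjacency matrix (self-links on the
diagonal).  Bounded confidence zeroes mutual influence between agents whose
current opinions differ by more than a threshold Delta, redistributing the
removed weight proportionally within each row.  Decay mixes W with the
identity through a convex coefficient lambda**t so agents grow progressively
more attached to their own opinions.  Both extensions reduce exactly — bit
for bit — to plain DeGroot at Delta = 1 and lambda = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DynamicsSpec",
    "DEGROOT",
    "validate_adjacency",
    "validate_weights",
    "degroot_step",
    "bounded_confidence_mask",
    "decay_factor",
    "model_step",
    "simulate_trajectory",
]

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DynamicsSpec:
    """Extension parameters of the opinion process.

    delta : bounded-confidence threshold in (0, 1]; 1 disables the extension.
    lam : decay base in (0, 1]; 1 disables the extension.
    """

    delta: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.delta <= 1.0):
            raise ValueError(f"delta must lie in (0, 1], got {self.delta}")
        if not (0.0 < self.lam <= 1.0):
            raise ValueError(f"lam must lie in (0, 1], got {self.lam}")

    @property
    def is_degroot(self) -> bool:
        return self.delta == 1.0 and self.lam == 1.0


DEGROOT = DynamicsSpec()


def validate_adjacency(A) -> np.ndarray:
    """Check symmetry, 0/1 entries and unit diagonal; return a float array."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if not np.all(np.isin(A, (0.0, 1.0))):
        raise ValueError("adjacency entries must be 0 or 1")
    if not np.all(np.diag(A) == 1.0):
        raise ValueError("adjacency must carry self-links (unit diagonal)")
    return A


def validate_weights(W, adjacency=None, tol: float = ROW_SUM_TOL) -> np.ndarray:
    """Check row-stochasticity, bounds and structural zeros of a weight matrix."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    if np.any(W < 0.0) or np.any(W > 1.0):
        raise ValueError("weights must lie in [0, 1]")
    sums = W.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ValueError(f"rows must sum to 1 within {tol}; got sums {sums}")
    if adjacency is not None:
        A = validate_adjacency(adjacency)
        if A.shape != W.shape:
            raise ValueError("adjacency and weight shapes differ")
        if np.any(W[A == 0.0] != 0.0):
            raise ValueError("weights violate structural zeros of the adjacency")
    return W


def degroot_step(W, X) -> np.ndarray:
    """One plain DeGroot update: the weighted average W @ X."""
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    if X.shape != (W.shape[0],):
        raise ValueError(
            f"opinion vector of length {X.shape} does not match W {W.shape}"
        )
    return W @ X


def bounded_confidence_mask(W, X, delta: float) -> np.ndarray:
    """Apply the bounded-confidence restriction to W at the current opinions.

    Entries w_ij with |x_i - x_j| > delta (strict) are zeroed symmetrically
    and each affected row is rescaled by 1 / (1 - removed mass) so it sums to
    one again.  Rows that lose nothing are returned unchanged (identically,
    not renormalised), so delta = 1 is an exact no-op.  Self-weights are never
    removed; a row left with zero mass (possible only when w_ii = 0) falls
    back to unit self-weight.
    """
    if not (0.0 < delta <= 1.0):
        raise ValueError(f"delta must lie in (0, 1], got {delta}")
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    diff = np.abs(X[:, None] - X[None, :])
    drop = diff > delta
    removed = np.where(drop, W, 0.0).sum(axis=1)
    affected = removed > 0.0
    if not np.any(affected):
        return W
    out = np.where(drop, 0.0, W)
    kept = out.sum(axis=1)
    for i in np.nonzero(affected)[0]:
        if kept[i] > 0.0:
            out[i] = out[i] / kept[i]
        else:
            out[i] = 0.0
            out[i, i] = 1.0
    return out


def decay_factor(lam: float, t: int) -> float:
    """Decay coefficient lambda**t; equals 1 at t = 0 for any lambda."""
    if not (0.0 < lam <= 1.0):
        raise ValueError(f"lam must lie in (0, 1], got {lam}")
    if t < 0 or t != int(t):
        raise ValueError(f"time index must be a non-negative integer, got {t}")
    return float(lam) ** int(t)


def model_step(W, X, t: int, spec: DynamicsSpec = DEGROOT) -> np.ndarray:
    """One update under the full dynamics at time index ``t``.

    The bounded-confidence mask is applied to W at the pre-update opinions to
    obtain W(t); the update is then the decay-weighted convex combination
    ((1 - lam**t) I + lam**t W(t)) X.  With delta = 1 and lam = 1 this is
    exactly ``degroot_step``.
    """
    X = np.asarray(X, dtype=float)
    Wt = bounded_confidence_mask(W, X, spec.delta)
    lt = decay_factor(spec.lam, t)
    return (1.0 - lt) * X + lt * (Wt @ X)


def simulate_trajectory(
    W, X0, n_steps: int, spec: DynamicsSpec = DEGROOT
) -> np.ndarray:
    """Simulate opinions forward, returning an (N, n_steps + 1) array.

    Column t holds X(t); column 0 is the initial opinion vector.  The update
    at time t uses the decay coefficient lambda**t and the bounded-confidence
    mask evaluated at the pre-update opinions X(t).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be at least 1, got {n_steps}")
    X0 = np.asarray(X0, dtype=float)
    if np.any(X0 < 0.0) or np.any(X0 > 1.0):
        raise ValueError("initial opinions must lie in [0, 1]")
    N = X0.shape[0]
    out = np.empty((N, n_steps + 1))
    out[:, 0] = X0
    x = X0
    for t in range(n_steps):
        x = model_step(W, x, t, spec)
        out[:, t + 1] = x
    return out
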