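"""Ordinal scale transformations.

Opinion data in behavioural research are almost always collected on Likert or
composite ordinal scales, while the DeGroot model operates on continuous
opinions in [0, 1].  Under the usual interval-property assumption, an n-point
scale partitions [0, 1] into n equal-width bins: the forward transform maps a
level to its bin midpoint, the back transform maps a continuous opinion to the
bin that contains it.  The bin deviation between two continuous opinions —
the distance between their bins — is the building block of both the fitting
objective and the ordinal-fit metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OrdinalScale", "shift_to_unit_start"]

# Continuous opinions produced by repeated convex combinations can land within
# representation error of a bin boundary; snap y*n to an integer before the
# ceiling when that close so boundary values are not pushed up a bin.
_BOUNDARY_SNAP = 1e-12


@dataclass(frozen=True)
class OrdinalScale:
    """An n-point ordinal scale over the unit interval.

    Parameters
    ----------
    n_points : int
        Number of ordinal levels, at least 2.  Levels are 1..n_points.
    """

    n_points: int

    def __post_init__(self) -> None:
        if not isinstance(self.n_points, (int, np.integer)) or isinstance(
            self.n_points, bool
        ):
            raise TypeError(f"n_points must be an integer, got {self.n_points!r}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be at least 2, got {self.n_points}")

    # ------------------------------------------------------------------ #
    def forward(self, x):
        """Map ordinal level(s) ``x`` in 1..n to bin-midpoint opinions.

        Level x maps to (x - 0.5) / n, the middle of the x-th of n
        equal-width sub-intervals of [0, 1].  Scalar in, scalar out; array
        in, array out.
        """
        arr = np.asarray(x)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("ordinal levels must be integers")
        if np.any(arr < 1) or np.any(arr > self.n_points):
            raise ValueError(
                f"ordinal levels must lie in 1..{self.n_points}, got {x!r}"
            )
        out = (arr - 0.5) / self.n_points
        return out if out.ndim else float(out)

    def back(self, y):
        """Map continuous opinion(s) ``y`` in [0, 1] to ordinal level(s) 1..n.

        The level is ceil(y * n); y = 0 belongs to the first bin.  Values
        within 1e-12 of a bin boundary are treated as sitting exactly on it.
        """
        arr = np.asarray(y, dtype=float)
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValueError(f"continuous opinions must lie in [0, 1], got {y!r}")
        levels = self._back_unchecked(arr)
        return levels if levels.ndim else int(levels)

    def _back_unchecked(self, arr: np.ndarray) -> np.ndarray:
        """Back transform without domain validation (hot path for the GA)."""
        z = arr * self.n_points
        nearest = np.rint(z)
        z = np.where(np.abs(z - nearest) <= _BOUNDARY_SNAP, nearest, z)
        levels = np.ceil(z).astype(np.int64)
        return np.clip(levels, 1, self.n_points)

    def bin_deviation(self, y_hat, y_obs):
        """Absolute deviation between two continuous opinions on the scale.

        Zero exactly when both opinions fall in the same bin — a "correctly
        modeled" opinion.  Bounded by n_points - 1.
        """
        a = self.back(y_hat)
        b = self.back(y_obs)
        d = np.abs(np.asarray(a) - np.asarray(b))
        return d if d.ndim else int(d)


def shift_to_unit_start(scores, minimum: int):
    """Rescale integer scores on ``minimum..minimum+n-1`` to ``1..n``.

    Composite scales built by summing items start above 1 (an 8-item
    4-point battery spans 8..32); subtracting ``minimum - 1`` yields the
    1..n coding the transforms expect.
    """
    arr = np.asarray(scores)
    out = arr - (int(minimum) - 1)
    if np.any(out < 1):
        raise ValueError("scores fall below the stated minimum")
    return out if out.ndim else int(out)
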