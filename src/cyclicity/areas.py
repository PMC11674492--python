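"""Oriented areas, area trajectories, lead matrices, discretization bound.

The oriented (algebraic) area of a pair of time series ``x, y`` is the
level-2 iterated integral

    a = 1/2 * integral( x dy - y dx )

of their parametric plot, i.e. the winding-number-weighted area the closed
curve encircles.  For linearly interpolated samples the integral is exact and
reduces to the shoelace sum

    a = 1/2 * sum_i ( x[i] * (y[i+1] - y[i]) - y[i] * (x[i+1] - x[i]) ).

A positive area is the lead-lag heuristic: ``x`` leads, ``y`` follows.
Proportional signals and signals with disjoint supports both give zero.  The
formula uses no time stamps at all, which is the source of the method's
invariance under monotone reparametrizations of the timeline.

The lead matrix ``A = (a_kl)`` collects all pairwise areas of a recording and
is skew-symmetric by construction; its spectral structure is analysed in
:mod:`cyclicity.spectral`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import ValidationError
from .io import Recording

__all__ = [
    "oriented_area",
    "area_trajectory",
    "AreaTrajectory",
    "LeadMatrix",
    "lead_matrix",
    "ErrorBoundInputs",
    "discretization_error_bound",
]


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValidationError("inputs must be 1-D sequences")
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValidationError(f"need at least 2 samples, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values")
    return x, y


def oriented_area(x, y) -> float:
    """Oriented area of the linearly interpolated parametric curve (x(t), y(t)).

    Positive when ``x`` leads ``y``; antisymmetric under argument swap; zero
    for proportional signals and for signals with non-overlapping supports.
    """
    x, y = _check_pair(x, y)
    return 0.5 * float(np.sum(x[:-1] * np.diff(y) - y[:-1] * np.diff(x)))


@dataclasses.dataclass
class AreaTrajectory:
    """Cumulative oriented area a_kl(t) over frames [0, t].

    ``values[0] == 0`` and ``values[-1]`` equals the lead-matrix entry for the
    pair.  How the total increment is reached over time is the raw material of
    the reversal and burstiness analyses.
    """

    values: np.ndarray
    pair: tuple[str, str]

    @property
    def n_frames(self) -> int:
        return self.values.size


def area_trajectory(x, y, pair: tuple[str, str] = ("x", "y")) -> AreaTrajectory:
    """Oriented area as a function of the expanding upper integration bound."""
    x, y = _check_pair(x, y)
    steps = x[:-1] * np.diff(y) - y[:-1] * np.diff(x)
    values = np.concatenate([[0.0], 0.5 * np.cumsum(steps)])
    return AreaTrajectory(values=values, pair=(str(pair[0]), str(pair[1])))


@dataclasses.dataclass
class LeadMatrix:
    """Skew-symmetric matrix of pairwise oriented areas with channel labels."""

    entries: np.ndarray
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.channel_labels)
        if self.entries.shape != (n, n):
            raise ValidationError("lead matrix shape does not match labels")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def entry(self, k: str, l: str) -> float:
        i = self.channel_labels.index(k)
        j = self.channel_labels.index(l)
        return float(self.entries[i, j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.entries, index=self.channel_labels, columns=self.channel_labels
        )


def lead_matrix(rec: Recording) -> LeadMatrix:
    """All pairwise oriented areas of a recording's channels.

    Each unordered pair is computed once; skew-symmetry and a zero diagonal
    are therefore exact.  Normally called on a :class:`NormalizedRecording`
    (the pipeline's convention), but any recording is accepted.
    """
    X = rec.values
    # vectorized shoelace over all pairs: S = X[:, :-1] @ dX.T is n x n with
    # S[k, l] = sum_i x_k[i] * (x_l[i+1] - x_l[i]); a_kl = (S[k,l]-S[l,k])/2.
    dX = np.diff(X, axis=1)
    S = X[:, :-1] @ dX.T
    A = 0.5 * (S - S.T)
    np.fill_diagonal(A, 0.0)
    # enforce exact skew-symmetry bit-for-bit
    iu = np.triu_indices(A.shape[0], k=1)
    A[(iu[1], iu[0])] = -A[iu]
    return LeadMatrix(entries=A, channel_labels=list(rec.channel_labels))


@dataclasses.dataclass
class ErrorBoundInputs:
    """Inputs of the discretization error bound.

    C_k, C_l bound the C^1 norms of the perturbations of the two channels
    (signal units); delta is the discretization step (time units).
    """

    C_k: float
    C_l: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("C_k", "C_l", "delta"):
            v = getattr(self, name)
            if not (float(v) > 0):
                raise ValidationError(f"{name} must be strictly positive, got {v}")
            setattr(self, name, float(v))


def discretization_error_bound(b: ErrorBoundInputs) -> float:
    """Bound |a'_kl - a_kl| <= 2 * C_k * C_l * delta on the area perturbation."""
    return 2.0 * b.C_k * b.C_l * b.delta
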