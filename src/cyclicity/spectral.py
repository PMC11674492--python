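"""Spectral analysis of lead matrices: constellations, rankings, phase order.

A real skew-symmetric matrix has purely imaginary eigenvalues in conjugate
pairs ``±i|λ|`` with complex-conjugate eigenvectors.  The components of the
eigenvector of the largest pair — the *constellation* — line up, for
chain-of-offsets (traveling-wave) data, along an ellipse in the complex
plane, in the cyclic order in which the channels are excited.  This module

* eigendecomposes the lead matrix (via the Hermitian matrix ``iA``, so the
  imaginary structure is exact and ordering deterministic),
* extracts and orients the leading constellation (conjugation ambiguity is
  resolved with the most confident lead-lag pair: the entry of largest
  absolute oriented area),
* fits the constellation ellipse, an origin-centered positive-definite
  quadratic form q(z) = a x^2 + 2 b x y + c y^2, by linear least squares,
* ranks channels by the elliptic norm |z|_q = q(z)^{1/2} (rank 1 = farthest
  from the origin = most exposed to the passing ripple), aggregates ranks
  across recordings,
* orders a kept subset of channels by phase after rotating the constellation
  so its centroid sits on the positive real axis (order proceeds
  counterclockwise starting from the negative real axis), and summarizes
  orderings across recordings as channel-by-position frequency histograms.

All tie-breaks use channel-label order; everything is seed-free and
deterministic.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .areas import LeadMatrix
from .exceptions import (
    DegenerateConstellationError,
    NotSkewSymmetricError,
    ValidationError,
)

__all__ = [
    "SpectralDecomposition",
    "eigendecompose",
    "dominance_ratio",
    "Constellation",
    "leading_constellation",
    "QuadraticForm",
    "fit_ellipse",
    "elliptic_rank",
    "average_rank",
    "PhaseOrdering",
    "phase_order",
    "ordering_histogram",
]

_SKEW_TOL = 1e-9


@dataclasses.dataclass
class SpectralDecomposition:
    """One representative per conjugate eigenvalue pair of a lead matrix.

    ``eigenvalue_magnitudes[s]`` is |λ| of the s-th largest pair (zero
    eigenvalues of odd-dimensional matrices appear with magnitude 0);
    ``eigenvectors[:, s]`` is the eigenvector for eigenvalue +i|λ|, unit
    Euclidean norm.
    """

    eigenvalue_magnitudes: np.ndarray
    eigenvectors: np.ndarray
    channel_labels: list[str]

    @property
    def n_pairs(self) -> int:
        return self.eigenvalue_magnitudes.size


def _check_skew(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    scale = max(float(np.abs(A).max()), 1.0)
    if float(np.abs(A + A.T).max()) > _SKEW_TOL * scale:
        raise NotSkewSymmetricError(
            "matrix is not skew-symmetric within 1e-9 relative tolerance"
        )
    return 0.5 * (A - A.T)


def eigendecompose(A: LeadMatrix) -> SpectralDecomposition:
    """Eigenvalue pairs ±i|λ| and one representative eigenvector per pair.

    Computed as the Hermitian eigenproblem of ``iA``: if ``iA w = μ w`` then
    ``A w = -iμ w``, so eigenvectors for negative μ carry eigenvalue +i|μ|.
    Magnitudes are returned sorted non-increasing; for odd n (or rank
    deficiency) leftover zero eigenvalues are reported with magnitude 0.
    """
    M = _check_skew(A.entries)
    n = M.shape[0]
    mu, W = np.linalg.eigh(1j * M)  # mu ascending, real
    # representatives: eigenvalue lambda = -i*mu, take mu <= 0 -> lambda = +i|mu|
    n_pairs = n // 2 + (n % 2)
    idx = np.argsort(mu)[:n_pairs]  # most negative first = largest |λ| first
    mags = np.abs(mu[idx])
    order = np.argsort(-mags, kind="stable")
    idx = idx[order]
    mags = mags[order]
    vecs = W[:, idx]
    return SpectralDecomposition(
        eigenvalue_magnitudes=mags,
        eigenvectors=vecs,
        channel_labels=list(A.channel_labels),
    )


def dominance_ratio(d: SpectralDecomposition) -> float:
    """|λ1|/|λ3| — dominance of the rank-2 approximation.

    Conjugate pairs are counted once, so the paper's λ3 (the second distinct
    magnitude, λ2 being the conjugate of λ1) is pair index 2 here.  Returns
    ``inf`` when the second pair is negligible (exactly rank-2 input).
    """
    if len(d.channel_labels) < 4:
        raise ValidationError("dominance ratio needs at least 4 channels")
    m1, m2 = float(d.eigenvalue_magnitudes[0]), float(d.eigenvalue_magnitudes[1])
    if m2 <= 1e-12 * m1:
        return math.inf
    return m1 / m2


@dataclasses.dataclass
class Constellation:
    """Leading-eigenvector components as labelled points of the complex plane."""

    points: np.ndarray  # complex, one per channel
    channel_labels: list[str]
    eigenvalue_magnitude: float
    orientation_reference: tuple[str, str]

    def point(self, label: str) -> complex:
        return complex(self.points[self.channel_labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.channel_labels,
                "re": self.points.real,
                "im": self.points.imag,
                "modulus": np.abs(self.points),
                "phase": np.angle(self.points),
            }
        )


def _reference_pair(A: np.ndarray) -> tuple[int, int]:
    """Index pair (k, l), k < l, with the largest |a_kl|; ties -> first."""
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    flat = np.abs(A[iu])
    best = int(np.argmax(flat))
    return int(iu[0][best]), int(iu[1][best])


def leading_constellation(A: LeadMatrix, pair_index: int = 1) -> Constellation:
    """The oriented eigenvector of the pair_index-th largest eigenvalue pair.

    The conjugation ambiguity is resolved so that for the reference pair
    (k*, l*) = argmax |a_kl| the signed angle arg(v_l*/v_k*) in (-π, π] has
    the same sign as a_{k*l*}: the leader precedes the follower
    counterclockwise, matching the lead-lag heuristic of the oriented area.
    """
    d = eigendecompose(A)
    if pair_index < 1 or pair_index > d.n_pairs:
        raise ValidationError(f"pair_index {pair_index} out of range")
    lam = float(d.eigenvalue_magnitudes[pair_index - 1])
    if lam <= 0.0:
        raise DegenerateConstellationError("requested eigenvalue pair is zero")
    v = d.eigenvectors[:, pair_index - 1].copy()
    k, l = _reference_pair(A.entries)
    akl = A.entries[k, l]
    if v[k] == 0 or v[l] == 0:
        raise DegenerateConstellationError(
            "reference-pair component vanishes; orientation undefined"
        )
    angle = float(np.angle(v[l] / v[k]))
    if angle == 0.0:
        raise DegenerateConstellationError("reference pair has zero phase shift")
    if np.sign(angle) != np.sign(akl):
        v = np.conj(v)
    v = v / np.linalg.norm(v)
    return Constellation(
        points=v,
        channel_labels=list(A.channel_labels),
        eigenvalue_magnitude=lam,
        orientation_reference=(A.channel_labels[k], A.channel_labels[l]),
    )


@dataclasses.dataclass
class QuadraticForm:
    """Positive-definite q(z) = a x^2 + 2 b x y + c y^2 with z = x + i y.

    The unit level set {q(z) = 1} is the constellation ellipse.  ``degenerate``
    flags a least-squares minimizer that had to be clipped to positive
    definiteness.
    """

    a: float
    b: float
    c: float
    degenerate: bool = False

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.b, self.c]], dtype=float)

    def is_positive_definite(self) -> bool:
        return self.a > 0 and self.a * self.c - self.b * self.b > 0

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=complex)
        x, y = z.real, z.imag
        return self.a * x * x + 2.0 * self.b * x * y + self.c * y * y

    def norm(self, z: np.ndarray) -> np.ndarray:
        """Elliptic norm |z|_q = q(z)^{1/2}."""
        return np.sqrt(self(z))


def fit_ellipse(points: np.ndarray) -> QuadraticForm:
    """Least-squares constellation ellipse: minimize sum (q(z_i) - 1)^2.

    Linear in (a, b, c) on the design (x^2, 2xy, y^2).  If the minimizer is
    not positive definite, the eigenvalues of its 2x2 form matrix are clipped
    at eps = 1e-6 * (largest eigenvalue, or 1 if both are <= 0) and the
    ``degenerate`` flag is set.
    """
    z = np.asarray(points, dtype=complex).ravel()
    if z.size < 3:
        raise ValidationError("ellipse fit needs at least 3 points")
    if np.allclose(z, 0):
        raise DegenerateConstellationError("all points at the origin")
    x, y = z.real, z.imag
    design = np.column_stack([x * x, 2.0 * x * y, y * y])
    coef, *_ = np.linalg.lstsq(design, np.ones_like(x), rcond=None)
    a, b, c = (float(v) for v in coef)
    q = QuadraticForm(a, b, c)
    if q.is_positive_definite():
        return q
    w, V = np.linalg.eigh(q.matrix)
    eps = 1e-6 * (w.max() if w.max() > 0 else 1.0)
    w = np.maximum(w, eps)
    Mclip = V @ np.diag(w) @ V.T
    return QuadraticForm(
        float(Mclip[0, 0]), float(Mclip[0, 1]), float(Mclip[1, 1]), degenerate=True
    )


def elliptic_rank(c: Constellation, q: QuadraticForm) -> pd.DataFrame:
    """Per-channel elliptic norms and integer ranks (1 = largest norm).

    Ties are broken by channel-label order.  Returns a DataFrame with columns
    ``channel``, ``norm``, ``rank``.
    """
    if not q.is_positive_definite():
        raise ValidationError("quadratic form must be positive definite")
    norms = q.norm(c.points)
    df = pd.DataFrame({"channel": c.channel_labels, "norm": norms})
    df = df.sort_values(["norm", "channel"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.sort_index().reset_index(drop=True)


def average_rank(rankings: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean integer rank per channel across recordings, sorted ascending.

    Low mean rank = dominant (consistently far from the origin in elliptic
    norm).  All rankings must share the same channel set.
    """
    if not rankings:
        raise ValidationError("no rankings given")
    channels = sorted(rankings[0]["channel"])
    for r in rankings[1:]:
        if sorted(r["channel"]) != channels:
            raise ValidationError("rankings do not share a common channel set")
    stacked = pd.concat(rankings, ignore_index=True)
    mean = stacked.groupby("channel", sort=True)["rank"].mean().reset_index()
    mean = mean.rename(columns={"rank": "mean_rank"})
    return mean.sort_values(
        ["mean_rank", "channel"], kind="stable", ignore_index=True
    )


@dataclasses.dataclass
class PhaseOrdering:
    """Channels ordered by normalized phase in (-π, π], non-decreasing."""

    channels: list[str]
    phases: np.ndarray
    rotation: float  # angle subtracted to put the centroid on the +real axis

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.channels) + 1),
                "channel": self.channels,
                "phase": self.phases,
            }
        )


def phase_order(c: Constellation, keep: list[str] | None = None) -> PhaseOrdering:
    """Order kept channels by phase after centroid-aligning rotation.

    The constellation is rotated so the centroid of the kept points lands on
    the positive real axis; phases are then reported in (-π, π] and channels
    listed in ascending phase, i.e. counterclockwise starting from the
    negative real axis.  The ordering is invariant to any global rotation of
    the constellation.
    """
    labels = list(c.channel_labels) if keep is None else list(keep)
    if not labels:
        raise ValidationError("keep subset is empty")
    missing = [lab for lab in labels if lab not in c.channel_labels]
    if missing:
        raise ValidationError(f"unknown channels: {missing}")
    pts = np.array([c.point(lab) for lab in labels])
    centroid = pts.mean()
    if abs(centroid) <= 1e-12 * max(np.abs(pts).max(), 1e-300):
        raise DegenerateConstellationError(
            "constellation centroid at the origin; rotation undefined"
        )
    rot = float(np.angle(centroid))
    phases = np.angle(pts * np.exp(-1j * rot))  # in (-π, π]
    order = sorted(range(len(labels)), key=lambda i: (phases[i], labels[i]))
    return PhaseOrdering(
        channels=[labels[i] for i in order],
        phases=phases[order],
        rotation=rot,
    )


def ordering_histogram(orderings: list[PhaseOrdering]) -> pd.DataFrame:
    """Channel-by-position frequency matrix over a collection of orderings.

    Row-stochastic: entry (channel, position) is the fraction of orderings in
    which the channel appeared at that (1-based) position.  Rows are sorted by
    the channel's mean position.
    """
    if not orderings:
        raise ValidationError("no orderings given")
    channels = sorted(orderings[0].channels)
    m = len(channels)
    for o in orderings[1:]:
        if sorted(o.channels) != channels:
            raise ValidationError("orderings do not share a common channel subset")
    counts = pd.DataFrame(
        np.zeros((m, m)), index=channels, columns=np.arange(1, m + 1)
    )
    for o in orderings:
        for pos, ch in enumerate(o.channels, start=1):
            counts.loc[ch, pos] += 1
    freq = counts / len(orderings)
    mean_pos = (freq * freq.columns.values[None, :]).sum(axis=1)
    freq = freq.loc[mean_pos.sort_values(kind="stable").index]
    freq.index.name = "channel"
    return freq
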