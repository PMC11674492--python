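"""0-dimensional sublevel-set persistence of 1-D trajectories.

Sweeping the values of a sequence ``f`` from low to high, a connected
component of the sublevel set {f <= v} is *born* at each local minimum and
*dies* when it merges with an older component at a local maximum (the elder
rule: of the two merging components, the one with the higher — younger —
birth dies).  The global minimum never dies and is the single *essential*
class.  The span d - b of a birth/death pair measures how robust the
corresponding dip is to perturbation: perturbing ``f`` by eps in sup-norm
moves every span by at most 2*eps.

Applied to cumulative oriented-area trajectories a_kl(t), the minima of the
most persistent features mark *reversals* — changes of the leader-follower
role between the two channels.  Because a reversal is any direction change,
the default analysis runs the filtration on both f and -f and merges the
feature lists (minima of the negated trajectory are the decreasing-to-
increasing turns seen from the other side); the ``signed_mode="f"`` option
restricts to the plain filtration.

*Burstiness* of a trajectory is the total length of its ``n_bars`` longest
bars (default 10): high when the accumulation happens in jagged task-locked
jumps, low for steady drift.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .areas import AreaTrajectory
from .exceptions import ValidationError

__all__ = [
    "PersistencePair",
    "PersistenceDiagram",
    "sublevel_persistence",
    "top_features",
    "ReversalEvents",
    "reversal_events",
    "CarpetSummary",
    "carpet",
    "uniform_null_max_count",
    "burstiness",
]


@dataclasses.dataclass(frozen=True)
class PersistencePair:
    """A finite feature: born at a local minimum, dying at a merge maximum."""

    birth: float
    death: float
    birth_index: int
    death_index: int

    @property
    def span(self) -> float:
        return self.death - self.birth


@dataclasses.dataclass
class PersistenceDiagram:
    """Finite pairs plus the one essential class (global minimum, infinity)."""

    finite_pairs: list[PersistencePair]
    essential_value: float
    essential_index: int

    def spans(self) -> np.ndarray:
        return np.array([p.span for p in self.finite_pairs], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p.birth, p.death, p.birth_index, p.death_index, p.span)
            for p in self.finite_pairs
        ]
        df = pd.DataFrame(
            rows, columns=["birth", "death", "birth_index", "death_index", "span"]
        )
        df.attrs["essential"] = (self.essential_value, self.essential_index)
        return df


def sublevel_persistence(f) -> PersistenceDiagram:
    """Union-find sublevel filtration of a 1-D sequence with the elder rule.

    Ties in value are broken by time index: the smaller index is older.  The
    birth index of each finite pair is a local minimum of ``f`` and the death
    index the merge maximum; for sequences with distinct values the number of
    finite pairs is (number of strict local minima) - 1.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or f.size < 2:
        raise ValidationError("need a 1-D sequence of length >= 2")
    if not np.isfinite(f).all():
        raise ValidationError("non-finite values")
    n = f.size
    order = np.lexsort((np.arange(n), f))  # ascending (value, index)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    parent = np.arange(n)
    # birth of the component rooted at i is (f[birth_idx[i]], birth_idx[i])
    birth_idx = np.arange(n)
    active = np.zeros(n, dtype=bool)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs: list[PersistencePair] = []
    for i in order:
        active[i] = True
        left = i - 1 if i > 0 and active[i - 1] else -1
        right = i + 1 if i + 1 < n and active[i + 1] else -1
        if left < 0 and right < 0:
            continue  # new component born at its minimum i
        if left >= 0 and right >= 0:
            rl, rr = find(left), find(right)
            # elder = smaller (value, index) birth, i.e. smaller rank
            if rank[birth_idx[rl]] <= rank[birth_idx[rr]]:
                elder, younger = rl, rr
            else:
                elder, younger = rr, rl
            pairs.append(
                PersistencePair(
                    birth=float(f[birth_idx[younger]]),
                    death=float(f[i]),
                    birth_index=int(birth_idx[younger]),
                    death_index=int(i),
                )
            )
            parent[younger] = elder
            parent[i] = elder
        else:
            parent[i] = find(left if left >= 0 else right)

    gmin = int(order[0])
    return PersistenceDiagram(
        finite_pairs=pairs, essential_value=float(f[gmin]), essential_index=gmin
    )


def top_features(d: PersistenceDiagram, p: int) -> list[PersistencePair]:
    """The <= p finite pairs of largest span, ties broken by earlier birth index.

    The essential class is never included.
    """
    if p < 1:
        raise ValidationError("p must be >= 1")
    ranked = sorted(d.finite_pairs, key=lambda q: (-q.span, q.birth_index))
    return ranked[:p]


@dataclasses.dataclass
class ReversalEvents:
    """Reversal timestamps of one oriented-area trajectory.

    ``minima`` are frames where the trajectory turns upward (births of kept
    features of f and deaths of kept features of -f); ``maxima`` the downward
    turns (the mirror set).  Extrema at the first or last frame are excluded
    — an endpoint has no direction change.  ``all_events`` is the sorted
    union.
    """

    pair: tuple[str, str]
    minima: list[int]
    maxima: list[int]
    p: int

    @property
    def all_events(self) -> list[int]:
        return sorted(set(self.minima) | set(self.maxima))


def reversal_events(
    traj: AreaTrajectory,
    p: int = 10,
    signed_mode: str = "both",
    min_span_fraction: float | None = None,
) -> ReversalEvents:
    """Timestamps of persistent direction changes of a trajectory.

    Runs the sublevel filtration on the trajectory (and, in the default
    ``"both"`` mode, on its negation), keeps the ``p`` longest-lived finite
    features of each filtration, and collects the frames of their minima and
    paired maxima.  Essential classes are not events: the global extremum of
    a trending trajectory marks where accumulation starts or stops, not a
    change of direction.

    ``min_span_fraction``, when set, additionally drops kept features whose
    span is below that fraction of the longest finite span (pooled over both
    filtrations) — a noise-floor filter separating genuine reversals from
    small-scale jitter when the count cutoff ``p`` alone is not selective.
    """
    if signed_mode not in ("f", "both"):
        raise ValidationError("signed_mode must be 'f' or 'both'")
    f = np.asarray(traj.values, dtype=float)
    T = f.size
    d_f = sublevel_persistence(f)
    keep_f = top_features(d_f, p)
    keep_n: list[PersistencePair] = []
    d_n = None
    if signed_mode == "both":
        d_n = sublevel_persistence(-f)
        keep_n = top_features(d_n, p)
    if min_span_fraction is not None:
        spans = [q.span for q in d_f.finite_pairs] + (
            [q.span for q in d_n.finite_pairs] if d_n is not None else []
        )
        if spans:
            floor = min_span_fraction * max(spans)
            keep_f = [q for q in keep_f if q.span >= floor]
            keep_n = [q for q in keep_n if q.span >= floor]
    minima = {q.birth_index for q in keep_f}
    maxima = {q.death_index for q in keep_f}
    if d_n is not None:
        maxima |= {q.birth_index for q in keep_n}
        minima |= {q.death_index for q in keep_n}
    interior = lambda s: sorted(i for i in s if 0 < i < T - 1)
    return ReversalEvents(
        pair=traj.pair, minima=interior(minima), maxima=interior(maxima), p=p
    )


@dataclasses.dataclass
class CarpetSummary:
    """Pairs x frames event raster with per-frame counts.

    ``counts[t]`` is the number of pairs recording a birth or death at frame
    ``t`` (the column sum of the raster).
    """

    raster: np.ndarray  # (n_pairs, T) binary
    counts: np.ndarray  # (T,)
    pairs: list[tuple[str, str]]


def carpet(events: list[ReversalEvents], T: int) -> CarpetSummary:
    """Aggregate reversal events of many pairs into a carpet raster."""
    raster = np.zeros((len(events), T), dtype=int)
    for row, ev in enumerate(events):
        for i in ev.all_events:
            if not (0 <= i < T):
                raise ValidationError(f"event frame {i} outside [0, {T})")
            raster[row, i] = 1
    return CarpetSummary(
        raster=raster, counts=raster.sum(axis=0), pairs=[e.pair for e in events]
    )


def uniform_null_max_count(
    events_per_pair: list[int],
    T: int,
    n_draws: int = 500,
    seed: int = 0,
    quantile: float = 0.99,
) -> float:
    """Null threshold for carpet peaks under uniform scatter.

    Scatters each pair's event count uniformly over the T frames, records the
    maximum per-frame count of each draw, and returns the requested quantile.
    A carpet whose observed maximum exceeds this threshold has temporally
    clustered (task-locked) reversals.
    """
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_draws)
    for d in range(n_draws):
        counts = np.zeros(T, dtype=int)
        for m in events_per_pair:
            frames = rng.choice(T, size=min(m, T), replace=False)
            counts[frames] += 1
        maxima[d] = counts.max()
    return float(np.quantile(maxima, quantile))


def burstiness(
    traj: AreaTrajectory, n_bars: int = 10, signed_mode: str = "both"
) -> float:
    """Total length of the n_bars longest persistence bars of a trajectory.

    In the default ``"both"`` mode the finite bars of the trajectory and of
    its negation are pooled before selecting the longest; a strictly monotone
    trajectory has no finite bars and burstiness 0.
    """
    if signed_mode not in ("f", "both"):
        raise ValidationError("signed_mode must be 'f' or 'both'")
    if n_bars < 1:
        raise ValidationError("n_bars must be >= 1")
    f = np.asarray(traj.values, dtype=float)
    spans = list(sublevel_persistence(f).spans())
    if signed_mode == "both":
        spans += list(sublevel_persistence(-f).spans())
    spans.sort(reverse=True)
    return float(sum(spans[:n_bars]))
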