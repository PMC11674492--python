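"""Reading, validating, normalizing and writing multichannel recordings.

A recording is an ``n`` channels x ``T`` frames real matrix with unique channel
labels and a fixed sampling interval ``dt`` (seconds).  On disk it is a
delimited text file (comma or tab, auto-detected) whose first row holds the
channel labels and whose subsequent rows each hold one time frame.

Normalization follows the energy convention used throughout the pipeline:
each channel is centered (time average removed) and divided by the square
root of its quadratic variation, the sum of squared successive differences,
so every normalized channel has unit quadratic variation.  ``dt`` is metadata
only — no oriented-area computation depends on it (reparametrization
invariance) — but event spacings are reported in both frames and seconds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateChannelError,
    DuplicateLabelError,
    MissingLabelError,
    NonFiniteError,
    NonNumericError,
    RaggedRowError,
    TooFewChannelsError,
    TooFewFramesError,
)

__all__ = [
    "Recording",
    "NormalizedRecording",
    "read_recording",
    "normalize",
    "quadratic_variation",
    "write_table",
    "read_table",
]


@dataclasses.dataclass
class Recording:
    """A validated multichannel recording (channels x frames).

    Parameters
    ----------
    values : ndarray, shape (n, T)
        Real signal values, one row per channel.
    channel_labels : list of str
        Unique channel names, one per row of ``values``.
    dt : float
        Sampling interval in seconds (> 0).
    id : str
        Recording identifier used in output provenance.
    """

    values: np.ndarray
    channel_labels: list[str]
    dt: float
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channel_labels = [str(c) for c in self.channel_labels]
        if self.values.ndim != 2:
            raise RaggedRowError("recording values must be a 2-D matrix")
        n, T = self.values.shape
        if n < 2:
            raise TooFewChannelsError(f"need at least 2 channels, got {n}")
        if T < 3:
            raise TooFewFramesError(f"need at least 3 frames, got {T}")
        if len(self.channel_labels) != n:
            raise MissingLabelError(
                f"{len(self.channel_labels)} labels for {n} channels"
            )
        if any(not lab for lab in self.channel_labels):
            raise MissingLabelError("empty channel label")
        if len(set(self.channel_labels)) != n:
            seen: set[str] = set()
            dups = []
            for lab in self.channel_labels:
                if lab in seen:
                    dups.append(lab)
                seen.add(lab)
            raise DuplicateLabelError(f"duplicate channel labels: {sorted(set(dups))}")
        if not np.isfinite(self.values).all():
            bad = [
                self.channel_labels[k]
                for k in np.nonzero(~np.isfinite(self.values).all(axis=1))[0]
            ]
            raise NonFiniteError(f"non-finite values in channels {bad}")
        if not (float(self.dt) > 0):
            raise TooFewFramesError(f"dt must be positive, got {self.dt}")
        self.dt = float(self.dt)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Total session duration T * dt in seconds."""
        return self.n_frames * self.dt

    @property
    def span(self) -> float:
        """Time between the first and last sample, (T - 1) * dt, in seconds."""
        return (self.n_frames - 1) * self.dt

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.channel_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        """Frames x channels DataFrame (the on-disk orientation)."""
        return pd.DataFrame(self.values.T, columns=self.channel_labels)


@dataclasses.dataclass
class NormalizedRecording(Recording):
    """A recording whose channels are centered with unit quadratic variation."""


def quadratic_variation(x: np.ndarray) -> np.ndarray:
    """Sum of squared successive differences along the last axis."""
    d = np.diff(np.asarray(x, dtype=float), axis=-1)
    return (d * d).sum(axis=-1)


def read_recording(path: str | Path, dt: float, id: str | None = None) -> Recording:
    """Read a delimited text recording (header = labels, rows = frames).

    The delimiter (comma or tab) is auto-detected from the header row.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise MissingLabelError(f"{path}: empty file")
    header = lines[0]
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    labels = [c.strip() for c in header.split(sep)]
    if any(lab == "" for lab in labels):
        raise MissingLabelError(f"{path}: empty label in header")
    # a numeric-looking header means the label row is missing
    def _is_number(s: str) -> bool:
        try:
            float(s)
            return True
        except ValueError:
            return False

    if all(_is_number(lab) for lab in labels):
        raise MissingLabelError(f"{path}: header row looks numeric; labels required")
    ncol = len(labels)
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in ln.split(sep)]
        if len(cells) != ncol:
            raise RaggedRowError(
                f"{path}:{i}: row has {len(cells)} cells, expected {ncol}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise NonNumericError(f"{path}:{i}: {exc}") from None
    if len(rows) < 3:
        raise TooFewFramesError(f"{path}: {len(rows)} frames, need at least 3")
    values = np.asarray(rows, dtype=float).T  # -> channels x frames
    return Recording(values, labels, dt=dt, id=id if id is not None else path.stem)


def normalize(rec: Recording) -> NormalizedRecording:
    """Center each channel and scale it to unit quadratic variation.

    Raises
    ------
    DegenerateChannelError
        If a channel is constant (zero quadratic variation), naming it.
    """
    centered = rec.values - rec.values.mean(axis=1, keepdims=True)
    qv = quadratic_variation(centered)
    if np.any(qv <= 0):
        bad = [rec.channel_labels[k] for k in np.nonzero(qv <= 0)[0]]
        raise DegenerateChannelError(
            f"constant channel(s) with zero quadratic variation: {bad}"
        )
    out = centered / np.sqrt(qv)[:, None]
    return NormalizedRecording(out, list(rec.channel_labels), dt=rec.dt, id=rec.id)


def write_table(
    obj: pd.DataFrame,
    path: str | Path,
    *,
    operation: str = "",
    parameters: dict | None = None,
    seed: int | None = None,
    index: bool = False,
) -> None:
    """Write a tabular result as CSV with a one-line JSON provenance comment.

    The first line is ``# {json}`` recording the producing operation, its
    parameters and the seed; the rest is plain CSV.  ``read_table`` inverts it.
    """
    path = Path(path)
    prov = {"operation": operation, "parameters": parameters or {}, "seed": seed}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# " + json.dumps(prov, sort_keys=True, default=str) + "\n")
        obj.to_csv(fh, index=index)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (frame, provenance)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        prov = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        df = pd.read_csv(fh)
    return df, prov
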