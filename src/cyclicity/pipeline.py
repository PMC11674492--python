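"""End-to-end orchestration: recordings -> lead -> spectral -> persistence.

``run_full`` executes the whole cyclicity pipeline on one or more recordings
(read from disk or generated by a named preset) and returns a result bundle
of tables; every written table carries a JSON provenance line with the
configuration hash and seed.  Defaults follow the analysis conventions used
throughout the package: leading eigenvalue pair, top k = 20 channels by
elliptic rank, p = 10 persistent features, 10 burstiness bars, both-signs
reversal mode.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .areas import area_trajectory, lead_matrix
from .exceptions import ValidationError
from .io import Recording, normalize, read_recording, write_table
from .persistence import burstiness, carpet, reversal_events
from .spectral import (
    average_rank,
    dominance_ratio,
    eigendecompose,
    elliptic_rank,
    fit_ellipse,
    leading_constellation,
    ordering_histogram,
    phase_order,
)

__all__ = ["PipelineConfig", "run_full", "preset_recordings", "PRESETS"]

log = logging.getLogger("cyclicity")

PRESETS = ("rest", "social-hcp", "motor-hcp")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    inputs: list[str] = dataclasses.field(default_factory=list)
    preset: str | None = None
    n_recordings: int = 1
    dt: float = 0.72
    pair_index: int = 1
    keep_top: int = 20
    p: int = 10
    n_bars: int = 10
    signed_mode: str = "both"
    seed: int = 0
    outdir: str | None = None

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("outdir", None)
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def preset_recordings(
    preset: str, seed: int, n_recordings: int = 1, dt: float = 0.72
) -> list[Recording]:
    """Generate the named preset's recordings.

    ``rest``: a steady 10-channel single-harmonic chain-of-offsets recording
    at SNR 10 (unidirectional ripple, no reversals).  ``social-hcp``: a
    two-channel pair whose leader alternates at every 38-s social-task
    segment boundary over 1,200 frames.  ``motor-hcp``: a two-channel pair
    under the 13-block motor run (10 movement + 3 fixation blocks of 15 s).
    """
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {PRESETS}")
    recs = []
    for r in range(n_recordings):
        s = int(seed) + r
        if preset == "rest":
            rng = np.random.default_rng(s)
            n = 10
            offsets = np.sort(rng.uniform(0, 2 * np.pi, n))
            spec0 = simulate.CoomSpec(
                n=n,
                amplitudes=rng.uniform(0.8, 1.2, n),
                offsets=offsets,
                seed_function=simulate.FourierSeed([0.5]),
                omega=2 * np.pi / 50.0,
                duration=1200 * dt,
                dt=dt,
                noise_sd=0.0,
                seed=s,
            )
            clean = simulate.coom_series(spec0)
            spec0.noise_sd = simulate.noise_sd_for_snr(clean.values, 10.0)
            recs.append(simulate.coom_series(spec0))
        elif preset == "social-hcp":
            recs.append(
                simulate.block_pair(
                    simulate.social_design(duration=1200 * dt, lag=2 * dt),
                    dt=dt,
                    seed=s,
                    snr=10.0,
                )
            )
        else:  # motor-hcp
            recs.append(
                simulate.block_pair(
                    simulate.motor_design(lag=4 * dt),
                    pulse_rate=1 / 3.0,
                    dt=dt,
                    seed=s,
                    snr=10.0,
                    pulse_width=2.5,
                )
            )
    return recs


def _stage(name: str, t0: float, **dims) -> None:
    log.info("stage %-14s %6.2fs %s", name, time.perf_counter() - t0, dims or "")


def run_full(config: PipelineConfig) -> dict:
    """Run normalize -> lead -> spectral -> rank -> order -> persistence.

    Returns a bundle (dict) of pandas DataFrames; when ``config.outdir`` is
    set each table is also written as provenance-stamped CSV.
    """
    t_start = time.perf_counter()
    if config.preset:
        recordings = preset_recordings(
            config.preset, config.seed, config.n_recordings, config.dt
        )
    elif config.inputs:
        recordings = [read_recording(p, dt=config.dt) for p in config.inputs]
    else:
        raise ValidationError("config needs input paths or a preset name")
    _stage("load", t_start, n_recordings=len(recordings))

    bundle: dict = {"config": config, "recordings": recordings}
    lead_frames, rankings, orderings = [], [], []
    event_rows, burst_rows = [], []
    carpets = {}

    for rec in recordings:
        t0 = time.perf_counter()
        try:
            nrec = normalize(rec)
            A = lead_matrix(nrec)
            lead_frames.append(A.to_frame())
            dec = eigendecompose(A)
            dom = dominance_ratio(dec) if A.n >= 4 else np.nan
            if A.n >= 3:
                con = leading_constellation(A, pair_index=config.pair_index)
                q = fit_ellipse(con.points)
                ranking = elliptic_rank(con, q)
                rankings.append(ranking)
                keep = (
                    ranking.sort_values(["rank"], kind="stable")["channel"]
                    .head(config.keep_top)
                    .tolist()
                )
                orderings.append(phase_order(con, keep=sorted(keep)))
            else:
                # a 2-channel recording has a trivial constellation; rank and
                # phase ordering carry no information
                keep = list(rec.channel_labels)
            events = []
            for k, l in itertools.combinations(sorted(keep), 2):
                traj = area_trajectory(nrec.channel(k), nrec.channel(l), (k, l))
                ev = reversal_events(traj, p=config.p, signed_mode=config.signed_mode)
                events.append(ev)
                burst_rows.append(
                    {
                        "recording": rec.id,
                        "pair": f"{k}|{l}",
                        "burstiness": burstiness(
                            traj, n_bars=config.n_bars, signed_mode=config.signed_mode
                        ),
                    }
                )
                for frame in ev.minima:
                    event_rows.append(
                        {"recording": rec.id, "pair": f"{k}|{l}", "frame": frame,
                         "kind": "minimum", "seconds": frame * rec.dt}
                    )
                for frame in ev.maxima:
                    event_rows.append(
                        {"recording": rec.id, "pair": f"{k}|{l}", "frame": frame,
                         "kind": "maximum", "seconds": frame * rec.dt}
                    )
            carpets[rec.id] = carpet(events, rec.n_frames)
            bundle.setdefault("dominance", {})[rec.id] = dom
        except ValidationError as exc:
            raise ValidationError(f"recording {rec.id!r}: {exc}") from exc
        _stage("recording", t0, id=rec.id, n=rec.n_channels, T=rec.n_frames)

    bundle["lead_matrices"] = lead_frames
    bundle["rankings"] = rankings
    bundle["average_rank"] = average_rank(rankings) if rankings else None
    bundle["orderings"] = orderings
    bundle["ordering_histogram"] = (
        ordering_histogram(orderings) if len(orderings) > 1 else None
    )
    bundle["events"] = pd.DataFrame(
        event_rows, columns=["recording", "pair", "frame", "kind", "seconds"]
    )
    bundle["burstiness"] = pd.DataFrame(
        burst_rows, columns=["recording", "pair", "burstiness"]
    )
    bundle["carpets"] = carpets
    carpet_rows = []
    for rid, cs in carpets.items():
        for frame, count in enumerate(cs.counts):
            if count:
                carpet_rows.append({"recording": rid, "frame": frame, "count": count})
    bundle["carpet_counts"] = pd.DataFrame(
        carpet_rows, columns=["recording", "frame", "count"]
    )

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = dict(config_hash=config.digest(), version=_version())
        for i, lf in enumerate(lead_frames):
            write_table(
                lf, outdir / f"lead_{recordings[i].id}.csv",
                operation="lead_matrix", parameters=meta, seed=config.seed, index=True,
            )
        if bundle["average_rank"] is not None:
            write_table(bundle["average_rank"], outdir / "average_rank.csv",
                        operation="average_rank", parameters=meta, seed=config.seed)
        write_table(bundle["events"], outdir / "events.csv",
                    operation="reversal_events", parameters=meta, seed=config.seed)
        write_table(bundle["burstiness"], outdir / "burstiness.csv",
                    operation="burstiness", parameters=meta, seed=config.seed)
        write_table(bundle["carpet_counts"], outdir / "carpet_counts.csv",
                    operation="carpet", parameters=meta, seed=config.seed)
    _stage("total", t_start)
    return bundle


def _version() -> str:
    from . import __version__

    return __version__
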