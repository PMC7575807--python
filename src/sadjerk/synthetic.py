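"""Seeded generator of heart-rate-like test traces.

Real exercise heart-rate recordings show a handful of structural features
that the analysis must cope with: piecewise exercise bouts with gradual
drift, measurement noise, short spikes on the order of 40 bpm above the
surrounding signal, shallow 1-2 bpm dips below a zone threshold that split
an otherwise continuous supra-threshold period, and sensor dropouts.  The
generator builds such traces as a pure function of (spec, seed) so every
pipeline stage is testable without downloading any recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .timeseries_io import UniformSeries

__all__ = [
    "Segment",
    "Artifact",
    "SyntheticHRSpec",
    "generate_hr",
    "dip_heal_scenario",
    "load_spec",
    "save_spec",
]

ARTIFACT_KINDS = ("spike", "dip", "dropout")
DROPOUT_RESTING_BPM = 60.0


@dataclass(frozen=True)
class Segment:
    """A piecewise-linear baseline segment: ``level + slope * t_local``."""

    level_bpm: float
    duration_s: float
    slope_bpm_per_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.duration_s > 0):
            raise ValueError(f"segment duration must be positive, got {self.duration_s}")


@dataclass(frozen=True)
class Artifact:
    """A rectangular disturbance.

    ``spike`` adds ``+magnitude_bpm`` and ``dip`` adds ``-magnitude_bpm``
    over ``[onset_s, onset_s + duration_s)``; ``dropout`` replaces the
    samples with a low resting value regardless of magnitude.
    """

    kind: str
    onset_s: float
    magnitude_bpm: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"artifact kind must be one of {ARTIFACT_KINDS}, got {self.kind!r}")
        if not (self.duration_s > 0):
            raise ValueError("artifact duration must be positive")
        if self.onset_s < 0:
            raise ValueError("artifact onset cannot be negative")


@dataclass(frozen=True)
class SyntheticHRSpec:
    segments: tuple
    noise_sd: float = 0.0
    artifacts: tuple = ()
    seed: int = 0
    sample_interval_s: float = 1.0

    def __post_init__(self) -> None:
        segs = tuple(s if isinstance(s, Segment) else Segment(*s) for s in self.segments)
        arts = tuple(a if isinstance(a, Artifact) else Artifact(*a) for a in self.artifacts)
        if not segs:
            raise ValueError("at least one segment is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")
        if not (self.sample_interval_s > 0):
            raise ValueError("sample_interval_s must be positive")
        total = sum(s.duration_s for s in segs)
        for a in arts:
            if a.onset_s + a.duration_s > total:
                raise ValueError(
                    f"artifact at {a.onset_s}s/{a.duration_s}s extends past total duration {total}s"
                )
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "artifacts", arts)

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def to_dict(self) -> dict:
        return {
            "segments": [[s.level_bpm, s.duration_s, s.slope_bpm_per_s] for s in self.segments],
            "noise_sd": self.noise_sd,
            "artifacts": [
                [a.kind, a.onset_s, a.magnitude_bpm, a.duration_s] for a in self.artifacts
            ],
            "seed": self.seed,
            "sample_interval_s": self.sample_interval_s,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticHRSpec":
        return cls(
            segments=tuple(tuple(s) for s in doc["segments"]),
            noise_sd=float(doc.get("noise_sd", 0.0)),
            artifacts=tuple(tuple(a) for a in doc.get("artifacts", ())),
            seed=int(doc.get("seed", 0)),
            sample_interval_s=float(doc.get("sample_interval_s", 1.0)),
        )


def generate_hr(spec: SyntheticHRSpec, seed: int | None = None) -> UniformSeries:
    """Generate a heart-rate trace from a spec.

    The trace is the piecewise-linear baseline, plus Gaussian noise of
    standard deviation ``noise_sd``, plus the artifacts (dropouts override
    everything with a resting value).  Generation is deterministic for a
    given (spec, seed); ``seed`` defaults to ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dt = spec.sample_interval_s
    n = int(round(spec.duration_s / dt))
    t = np.arange(n) * dt

    values = np.empty(n)
    seg_start = 0.0
    for seg in spec.segments:
        in_seg = (t >= seg_start) & (t < seg_start + seg.duration_s)
        values[in_seg] = seg.level_bpm + seg.slope_bpm_per_s * (t[in_seg] - seg_start)
        seg_start += seg.duration_s

    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=n)

    for art in spec.artifacts:
        in_art = (t >= art.onset_s) & (t < art.onset_s + art.duration_s)
        if art.kind == "spike":
            values[in_art] += art.magnitude_bpm
        elif art.kind == "dip":
            values[in_art] -= art.magnitude_bpm
        else:  # dropout
            values[in_art] = DROPOUT_RESTING_BPM

    return UniformSeries(values, sample_interval_s=dt, start_time_s=0.0, label="bpm")


def dip_heal_scenario(seed: int = 0) -> tuple[UniformSeries, float]:
    """Canonical fixture: a shallow dip that splits a supra-threshold bout.

    A 1200 s trace at 1 Hz: 200 s at 95 bpm, an 800 s exercise bout at
    115 bpm, 200 s at 95 bpm, with a 3 s dip to 103 bpm (2 bpm below the
    105 bpm threshold) at mid-bout.  The fixture is noise-free so its
    guarantees are deterministic: the raw trace has (at least) two periods
    above the threshold, while after a moving average with any window of 7
    samples or more the dip is averaged back above the threshold and a
    single period spans the whole bout.

    Returns ``(series, thr)`` with ``thr = 105.0``.
    """
    thr = 105.0
    spec = SyntheticHRSpec(
        segments=(
            Segment(95.0, 200.0),
            Segment(115.0, 800.0),
            Segment(95.0, 200.0),
        ),
        noise_sd=0.0,
        artifacts=(Artifact("dip", 598.0, 12.0, 3.0),),  # down to thr - 2 = 103 bpm
        seed=seed,
    )
    return generate_hr(spec), thr


def load_spec(path) -> SyntheticHRSpec:
    """Read a spec from a YAML (or JSON — a YAML subset) file."""
    with open(path, "r") as fh:
        return SyntheticHRSpec.from_dict(yaml.safe_load(fh))


def save_spec(spec: SyntheticHRSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)
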