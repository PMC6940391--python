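"""Design and scoring of phase-scrambled grating stimuli.

A drifting sinusoidal grating is discretized into ``n`` spatial-phase steps
per temporal cycle (default 8).  Smooth forward motion is the ordered
sequence ``[1 2 ... 8]``, smooth backward motion its reverse, and any other
permutation is a "scrambled" motion stimulus.  Because the sequence repeats
cyclically on screen, two sequences that are circular rotations of one
another are the same stimulus; the 8! = 40,320 permutations therefore
collapse to 5040 circularly unique sequences.

This module enumerates those sequences, scores each one with three
irregularity metrics (best-aligned correlation with smooth motion, summed
total phase interval, and spatiotemporal motion energy), renders sequences
and counterphase gratings as X-T luminance movies, and assembles the
10-stimulus family (F, B, S1..S6, CP1, CP2) used throughout the package.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhaseSequence",
    "StimulusSpec",
    "StimulusMovie",
    "IrregularityMetrics",
    "FORWARD_LABEL",
    "BACKWARD_LABEL",
    "DEFAULT_S6_STEPS",
    "DEFAULT_CORRELATION_GRID",
    "DEFAULT_SPATIAL_SAMPLES",
    "enumerate_sequences",
    "canonicalize",
    "best_aligned_correlation",
    "smooth_motion_metrics",
    "summed_phase_interval",
    "motion_energy",
    "motion_energy_of_movie",
    "render_movie",
    "build_family",
    "select_scrambled_sequences",
    "irregularity_table",
    "load_family",
    "save_family",
]

FORWARD_LABEL = "F"
BACKWARD_LABEL = "B"

#: Scrambled sequence used for training in the hardest condition.
DEFAULT_S6_STEPS = (8, 3, 6, 2, 7, 4, 1, 5)

#: Spatial sample grid used for the phase-product correlation metric,
#: x = [0, 1, ..., 10] / 10 (11 samples across one spatial period).
DEFAULT_CORRELATION_GRID = np.arange(11) / 10.0

#: Spatial samples per grating cycle for rendered movies / Fourier analysis.
DEFAULT_SPATIAL_SAMPLES = 16

CorrelationMode = Literal["sensible", "as_printed"]


@dataclass(frozen=True)
class PhaseSequence:
    """An ordering of the ``n`` discretized spatial phases of one cycle.

    ``steps`` is a permutation of ``1..n``.  Sequences that are circular
    rotations of each other describe the same repeating stimulus; the
    canonical representative starts with step 1.
    """

    steps: tuple[int, ...]

    def __post_init__(self) -> None:
        steps = tuple(int(s) for s in self.steps)
        object.__setattr__(self, "steps", steps)
        n = len(steps)
        if n < 2:
            raise ValueError("a phase sequence needs at least 2 steps")
        if sorted(steps) != list(range(1, n + 1)):
            raise ValueError(
                f"steps must be a permutation of 1..{n}, got {steps}"
            )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def rotated(self, k: int) -> "PhaseSequence":
        """Circular rotation bringing position ``k`` to the front."""
        k %= self.n_steps
        return PhaseSequence(self.steps[k:] + self.steps[:k])

    def reversed(self) -> "PhaseSequence":
        return PhaseSequence(self.steps[::-1])

    def canonical(self) -> "PhaseSequence":
        """The rotation of this sequence that begins with step 1."""
        return self.rotated(self.steps.index(1))

    def __str__(self) -> str:  # e.g. "[8 3 6 2 7 4 1 5]"
        return "[" + " ".join(str(s) for s in self.steps) + "]"


def _as_sequence(seq: "PhaseSequence | Sequence[int]") -> PhaseSequence:
    if isinstance(seq, PhaseSequence):
        return seq
    return PhaseSequence(tuple(seq))


def forward_sequence(n_steps: int = 8) -> PhaseSequence:
    return PhaseSequence(tuple(range(1, n_steps + 1)))


def backward_sequence(n_steps: int = 8) -> PhaseSequence:
    return PhaseSequence(tuple(range(n_steps, 0, -1)))


def canonicalize(seq: "PhaseSequence | Sequence[int]") -> PhaseSequence:
    """Rotate ``seq`` so that it starts with step 1 (unique dedup key)."""
    return _as_sequence(seq).canonical()


def enumerate_sequences(n_steps: int = 8) -> list[PhaseSequence]:
    """All circularly unique phase sequences of ``n_steps`` phases.

    Fixing step 1 in the leading position selects exactly one representative
    per rotation class, so the count is ``n!/n = (n-1)!``.

    Parameters
    ----------
    n_steps : int
        Number of phase steps per cycle; limited to 2..10 to keep the
        factorial enumeration tractable.
    """
    if not 2 <= n_steps <= 10:
        raise ValueError(f"n_steps must be in 2..10, got {n_steps}")
    return [
        PhaseSequence((1,) + rest)
        for rest in itertools.permutations(range(2, n_steps + 1))
    ]


# ---------------------------------------------------------------------------
# Irregularity metrics
# ---------------------------------------------------------------------------


def _phase_frame(
    step: int, n_steps: int, x: np.ndarray, mode: CorrelationMode
) -> np.ndarray:
    """Spatial luminance profile of one phase step on grid ``x``.

    ``sensible`` treats the step as a spatial-phase offset,
    sin(2*pi*(x + (step-1)/n)).  ``as_printed`` evaluates the literal
    product kernel sin(2*pi*((step-1)/n)*x), in which step 1 is identically
    zero; it is kept purely for auditability of the correlation metric.
    """
    if mode == "sensible":
        return np.sin(2 * np.pi * (x + (step - 1) / n_steps))
    if mode == "as_printed":
        return np.sin(2 * np.pi * ((step - 1) / n_steps) * x)
    raise ValueError(f"unknown correlation mode {mode!r}")


def _phase_product_table(
    n_steps: int, x: np.ndarray, mode: CorrelationMode
) -> np.ndarray:
    """P[a-1, b-1] = sum_x frame(a) * frame(b) for all phase-step pairs."""
    frames = np.stack(
        [_phase_frame(s, n_steps, x, mode) for s in range(1, n_steps + 1)]
    )
    return frames @ frames.T


def best_aligned_correlation(
    a: "PhaseSequence | Sequence[int]",
    b: "PhaseSequence | Sequence[int]",
    mode: CorrelationMode = "sensible",
    spatial_samples: np.ndarray | None = None,
    normalize: bool = True,
) -> float:
    """Maximum frame-product correlation over all circular offsets of ``b``.

    For each of the ``n`` rotations of ``b``, the score is the sum over
    phase steps of the spatial product of the two sinusoid frames; the
    maximum over rotations is returned.  With ``normalize=True`` the score
    is divided by the geometric mean of the two self-products so that the
    self-correlation is 1 and all values lie in [-1, 1].
    """
    a = _as_sequence(a)
    b = _as_sequence(b)
    if a.n_steps != b.n_steps:
        raise ValueError(
            f"sequence lengths differ: {a.n_steps} vs {b.n_steps}"
        )
    x = DEFAULT_CORRELATION_GRID if spatial_samples is None else np.asarray(
        spatial_samples, dtype=float
    )
    P = _phase_product_table(a.n_steps, x, mode)
    ai = np.asarray(a.steps) - 1
    bi = np.asarray(b.steps) - 1
    n = a.n_steps
    scores = [
        float(P[ai, np.roll(bi, -k)].sum()) for k in range(n)
    ]
    best = max(scores)
    if not normalize:
        return best
    self_a = float(P[ai, ai].sum())
    self_b = float(P[bi, bi].sum())
    denom = np.sqrt(self_a * self_b)
    if denom == 0:
        raise ZeroDivisionError(
            "self-product is zero; cannot normalize (as_printed mode with a "
            "degenerate grid?)"
        )
    return best / denom


def smooth_motion_metrics(
    seq: "PhaseSequence | Sequence[int]",
    mode: CorrelationMode = "sensible",
    spatial_samples: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Best-aligned correlation of ``seq`` with smooth forward and backward
    motion, and their average ``(corr_F, corr_B, corr_smooth_avg)``."""
    seq = _as_sequence(seq)
    n = seq.n_steps
    cf = best_aligned_correlation(
        seq, forward_sequence(n), mode=mode, spatial_samples=spatial_samples
    )
    cb = best_aligned_correlation(
        seq, backward_sequence(n), mode=mode, spatial_samples=spatial_samples
    )
    return cf, cb, (cf + cb) / 2.0


def summed_phase_interval(seq: "PhaseSequence | Sequence[int]") -> float:
    """Summed total phase interval of a sequence, in radians.

    The distance between consecutive phase steps (including the wrap from
    the last step back to the first, since the sequence repeats) is the
    circular step distance ``min(|d|, n - |d|)`` converted to radians by
    ``2*pi/n``.  Smooth sequences attain the minimum ``2*pi``.
    """
    seq = _as_sequence(seq)
    n = seq.n_steps
    s = np.asarray(seq.steps)
    d = np.abs(np.roll(s, -1) - s)
    d = np.minimum(d, n - d)
    return float(d.sum() * (2 * np.pi / n))


def motion_energy_of_movie(frames: np.ndarray) -> float:
    """Sum of |2-D DFT coefficients| excluding zero temporal frequency.

    ``frames`` is a (time x space) array of one stimulus cycle.  The zero
    temporal-frequency row of the spectrum corresponds to the static
    grating and is excluded, so a constant-in-time movie has zero energy.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2:
        raise ValueError("expected a 2-D (time x space) array")
    if frames.shape[1] < 2:
        raise ValueError("need at least 2 spatial samples")
    spectrum = np.fft.fft2(frames)
    mag = np.abs(spectrum)
    mag[0, :] = 0.0  # zero temporal frequency: static component
    return float(mag.sum())


def motion_energy(
    seq: "PhaseSequence | Sequence[int]",
    spatial_samples_per_cycle: int = DEFAULT_SPATIAL_SAMPLES,
) -> float:
    """Total motion energy of one rendered cycle of a phase sequence."""
    seq = _as_sequence(seq)
    if spatial_samples_per_cycle < 2:
        raise ValueError("need at least 2 spatial samples per cycle")
    x = np.arange(spatial_samples_per_cycle) / spatial_samples_per_cycle
    frames = np.stack(
        [np.sin(2 * np.pi * (x + (s - 1) / seq.n_steps)) for s in seq.steps]
    )
    return motion_energy_of_movie(frames)


@dataclass(frozen=True)
class IrregularityMetrics:
    """The three irregularity scores of one phase sequence."""

    corr_F: float
    corr_B: float
    corr_smooth_avg: float
    summed_phase_interval: float
    motion_energy: float


def score_sequence(
    seq: "PhaseSequence | Sequence[int]",
    mode: CorrelationMode = "sensible",
    spatial_samples_per_cycle: int = DEFAULT_SPATIAL_SAMPLES,
) -> IrregularityMetrics:
    cf, cb, avg = smooth_motion_metrics(seq, mode=mode)
    return IrregularityMetrics(
        corr_F=cf,
        corr_B=cb,
        corr_smooth_avg=avg,
        summed_phase_interval=summed_phase_interval(seq),
        motion_energy=motion_energy(seq, spatial_samples_per_cycle),
    )


def _vectorized_smooth_correlations(
    sequences: list[PhaseSequence], mode: CorrelationMode = "sensible"
) -> tuple[np.ndarray, np.ndarray]:
    """(corr_F, corr_B) for many sequences at once (normalized)."""
    n = sequences[0].n_steps
    P = _phase_product_table(n, DEFAULT_CORRELATION_GRID, mode)
    idx = np.asarray([s.steps for s in sequences]) - 1  # (m, n)
    self_prod = P[idx, idx].sum(axis=1)

    def against(ref: PhaseSequence) -> np.ndarray:
        ri = np.asarray(ref.steps) - 1
        ref_self = P[ri, ri].sum()
        scores = np.stack(
            [P[idx, np.roll(ri, -k)].sum(axis=1) for k in range(n)]
        )
        return scores.max(axis=0) / np.sqrt(self_prod * ref_self)

    return against(forward_sequence(n)), against(backward_sequence(n))


def irregularity_table(
    n_steps: int = 8,
    mode: CorrelationMode = "sensible",
    spatial_samples_per_cycle: int = DEFAULT_SPATIAL_SAMPLES,
) -> pd.DataFrame:
    """Score every circularly unique sequence; one row per sequence."""
    seqs = enumerate_sequences(n_steps)
    corr_f, corr_b = _vectorized_smooth_correlations(seqs, mode)
    x = np.arange(spatial_samples_per_cycle) / spatial_samples_per_cycle
    phase_frames = np.stack(
        [np.sin(2 * np.pi * (x + k / n_steps)) for k in range(n_steps)]
    )
    idx = np.asarray([s.steps for s in seqs]) - 1
    movies = phase_frames[idx]  # (m, n_steps, spatial)
    spectra = np.abs(np.fft.fft2(movies, axes=(1, 2)))
    spectra[:, 0, :] = 0.0
    energies = spectra.sum(axis=(1, 2))
    steps = np.asarray([s.steps for s in seqs])
    d = np.abs(np.roll(steps, -1, axis=1) - steps)
    d = np.minimum(d, n_steps - d)
    spi = d.sum(axis=1) * (2 * np.pi / n_steps)
    return pd.DataFrame(
        {
            "sequence": [str(s) for s in seqs],
            "corr_F": corr_f,
            "corr_B": corr_b,
            "corr_smooth_avg": (corr_f + corr_b) / 2.0,
            "summed_phase_interval": spi,
            "motion_energy": energies,
        }
    )


# ---------------------------------------------------------------------------
# Stimulus specs and rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSpec:
    """One member of the stimulus family.

    ``kind='sequence'`` stimuli animate a grating along ``sequence``;
    ``kind='counterphase'`` stimuli are standing gratings whose contrast
    reverses in time (mathematically the mean of the forward and backward
    movies at the configured spatial phase).
    """

    label: str
    kind: Literal["sequence", "counterphase"] = "sequence"
    sequence: PhaseSequence | None = None
    spatial_phase_offset: float = 0.0
    temporal_frequency: float = 2.0
    n_cycles: int = 10
    n_steps: int = 8

    def __post_init__(self) -> None:
        if self.kind not in ("sequence", "counterphase"):
            raise ValueError(f"invalid stimulus kind {self.kind!r}")
        if self.kind == "sequence":
            if self.sequence is None:
                raise ValueError("sequence stimuli need a PhaseSequence")
            object.__setattr__(self, "n_steps", self.sequence.n_steps)
        if self.temporal_frequency <= 0 or self.n_cycles < 1:
            raise ValueError("temporal_frequency and n_cycles must be positive")

    @property
    def step_duration(self) -> float:
        """Seconds per phase step: 1/(temporal_frequency * n_steps)."""
        return 1.0 / (self.temporal_frequency * self.n_steps)

    @property
    def duration(self) -> float:
        return self.step_duration * self.n_steps * self.n_cycles


@dataclass(frozen=True)
class StimulusMovie:
    """Discretized X-T luminance array for one stimulus."""

    frames: np.ndarray  # (time, space), values in [-1, 1]
    frame_duration: float
    spatial_samples_per_cycle: int
    label: str = ""

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def render_movie(
    spec: StimulusSpec,
    spatial_samples_per_cycle: int = DEFAULT_SPATIAL_SAMPLES,
    n_cycles: int | None = None,
) -> StimulusMovie:
    """Render a stimulus spec as an X-T movie.

    Sequence stimuli: frame ``i`` is the pure spatial sinusoid
    ``sin(2*pi*(x + (step_i - 1)/n) + phase_offset)``.  Counterphase
    stimuli are the element-wise mean of the forward and backward movies
    rendered at the spec's spatial phase offset, which collapses to a
    standing grating ``sin(2*pi*x + phase)*cos(2*pi*t/n)``.
    """
    cycles = spec.n_cycles if n_cycles is None else n_cycles
    x = np.arange(spatial_samples_per_cycle) / spatial_samples_per_cycle
    if spec.kind == "sequence":
        assert spec.sequence is not None
        one_cycle = np.stack(
            [
                np.sin(
                    2 * np.pi * (x + (s - 1) / spec.n_steps)
                    + spec.spatial_phase_offset
                )
                for s in spec.sequence.steps
            ]
        )
    else:
        n = spec.n_steps
        fwd = StimulusSpec(
            label="F",
            sequence=forward_sequence(n),
            spatial_phase_offset=spec.spatial_phase_offset,
            temporal_frequency=spec.temporal_frequency,
            n_cycles=1,
        )
        bwd = StimulusSpec(
            label="B",
            sequence=backward_sequence(n),
            spatial_phase_offset=spec.spatial_phase_offset,
            temporal_frequency=spec.temporal_frequency,
            n_cycles=1,
        )
        one_cycle = (
            render_movie(fwd, spatial_samples_per_cycle, n_cycles=1).frames
            + render_movie(bwd, spatial_samples_per_cycle, n_cycles=1).frames
        ) / 2.0
    frames = np.tile(one_cycle, (cycles, 1))
    return StimulusMovie(
        frames=frames,
        frame_duration=spec.step_duration,
        spatial_samples_per_cycle=spatial_samples_per_cycle,
        label=spec.label,
    )


# ---------------------------------------------------------------------------
# Family construction
# ---------------------------------------------------------------------------


def select_scrambled_sequences(
    n_select: int = 5,
    corr_ceiling: float = 0.5,
    mutual_ceiling: float = 0.6,
    anchors: Iterable[PhaseSequence] = (),
    exclude: Iterable[PhaseSequence] = (),
    n_steps: int = 8,
) -> list[PhaseSequence]:
    """Deterministically pick scrambled sequences spanning irregularity.

    Candidates are all circularly unique sequences except F, B and
    ``exclude``, restricted to average smooth-motion correlation at or
    below ``corr_ceiling`` (sequences too similar to smooth motion are
    deliberately excluded so that training with them could not amount to
    smooth-motion training).  Selection targets are evenly spaced
    correlation levels between the candidate minimum and the ceiling,
    processed from most scrambled upward; for each target the candidate
    closest in correlation is taken (ties broken by step order), subject
    to a mutual-dissimilarity constraint: its best-aligned correlation
    with every ``anchor`` and every already-chosen sequence must not
    exceed ``mutual_ceiling``, so the scrambled members respond poorly to
    one another's optimal stimuli.  The result is ordered from most to
    least smooth-correlated.
    """
    seqs = enumerate_sequences(n_steps)
    corr_f, corr_b = _vectorized_smooth_correlations(seqs)
    avg = (corr_f + corr_b) / 2.0
    banned = {forward_sequence(n_steps).steps, backward_sequence(n_steps).steps}
    banned |= {canonicalize(s).steps for s in exclude}
    cand = [
        (a, s)
        for a, s in zip(avg, seqs)
        if s.steps not in banned and a <= corr_ceiling
    ]
    if len(cand) < n_select:
        raise ValueError(
            f"only {len(cand)} candidate sequences below ceiling "
            f"{corr_ceiling}; cannot select {n_select}"
        )
    lo = min(a for a, _ in cand)
    targets = np.linspace(lo, corr_ceiling, n_select)
    chosen: list[tuple[float, PhaseSequence]] = []
    picked: list[PhaseSequence] = [canonicalize(a) for a in anchors]
    taken: set[tuple[int, ...]] = {s.steps for s in picked}

    def admissible(s: PhaseSequence) -> bool:
        return s.steps not in taken and all(
            best_aligned_correlation(s, p) <= mutual_ceiling for p in picked
        )

    for t in targets:
        pool = sorted(cand, key=lambda c: (abs(c[0] - t), c[1].steps))
        best = next((c for c in pool if admissible(c[1])), None)
        if best is None:
            raise ValueError(
                "no admissible candidate under the mutual-dissimilarity "
                f"ceiling {mutual_ceiling} near correlation target {t:.3f}"
            )
        taken.add(best[1].steps)
        picked.append(best[1])
        chosen.append(best)
    chosen.sort(key=lambda c: -c[0])  # most smooth-like first (S1), down
    return [s for _, s in chosen]


def build_family(
    sequences: dict[str, Sequence[int]] | None = None,
    temporal_frequency: float = 2.0,
    n_cycles: int = 10,
    cp_phases: tuple[float, float] = (0.0, np.pi / 2),
    corr_ceiling: float = 0.5,
) -> list[StimulusSpec]:
    """Assemble the 10-stimulus family F, B, S1..S6, CP1, CP2.

    ``sequences`` may override the scrambled members (keys ``"S1"``..
    ``"S6"``).  By default S6 is the fixed training sequence
    ``[8 3 6 2 7 4 1 5]`` and S1..S5 are chosen deterministically by
    :func:`select_scrambled_sequences`.  CP1 and CP2 are counterphase
    gratings at two spatial phases (default quadrature).
    """
    n_steps = 8
    overrides = {
        k: PhaseSequence(tuple(v)) for k, v in (sequences or {}).items()
    }
    s6 = overrides.get("S6", PhaseSequence(DEFAULT_S6_STEPS))
    scrambled: dict[str, PhaseSequence] = {"S6": s6}
    missing = [f"S{i}" for i in range(1, 6) if f"S{i}" not in overrides]
    if missing:
        auto = select_scrambled_sequences(
            n_select=len(missing),
            corr_ceiling=corr_ceiling,
            anchors=[s6] + [overrides[k] for k in overrides if k != "S6"],
            n_steps=n_steps,
        )
        for label, seq in zip(missing, auto):
            scrambled[label] = seq
    for i in range(1, 6):
        lab = f"S{i}"
        if lab in overrides:
            scrambled[lab] = overrides[lab]
    # contract: no selected scrambled sequence may exceed the ceiling
    for lab, seq in scrambled.items():
        if lab not in overrides:
            _, _, cavg = smooth_motion_metrics(seq)
            if cavg > corr_ceiling:
                raise ValueError(
                    f"selected sequence {lab}={seq} exceeds the smooth-"
                    f"correlation ceiling {corr_ceiling}"
                )
    kw = dict(temporal_frequency=temporal_frequency, n_cycles=n_cycles)
    family = [
        StimulusSpec(label="F", sequence=forward_sequence(n_steps), **kw),
        StimulusSpec(label="B", sequence=backward_sequence(n_steps), **kw),
    ]
    family += [
        StimulusSpec(label=f"S{i}", sequence=scrambled[f"S{i}"], **kw)
        for i in range(1, 7)
    ]
    family += [
        StimulusSpec(
            label="CP1", kind="counterphase",
            spatial_phase_offset=cp_phases[0], **kw
        ),
        StimulusSpec(
            label="CP2", kind="counterphase",
            spatial_phase_offset=cp_phases[1], **kw
        ),
    ]
    return family


# ---------------------------------------------------------------------------
# Family config I/O
# ---------------------------------------------------------------------------


def load_family(path: str | Path) -> list[StimulusSpec]:
    """Load a family from a YAML or JSON config file.

    Recognized keys: ``sequences`` (mapping label -> list of ints),
    ``temporal_frequency``, ``n_cycles``, ``cp_phases`` (two floats,
    radians), ``corr_ceiling``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text) or {}
    else:
        cfg = json.loads(text)
    kwargs = {}
    for key in ("sequences", "temporal_frequency", "n_cycles", "corr_ceiling"):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "cp_phases" in cfg:
        kwargs["cp_phases"] = tuple(cfg["cp_phases"])
    return build_family(**kwargs)


def save_family(family: list[StimulusSpec], path: str | Path) -> None:
    """Write a family back out as YAML/JSON (sequences and timing only)."""
    cfg = {
        "sequences": {
            s.label: list(s.sequence.steps)
            for s in family
            if s.kind == "sequence" and s.label not in ("F", "B")
        },
        "temporal_frequency": family[0].temporal_frequency,
        "n_cycles": family[0].n_cycles,
        "cp_phases": [
            s.spatial_phase_offset for s in family if s.kind == "counterphase"
        ],
    }
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2))
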