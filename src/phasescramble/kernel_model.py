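"""Ideal linear kernels and their response vectors to the stimulus family.

An ideal kernel for stimulus X is the space-time receptive-field profile
that maximally drives a linear neuron when X is shown: the stimulus's own
one-cycle X-T movie reversed in time.  The response of a kernel to any
stimulus is the peak of the circular cross-correlation between the kernel
and the stimulus movie over temporal lags, normalized so that the kernel's
response to its preferred stimulus is 1.  Negative responses are rectified
to zero by default, consistent with firing-rate semantics.

The 10x10 matrix of every kernel's response to every family stimulus is
the referent set for the Response Projection Index.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .stimulus_design import (
    DEFAULT_SPATIAL_SAMPLES,
    StimulusMovie,
    StimulusSpec,
    build_family,
    render_movie,
)

__all__ = [
    "Kernel",
    "make_kernel",
    "kernel_response",
    "kernel_response_matrix",
    "default_kernel_matrix",
]


@dataclass(frozen=True)
class Kernel:
    """Ideal receptive-field kernel for one stimulus.

    ``profile`` is the preferred stimulus's one-cycle movie reversed in
    time; ``self_response`` is the raw (unnormalized) peak response to the
    preferred stimulus, used to normalize responses to 1 on the diagonal.
    """

    label: str
    profile: np.ndarray  # (n_steps, spatial_samples), time-reversed movie
    preferred_label: str
    self_response: float


def _one_cycle(spec: StimulusSpec, spatial_samples: int) -> np.ndarray:
    return render_movie(spec, spatial_samples, n_cycles=1).frames


def _raw_response(profile: np.ndarray, movie: np.ndarray) -> float:
    """Peak over circular temporal lags of the kernel-stimulus correlation.

    A linear neuron's output is the convolution of its space-time kernel
    with the stimulus; at lag ``t`` that is the frame-wise product of the
    time-reversed kernel with the stimulus shifted by ``t``.  Since the
    kernel profile is itself stored time-reversed, re-reversing it
    recovers the preferred movie, which is then slid over all circular
    temporal offsets of the stimulus cycle.
    """
    if profile.shape != movie.shape:
        raise ValueError(
            f"kernel/stimulus sampling mismatch: {profile.shape} vs "
            f"{movie.shape}"
        )
    matched = profile[::-1]
    n = movie.shape[0]
    return max(
        float(np.sum(matched * np.roll(movie, -lag, axis=0)))
        for lag in range(n)
    )


def make_kernel(
    spec: StimulusSpec, spatial_samples: int = DEFAULT_SPATIAL_SAMPLES
) -> Kernel:
    """Ideal kernel for ``spec``: its one-cycle movie reversed in time."""
    movie = _one_cycle(spec, spatial_samples)
    profile = movie[::-1].copy()
    return Kernel(
        label=f"K{spec.label}",
        profile=profile,
        preferred_label=spec.label,
        self_response=_raw_response(profile, movie),
    )


def kernel_response(
    kernel: Kernel,
    stimulus: "StimulusSpec | StimulusMovie | np.ndarray",
    rectify: bool = True,
    spatial_samples: int = DEFAULT_SPATIAL_SAMPLES,
) -> float:
    """Normalized response of an ideal kernel to a stimulus.

    The peak aligned correlation is divided by the kernel's response to
    its preferred stimulus, so a kernel responds 1 to its own stimulus.
    With ``rectify`` (default) negative responses clamp to 0.
    """
    if isinstance(stimulus, StimulusSpec):
        movie = _one_cycle(stimulus, spatial_samples)
    elif isinstance(stimulus, StimulusMovie):
        movie = stimulus.frames[: kernel.profile.shape[0]]
    else:
        movie = np.asarray(stimulus, dtype=float)
    if kernel.self_response <= 0:
        raise ValueError(
            f"kernel {kernel.label} has non-positive self response; cannot "
            "normalize"
        )
    r = _raw_response(kernel.profile, movie) / kernel.self_response
    if rectify:
        r = max(r, 0.0)
    return r


def kernel_response_matrix(
    family: list[StimulusSpec],
    rectify: bool = True,
    spatial_samples: int = DEFAULT_SPATIAL_SAMPLES,
) -> pd.DataFrame:
    """10x10 ideal-response matrix: rows = kernels KX, columns = stimuli X.

    Row ``KX`` is the ideal response vector of a hypothetical neuron
    optimized for stimulus X.  The diagonal is exactly 1 by normalization.
    """
    labels = [s.label for s in family]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate stimulus labels in family: {labels}")
    kernels = [make_kernel(s, spatial_samples) for s in family]
    movies = [_one_cycle(s, spatial_samples) for s in family]
    values = np.empty((len(family), len(family)))
    for i, k in enumerate(kernels):
        for j, m in enumerate(movies):
            if i == j:
                values[i, j] = 1.0
                continue
            values[i, j] = kernel_response(k, m, rectify=rectify)
    return pd.DataFrame(
        values, index=[k.label for k in kernels], columns=labels
    )


@lru_cache(maxsize=1)
def _default_kernel_matrix_cached() -> pd.DataFrame:
    return kernel_response_matrix(build_family())


def default_kernel_matrix() -> pd.DataFrame:
    """Kernel response matrix of the default 10-stimulus family (cached)."""
    return _default_kernel_matrix_cached().copy()
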