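"""Seeded synthetic data with the statistical structure the pipeline assumes.

Three layers of emulation:

* **Cells.** A simulated neuron's 10-stimulus tuning is a noisy mixture of
  the ideal-kernel response vectors: its mean response to stimulus j is
  ``gain * sum_k w_k M[k, j]`` for mixture weights w on the 10 kernels,
  with additive Gaussian trial noise; blank trials are noise only.
  Direction tuning trials are drawn from the double-Gaussian curve with
  ``Rn = Rp * (1 - DI_true)``.

* **Animals.** An animal is a before population and an after population of
  such cells plus maturity covariates.  In the *instructive* regime,
  training shifts the after population's mixture weights toward the
  trained kernel (raising RPI toward the trained stimulus) while direction
  selectivity does not increase.  In the *permissive* regime the mixture
  weights stay put and instead the direction-tuning generator's DI is
  scaled up, emulating a developmentally typical increase in direction
  selectivity.

* **Fluorescence.** Trial dF/F values can be rendered as GCaMP-like
  fluorescence traces: a baseline-scaled transient that rises with a fast
  time constant during the 5 s stimulus and decays exponentially through
  the interstimulus interval, sampled at the slow imaging frame rate.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize

from .response_extraction import BLANK_LABEL, TraceRecording
from .tuning_metrics import (
    DirectionTrialSet,
    direction_index,
    double_gaussian,
    fit_double_gaussian,
    hotelling_orientation_test,
    orientation_selectivity_1mcv,
    response_projection_index,
)
from .population_analysis import AnimalRecord

__all__ = [
    "SimCellSpec",
    "SimAnimalSpec",
    "SimEpoch",
    "simulate_cell_responses",
    "simulate_direction_trials",
    "simulate_animal",
    "simulate_fluorescence_traces",
    "score_epoch",
    "calibrate_offset_for_osi",
]

DEFAULT_ANGLES = np.arange(8) * 45.0


@dataclass(frozen=True)
class SimCellSpec:
    """Generator parameters for one simulated cell's family responses."""

    mixture_weights: np.ndarray  # 10-vector, nonnegative, sums to 1
    gain: float = 0.3  # dF/F scale of the ideal response
    noise_sd: float = 0.03  # additive trial noise on dF/F
    n_trials: int = 8

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        object.__setattr__(self, "mixture_weights", w)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must be >= 0 and sum to 1")
        if self.gain <= 0 or self.noise_sd < 0 or self.n_trials < 1:
            raise ValueError("invalid gain / noise_sd / n_trials")


def simulate_cell_responses(
    spec: SimCellSpec, M: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Trial dF/F responses of one kernel-mixture cell to the family.

    Returns a long DataFrame (stimulus, trial, dff) including blank
    trials (noise only).  Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    means = spec.gain * (spec.mixture_weights @ M.to_numpy(dtype=float))
    labels = list(M.columns)
    rows = []
    for label, mu in zip(labels, means):
        draws = mu + rng.normal(0.0, spec.noise_sd, size=spec.n_trials)
        rows += [
            {"stimulus": label, "trial": t, "dff": float(v)}
            for t, v in enumerate(draws)
        ]
    blanks = rng.normal(0.0, spec.noise_sd, size=spec.n_trials)
    rows += [
        {"stimulus": BLANK_LABEL, "trial": t, "dff": float(v)}
        for t, v in enumerate(blanks)
    ]
    return pd.DataFrame(rows)


def simulate_direction_trials(
    theta_pref: float,
    di_true: float,
    sigma: float = 30.0,
    C: float = 0.05,
    gain: float = 0.3,
    noise_sd: float = 0.03,
    n_angles: int = 8,
    n_trials: int = 8,
    seed: int = 0,
) -> DirectionTrialSet:
    """Direction-sweep trials drawn from the double-Gaussian curve.

    The preferred-direction amplitude is ``gain`` (Rp) and the null lobe
    is ``Rn = Rp * (1 - di_true)``, so ``di_true`` is the direction index
    of the noiseless generator.  Blank trials are noise only.
    """
    if not 0.0 <= di_true <= 1.0:
        raise ValueError("di_true must lie in [0, 1]")
    if sigma <= 0 or gain <= 0 or noise_sd < 0:
        raise ValueError("invalid sigma / gain / noise_sd")
    if n_angles < 4 or n_trials < 1:
        raise ValueError("need >= 4 angles and >= 1 trial")
    rng = np.random.default_rng(seed)
    angles = np.arange(n_angles) * (360.0 / n_angles)
    means = double_gaussian(
        angles, C, gain, gain * (1.0 - di_true), theta_pref, sigma
    )
    responses = means + rng.normal(0.0, noise_sd, size=(n_trials, n_angles))
    blank = rng.normal(0.0, noise_sd, size=n_trials)
    return DirectionTrialSet(angles_deg=angles, responses=responses,
                             blank=blank)


# ---------------------------------------------------------------------------
# Orientation-selectivity calibration
# ---------------------------------------------------------------------------


def calibrate_offset_for_osi(
    target_osi: float,
    sigma: float,
    di_true: float,
    n_angles: int = 8,
) -> float:
    """Untuned-offset-to-amplitude ratio C/Rp hitting a target 1-CV.

    The orientation selectivity (1 minus circular variance) of the
    noiseless double-Gaussian curve falls monotonically as the untuned
    offset C grows relative to the tuned amplitude Rp.  This solves for
    the ratio that attains ``target_osi``; if the target exceeds the
    zero-offset maximum for the given width, 0 is returned with a warning.
    """
    if not 0.0 <= target_osi < 1.0:
        raise ValueError("target_osi must lie in [0, 1)")
    angles = np.arange(n_angles) * (360.0 / n_angles)

    def osi_at(c: float) -> float:
        y = double_gaussian(angles, c, 1.0, 1.0 - di_true, 0.0, sigma)
        return orientation_selectivity_1mcv(angles, y, blank_mean=0.0)

    top = osi_at(0.0)
    if target_osi >= top:
        warnings.warn(
            f"target 1-CV {target_osi:.3f} exceeds the zero-offset maximum "
            f"{top:.3f} at sigma={sigma:g}; using offset 0"
        )
        return 0.0
    return float(
        optimize.brentq(lambda c: osi_at(c) - target_osi, 0.0, 1e3)
    )


# ---------------------------------------------------------------------------
# Whole-animal simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimAnimalSpec:
    """One synthetic animal: populations, covariates, training regime.

    ``training_effect`` (instructive regime only) linearly shifts the
    after population's mixture weights toward the trained kernel;
    ``di_gain`` (permissive regime only) raises the after population's
    generated direction index.  ``di_baseline`` is the mean DI of the
    before population; instructive training nudges it down by
    ``di_instructive_drop`` (training toward scrambled patterns does not
    increase smooth-motion direction selectivity).
    """

    animal_id: str = "sim"
    n_cells_before: int = 100
    n_cells_after: int = 100
    eo: float = 0.0  # days since eye-opening; 0 = opened prematurely
    age: float = 30.0  # postnatal days
    initial_osi_target: float = 0.2
    trained_stimulus: str = "S4"
    training_effect: float = 0.5
    regime: Literal["instructive", "permissive"] = "instructive"
    seed: int = 0
    gain: float = 0.3
    noise_sd: float = 0.03
    n_trials: int = 8
    n_angles: int = 8
    di_baseline: float = 0.25
    di_gain: float = 0.25
    di_instructive_drop: float = 0.05
    di_sd: float = 0.1
    sigma_mean: float = 30.0
    sigma_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.regime not in ("instructive", "permissive"):
            raise ValueError(f"invalid regime {self.regime!r}")
        if not 0.0 <= self.training_effect <= 1.0:
            raise ValueError("training_effect must lie in [0, 1]")
        if self.eo < 0:
            raise ValueError("eo cannot be negative")


@dataclass
class SimEpoch:
    """One imaging epoch: family trial table plus direction sweeps."""

    family: pd.DataFrame  # columns cell_id, stimulus, trial, dff
    direction: dict[str, DirectionTrialSet]
    epoch: str  # 'before' | 'after'


def _base_weight_alpha(labels: list[str]) -> np.ndarray:
    """Dirichlet concentration of the naive population's kernel mixture.

    Immature cortex responds like typical V1: weight favors the smooth-
    motion and counterphase kernels over the scrambled ones.
    """
    return np.array(
        [1.5 if lab in ("F", "B", "CP1", "CP2") else 0.5 for lab in labels]
    )


def _simulate_epoch(
    spec: SimAnimalSpec,
    M: pd.DataFrame,
    rng: np.random.Generator,
    epoch: str,
    n_cells: int,
) -> SimEpoch:
    labels = list(M.columns)
    alpha = _base_weight_alpha(labels)
    trained_idx = labels.index(spec.trained_stimulus)
    one_hot = np.zeros(len(labels))
    one_hot[trained_idx] = 1.0

    if epoch == "after":
        if spec.regime == "instructive":
            di_mean = spec.di_baseline - spec.di_instructive_drop
        else:
            di_mean = spec.di_baseline + spec.di_gain
    else:
        di_mean = spec.di_baseline

    fam_frames = []
    direction: dict[str, DirectionTrialSet] = {}
    for i in range(n_cells):
        cell_id = f"{spec.animal_id}_{epoch}_{i:04d}"
        w = rng.dirichlet(alpha)
        if epoch == "after" and spec.regime == "instructive":
            w = (1.0 - spec.training_effect) * w + spec.training_effect * one_hot
        gain_i = spec.gain * rng.uniform(0.7, 1.3)
        cell = SimCellSpec(
            mixture_weights=w, gain=gain_i, noise_sd=spec.noise_sd,
            n_trials=spec.n_trials,
        )
        fam = simulate_cell_responses(
            cell, M, seed=int(rng.integers(2**31))
        )
        fam.insert(0, "cell_id", cell_id)
        fam_frames.append(fam)

        di = float(np.clip(rng.normal(di_mean, spec.di_sd), 0.0, 1.0))
        sigma = float(np.clip(rng.normal(spec.sigma_mean, spec.sigma_sd),
                              15.0, 60.0))
        osi_i = float(np.clip(
            rng.normal(spec.initial_osi_target, 0.05), 0.02, 0.95
        ))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c_ratio = calibrate_offset_for_osi(osi_i, sigma, di,
                                               spec.n_angles)
        direction[cell_id] = simulate_direction_trials(
            theta_pref=float(rng.uniform(0.0, 360.0)),
            di_true=di,
            sigma=sigma,
            C=c_ratio * gain_i,
            gain=gain_i,
            noise_sd=spec.noise_sd,
            n_angles=spec.n_angles,
            n_trials=spec.n_trials,
            seed=int(rng.integers(2**31)),
        )
    return SimEpoch(
        family=pd.concat(fam_frames, ignore_index=True),
        direction=direction,
        epoch=epoch,
    )


def score_epoch(
    epoch: SimEpoch,
    M: pd.DataFrame,
    trained_stimulus: str,
    alpha: float = 0.05,
    n_restarts: int = 2,
    compute_di: bool = True,
) -> pd.DataFrame:
    """Per-cell pipeline statistics for one simulated epoch.

    Returns one row per cell with the mean-response RPI(F vs trained),
    the 1-CV orientation index, the Hotelling gate p-value and, for cells
    passing the gate, the fitted direction index (``compute_di=False``
    skips the direction fits when only the RPI is needed).
    """
    means = (
        epoch.family[epoch.family["stimulus"] != BLANK_LABEL]
        .groupby(["cell_id", "stimulus"])["dff"]
        .mean()
        .unstack("stimulus")
        .reindex(columns=list(M.columns))
    )
    rows = []
    for cell_id, resp in means.iterrows():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rpi = response_projection_index(
                resp.to_numpy(dtype=float), "KF", f"K{trained_stimulus}", M
            )
        di = float("nan")
        osi = float("nan")
        p_hot = float("nan")
        trials = epoch.direction.get(cell_id)
        if trials is not None:
            osi = orientation_selectivity_1mcv(
                trials.angles_deg, trials.mean_responses, trials.blank_mean
            )
            p_hot = hotelling_orientation_test(trials)
            if compute_di and np.isfinite(p_hot) and p_hot < alpha:
                fit = fit_double_gaussian(trials, n_restarts=n_restarts)
                if fit.success:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        di = direction_index(fit)
        rows.append(
            {
                "cell_id": cell_id,
                "rpi_f_vs_trained": rpi,
                "osi_1mcv": osi,
                "hotelling_p": p_hot,
                "di": di,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def simulate_animal(
    spec: SimAnimalSpec, M: pd.DataFrame, score: bool = True
) -> tuple[SimEpoch, SimEpoch, AnimalRecord]:
    """Simulate one animal's before and after populations.

    Returns the two epochs and an :class:`AnimalRecord` whose
    ``delta_rpi`` and ``delta_di`` are point estimates computed by running
    the measurement pipeline (mean-response RPI and Hotelling-gated
    double-Gaussian DI) on the simulated populations, and whose
    ``initial_osi`` is the measured mean 1-CV of the before population.
    With ``score=False`` the scoring pass is skipped (callers that score
    the epochs themselves avoid the duplicate work) and the record's
    measured fields are NaN.
    """
    if spec.trained_stimulus not in M.columns:
        raise ValueError(
            f"trained stimulus {spec.trained_stimulus!r} not in family"
        )
    rng = np.random.default_rng(spec.seed)
    before = _simulate_epoch(spec, M, rng, "before", spec.n_cells_before)
    after = _simulate_epoch(spec, M, rng, "after", spec.n_cells_after)
    if not score:
        record = AnimalRecord(
            animal_id=spec.animal_id, age=spec.age, eo=spec.eo,
            initial_osi=float("nan"),
            trained_stimulus=spec.trained_stimulus,
            delta_rpi=float("nan"), delta_di=float("nan"),
        )
        return before, after, record
    stats_b = score_epoch(before, M, spec.trained_stimulus)
    stats_a = score_epoch(after, M, spec.trained_stimulus)
    record = AnimalRecord(
        animal_id=spec.animal_id,
        age=spec.age,
        eo=spec.eo,
        initial_osi=float(stats_b["osi_1mcv"].mean()),
        trained_stimulus=spec.trained_stimulus,
        delta_rpi=float(
            stats_a["rpi_f_vs_trained"].mean()
            - stats_b["rpi_f_vs_trained"].mean()
        ),
        delta_di=float(stats_a["di"].mean() - stats_b["di"].mean()),
    )
    return before, after, record


# ---------------------------------------------------------------------------
# Fluorescence trace synthesis
# ---------------------------------------------------------------------------


def simulate_fluorescence_traces(
    responses: pd.DataFrame,
    frame_interval: float = 1.5,
    tau_decay: float = 1.0,
    baseline: float = 100.0,
    seed: int = 0,
    tau_rise: float = 0.2,
    stim_duration: float = 5.0,
    isi: float = 5.0,
    trace_noise_sd: float = 0.0,
    dt: float = 0.05,
) -> TraceRecording:
    """Render trial dF/F values as slow-frame-rate fluorescence traces.

    ``responses`` is a long table (cell_id optional, stimulus, trial, dff).
    Presentations are scheduled trial-by-trial in a seeded shuffled order,
    each 5 s long with an interstimulus interval of ``isi`` seconds.  The
    per-cell transient follows first-order kinetics: it relaxes toward the
    programmed dF/F with time constant ``tau_rise`` while the stimulus is
    on and decays back to zero with ``tau_decay`` afterwards.  The trace
    is ``baseline * (1 + transient + noise)`` sampled at frame midpoints
    every ``frame_interval`` seconds.
    """
    if tau_decay <= 0 or tau_rise <= 0:
        raise ValueError("time constants must be positive")
    if isi < 3.0:
        raise ValueError(
            "interstimulus interval must allow a 3 s baseline window"
        )
    df = responses.copy()
    if "cell_id" not in df.columns:
        df.insert(0, "cell_id", "cell_0")
    cells = list(dict.fromkeys(df["cell_id"]))
    rng = np.random.default_rng(seed)

    pres = df[["stimulus", "trial"]].drop_duplicates().reset_index(drop=True)
    order = rng.permutation(len(pres))
    pres = pres.iloc[order].reset_index(drop=True)
    onsets = isi + np.arange(len(pres)) * (stim_duration + isi)
    schedule = pd.DataFrame(
        {
            "label": pres["stimulus"],
            "onset": onsets,
            "duration": stim_duration,
        }
    )
    total = float(onsets[-1] + stim_duration + isi)
    grid = np.arange(0.0, total, dt)

    lookup = df.set_index(["cell_id", "stimulus", "trial"])["dff"]
    traces = {}
    for cell in cells:
        target = np.zeros_like(grid)
        for onset, (_, row) in zip(onsets, pres.iterrows()):
            key = (cell, row["stimulus"], row["trial"])
            amp = float(lookup.get(key, 0.0))
            on = (grid >= onset) & (grid < onset + stim_duration)
            target[on] = amp
        r = np.zeros_like(grid)
        for i in range(1, grid.size):
            tau = tau_rise if target[i] != r[i - 1] and abs(
                target[i]
            ) > abs(r[i - 1]) else tau_decay
            r[i] = r[i - 1] + dt * (target[i] - r[i - 1]) / tau
        traces[cell] = r

    frame_times = np.arange(
        frame_interval / 2.0, total, frame_interval
    )
    idx = np.clip((frame_times / dt).astype(int), 0, grid.size - 1)
    data = {}
    for cell in cells:
        sampled = traces[cell][idx]
        noise = (
            rng.normal(0.0, trace_noise_sd, size=sampled.size)
            if trace_noise_sd > 0
            else 0.0
        )
        data[cell] = baseline * (1.0 + sampled + noise)
    return TraceRecording(
        times=frame_times,
        traces=pd.DataFrame(data),
        schedule=schedule,
    )
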