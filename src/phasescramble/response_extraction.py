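"""From fluorescence traces to trial-level dF/F response tables.

Calcium-imaging frames arrive slowly (one frame every ~1.3-1.8 s) relative
to the 5 s stimulus and 5-10 s interstimulus interval, so frames are
assigned to analysis windows by their acquisition midpoint.  The response
to one stimulus presentation is

    dF/F = (F_stim - F_base) / F_base

where F_stim is the mean fluorescence over the response window (default
[0, 5] s after onset; a [0, 7] s window is available for cells with slow,
delayed responses) and F_base is the mean over the final 3 s of the
preceding interstimulus interval.  Cells are gated as visually responsive
by a one-way ANOVA across all stimulus conditions plus the blank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TraceRecording",
    "compute_dff",
    "responsiveness_test",
    "BLANK_LABEL",
]

BLANK_LABEL = "blank"


@dataclass
class TraceRecording:
    """Per-ROI fluorescence time series plus the stimulus schedule.

    ``times`` are frame acquisition midpoints in seconds (strictly
    increasing); ``traces`` has one column per ROI/cell; ``schedule`` has
    columns ``label``, ``onset`` and ``duration`` (seconds), with onsets
    strictly increasing.  Blank presentations use the label ``"blank"``.
    """

    times: np.ndarray
    traces: pd.DataFrame
    schedule: pd.DataFrame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.traces):
            raise ValueError("times must align with trace rows")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        required = {"label", "onset", "duration"}
        if not required.issubset(self.schedule.columns):
            raise ValueError(f"schedule needs columns {sorted(required)}")
        onsets = self.schedule["onset"].to_numpy(dtype=float)
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")

    @property
    def cell_ids(self) -> list:
        return list(self.traces.columns)


def _window_mean(
    rec: TraceRecording, t0: float, t1: float
) -> "np.ndarray | None":
    """Mean fluorescence per cell over frames with midpoint in [t0, t1)."""
    mask = (rec.times >= t0) & (rec.times < t1)
    if not mask.any():
        return None
    return rec.traces.to_numpy(dtype=float)[mask].mean(axis=0)


def compute_dff(
    rec: TraceRecording,
    response_window: tuple[float, float] = (0.0, 5.0),
    baseline_window: float = 3.0,
) -> pd.DataFrame:
    """Trial-level dF/F table from a recording and its schedule.

    Returns a long DataFrame with columns ``cell_id``, ``stimulus``,
    ``trial`` (0-based presentation index within each stimulus) and
    ``dff``.  Trials whose baseline fluorescence is non-positive for a
    cell are dropped and logged rather than imputed.

    Parameters
    ----------
    response_window : (t0, t1)
        Seconds after stimulus onset over which F_stim is averaged.
        ``(0, 5)`` matches the stimulus-on period; ``(0, 7)`` captures
        slowly decaying responses.
    baseline_window : float
        Seconds of interstimulus interval immediately before onset over
        which F_base is averaged (default 3 s).
    """
    t0, t1 = response_window
    if t1 <= t0:
        raise ValueError("response window must have positive length")
    if baseline_window <= 0:
        raise ValueError("baseline window must be positive")
    rows: list[dict] = []
    n_dropped = 0
    trial_counter: dict[str, int] = {}
    for _, pres in rec.schedule.iterrows():
        label = pres["label"]
        onset = float(pres["onset"])
        trial = trial_counter.get(label, 0)
        trial_counter[label] = trial + 1
        f_base = _window_mean(rec, onset - baseline_window, onset)
        if f_base is None:
            raise ValueError(
                f"no baseline frames before onset at {onset:g} s "
                f"(stimulus {label!r})"
            )
        f_stim = _window_mean(rec, onset + t0, onset + t1)
        if f_stim is None:
            raise ValueError(
                f"no response frames for stimulus {label!r} at {onset:g} s"
            )
        for cell, fb, fs in zip(rec.cell_ids, f_base, f_stim):
            if fb <= 0:
                n_dropped += 1
                logger.warning(
                    "dropping trial %d of %r for cell %r: non-positive "
                    "baseline %.4g", trial, label, cell, fb,
                )
                continue
            rows.append(
                {
                    "cell_id": cell,
                    "stimulus": label,
                    "trial": trial,
                    "dff": (fs - fb) / fb,
                }
            )
    if n_dropped:
        logger.info("dropped %d invalid trials (non-positive baseline)",
                    n_dropped)
    return pd.DataFrame(rows, columns=["cell_id", "stimulus", "trial", "dff"])


def responsiveness_test(
    table: pd.DataFrame, cell_id, alpha: float = 0.05
) -> tuple[float, bool]:
    """Visual-responsiveness gate: one-way ANOVA over all conditions.

    Groups the cell's trial dF/F values by stimulus (the blank condition
    included like any other) and runs a classical fixed-effects one-way
    ANOVA.  The cell is responsive when p < ``alpha``.  If every group has
    zero within-group variance the F statistic is undefined; the p-value
    is NaN and the cell is flagged non-responsive with a warning.
    """
    sub = table[table["cell_id"] == cell_id]
    if sub.empty:
        raise KeyError(f"cell {cell_id!r} not in table")
    groups = [g["dff"].to_numpy(dtype=float)
              for _, g in sub.groupby("stimulus")]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 stimulus conditions")
    if any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs at least 2 trials per condition")
    if all(np.ptp(g) == 0 for g in groups):
        warnings.warn(
            f"cell {cell_id!r}: zero within-group variance everywhere; "
            "ANOVA undefined"
        )
        return float("nan"), False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        _, p = stats.f_oneway(*groups)
    p = float(p)
    return p, bool(np.isfinite(p) and p < alpha)
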