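"""Population-level inference for before/after training comparisons.

The central tool is a bootstrap difference analysis: with N cells measured
before training and M after, each of 10,000 replicates resamples N cells
from the before population and M from the after population (both with
replacement) and records the difference of means.  The 5th and 95th
percentiles of the replicate distribution are reported as confidence
bounds, and the change is called significant when the interval excludes
zero (the positive direction when the lower bound exceeds zero; the
symmetric negative case is flagged as a significant decrease).

Also here: per-animal covariate correlations (Pearson, t-based p-value,
n - 2 degrees of freedom), unpaired two-sample t-tests between animal
groups, the joint PCA projection of 10-d mean response vectors with the
ideal-kernel response vectors, and the per-reference-stimulus change in
RPI toward the trained stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .tuning_metrics import response_projection_index

__all__ = [
    "BootstrapResult",
    "AnimalRecord",
    "bootstrap_delta",
    "covariate_correlation",
    "group_ttest",
    "pca_project",
    "delta_rpi_by_stimulus",
]


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap difference of means with percentile confidence bounds."""

    mean_delta: float
    ci_low: float  # 5th percentile of the replicate distribution
    ci_high: float  # 95th percentile
    n_boot: int
    seed: int
    significant: bool
    direction: "str | None"  # 'positive' | 'negative' | None


@dataclass
class AnimalRecord:
    """Per-animal covariates and training outcome summary."""

    animal_id: str
    age: float  # postnatal days
    eo: float  # days since eye-opening (0 = opened prematurely)
    initial_osi: float  # mean 1-CV before training
    trained_stimulus: str  # S4 or S6
    delta_rpi: float  # mean RPI(F vs ST) after - before
    delta_di: float  # mean DI after - before

    def __post_init__(self) -> None:
        if self.eo < 0:
            raise ValueError("days since eye-opening cannot be negative")


def bootstrap_delta(
    before: np.ndarray,
    after: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the change (after minus before) in a population mean.

    Each replicate draws ``len(before)`` values from the before population
    and ``len(after)`` values from the after population, both with
    replacement, and records the difference of resampled means.  The mean
    of the replicate distribution is the reported effect; its 5th/95th
    percentiles (linear interpolation between order statistics) are the
    confidence bounds.  Bit-identical for a fixed seed and n_boot.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size == 0 or after.size == 0:
        raise ValueError("both populations must be non-empty")
    rng = np.random.default_rng(seed)
    idx_b = rng.integers(0, before.size, size=(n_boot, before.size))
    idx_a = rng.integers(0, after.size, size=(n_boot, after.size))
    deltas = after[idx_a].mean(axis=1) - before[idx_b].mean(axis=1)
    lo, hi = np.percentile(deltas, [5.0, 95.0])
    direction = None
    if lo > 0:
        direction = "positive"
    elif hi < 0:
        direction = "negative"
    return BootstrapResult(
        mean_delta=float(deltas.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        significant=direction is not None,
        direction=direction,
    )


def covariate_correlation(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of a per-animal covariate with a per-animal
    effect, with the standard t-based p-value (DF = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined: zero variance")
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def group_ttest(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float]:
    """Unpaired two-sample t-test (pooled variance) between animal groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):
        warnings.warn("t statistic undefined (degenerate variance)")
    return float(t), float(p)


def pca_project(
    animal_means: "pd.DataFrame | np.ndarray",
    M: pd.DataFrame,
    fit_on: str = "joint",
) -> pd.DataFrame:
    """Project 10-d mean response vectors and kernel rows to two PCs.

    All vectors (animal means and the ideal-kernel response rows of ``M``)
    are unit-normalized, jointly mean-centered, and projected onto the top
    two principal components.  With ``fit_on='joint'`` (default) the
    components are fit to animal means and kernel rows together; with
    ``'kernels'`` they are fit to the kernel rows only and the animal
    means merely transformed.  The sign of each component is fixed so that
    its largest-magnitude loading is positive, making the projection
    deterministic.

    Returns a DataFrame with columns ``label``, ``kind`` ('animal' or
    'kernel'), ``pc1`` and ``pc2``.
    """
    if isinstance(animal_means, pd.DataFrame):
        labels = [str(i) for i in animal_means.index]
        A = animal_means.to_numpy(dtype=float)
    else:
        A = np.atleast_2d(np.asarray(animal_means, dtype=float))
        labels = [f"animal_{i}" for i in range(A.shape[0])]
    if A.shape[0] < 2:
        raise ValueError("need at least 2 input vectors")
    K = M.to_numpy(dtype=float)
    if A.shape[1] != K.shape[1]:
        raise ValueError("animal means and kernel rows disagree in dimension")

    def unit_rows(X: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot unit-normalize a zero vector")
        return X / norms

    A, K = unit_rows(A), unit_rows(K)
    joint = np.vstack([A, K])
    fit_set = joint if fit_on == "joint" else K
    if fit_on not in ("joint", "kernels"):
        raise ValueError("fit_on must be 'joint' or 'kernels'")
    center = fit_set.mean(axis=0)
    if np.linalg.matrix_rank(fit_set - center) < 2:
        raise ValueError("fit set has rank < 2; cannot extract 2 components")
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(fit_set - center)
    components = pca.components_.copy()
    for i in range(2):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    coords = (joint - center) @ components.T
    return pd.DataFrame(
        {
            "label": labels + [str(i) for i in M.index],
            "kind": ["animal"] * A.shape[0] + ["kernel"] * K.shape[0],
            "pc1": coords[:, 0],
            "pc2": coords[:, 1],
        }
    )


def delta_rpi_by_stimulus(
    cells_before: pd.DataFrame,
    cells_after: pd.DataFrame,
    M: pd.DataFrame,
    trained: str,
) -> pd.Series:
    """Change in mean RPI(X vs trained) for every non-trained stimulus X.

    ``cells_before`` / ``cells_after`` are per-cell mean response tables
    (rows = cells, columns = the 10 stimulus labels).  For each reference
    stimulus X other than the trained one, the per-cell RPI(X vs trained)
    is averaged within each epoch and the after-minus-before difference
    returned.  The trained-vs-trained pair is excluded (0 by definition).
    Cells whose RPI is undefined are dropped with a warning.
    """
    stim_labels = list(M.columns)
    if trained not in stim_labels:
        raise ValueError(f"trained stimulus {trained!r} not in family")

    def epoch_means(cells: pd.DataFrame, ref: str) -> float:
        vals = []
        n_bad = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _, row in cells.iterrows():
                v = response_projection_index(
                    row[stim_labels].to_numpy(dtype=float), ref, trained, M
                )
                if np.isfinite(v):
                    vals.append(v)
                else:
                    n_bad += 1
        if n_bad:
            warnings.warn(f"dropped {n_bad} undefined RPI values for "
                          f"reference {ref!r}")
        if not vals:
            return float("nan")
        return float(np.mean(vals))

    out = {}
    for ref in stim_labels:
        if ref == trained:
            continue
        out[ref] = epoch_means(cells_after, ref) - epoch_means(
            cells_before, ref
        )
    return pd.Series(out, name=f"delta_rpi_vs_{trained}")
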