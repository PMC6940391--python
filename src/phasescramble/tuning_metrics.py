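"""Single-cell selectivity statistics.

Covers the statistics computed per neuron:

* Selectivity Index (SI): each stimulus's share of the summed response
  across the 10-stimulus family.
* Response Projection Index (RPI): a [-1, 1] statistic locating a cell's
  10-d response vector between the lines spanned by two ideal-kernel
  response vectors; RPI = (D1 - D2)/(D1 + D2) with D1, D2 the distances
  from the response to those lines.
* Orientation selectivity as 1 minus the circular variance in doubled-
  angle orientation space, on blank-subtracted responses.
* A one-sample Hotelling T^2 gate on the trial-wise orientation vectors,
  used to decide whether a cell is orientation tuned.
* A double-Gaussian fit to direction tuning curves, from which the
  direction index DI = (Rp - max(Rn, 0))/Rp is derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DirectionTrialSet",
    "DoubleGaussianFit",
    "CellTuning",
    "selectivity_index",
    "response_projection_index",
    "orientation_selectivity_1mcv",
    "hotelling_orientation_test",
    "ang_diff",
    "double_gaussian",
    "fit_double_gaussian",
    "direction_index",
    "tuning_half_width",
]


# ---------------------------------------------------------------------------
# Selectivity index
# ---------------------------------------------------------------------------


def selectivity_index(
    responses: "np.ndarray | pd.Series",
    stimulus: "int | str | None" = None,
    clamp_negative: bool = True,
) -> "np.ndarray | pd.Series | float":
    """SI(n) = R(S_n) / sum of responses over the stimulus family.

    With ``clamp_negative`` (default) negative mean responses are clamped
    to zero before normalization, following firing-rate semantics.  The SI
    vector sums to 1 whenever the denominator is positive.  If ``stimulus``
    is given (index or label for a Series), the single SI value is
    returned; otherwise the full vector.
    """
    is_series = isinstance(responses, pd.Series)
    r = np.asarray(responses, dtype=float)
    if clamp_negative:
        r = np.clip(r, 0.0, None)
    total = r.sum()
    if total <= 0:
        warnings.warn("SI undefined: non-positive total response")
        si = np.full_like(r, np.nan)
    else:
        si = r / total
    if is_series:
        si = pd.Series(si, index=responses.index)
        return si if stimulus is None else float(si[stimulus])
    if stimulus is None:
        return si
    return float(si[stimulus])


# ---------------------------------------------------------------------------
# Response projection index
# ---------------------------------------------------------------------------


def _referent_row(M: pd.DataFrame, ref: str) -> np.ndarray:
    """Resolve a referent kernel row by 'KX' or bare stimulus label 'X'."""
    if ref in M.index:
        return M.loc[ref].to_numpy(dtype=float)
    alt = f"K{ref}"
    if alt in M.index:
        return M.loc[alt].to_numpy(dtype=float)
    raise KeyError(f"referent {ref!r} not found in kernel matrix index")


def response_projection_index(
    R: "np.ndarray | pd.Series",
    ref_i: str,
    ref_j: str,
    M: pd.DataFrame,
) -> float:
    """RPI of a response vector relative to two ideal-kernel referents.

    D1 = ||R - (R.u1)u1|| with u1 the unit vector along the ideal response
    row of ``ref_i`` (likewise D2 / u2 for ``ref_j``), and
    RPI = (D1 - D2)/(D1 + D2).  A response identical to the first referent
    gives -1, identical to the second gives +1.  The statistic is invariant
    to positive rescaling of R and antisymmetric in the referents.

    Returns NaN (with a warning) for a zero response vector, collinear
    referents, or a response equidistant at zero distance.
    """
    r = np.asarray(R, dtype=float)
    v1 = _referent_row(M, ref_i)
    v2 = _referent_row(M, ref_j)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        warnings.warn("RPI undefined: zero referent row")
        return float("nan")
    u1, u2 = v1 / n1, v2 / n2
    if abs(abs(float(u1 @ u2)) - 1.0) < 1e-12:
        warnings.warn("RPI undefined: collinear referents")
        return float("nan")
    if not np.any(r):
        warnings.warn("RPI undefined: zero response vector")
        return float("nan")
    d1 = float(np.linalg.norm(r - (r @ u1) * u1))
    d2 = float(np.linalg.norm(r - (r @ u2) * u2))
    if d1 + d2 == 0:
        warnings.warn("RPI undefined: response collinear with both referents")
        return float("nan")
    return (d1 - d2) / (d1 + d2)


# ---------------------------------------------------------------------------
# Orientation selectivity and the Hotelling gate
# ---------------------------------------------------------------------------


@dataclass
class DirectionTrialSet:
    """Trial responses to a full direction sweep.

    ``angles_deg`` are equally spaced directions covering 0..360 degrees;
    ``responses`` is (n_trials, n_angles); ``blank`` holds blank-screen
    trial responses (may be empty).
    """

    angles_deg: np.ndarray
    responses: np.ndarray  # (n_trials, n_angles)
    blank: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        self.blank = np.asarray(self.blank, dtype=float)
        if self.responses.shape[1] != self.angles_deg.size:
            raise ValueError("responses must be (n_trials, n_angles)")
        if self.angles_deg.size >= 2:
            gaps = np.diff(np.sort(self.angles_deg))
            if not np.allclose(gaps, gaps[0]):
                raise ValueError("angles must be equally spaced")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def mean_responses(self) -> np.ndarray:
        return self.responses.mean(axis=0)

    @property
    def blank_mean(self) -> float:
        return float(self.blank.mean()) if self.blank.size else 0.0


def orientation_selectivity_1mcv(
    angles_deg: np.ndarray,
    responses: np.ndarray,
    blank_mean: float = 0.0,
) -> float:
    """1 - CirVar = |sum R(theta_k) exp(2i theta_k) / sum R(theta_k)|.

    Computed in orientation space (doubled angles) on blank-subtracted
    per-angle mean responses.  For nonnegative responses the value lies in
    [0, 1]: 0 for an isotropic cell, 1 for response at a single
    orientation.  Undefined (NaN) when the summed response is zero.
    """
    theta = np.deg2rad(np.asarray(angles_deg, dtype=float))
    r = np.asarray(responses, dtype=float) - blank_mean
    denom = r.sum()
    if denom == 0:
        warnings.warn("1-CirVar undefined: zero summed response")
        return float("nan")
    return float(np.abs(np.sum(r * np.exp(2j * theta)) / denom))


def hotelling_orientation_test(trials: DirectionTrialSet) -> float:
    """One-sample Hotelling T^2 p-value for significant orientation tuning.

    Each trial's responses are collapsed to the complex orientation vector
    sum_k R_t(theta_k) exp(2i theta_k); its real and imaginary parts form a
    2-d point per trial.  The test asks whether the mean of those points
    differs from the origin, via the exact T^2 -> F transform
    F = (n - p) / (p (n - 1)) * T^2 with p = 2.
    """
    if trials.n_trials < 3:
        raise ValueError("Hotelling test needs at least 3 trials")
    theta = np.deg2rad(trials.angles_deg)
    z = trials.responses @ np.exp(2j * theta)
    X = np.column_stack([z.real, z.imag])
    n, p = X.shape
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    try:
        t2 = float(n * mean @ np.linalg.solve(cov, mean))
    except np.linalg.LinAlgError:
        warnings.warn("Hotelling test undefined: singular trial covariance")
        return float("nan")
    if not np.isfinite(t2) or t2 < 0:
        warnings.warn("Hotelling test undefined: degenerate statistic")
        return float("nan")
    f_stat = (n - p) / (p * (n - 1)) * t2
    return float(stats.f.sf(f_stat, p, n - p))


# ---------------------------------------------------------------------------
# Double-Gaussian direction fit and DI
# ---------------------------------------------------------------------------


def ang_diff(x: np.ndarray) -> np.ndarray:
    """Wrap angular differences onto 0..180 degrees.

    min(|x|, |x - 360|, |x + 360|), vectorized.
    """
    x = np.asarray(x, dtype=float)
    return np.minimum.reduce([np.abs(x), np.abs(x - 360), np.abs(x + 360)])


def double_gaussian(
    theta: np.ndarray,
    C: float,
    r_pref: float,
    r_null: float,
    theta_pref: float,
    sigma: float,
) -> np.ndarray:
    """Direction tuning curve: offset plus Gaussians at the preferred and
    opposite (null) directions, with angular distances wrapped circularly."""
    theta = np.asarray(theta, dtype=float)
    dp = ang_diff(theta - theta_pref)
    dn = ang_diff(theta + 180 - theta_pref)
    return (
        C
        + r_pref * np.exp(-(dp**2) / (2 * sigma**2))
        + r_null * np.exp(-(dn**2) / (2 * sigma**2))
    )


@dataclass(frozen=True)
class DoubleGaussianFit:
    """Least-squares double-Gaussian fit to a direction tuning curve."""

    C: float
    r_pref: float
    r_null: float
    theta_pref: float  # degrees in [0, 360)
    sigma: float  # degrees
    sse: float
    success: bool

    @property
    def half_width(self) -> float:
        """Tuning half-width at half-height, sqrt(log 4) * sigma."""
        return tuning_half_width(self.sigma)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        return double_gaussian(
            theta, self.C, self.r_pref, self.r_null, self.theta_pref,
            self.sigma,
        )


def tuning_half_width(sigma: float) -> float:
    """Half-width at half-height of the fitted Gaussian lobe."""
    return float(np.sqrt(np.log(4.0)) * sigma)


_SIGMA_BOUNDS = (5.0, 90.0)


def fit_double_gaussian(
    trials: "DirectionTrialSet | None" = None,
    angles_deg: np.ndarray | None = None,
    mean_responses: np.ndarray | None = None,
    n_restarts: int = 5,
) -> DoubleGaussianFit:
    """Fit the double-Gaussian direction model to per-angle mean responses.

    Either a :class:`DirectionTrialSet` or explicit ``angles_deg`` and
    ``mean_responses`` may be given.  The fit is a bounded least-squares
    over (C, Rp, Rn, theta_pref, sigma), initialized at the peak-response
    angle with sigma = 30 degrees and C at the minimum response, and
    restarted from a deterministic grid of sigma values (and the
    180-degree-flipped preference) to avoid local minima; the lowest-SSE
    solution wins.  sigma is bounded to [5, 90] degrees.
    """
    if trials is not None:
        angles_deg = trials.angles_deg
        mean_responses = trials.mean_responses
    if angles_deg is None or mean_responses is None:
        raise ValueError("need a DirectionTrialSet or angles and means")
    theta = np.asarray(angles_deg, dtype=float)
    y = np.asarray(mean_responses, dtype=float)
    if theta.size < 5:
        raise ValueError("need at least 5 angles to fit 5 parameters")

    c0 = float(y.min())
    amp = float(y.max() - y.min())
    if amp == 0:
        amp = max(abs(c0), 1.0) * 1e-3
    peak = float(theta[int(np.argmax(y))])
    span = max(abs(y).max(), 1e-9)
    lower = np.array([c0 - 10 * span, 0.0, -10 * span, -360.0, _SIGMA_BOUNDS[0]])
    upper = np.array([y.max() + 10 * span, 20 * span, 20 * span, 720.0,
                      _SIGMA_BOUNDS[1]])

    def residuals(p: np.ndarray) -> np.ndarray:
        return double_gaussian(theta, *p) - y

    def jacobian(p: np.ndarray) -> np.ndarray:
        _, rp, rn, th, sg = p
        dp = ang_diff(theta - th)
        dn = ang_diff(theta + 180 - th)
        ep = np.exp(-(dp**2) / (2 * sg**2))
        en = np.exp(-(dn**2) / (2 * sg**2))
        # signed wrapped differences: d(ang_diff(x)^2)/dx = 2*wrap(x)
        wp = (theta - th + 180) % 360 - 180
        wn = (theta + 180 - th + 180) % 360 - 180
        d_th = rp * ep * wp / sg**2 + rn * en * wn / sg**2
        d_sg = (rp * ep * dp**2 + rn * en * dn**2) / sg**3
        return np.column_stack(
            [np.ones_like(theta), ep, en, d_th, d_sg]
        )

    sigma_grid = [30.0, 15.0, 45.0, 60.0, 75.0][: max(n_restarts, 1)]
    best: optimize.OptimizeResult | None = None
    for flip in (0.0, 180.0):
        # null-lobe estimate from the response opposite the assumed peak
        th0 = peak + flip
        opp = y[int(np.argmin(ang_diff(theta - (th0 + 180))))]
        for s0 in sigma_grid:
            p0 = np.array([c0, amp, max(float(opp) - c0, 0.0), th0, s0])
            p0 = np.clip(p0, lower, upper)
            try:
                res = optimize.least_squares(
                    residuals, p0, jac=jacobian, bounds=(lower, upper),
                    method="trf", max_nfev=2000,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        warnings.warn("double-Gaussian fit failed to converge")
        return DoubleGaussianFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False
        )
    C, rp, rn, th, sg = best.x
    # canonical orientation: preferred lobe carries the larger amplitude
    if rn > rp:
        rp, rn = rn, rp
        th = th + 180.0
    th = float(np.mod(th, 360.0))
    return DoubleGaussianFit(
        C=float(C), r_pref=float(rp), r_null=float(rn), theta_pref=th,
        sigma=float(sg), sse=float(2 * best.cost), success=bool(best.success),
    )


def direction_index(fit: "DoubleGaussianFit | tuple[float, float]") -> float:
    """DI = (Rp - max(Rn, 0)) / Rp from the double-Gaussian fit.

    The max constrains DI to be at most 1 (a suppressive null lobe counts
    as full direction selectivity).  Undefined (NaN) when Rp <= 0.
    """
    if isinstance(fit, DoubleGaussianFit):
        rp, rn = fit.r_pref, fit.r_null
    else:
        rp, rn = fit
    if not rp > 0:
        warnings.warn("DI undefined: non-positive preferred response")
        return float("nan")
    return (rp - max(rn, 0.0)) / rp


# ---------------------------------------------------------------------------
# Per-cell summary
# ---------------------------------------------------------------------------


@dataclass
class CellTuning:
    """Bundle of the single-cell statistics for one neuron."""

    si: "pd.Series | None" = None
    rpi: dict[tuple[str, str], float] = field(default_factory=dict)
    osi_1mcv: float = float("nan")
    hotelling_p: float = float("nan")
    fit: "DoubleGaussianFit | None" = None
    di: float = float("nan")


def characterize_cell(
    family_responses: "pd.Series | None" = None,
    direction_trials: "DirectionTrialSet | None" = None,
    M: "pd.DataFrame | None" = None,
    rpi_pairs: tuple[tuple[str, str], ...] = (("KF", "KB"),),
    alpha: float = 0.05,
    n_restarts: int = 5,
) -> CellTuning:
    """Compute all applicable statistics for one cell.

    ``family_responses`` are mean responses to the 10-stimulus family
    (Series indexed by stimulus label); ``direction_trials`` is an
    optional direction sweep.  The double-Gaussian fit (and hence DI) is
    only attempted when the Hotelling gate passes at ``alpha``.
    """
    out = CellTuning()
    if family_responses is not None:
        out.si = selectivity_index(family_responses)
        if M is not None:
            for pair in rpi_pairs:
                out.rpi[pair] = response_projection_index(
                    family_responses.to_numpy(), pair[0], pair[1], M
                )
    if direction_trials is not None:
        out.osi_1mcv = orientation_selectivity_1mcv(
            direction_trials.angles_deg,
            direction_trials.mean_responses,
            direction_trials.blank_mean,
        )
        out.hotelling_p = hotelling_orientation_test(direction_trials)
        if np.isfinite(out.hotelling_p) and out.hotelling_p < alpha:
            out.fit = fit_double_gaussian(
                direction_trials, n_restarts=n_restarts
            )
            if out.fit.success:
                out.di = direction_index(out.fit)
    return out
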