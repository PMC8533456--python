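"""Fixed-interval (Rauch-Tung-Striebel) smoothing of feature trajectories.

Each feature dimension is modeled as a scalar local-level state space:
a random-walk state x_k = x_{k-1} + w_k, w_k ~ N(0, q), observed as
y_k = x_k + v_k, v_k ~ N(0, r).  A forward Kalman filter produces the
filtered posterior p(x_k | y_{1:k}); the backward RTS recursion, started
from the last filtered estimate, yields the smoothed posterior
p(x_k | y_{1:T}).  Noise variances (q, r) can be fixed by ratio or
estimated by expectation-maximization.  Applied to a feature matrix, each
column is smoothed independently within each contiguous stimulus block,
so level shifts at stimulus boundaries are preserved as signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FeatureMatrix

__all__ = [
    "StateSpace",
    "KalmanResult",
    "kalman_forward",
    "rts_smooth",
    "estimate_noise",
    "FeatureSmoother",
    "smooth_feature_matrix",
]


@dataclass(frozen=True)
class StateSpace:
    """Scalar local-level model parameters.

    q: process-noise variance; r: observation-noise variance;
    m0/p0: prior mean and variance of the initial state.
    """

    q: float
    r: float
    m0: float = 0.0
    p0: float = 1.0

    def __post_init__(self) -> None:
        if self.q < 0 or self.r < 0:
            raise ValueError("noise variances must be non-negative")
        if self.p0 <= 0:
            raise ValueError("initial state variance must be positive")
        if self.q == 0 and self.r == 0:
            raise ValueError("q and r cannot both be zero")


@dataclass(frozen=True)
class KalmanResult:
    """Forward-pass output: filtered means/variances and the innovations
    log-likelihood."""

    means: np.ndarray
    variances: np.ndarray
    loglik: float


def kalman_forward(y: np.ndarray, ss: StateSpace) -> KalmanResult:
    """Forward Kalman filter for the scalar local-level model.

    The prior on the first state is N(m0, p0); prediction adds q before
    each subsequent update.  Returns per-step filtered mean/variance and
    the innovations log-likelihood.

    Raises
    ------
    ValueError
        On empty or non-finite observations (naming the offending index).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 1:
        raise ValueError("observation sequence must be 1-D and non-empty")
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        raise ValueError(f"non-finite observation at index {bad[0]}")
    T = len(y)
    means = np.empty(T)
    variances = np.empty(T)
    loglik = 0.0
    m_pred, p_pred = ss.m0, ss.p0
    for k in range(T):
        if k > 0:
            m_pred = means[k - 1]
            p_pred = variances[k - 1] + ss.q
        s = p_pred + ss.r
        innov = y[k] - m_pred
        loglik += -0.5 * (np.log(2.0 * np.pi * s) + innov * innov / s)
        gain = p_pred / s
        means[k] = m_pred + gain * innov
        variances[k] = (1.0 - gain) * p_pred
    return KalmanResult(means=means, variances=variances, loglik=float(loglik))


def rts_smooth(
    filtered: KalmanResult, ss: StateSpace
) -> tuple[np.ndarray, np.ndarray]:
    """Backward RTS recursion giving the smoothed posterior.

    Initialized with the last filtered estimate (smoothed == filtered at
    time T); at every step the smoothed variance is at most the filtered
    one.
    """
    m, p = filtered.means, filtered.variances
    if len(m) != len(p):
        raise ValueError("filtered means and variances length mismatch")
    T = len(m)
    ms = m.copy()
    ps = p.copy()
    for k in range(T - 2, -1, -1):
        p_pred = p[k] + ss.q
        gain = p[k] / p_pred
        ms[k] = m[k] + gain * (ms[k + 1] - m[k])
        ps[k] = p[k] + gain * gain * (ps[k + 1] - p_pred)
    return ms, ps


def _lag_one_cov(filtered: KalmanResult, ps: np.ndarray, ss: StateSpace) -> np.ndarray:
    """Smoothed lag-one covariances cov(x_k, x_{k-1} | y_{1:T}) for k>=1."""
    p = filtered.variances
    T = len(p)
    cov = np.empty(max(T - 1, 0))
    for k in range(1, T):
        gain = p[k - 1] / (p[k - 1] + ss.q)
        cov[k - 1] = gain * ps[k]
    return cov


def estimate_noise(
    y: np.ndarray, max_iter: int = 50, tol: float = 1e-6
) -> StateSpace:
    """Expectation-maximization estimate of (q, r) for the local-level model.

    The initial-state prior is held fixed at m0 = y[0], p0 = 10x the
    sample variance (diffuse), so the log-likelihood is monotone
    non-decreasing in (q, r) across iterations.  A constant input returns
    q = 0 with r equal to the (zero) sample variance, floored at a tiny
    positive value to keep the model well-defined.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("noise estimation needs at least 10 observations")
    var = float(y.var(ddof=1))
    if var == 0.0:
        return StateSpace(q=0.0, r=max(var, 1e-15), m0=float(y[0]), p0=1.0)
    m0, p0 = float(y[0]), 10.0 * var
    diff_var = float(np.diff(y).var(ddof=1)) if len(y) > 2 else var
    q = max(diff_var / 2.0, 1e-12)
    r = max(diff_var / 2.0, 1e-12)
    prev_ll = -np.inf
    T = len(y)
    for _ in range(max_iter):
        ss = StateSpace(q=q, r=r, m0=m0, p0=p0)
        fwd = kalman_forward(y, ss)
        ms, ps = rts_smooth(fwd, ss)
        cov = _lag_one_cov(fwd, ps, ss)
        # M-step (closed form for the linear-Gaussian model).
        r = float(np.mean((y - ms) ** 2 + ps))
        dm = np.diff(ms)
        q = float(np.mean(dm * dm + ps[1:] + ps[:-1] - 2.0 * cov))
        q, r = max(q, 1e-15), max(r, 1e-15)
        if np.isfinite(prev_ll) and abs(fwd.loglik - prev_ll) <= tol * abs(prev_ll):
            prev_ll = fwd.loglik
            break
        prev_ll = fwd.loglik
    return StateSpace(q=q, r=r, m0=m0, p0=p0)


def _smooth_segment(y: np.ndarray, ss: StateSpace) -> np.ndarray:
    fwd = kalman_forward(y, ss)
    ms, _ = rts_smooth(fwd, ss)
    return ms


class FeatureSmoother:
    """Per-column RTS smoothing with noise statistics fitted separately.

    ``mode='fixed'`` sets r to the column's sample variance and
    q = ratio * r (default ratio 0.01); ``mode='em'`` estimates (q, r)
    per column by EM over the chronologically ordered training sequence.
    ``transform`` smooths each column independently within each
    contiguous stimulus block, initializing m0 at the block's first
    observation with a diffuse p0; labels are never consulted.
    """

    def __init__(self, mode: str = "fixed", ratio: float = 0.01) -> None:
        if mode not in {"fixed", "em"}:
            raise ValueError("mode must be 'fixed' or 'em'")
        self.mode = mode
        self.ratio = ratio
        self.params_: list[tuple[float, float]] | None = None

    def fit(self, fm: FeatureMatrix) -> "FeatureSmoother":
        order = np.argsort(fm.order)
        params = []
        for j in range(fm.n_features):
            col = fm.values[order, j]
            var = float(col.var(ddof=1)) if len(col) > 1 else 0.0
            if var == 0.0:
                params.append((0.0, 0.0))  # sentinel: leave column unchanged
            elif self.mode == "fixed":
                params.append((self.ratio * var, var))
            else:
                ss = estimate_noise(col)
                params.append((ss.q, ss.r))
        self.params_ = params
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if self.params_ is None:
            raise RuntimeError("smoother not fitted")
        if len(self.params_) != fm.n_features:
            raise ValueError("feature count differs from the fitted matrix")
        values = fm.values.copy()
        order = np.argsort(fm.order)
        blocks = fm.block[order]
        boundaries = np.flatnonzero(np.diff(blocks) != 0) + 1
        segments = np.split(order, boundaries)
        for j, (q, r) in enumerate(self.params_):
            if r == 0.0:
                continue
            for seg in segments:
                y = fm.values[seg, j]
                if len(y) < 2:
                    continue
                var = float(y.var(ddof=1))
                p0 = max(10.0 * var, 10.0 * r)
                ss = StateSpace(q=q, r=r, m0=float(y[0]), p0=p0)
                values[seg, j] = _smooth_segment(y, ss)
        return fm.with_values(values)


def smooth_feature_matrix(
    fm: FeatureMatrix, mode: str = "fixed", ratio: float = 0.01
) -> FeatureMatrix:
    """Fit a :class:`FeatureSmoother` on ``fm`` and apply it to ``fm``.

    Requires chronological order metadata; label columns are untouched,
    so smoothing cannot leak class information by construction.
    """
    return FeatureSmoother(mode=mode, ratio=ratio).fit(fm).transform(fm)
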