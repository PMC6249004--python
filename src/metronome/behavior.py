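"""Scalar-variability psychometrics, RT regression, attrition averaging.

The probability of a correct left/right report at a go-cue ``t_go``
seconds into maintenance of a tempo ``T`` follows from a Gaussian
subjective elapsed time ``t_hat ~ Normal(t_go / g, (w t_go)^2)`` (Weber's
law: sd proportional to elapsed time; ``g`` the internal-period gain):
the report is correct when ``floor(t_hat / T)`` has the parity of the true
elapsed interval count, so the correct-response probability is a sum of
Gaussian interval masses over same-parity intervals, mixed with a lapse
rate ``lambda`` (random guess).  Fits are binomial maximum likelihood
with profile-likelihood confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .session import TrialRecord
from .spectral import InputError
from .synth import ParameterError, ScalarTimingParams


@dataclass
class PsychometricCurve:
    elapsed_s: np.ndarray
    p_correct: np.ndarray
    params: ScalarTimingParams
    tempo_ms: float


@dataclass(frozen=True)
class DelayedReachDesign:
    """Variable-delay design: truncated exponential between 1.1 and 3 s."""
    delay_min_s: float = 1.1
    delay_max_s: float = 3.0
    rate_per_s: float = 1.0

    def __post_init__(self):
        if not self.delay_min_s < self.delay_max_s:
            raise ParameterError("delay_min_s must be < delay_max_s")

    def sample(self, n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        lo, hi = self.delay_min_s, self.delay_max_s
        u = rng.random(n)
        # inverse-CDF of an exponential truncated to [lo, hi]
        c = 1.0 - np.exp(-self.rate_per_s * (hi - lo))
        return lo - np.log1p(-u * c) / self.rate_per_s


def pcorrect_scalar(t_go: float, T: float, params: ScalarTimingParams,
                    J: int = 10, return_truncation: bool = False):
    """Closed-form correct-response probability of the scalar-timing agent.

    Sums the Gaussian mass of ``t_hat`` over intervals ``j`` of the same
    parity as the true interval ``j0 = floor(t_go / T)``, for
    ``|j - j0| <= J`` (mass below zero is folded into interval 0, matching
    the clipped generator); the lapse contributes ``lambda / 2``.
    """
    if T <= 0:
        raise ParameterError("T must be positive")
    if t_go <= 0:
        raise ParameterError("t_go must be positive")
    w, lam, g = params.weber_fraction, params.lapse, params.clock_gain
    j0 = int(np.floor(t_go / T))
    if w == 0:
        match = 1.0 if int(np.floor(t_go / g / T)) % 2 == j0 % 2 else 0.0
        trunc = 0.0
    else:
        # parity of floor(t_hat / T) over the whole real line (the count
        # model is symmetric, so a diffuse clock tends to chance exactly)
        mu, sd = t_go / g, w * t_go
        js = np.arange(j0 - J, j0 + J + 1)
        upper = stats.norm.cdf(((js + 1) * T - mu) / sd)
        lower = stats.norm.cdf((js * T - mu) / sd)
        masses = upper - lower
        match = float(masses[(js % 2) == (j0 % 2)].sum())
        trunc = float(1.0 - masses.sum())
        # mass outside the truncation window splits evenly by parity
        match += trunc / 2.0
    p = (1.0 - lam) * match + lam / 2.0
    if return_truncation:
        return p, abs(trunc)
    return p


def psychometric_curve(params: ScalarTimingParams, tempo_ms: float,
                       n_maintenance: int = 4, go_cue_fraction: float = 0.5
                       ) -> PsychometricCurve:
    T = tempo_ms / 1000.0
    t_go = (np.arange(1, n_maintenance + 1) - (1.0 - go_cue_fraction)) * T
    p = np.array([pcorrect_scalar(t, T, params) for t in t_go])
    return PsychometricCurve(elapsed_s=t_go, p_correct=p, params=params,
                             tempo_ms=tempo_ms)


def _aggregate(trials: list[TrialRecord]) -> list[tuple[float, float, int, int]]:
    """(T_s, t_go_s, n, k) per unique tempo x go-cue cell."""
    cells: dict = {}
    for tr in trials:
        if tr.correct is None:
            continue
        key = (tr.tempo_ms / 1000.0, tr.t_go_ms / 1000.0)
        n, k = cells.get(key, (0, 0))
        cells[key] = (n + 1, k + int(tr.correct))
    return [(T, t, n, k) for (T, t), (n, k) in sorted(cells.items())]


def fit_scalar_model(trials: list[TrialRecord], fix_lapse: float | None = None,
                     free_gain: bool = False, ci_level: float = 0.95) -> dict:
    """Binomial ML fit of (w, lambda[, g]) with profile-likelihood CIs.

    The clock gain is fixed at 1 by default (unbiased timing, the
    behavioral-curve convention); ``free_gain=True`` frees it.  An
    estimate at the lower ``w`` bound is flagged as a boundary solution.
    """
    cells = _aggregate(trials)
    if len(cells) < 2 or min(n for _, _, n, _ in cells) < 1:
        raise InputError("need >= 2 go-cue cells with outcomes")

    w_lo, w_hi = 1e-4, 5.0

    def nll(theta):
        w = theta[0]
        lam = fix_lapse if fix_lapse is not None else theta[1]
        g = theta[-1] if free_gain else 1.0
        params = ScalarTimingParams(weber_fraction=w, lapse=lam, clock_gain=g)
        ll = 0.0
        for T, t, n, k in cells:
            p = np.clip(pcorrect_scalar(t, T, params), 1e-12, 1 - 1e-12)
            ll += k * np.log(p) + (n - k) * np.log1p(-p)
        return -ll

    x0 = [0.1]
    bounds = [(w_lo, w_hi)]
    if fix_lapse is None:
        x0.append(0.02)
        bounds.append((0.0, 0.5))
    if free_gain:
        x0.append(1.0)
        bounds.append((0.5, 2.0))
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    w_hat = float(res.x[0])
    lam_hat = fix_lapse if fix_lapse is not None else float(res.x[1])
    g_hat = float(res.x[-1]) if free_gain else 1.0
    nll_min = float(res.fun)
    boundary = w_hat <= w_lo * 1.01

    # profile CI for w: deviance crosses the chi2(1) quantile
    crit = stats.chi2.ppf(ci_level, 1) / 2.0

    def profile(w):
        if fix_lapse is not None and not free_gain:
            return nll([w])
        x0p = [v for v in res.x[1:]]
        rp = optimize.minimize(lambda th: nll([w, *th]), x0p,
                               method="L-BFGS-B", bounds=bounds[1:])
        return float(rp.fun)

    def bisect(lo, hi, increasing):
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if (profile(mid) - nll_min > crit) == increasing:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    ci_lo = w_lo if profile(w_lo) - nll_min <= crit \
        else bisect(w_lo, w_hat, increasing=False)
    ci_hi = w_hi if profile(w_hi) - nll_min <= crit \
        else bisect(w_hat, w_hi, increasing=True)
    # bisect orientation: below w_hat deviance decreases toward w_hat
    if ci_lo > w_hat:
        ci_lo = w_lo
    params = ScalarTimingParams(weber_fraction=w_hat, lapse=lam_hat,
                                clock_gain=g_hat)
    tempos = sorted({T for T, _, _, _ in cells})
    curves = [psychometric_curve(params, T * 1000.0) for T in tempos]
    return {"weber_fraction": w_hat, "lapse": lam_hat, "clock_gain": g_hat,
            "w_ci": (float(ci_lo), float(ci_hi)), "nll": nll_min,
            "boundary": bool(boundary), "curves": curves,
            "n_trials": int(sum(n for _, _, n, _ in cells))}


def rt_regression(rt_ms: np.ndarray, elapsed_s: np.ndarray,
                  median_per_time: bool = True) -> dict:
    """OLS of reaction time on elapsed time (ms per s).

    By default regresses the median RT per unique elapsed-time point (the
    published convention); ``median_per_time=False`` uses single trials.
    """
    rt_ms = np.asarray(rt_ms, float)
    elapsed_s = np.asarray(elapsed_s, float)
    ok = np.isfinite(rt_ms) & np.isfinite(elapsed_s)
    rt_ms, elapsed_s = rt_ms[ok], elapsed_s[ok]
    if median_per_time:
        pts = np.unique(elapsed_s)
        if pts.size < 3:
            raise InputError("need >= 3 distinct elapsed times")
        x = pts
        y = np.array([np.median(rt_ms[elapsed_s == p]) for p in pts])
    else:
        if np.unique(elapsed_s).size < 3:
            raise InputError("need >= 3 distinct elapsed times")
        x, y = elapsed_s, rt_ms
    fit = stats.linregress(x, y)
    return {"slope_ms_per_s": float(fit.slope),
            "intercept_ms": float(fit.intercept),
            "r2": float(fit.rvalue ** 2), "p": float(fit.pvalue),
            "n_points": int(x.size)}


def attrition_mean(series: np.ndarray, time_s: np.ndarray,
                   delays_s: np.ndarray,
                   design: DelayedReachDesign | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Mean over trials still active at each time point.

    ``series`` is trials x time; trial ``i`` contributes at ``t`` only
    while ``t <= delays_s[i]``.  Times beyond the design's maximum delay
    are masked (NaN mean, n = 0).  Before the minimum delay every trial
    contributes.
    """
    series = np.asarray(series, float)
    delays_s = np.asarray(delays_s, float)
    if series.shape[0] != delays_s.size:
        raise InputError("one delay per trial required")
    active = time_s[None, :] <= delays_s[:, None]
    n = active.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0,
                        np.where(active, series, 0.0).sum(axis=0)
                        / np.maximum(n, 1), np.nan)
    if design is not None:
        mean = np.where(time_s > design.delay_max_s, np.nan, mean)
    return mean, n
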