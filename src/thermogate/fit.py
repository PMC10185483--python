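"""Maximum-likelihood and least-squares estimation of (T_half, dS).

Counts of open observations at each temperature are modelled as binomial
draws with success probability given by the two-state open-probability
curve. The binomial likelihood is the primary estimator; least squares on
the observed proportions is a fallback when only proportions are trusted.

Internally the optimizer works in (T_half, ln|dS|) with the entropy sign
fixed by the declared channel type, which prevents sign flips and keeps the
two parameters on comparable scales. Uncertainty comes from a parametric
bootstrap (resample counts from the fitted curve, refit, take percentile
intervals).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from . import model
from .constants import R
from .data import InsufficientDataError, PopenDataset
from .model import EntropyClass, GatingParams

__all__ = [
    "FitResult",
    "InitialGuess",
    "NonIdentifiableError",
    "BootstrapError",
    "estimate_initials",
    "fit_mle",
    "fit_lsq",
    "bootstrap_ci",
    "derived_report",
    "grid_search_mle",
]

#: Default entropy magnitude, in units of R, used when the observed curve
#: gives no usable quartile crossings (the canonical steep thermo-TRP value).
FALLBACK_DELTA_S_IN_R = 125.0

_P_FLOOR = 1e-12  # probability clip inside the log-likelihood


class NonIdentifiableError(ValueError):
    """The data carry no information about one or both parameters."""


class BootstrapError(RuntimeError):
    """Too many bootstrap refits failed to converge."""


@dataclass(frozen=True)
class InitialGuess:
    """Starting point for the optimizer plus provenance flags."""

    params: GatingParams
    from_crossing: bool  # T_half from an observed 0.5 crossing
    from_quartiles: bool  # |dS| from observed 0.25/0.75 crossings


@dataclass(frozen=True)
class FitResult:
    """Point estimates and diagnostics of one fit.

    Confidence intervals are absent (None) until :func:`bootstrap_ci`
    populates them.
    """

    delta_S_hat: float
    T_half_hat: float
    log_likelihood: float
    converged: bool
    method: str  # "mle" or "lsq"
    channel_type: EntropyClass
    init: InitialGuess
    message: str = ""
    ci_level: float | None = None
    ci_delta_S: tuple[float, float] | None = None
    ci_T_half: tuple[float, float] | None = None
    n_boot: int | None = None
    seed: int | None = None

    @property
    def params(self) -> GatingParams:
        return GatingParams(delta_S=self.delta_S_hat, T_half=self.T_half_hat)

    def to_dict(self) -> dict:
        """JSON-ready summary (schema version 1)."""
        return {
            "schema_version": 1,
            "method": self.method,
            "channel_type": self.channel_type.value,
            "delta_S_J_per_mol_K": self.delta_S_hat,
            "delta_S_in_R": self.delta_S_hat / R,
            "T_half_K": self.T_half_hat,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "message": self.message,
            "init_from_crossing": self.init.from_crossing,
            "init_from_quartiles": self.init.from_quartiles,
            "ci_level": self.ci_level,
            "ci_delta_S_J_per_mol_K": list(self.ci_delta_S) if self.ci_delta_S else None,
            "ci_T_half_K": list(self.ci_T_half) if self.ci_T_half else None,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _pooled_curve(data: PopenDataset) -> tuple[np.ndarray, np.ndarray]:
    """Temperatures and pooled open proportions, sorted and deduplicated."""
    d = data.sorted_by_temperature()
    T_unique, inverse = np.unique(d.T, return_inverse=True)
    trials = np.bincount(inverse, weights=d.n_trials)
    opens = np.bincount(inverse, weights=d.n_open)
    return T_unique, opens / trials


def _interp_crossing(T: np.ndarray, p: np.ndarray, level: float) -> float | None:
    """Temperature of the first crossing of ``p`` through ``level``, or None."""
    dp = p - level
    for i in range(len(T) - 1):
        if dp[i] == 0.0:
            return float(T[i])
        if dp[i] * dp[i + 1] < 0:
            frac = dp[i] / (p[i] - p[i + 1])
            return float(T[i] + frac * (T[i + 1] - T[i]))
    if dp[-1] == 0.0:
        return float(T[-1])
    return None


def _sign(channel_type: EntropyClass | str) -> float:
    ct = EntropyClass(channel_type)
    return 1.0 if ct is EntropyClass.TYPE_I else -1.0


def estimate_initials(
    data: PopenDataset, channel_type: EntropyClass | str = EntropyClass.TYPE_I
) -> InitialGuess:
    """Moment-style starting values for (T_half, dS) from the observed curve.

    T_half starts at the linearly interpolated first 0.5 crossing of the
    pooled proportions (or, without a crossing, the temperature whose
    proportion is nearest 0.5). |dS| starts from the steepness relation
    |dS| = 4 R T_half / dT with dT read off as twice the temperature span
    between the 0.25 and 0.75 crossings; without those crossings it falls
    back to the canonical 125 R. The sign is fixed by ``channel_type``.
    """
    data.require_fittable()
    T, p = _pooled_curve(data)
    sign = _sign(channel_type)

    t_half0 = _interp_crossing(T, p, 0.5)
    from_crossing = t_half0 is not None
    if t_half0 is None:
        t_half0 = float(T[np.argmin(np.abs(p - 0.5))])

    t_lo = _interp_crossing(T, p, 0.25)
    t_hi = _interp_crossing(T, p, 0.75)
    from_quartiles = t_lo is not None and t_hi is not None and t_lo != t_hi
    if from_quartiles:
        width = 2.0 * abs(t_hi - t_lo)
        delta_s0 = sign * model.entropy_from_width(t_half0, width)
    else:
        delta_s0 = sign * FALLBACK_DELTA_S_IN_R * R

    return InitialGuess(
        params=GatingParams(delta_S=delta_s0, T_half=t_half0),
        from_crossing=from_crossing,
        from_quartiles=from_quartiles,
    )


def _check_identifiable(data: PopenDataset) -> None:
    if np.all(data.n_open == 0):
        raise NonIdentifiableError("all observations closed: T_half is unidentifiable")
    if np.all(data.n_open == data.n_trials):
        raise NonIdentifiableError("all observations open: T_half is unidentifiable")


def _popen(T: np.ndarray, t_half: float, delta_s: float) -> np.ndarray:
    arg = np.clip(delta_s * (t_half - T) / (R * T), -model.EXP_CLIP, model.EXP_CLIP)
    return 1.0 / (1.0 + np.exp(arg))


def _neg_loglik_and_grad(
    x: np.ndarray, T: np.ndarray, n: np.ndarray, k: np.ndarray, sign: float
) -> tuple[float, np.ndarray]:
    """Negative binomial log-likelihood (without the combinatorial constant)
    and its gradient in (T_half, ln|dS|) coordinates."""
    t_half, s = x
    delta_s = sign * np.exp(s)
    u = delta_s * (t_half - T) / (R * T)
    u = np.clip(u, -model.EXP_CLIP, model.EXP_CLIP)
    p = 1.0 / (1.0 + np.exp(u))
    pc = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    nll = -float(np.sum(k * np.log(pc) + (n - k) * np.log(1.0 - pc)))
    resid = k - n * p  # d(loglik)/du = -(k - n p)
    grad_t_half = float(np.sum(resid * delta_s / (R * T)))
    grad_s = float(np.sum(resid * u))
    return nll, np.array([grad_t_half, grad_s])


def _full_loglik(data: PopenDataset, params: GatingParams) -> float:
    """Binomial log-likelihood including the combinatorial term."""
    p = np.clip(model.open_probability(params, data.T), _P_FLOOR, 1.0 - _P_FLOOR)
    return float(np.sum(stats.binom.logpmf(data.n_open, data.n_trials, p)))


def fit_mle(
    data: PopenDataset,
    channel_type: EntropyClass | str = EntropyClass.TYPE_I,
    init: GatingParams | None = None,
    seed: int | None = None,
) -> FitResult:
    """Binomial maximum-likelihood fit of (T_half, dS).

    Maximizes sum over records of ``n_open*ln p(T) + (n_trials - n_open) *
    ln(1 - p(T))`` with p from the two-state curve, the entropy sign fixed by
    ``channel_type``. Non-convergence is flagged on the result, never
    silently ignored.
    """
    data.require_fittable()
    _check_identifiable(data)
    sign = _sign(channel_type)
    guess = estimate_initials(data, channel_type)
    start = guess.params if init is None else init
    if np.sign(start.delta_S) != sign:
        raise ValueError("init entropy sign contradicts channel_type")

    x0 = np.array([start.T_half, np.log(abs(start.delta_S))])
    args = (data.T, data.n_trials.astype(float), data.n_open.astype(float), sign)
    res = optimize.minimize(
        _neg_loglik_and_grad,
        x0,
        args=args,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    # Polish with a derivative-free pass; helps when L-BFGS-B stops on ftol
    # just short of the optimum.
    res2 = optimize.minimize(
        lambda x, *a: _neg_loglik_and_grad(x, *a)[0],
        res.x,
        args=args,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    best = res2 if res2.fun <= res.fun else res
    t_half_hat, s_hat = best.x
    converged = bool((res.success or res2.success) and np.isfinite(best.fun) and t_half_hat > 0)
    params_hat = GatingParams(delta_S=sign * float(np.exp(s_hat)), T_half=float(t_half_hat))
    return FitResult(
        delta_S_hat=params_hat.delta_S,
        T_half_hat=params_hat.T_half,
        log_likelihood=_full_loglik(data, params_hat) if converged else float("nan"),
        converged=converged,
        method="mle",
        channel_type=EntropyClass(channel_type),
        init=guess,
        message=str(best.message),
        seed=seed,
    )


def fit_lsq(
    data: PopenDataset,
    channel_type: EntropyClass | str = EntropyClass.TYPE_I,
    init: GatingParams | None = None,
) -> FitResult:
    """Least-squares fit of (T_half, dS) to the observed open proportions.

    Minimizes the sum of squared deviations between observed proportions and
    the model curve. On noiseless data it agrees with the MLE; with binomial
    noise it ignores the per-point trial counts, so prefer :func:`fit_mle`
    when counts are available.
    """
    data.require_fittable()
    p_obs = data.proportions
    if np.all(p_obs == p_obs[0]):
        raise NonIdentifiableError("observed proportions are constant: dS is unidentifiable")
    _check_identifiable(data)
    sign = _sign(channel_type)
    guess = estimate_initials(data, channel_type)
    start = guess.params if init is None else init
    if np.sign(start.delta_S) != sign:
        raise ValueError("init entropy sign contradicts channel_type")

    def residuals(x: np.ndarray) -> np.ndarray:
        return _popen(data.T, x[0], sign * np.exp(x[1])) - p_obs

    x0 = np.array([start.T_half, np.log(abs(start.delta_S))])
    res = optimize.least_squares(residuals, x0, xtol=1e-12, ftol=1e-14, gtol=1e-12)
    t_half_hat, s_hat = res.x
    converged = bool(res.success and np.isfinite(res.cost) and t_half_hat > 0)
    params_hat = GatingParams(delta_S=sign * float(np.exp(s_hat)), T_half=float(t_half_hat))
    return FitResult(
        delta_S_hat=params_hat.delta_S,
        T_half_hat=params_hat.T_half,
        log_likelihood=_full_loglik(data, params_hat) if converged else float("nan"),
        converged=converged,
        method="lsq",
        channel_type=EntropyClass(channel_type),
        init=guess,
        message=str(res.message),
    )


def bootstrap_ci(
    data: PopenDataset,
    fit: FitResult,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> FitResult:
    """Parametric-bootstrap percentile intervals for (T_half, dS).

    Resamples ``n_open ~ Binomial(n_trials, p_hat(T))`` per record from the
    fitted curve, refits with the same estimator started at the point
    estimate, and takes percentile intervals of the replicate estimates.
    Deterministic given ``seed``.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p_hat = np.asarray(model.open_probability(fit.params, data.T))
    refit = fit_mle if fit.method == "mle" else fit_lsq

    est = np.empty((n_boot, 2))
    n_fail = 0
    for b in range(n_boot):
        k = rng.binomial(data.n_trials, p_hat)
        boot = PopenDataset(T=data.T, n_trials=data.n_trials, n_open=k, label="bootstrap")
        try:
            r = refit(boot, fit.channel_type, init=fit.params)
        except NonIdentifiableError:
            r = None
        if r is None or not r.converged:
            n_fail += 1
            est[b] = np.nan
        else:
            est[b] = (r.delta_S_hat, r.T_half_hat)
    if n_fail > 0.2 * n_boot:
        raise BootstrapError(
            f"{n_fail}/{n_boot} bootstrap refits failed to converge; "
            "the design may be too weak for interval estimation"
        )
    lo, hi = 100.0 * (1.0 - level) / 2.0, 100.0 * (1.0 + level) / 2.0
    q_ds = np.nanpercentile(est[:, 0], [lo, hi])
    q_th = np.nanpercentile(est[:, 1], [lo, hi])
    return dataclasses.replace(
        fit,
        ci_level=level,
        ci_delta_S=(float(q_ds[0]), float(q_ds[1])),
        ci_T_half=(float(q_th[0]), float(q_th[1])),
        n_boot=n_boot,
        seed=seed,
    )


def derived_report(fit: FitResult, p_thr: float = 0.05, T_rest: float = 310.0) -> dict:
    """Thermodynamic summary of a converged fit.

    Reports the derived enthalpy, midpoint slope, linear-rise width,
    threshold temperature at ``p_thr`` and the gating classification at
    ``T_rest``, all computed from the fitted parameters.
    """
    if not fit.converged:
        raise ValueError("derived_report requires a converged fit")
    params = fit.params
    cls = model.classify(params, T_rest)
    return {
        "delta_S_J_per_mol_K": params.delta_S,
        "delta_S_in_R": params.delta_S_in_R,
        "T_half_K": params.T_half,
        "delta_H_J_per_mol": model.enthalpy(params),
        "delta_H_kJ_per_mol": model.enthalpy(params) / 1000.0,
        "delta_H_in_RT_half": model.enthalpy(params) / (R * params.T_half),
        "slope_at_T_half_per_K": model.slope_at_midpoint(params),
        "linear_rise_width_K": model.linear_rise_width(params),
        "p_thr": p_thr,
        "T_thr_K": model.threshold_temperature(params, p_thr),
        "T_rest_K": T_rest,
        "entropy_class": cls.entropy_class.value,
        "temperature_class": cls.temperature_class.value,
    }


def grid_search_mle(
    data: PopenDataset,
    channel_type: EntropyClass | str,
    center: GatingParams,
    t_half_halfspan: float = 10.0,
    ds_factor: tuple[float, float] = (0.5, 2.0),
    n_grid: int = 400,
) -> tuple[GatingParams, float, tuple[float, float]]:
    """Brute-force likelihood maximization on a dense (T_half, dS) grid.

    Independent cross-check for the gradient-based fit: evaluates the exact
    binomial log-pmf on an ``n_grid x n_grid`` grid spanning ``center.T_half
    +/- t_half_halfspan`` and ``|dS|`` scaled by ``ds_factor`` (log-spaced),
    and returns the grid maximizer, its log-likelihood and the grid cell
    size ``(dT_half, d ln|dS|)``.
    """
    sign = _sign(channel_type)
    t_grid = np.linspace(center.T_half - t_half_halfspan, center.T_half + t_half_halfspan, n_grid)
    s_grid = np.log(abs(center.delta_S)) + np.linspace(
        np.log(ds_factor[0]), np.log(ds_factor[1]), n_grid
    )
    ds_grid = sign * np.exp(s_grid)
    # p has shape (n_grid T_half, n_grid dS, n_records)
    u = ds_grid[None, :, None] * (t_grid[:, None, None] - data.T[None, None, :]) / (R * data.T)
    p = 1.0 / (1.0 + np.exp(np.clip(u, -model.EXP_CLIP, model.EXP_CLIP)))
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    ll = stats.binom.logpmf(data.n_open, data.n_trials, p).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    best = GatingParams(delta_S=float(ds_grid[j]), T_half=float(t_grid[i]))
    cell = (float(t_grid[1] - t_grid[0]), float(s_grid[1] - s_grid[0]))
    return best, float(ll[i, j]), cell
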