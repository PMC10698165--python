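"""Bayesian random-walk (local-level) state-space model for annual series.

The model treats each year's true value as a latent state evolving as a
random walk, observed through replicate measurements with noise:

    state:        x_t = x_{t-1} + w_t,     w_t ~ N(0, Q)
    observation:  y_{i,t} = x_t + v_{i,t},  v_{i,t} ~ N(0, R)

Years with no observations stay on the latent grid and are interpolated by
the model; years with several replicates shrink toward their mean.  Q is the
annual process variance, R the observation variance.

Because the model is linear-Gaussian, it is sampled with an exact conjugate
Gibbs scheme: the full state path x_{1:T} is drawn jointly by
forward-filter backward-sampling (FFBS) given (Q, R), then Q and R are drawn
from their conjugate inverse-gamma full conditionals.  Convergence is
checked with split-chain Gelman-Rubin potential scale reduction factors
(R-hat), with ≤ 1.05 taken as converged.  Per-year summaries are the
maximum a posteriori value (mode of a Gaussian-kernel density estimate over
pooled draws, Silverman bandwidth), the median, and the central 95%
credible interval.

An exact Kalman filter/smoother at fixed (Q, R) is also provided; it is the
analytic benchmark the Gibbs sampler must agree with.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnualSeries",
    "SSMConfig",
    "SSMPosterior",
    "fit_ssm",
    "kalman_smoother",
    "gelman_rubin",
    "map_series",
    "ConvergenceWarning",
    "DegenerateSeriesError",
]


class ConvergenceWarning(UserWarning):
    """Emitted when any parameter's R-hat exceeds the configured threshold."""


class DegenerateSeriesError(ValueError):
    """Series carries no information to separate process from observation noise."""


@dataclass
class AnnualSeries:
    """Year-indexed observations; replicates allowed, missing years retained.

    ``year_range`` is the inclusive latent grid; years inside it with no
    observations are "missing" and still receive a latent state.
    """

    name: str
    observations: list[tuple[int, float, str | None]]
    year_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.year_range is None:
            yrs = [y for y, _, _ in self.observations]
            if not yrs:
                raise ValueError(f"series {self.name!r} has no observations")
            self.year_range = (min(yrs), max(yrs))
        lo, hi = self.year_range
        for y, v, _ in self.observations:
            if not lo <= y <= hi:
                raise ValueError(f"observation year {y} outside range {self.year_range}")
            if not math.isfinite(v):
                raise ValueError(f"non-finite observation in series {self.name!r}")

    @property
    def years(self) -> np.ndarray:
        """Full latent year grid (inclusive)."""
        lo, hi = self.year_range
        return np.arange(lo, hi + 1)

    @property
    def n_years(self) -> int:
        lo, hi = self.year_range
        return hi - lo + 1

    def observed_years(self) -> list[int]:
        return sorted({y for y, _, _ in self.observations})

    def grid_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_obs per grid year, sum of obs per grid year)."""
        lo, _ = self.year_range
        n = np.zeros(self.n_years, dtype=int)
        s = np.zeros(self.n_years)
        for y, v, _ in self.observations:
            n[y - lo] += 1
            s[y - lo] += v
        return n, s

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, name: str = "series",
        year_range: tuple[int, int] | None = None,
    ) -> "AnnualSeries":
        if not {"year", "value"} <= set(df.columns):
            raise ValueError("need 'year' and 'value' columns")
        obs = [
            (
                int(r["year"]),
                float(r["value"]),
                str(r["replicate_id"]) if "replicate_id" in df.columns and pd.notna(r.get("replicate_id")) else None,
            )
            for _, r in df.iterrows()
            if pd.notna(r["value"])
        ]
        return cls(name=name, observations=obs, year_range=year_range)

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "AnnualSeries":
        """Read ``year,value[,replicate_id]``; missing years simply absent."""
        return cls.from_dataframe(pd.read_csv(path), name=name or Path(path).stem)

    @classmethod
    def from_mapping(cls, values: Mapping[int, float], name: str = "series") -> "AnnualSeries":
        return cls(name=name, observations=[(int(y), float(v), None) for y, v in values.items()])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.observations, columns=["year", "value", "replicate_id"])


@dataclass(frozen=True)
class SSMConfig:
    """Sampler settings and priors.

    Priors are conjugate: inverse-gamma(shape, scale) on Q and R and a
    normal prior on the initial state x_1.  When ``prior_x1`` is None it
    defaults to N(mean of the first observed year's values, 10 × sample
    variance of all observations) — weakly informative and data-scaled.
    ``fixed_R`` pins the observation variance instead of sampling it
    (fallback for degenerate series, and the noiseless-observation limit).
    """

    prior_q: tuple[float, float] = (0.01, 0.01)
    prior_r: tuple[float, float] = (0.01, 0.01)
    prior_x1: tuple[float, float] | None = None  # (mean, variance)
    n_chains: int = 3
    n_iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 5
    seed: int = 0
    rhat_threshold: float = 1.05
    fixed_r: float | None = None
    fixed_q: float | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("R-hat needs ≥ 2 chains")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 ≤ burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be ≥ 1")


@dataclass
class SSMPosterior:
    """MCMC output: per-chain draws plus per-year summaries."""

    series_name: str
    years: np.ndarray
    draws_x: np.ndarray   # (chains, draws, T)
    draws_q: np.ndarray   # (chains, draws)
    draws_r: np.ndarray   # (chains, draws)
    map_series: dict[int, float]
    median_series: dict[int, float]
    ci95: dict[int, tuple[float, float]]
    rhat: dict[str, float]
    seed_used: int
    converged: bool
    config: SSMConfig
    n_obs: dict[int, int] = field(default_factory=dict)

    def pooled_x(self) -> np.ndarray:
        """(total draws, T) states pooled over chains."""
        return self.draws_x.reshape(-1, self.draws_x.shape[-1])

    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def summary_frame(self) -> pd.DataFrame:
        """``year,map,median,lower95,upper95,n_obs`` summary table."""
        return pd.DataFrame(
            {
                "year": self.years,
                "map": [self.map_series[y] for y in self.years],
                "median": [self.median_series[y] for y in self.years],
                "lower95": [self.ci95[y][0] for y in self.years],
                "upper95": [self.ci95[y][1] for y in self.years],
                "n_obs": [self.n_obs.get(int(y), 0) for y in self.years],
            }
        )

    def map_mapping(self) -> dict[int, float]:
        return dict(self.map_series)


# ---------------------------------------------------------------------------
# Exact inference at fixed (Q, R): Kalman filter + RTS smoother


def kalman_smoother(
    n_obs: np.ndarray,
    obs_sum: np.ndarray,
    q: float,
    r: float,
    prior_mean: float,
    prior_var: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact smoothed state means and variances for the local-level model.

    Parameters are the per-year observation counts and sums on the full
    grid (0 for missing years), the process and observation variances, and
    the N(prior_mean, prior_var) prior on the first state.  Replicates in a
    year are absorbed through their sufficient statistics: the year's
    effective observation is the replicate mean with variance R/n_t.
    """
    T = len(n_obs)
    fm = np.empty(T)  # filtered means
    fv = np.empty(T)  # filtered variances
    m, v = prior_mean, prior_var
    for t in range(T):
        if t > 0:
            v = v + q
        if n_obs[t] > 0:
            prec = 1.0 / v + n_obs[t] / r
            m = (m / v + obs_sum[t] / r) / prec
            v = 1.0 / prec
        fm[t], fv[t] = m, v
    sm = np.empty(T)
    sv = np.empty(T)
    sm[-1], sv[-1] = fm[-1], fv[-1]
    for t in range(T - 2, -1, -1):
        pred_v = fv[t] + q
        gain = fv[t] / pred_v
        sm[t] = fm[t] + gain * (sm[t + 1] - fm[t])
        sv[t] = fv[t] + gain**2 * (sv[t + 1] - pred_v)
    return sm, sv


def _ffbs(
    n_obs: np.ndarray,
    obs_sum: np.ndarray,
    q: float,
    r: float,
    prior_mean: float,
    prior_var: float,
    z: np.ndarray,
) -> np.ndarray:
    """Joint draw of x_{1:T} | Q, R, y by forward-filter backward-sampling.

    ``z`` is a vector of T standard-normal variates (pre-drawn so the
    sampler is bit-reproducible and the hot loop stays scalar).
    """
    T = len(n_obs)
    fm = np.empty(T)
    fv = np.empty(T)
    m, v = prior_mean, prior_var
    for t in range(T):
        if t > 0:
            v = v + q
        nt = n_obs[t]
        if nt > 0:
            prec = 1.0 / v + nt / r
            m = (m / v + obs_sum[t] / r) / prec
            v = 1.0 / prec
        fm[t], fv[t] = m, v
    x = np.empty(T)
    x[-1] = fm[-1] + math.sqrt(fv[-1]) * z[-1]
    for t in range(T - 2, -1, -1):
        pred_v = fv[t] + q
        gain = fv[t] / pred_v
        mean = fm[t] + gain * (x[t + 1] - fm[t])
        var = fv[t] * q / pred_v
        x[t] = mean + math.sqrt(var) * z[t]
    return x


# ---------------------------------------------------------------------------
# Gibbs sampler


def _run_chain(
    n_obs: np.ndarray,
    obs_sum: np.ndarray,
    obs_by_year: list[np.ndarray],
    config: SSMConfig,
    prior_mean: float,
    prior_var: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    T = len(n_obs)
    n_total = int(n_obs.sum())
    aq, bq = config.prior_q
    ar, br = config.prior_r

    # Overdispersed initialisation: variances scattered around the
    # observation variance so chains start apart (R-hat is meaningful).
    all_obs = np.concatenate([o for o in obs_by_year if len(o)])
    s2 = float(np.var(all_obs)) or 1.0
    q = config.fixed_q if config.fixed_q is not None else s2 * float(
        np.exp(rng.uniform(-2.0, 1.0))
    )
    r = config.fixed_r if config.fixed_r is not None else s2 * float(
        np.exp(rng.uniform(-2.0, 1.0))
    )

    keep = (config.n_iterations - config.burn_in) // config.thinning
    out_x = np.empty((keep, T))
    out_q = np.empty(keep)
    out_r = np.empty(keep)
    k = 0

    # residual sum uses per-year obs arrays; precompute list of (t, y_array)
    obs_pairs = [(t, o) for t, o in enumerate(obs_by_year) if len(o)]

    zs = rng.standard_normal((config.n_iterations, T))
    for it in range(config.n_iterations):
        x = _ffbs(n_obs, obs_sum, q, r, prior_mean, prior_var, zs[it])
        if config.fixed_q is None:
            dx = np.diff(x)
            q = float(
                (bq + 0.5 * float(dx @ dx))
                / rng.gamma(aq + 0.5 * (T - 1))
            )
        if config.fixed_r is None:
            ss = 0.0
            for t, o in obs_pairs:
                d = o - x[t]
                ss += float(d @ d)
            r = float((br + 0.5 * ss) / rng.gamma(ar + 0.5 * n_total))
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            out_x[k] = x
            out_q[k] = q
            out_r[k] = r
            k += 1
    return out_x[:k], out_q[:k], out_r[:k]


def gelman_rubin(chains: np.ndarray | Sequence[np.ndarray]) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor R-hat.

    ``chains`` is (n_chains, n_draws) for a scalar parameter.  Each chain is
    split in half, then R-hat = sqrt(V-hat / W) with W the mean within-chain
    variance and V-hat the pooled variance estimate.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("gelman_rubin needs ≥ 2 chains of equal length")
    m, n = arr.shape
    if n < 4:
        raise ValueError("chains too short to split")
    half = n // 2
    split = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    n_s = half
    means = split.mean(axis=1)
    w = float(split.var(axis=1, ddof=1).mean())
    if w == 0.0:
        return 1.0  # all draws identical within chains: point mass
    b = n_s * float(means.var(ddof=1))
    v_hat = (n_s - 1) / n_s * w + b / n_s
    return float(math.sqrt(v_hat / w))


def _kde_mode(draws: np.ndarray, grid_size: int = 512, max_draws: int = 4000) -> float:
    """Mode of a Gaussian KDE with Silverman bandwidth over a draw vector."""
    x = np.asarray(draws, dtype=float)
    if len(x) > max_draws:  # deterministic thinning keeps evaluation cheap
        x = x[:: len(x) // max_draws + 1]
    lo, hi = x.min(), x.max()
    if hi == lo:
        return float(lo)
    sd = x.std(ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * len(x) ** (-0.2)
    grid = np.linspace(lo, hi, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bw) ** 2).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def map_series(
    draws_x: np.ndarray, years: Sequence[int]
) -> dict[int, tuple[float, float, float]]:
    """Per-year (MAP, lower95, upper95) from pooled state draws.

    The MAP is the mode of a Gaussian-kernel density estimate (Silverman
    bandwidth) of the year's marginal posterior; the interval is the central
    2.5–97.5 percentile band.
    """
    pooled = np.asarray(draws_x, dtype=float)
    if pooled.ndim == 3:
        pooled = pooled.reshape(-1, pooled.shape[-1])
    if pooled.shape[0] < 200:
        raise ValueError(f"too few pooled draws ({pooled.shape[0]} < 200)")
    if pooled.shape[1] != len(years):
        raise ValueError("draws/year shape mismatch")
    out = {}
    for j, y in enumerate(years):
        col = pooled[:, j]
        lo, hi = np.percentile(col, [2.5, 97.5])
        out[int(y)] = (_kde_mode(col), float(lo), float(hi))
    return out


def fit_ssm(series: AnnualSeries, config: SSMConfig | None = None) -> SSMPosterior:
    """Fit the local-level model to an annual series by conjugate Gibbs.

    Alternates a joint FFBS draw of the state path with inverse-gamma draws
    of Q (from state increments) and R (from observation residuals).
    Reproducible: the same seed, config and data give bit-identical draws.
    Emits a :class:`ConvergenceWarning` (and ``converged=False``) if any
    split R-hat exceeds the threshold; never fails silently.
    """
    config = config or SSMConfig()
    n_obs, obs_sum = series.grid_arrays()
    observed = n_obs > 0
    if observed.sum() < 2:
        raise ValueError(f"series {series.name!r}: need observations in ≥ 2 years")
    values = np.array([v for _, v, _ in series.observations])
    if config.log_scale:
        if np.any(values <= 0):
            raise ValueError("log_scale requires strictly positive observations")
        values = np.log(values)
        lo = series.year_range[0]
        obs_sum = np.zeros_like(obs_sum)
        for (y, v, _), lv in zip(series.observations, values):
            obs_sum[y - lo] += lv
    if np.unique(values).size < 2 and config.fixed_r is None:
        raise DegenerateSeriesError(
            f"series {series.name!r}: all observed values identical; Q and R are "
            "not separable — refit with fixed_r set (e.g. a known measurement "
            "variance)"
        )

    lo = series.year_range[0]
    obs_by_year: list[np.ndarray] = [np.empty(0)] * series.n_years
    tmp: dict[int, list[float]] = {}
    for (y, v, _), lv in zip(series.observations, values):
        tmp.setdefault(y - lo, []).append(float(lv))
    for t, vs in tmp.items():
        obs_by_year[t] = np.array(vs)

    if config.prior_x1 is not None:
        prior_mean, prior_var = config.prior_x1
    else:
        first_t = int(np.argmax(observed))
        prior_mean = float(obs_by_year[first_t].mean())
        prior_var = 10.0 * float(np.var(values, ddof=1))
        if prior_var == 0.0 and config.fixed_r is not None:
            prior_var = max(1.0, 10.0 * config.fixed_r)
    if prior_var <= 0:
        raise ValueError("prior variance on x_1 must be positive")

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    xs, qs, rs = [], [], []
    for cs in chain_seeds:
        rng = np.random.Generator(np.random.PCG64(cs))
        cx, cq, cr = _run_chain(
            n_obs, obs_sum, obs_by_year, config, prior_mean, prior_var, rng
        )
        xs.append(cx)
        qs.append(cq)
        rs.append(cr)
    draws_x = np.stack(xs)          # (chains, keep, T)
    draws_q = np.stack(qs)
    draws_r = np.stack(rs)

    years = series.years
    rhat: dict[str, float] = {"Q": gelman_rubin(draws_q)}
    if config.fixed_r is None:
        rhat["R"] = gelman_rubin(draws_r)
    for j, y in enumerate(years):
        rhat[f"x[{int(y)}]"] = gelman_rubin(draws_x[:, :, j])
    converged = max(rhat.values()) <= config.rhat_threshold
    if not converged:
        bad = {k: v for k, v in rhat.items() if v > config.rhat_threshold}
        warnings.warn(
            f"series {series.name!r}: R-hat above {config.rhat_threshold} for "
            f"{sorted(bad)[:5]} (max {max(bad.values()):.3f}); "
            "increase iterations or thinning",
            ConvergenceWarning,
            stacklevel=2,
        )

    summaries = map_series(draws_x, years)
    pooled = draws_x.reshape(-1, len(years))
    medians = np.median(pooled, axis=0)
    if config.log_scale:
        # report on the original scale
        summaries = {
            y: (math.exp(m), math.exp(l), math.exp(u))
            for y, (m, l, u) in summaries.items()
        }
        medians = np.exp(medians)
    return SSMPosterior(
        series_name=series.name,
        years=years,
        draws_x=draws_x,
        draws_q=draws_q,
        draws_r=draws_r,
        map_series={y: s[0] for y, s in summaries.items()},
        median_series={int(y): float(m) for y, m in zip(years, medians)},
        ci95={y: (s[1], s[2]) for y, s in summaries.items()},
        rhat=rhat,
        seed_used=config.seed,
        converged=converged,
        config=config,
        n_obs={int(y): int(n) for y, n in zip(years, n_obs)},
    )


def write_posterior(posterior: SSMPosterior, csv_path: str | Path,
                    json_path: str | Path | None = None) -> None:
    """Write the per-year summary CSV and an optional JSON sidecar with the
    Q/R posteriors, R-hat diagnostics, config echo and seed."""
    import json

    posterior.summary_frame().to_csv(csv_path, index=False)
    if json_path is not None:
        cfg = posterior.config
        sidecar = {
            "series": posterior.series_name,
            "seed": posterior.seed_used,
            "converged": posterior.converged,
            "rhat": posterior.rhat,
            "Q": {
                "mean": float(posterior.draws_q.mean()),
                "median": float(np.median(posterior.draws_q)),
                "ci95": [float(v) for v in np.percentile(posterior.draws_q, [2.5, 97.5])],
            },
            "R": {
                "mean": float(posterior.draws_r.mean()),
                "median": float(np.median(posterior.draws_r)),
                "ci95": [float(v) for v in np.percentile(posterior.draws_r, [2.5, 97.5])],
            },
            "config": {
                "prior_q": list(cfg.prior_q),
                "prior_r": list(cfg.prior_r),
                "prior_x1": list(cfg.prior_x1) if cfg.prior_x1 else None,
                "n_chains": cfg.n_chains,
                "n_iterations": cfg.n_iterations,
                "burn_in": cfg.burn_in,
                "thinning": cfg.thinning,
                "fixed_r": cfg.fixed_r,
                "log_scale": cfg.log_scale,
            },
        }
        with open(json_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)


def fast_config(seed: int = 0, **overrides) -> SSMConfig:
    """Reduced-iteration settings for simulation studies and smoke tests."""
    defaults = dict(n_chains=2, n_iterations=3000, burn_in=1000, thinning=2, seed=seed)
    defaults.update(overrides)
    return SSMConfig(**defaults)
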