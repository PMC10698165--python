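"""Lagged cross-correlation between annual series with white-noise bands.

The cross-correlation at lag k is the Pearson correlation of
(x_{t+k}, y_t) over the years where both are available — positive k means
x LEADS y by k years.  This orientation is fixed and echoed in every
output, since lag-sign conventions differ between environments.

The ±1.96/sqrt(n) threshold is the band a white-noise pair would exceed 5%
of the time by chance at any single lag; for series interpolated by a
state-space model it is a descriptive band, not a significance test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CCFResult", "ccf", "lagged_r2", "pearson", "LAG_CONVENTION"]

LAG_CONVENTION = "r(k) = corr(x[t+k], y[t]); positive lag means x leads y"


def pearson(x_values: Sequence[float], y_values: Sequence[float]) -> float:
    """Pearson product-moment correlation of two paired samples."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError(f"need ≥ 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CCFResult:
    """Cross-correlations per lag plus the lag-0 white-noise threshold.

    ``correlations[k]`` may be absent when fewer than 3 year pairs overlap
    at lag k (reported missing, never zero-filled).
    """

    series_x: str
    series_y: str
    lags: np.ndarray
    correlations: dict[int, float]
    n_overlap: dict[int, int]
    threshold: float
    convention: str = LAG_CONVENTION

    def peak(self) -> tuple[int, float]:
        """(lag, r) of the largest |r| across computed lags."""
        lag = max(self.correlations, key=lambda k: abs(self.correlations[k]))
        return lag, self.correlations[lag]

    def r(self, lag: int) -> float:
        try:
            return self.correlations[lag]
        except KeyError:
            raise KeyError(f"lag {lag} not available (insufficient overlap or out of window)")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"lag": int(k), "r": self.correlations.get(int(k)), "n": self.n_overlap.get(int(k), 0)}
            for k in self.lags
        ]
        return pd.DataFrame(rows)

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        df = self.to_dataframe()
        with open(csv_path, "w") as fh:
            fh.write(f"# {self.convention}\n")
            df.to_csv(fh, index=False)
        if json_path is not None:
            lag, r = self.peak()
            with open(json_path, "w") as fh:
                json.dump(
                    {
                        "series_x": self.series_x,
                        "series_y": self.series_y,
                        "convention": self.convention,
                        "threshold": self.threshold,
                        "peak": {"lag": lag, "r": r},
                    },
                    fh,
                    indent=2,
                )


def ccf(
    x: Mapping[int, float],
    y: Mapping[int, float],
    max_lag: int = 10,
    name_x: str = "x",
    name_y: str = "y",
) -> CCFResult:
    """Cross-correlation function between two year-indexed series.

    Correlations are computed on the overlapping year pairs at each lag
    (pairwise-complete).  The threshold is 1.96/sqrt(n) with n the lag-0
    overlap.
    """
    if max_lag < 0:
        raise ValueError("max_lag must be ≥ 0")
    lags = np.arange(-max_lag, max_lag + 1)
    corrs: dict[int, float] = {}
    n_overlap: dict[int, int] = {}
    y_years = set(y)
    for k in lags:
        pairs = [(x[t + k], y[t]) for t in y_years if (t + k) in x]
        n_overlap[int(k)] = len(pairs)
        if len(pairs) < 3:
            continue
        xa = np.array([p[0] for p in pairs])
        ya = np.array([p[1] for p in pairs])
        if np.ptp(xa) == 0 or np.ptp(ya) == 0:
            continue
        corrs[int(k)] = float(stats.pearsonr(xa, ya).statistic)
    n0 = n_overlap.get(0, 0)
    if n0 < 3:
        raise ValueError(f"need ≥ 3 overlapping years at lag 0, got {n0}")
    return CCFResult(
        series_x=name_x,
        series_y=name_y,
        lags=lags,
        correlations=corrs,
        n_overlap=n_overlap,
        threshold=1.96 / math.sqrt(n0),
    )


def lagged_r2(result: CCFResult, lag: int) -> float:
    """Squared cross-correlation at the requested lag."""
    return result.r(lag) ** 2
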