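"""Zooplankton community change detection.

Yearly taxon-abundance matrices are log(x+1) transformed, turned into a
Bray-Curtis dissimilarity matrix, and clustered agglomeratively under a
chronological-contiguity constraint (only temporally adjacent clusters may
merge) with an incremental sum-of-squares merge criterion — the standard
stratigraphically constrained approach for locating regime breaks in time.
The full merge-height profile is reported and the deepest breaks suggested
by the largest merge increments; the final zone count is left to the user,
since break depth is ultimately a judgement call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CommunityMatrix",
    "Zonation",
    "log_transform",
    "bray_curtis",
    "chronological_cluster",
    "zscore_series",
    "aggregate_taxa",
]


@dataclass
class CommunityMatrix:
    """Year × taxon abundance matrix (individuals per m², nonnegative)."""

    years: np.ndarray
    taxa: list[str]
    abundance: np.ndarray  # (n_years, n_taxa)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.years), len(self.taxa)):
            raise ValueError("abundance shape must be (n_years, n_taxa)")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be nonnegative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CommunityMatrix":
        """First column ``year``, remaining columns taxon abundances."""
        df = pd.read_csv(path)
        if df.columns[0] != "year":
            raise ValueError("first column of a community CSV must be 'year'")
        return cls(
            years=df["year"].to_numpy(),
            taxa=list(df.columns[1:]),
            abundance=df.iloc[:, 1:].to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.abundance, columns=self.taxa)
        df.insert(0, "year", self.years)
        return df

    def taxon_series(self, taxon: str) -> dict[int, float]:
        j = self.taxa.index(taxon)
        return {int(y): float(v) for y, v in zip(self.years, self.abundance[:, j])}


def log_transform(matrix: CommunityMatrix | np.ndarray, offset: float = 1.0):
    """Elementwise ln(a + offset); the offset (default 1) handles zeros."""
    a = matrix.abundance if isinstance(matrix, CommunityMatrix) else np.asarray(matrix, float)
    if np.any(a < 0):
        raise ValueError("abundances must be nonnegative")
    out = np.log(a + offset)
    if isinstance(matrix, CommunityMatrix):
        return CommunityMatrix(matrix.years, list(matrix.taxa), out)
    return out


def bray_curtis(matrix: CommunityMatrix | np.ndarray) -> np.ndarray:
    """Year × year Bray-Curtis dissimilarity, d = Σ|a−b| / Σ(a+b) ∈ [0, 1].

    A pair of all-zero rows has an undefined quotient; it is reported as 0
    (identical emptiness) with a warning.
    """
    a = matrix.abundance if isinstance(matrix, CommunityMatrix) else np.asarray(matrix, float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need a 2-D matrix with ≥ 2 rows")
    zero_rows = ~a.any(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(a, metric="braycurtis"))
    if zero_rows.sum() >= 2:
        warnings.warn(
            "all-zero year rows present; their mutual dissimilarity is set to 0",
            UserWarning,
            stacklevel=2,
        )
    d = np.nan_to_num(d, nan=0.0)
    return d


@dataclass
class Zonation:
    """Result of chronologically constrained clustering.

    ``merge_heights[i]`` is the within-zone dispersion increment of the
    (i+1)-th merge; ``boundary_removed[i]`` the year boundary erased by that
    merge (a boundary at year y separates years < y from years ≥ y).  Zone
    boundaries for any zone count are recovered by undoing the last merges.
    """

    years: np.ndarray
    merge_heights: np.ndarray
    boundary_removed: list[int]
    n_zones: int
    zone_boundaries: list[int]

    def boundaries(self, n_zones: int) -> list[int]:
        """Break years delimiting the requested number of contiguous zones."""
        n = len(self.years)
        if not 1 <= n_zones <= n:
            raise ValueError(f"n_zones must be in [1, {n}], got {n_zones}")
        kept = self.boundary_removed[len(self.boundary_removed) - (n_zones - 1):]
        return sorted(kept)

    def zones(self, n_zones: int) -> list[tuple[int, int]]:
        """(first_year, last_year) per zone for the requested count."""
        bounds = self.boundaries(n_zones)
        edges = [int(self.years[0])] + bounds + [int(self.years[-1]) + 1]
        return [(edges[i], edges[i + 1] - 1) for i in range(len(edges) - 1)]

    def suggest_n_zones(self) -> int:
        """Largest-gap heuristic on the merge-height profile.

        The deepest break is where consecutive merge heights jump most;
        cutting just before the jump gives the suggested zone count.  A
        heuristic aid only — break depth is meant to be judged by eye on
        the full profile.
        """
        h = self.merge_heights
        if len(h) < 2:
            return 1
        gaps = np.diff(h)
        return len(h) - int(np.argmax(gaps))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "merge": np.arange(1, len(self.merge_heights) + 1),
                "height": self.merge_heights,
                "cumulative": np.cumsum(self.merge_heights),
                "boundary_removed": self.boundary_removed,
            }
        )


def _within_dispersion(d2: np.ndarray, members: range) -> float:
    """CONISS-style dispersion of a contiguous block: Σ_{i<j} d²_ij / |C|."""
    idx = np.fromiter(members, dtype=int)
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def chronological_cluster(
    dissimilarity: np.ndarray,
    years: Sequence[int],
    n_zones: int | None = None,
) -> Zonation:
    """Chronologically constrained agglomerative clustering (CONISS-style).

    Only temporally adjacent clusters may merge; the pair merged at each
    step is the one with the smallest increase in within-cluster dispersion,
    computed from squared dissimilarities.  Returns the full merge-height
    sequence plus zone boundaries for ``n_zones`` (default: the largest-gap
    suggestion).
    """
    d = np.asarray(dissimilarity, dtype=float)
    years = np.asarray(years, dtype=int)
    n = len(years)
    if d.shape != (n, n):
        raise ValueError("dissimilarity must be square and match years")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be symmetric")
    if n_zones is not None and not 1 <= n_zones <= n:
        raise ValueError(f"n_zones must be in [1, {n}], got {n_zones}")
    d2 = d**2

    # clusters as contiguous index ranges, in chronological order
    clusters: list[range] = [range(i, i + 1) for i in range(n)]
    disp = [0.0] * n
    heights: list[float] = []
    removed: list[int] = []
    while len(clusters) > 1:
        best_j = -1
        best_inc = float("inf")
        for j in range(len(clusters) - 1):
            a, b = clusters[j], clusters[j + 1]
            merged = range(a.start, b.stop)
            inc = _within_dispersion(d2, merged) - disp[j] - disp[j + 1]
            if inc < best_inc - 1e-15:
                best_inc = inc
                best_j = j
        a, b = clusters[best_j], clusters[best_j + 1]
        removed.append(int(years[b.start]))
        merged = range(a.start, b.stop)
        clusters[best_j : best_j + 2] = [merged]
        disp[best_j : best_j + 2] = [_within_dispersion(d2, merged)]
        heights.append(best_inc)

    zn = Zonation(
        years=years,
        merge_heights=np.asarray(heights),
        boundary_removed=removed,
        n_zones=0,
        zone_boundaries=[],
    )
    k = n_zones if n_zones is not None else zn.suggest_n_zones()
    zn.n_zones = k
    zn.zone_boundaries = zn.boundaries(k)
    return zn


def zscore_series(values: Sequence[float]) -> np.ndarray:
    """(v − mean)/SD with the sample SD (denominator n−1)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need ≥ 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; z-scores undefined")
    return (v - v.mean()) / sd


def aggregate_taxa(
    matrix: CommunityMatrix, taxa: Sequence[str], name: str = "group"
) -> dict[int, float]:
    """Sum abundances over a taxon group (e.g. all 'small copepod' taxa)."""
    missing = [t for t in taxa if t not in matrix.taxa]
    if missing:
        raise ValueError(f"taxa not in matrix: {missing}")
    idx = [matrix.taxa.index(t) for t in taxa]
    total = matrix.abundance[:, idx].sum(axis=1)
    return {int(y): float(v) for y, v in zip(matrix.years, total)}
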