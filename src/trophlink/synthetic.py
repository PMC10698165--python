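"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a multi-decadal larval-fish isotope study: latent
annual random walks (food chain length and the source-nitrogen baseline)
observed through per-specimen amino-acid δ¹⁵N with procedural noise, only a
fraction of years sampled, companion annual series (larval size ratio,
spawning stock biomass) coupled to the trophic series at known lags, and a
taxon-abundance matrix with an optional planted community break.  Every
latent truth is emitted alongside the observations so recovery can be
tested end to end; couplings are built constructively on the random-walk
innovations (shared innovations with scaled loadings), so correlation
targets hold in expectation rather than by rejection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .community import CommunityMatrix
from .isotope import (
    ALL_AAS,
    SOURCE_AAS,
    TROPHIC_AAS,
    AAProfile,
    CalibrationConstants,
    write_specimen_csv,
)
from .ssm import AnnualSeries

__all__ = [
    "BoomBust",
    "ScenarioConfig",
    "SyntheticDataset",
    "simulate_latent_walk",
    "simulate_aa_profiles",
    "simulate_coupled_system",
    "write_dataset",
]


@dataclass(frozen=True)
class BoomBust:
    """Step change planted in the latent series (a regime shift).

    ``delta_fcl`` is added to the food-chain-length walk from ``year`` on;
    ``delta_source`` (‰) shifts the source-nitrogen baseline the same way.
    The community matrix breaks at the same year.
    """

    year: int
    delta_fcl: float = 0.5
    delta_source: float = -2.5


@dataclass
class ScenarioConfig:
    """Study-design parameters for a full synthetic dataset.

    Defaults emulate the reference study design: a 45-year window with
    roughly 20 sampled springs, 3–15 specimens per sampled year, random-walk
    latent dynamics, a strong positive size-ratio coupling at lag 0 and a
    negative spawning-stock coupling at a 1-year lag.
    """

    n_years: int = 45
    start_year: int = 1961
    sampled_year_fraction: float = 0.45
    specimens_per_year: tuple[int, int] = (3, 15)
    q_fcl: float = 0.04          # process variance of the FCL walk
    fcl_start: float = 3.0
    source_walk_q: float = 0.04  # ‰² per year, source-baseline walk
    source_start: float = 8.0    # ‰, typical coastal Phe baseline
    q_size: float = 0.04         # log10 size-ratio walk
    q_ssb: float = 0.04          # log10 SSB walk
    r_obs: float = 0.25          # observation variance of companion series
    obs_per_year: int = 5
    coupling_fcl_size: float = 0.8    # lag-0 innovation correlation
    coupling_size_ssb: float = -0.6   # lag-1 innovation correlation
    boom_bust: BoomBust | None = None
    noise_scale: float = 1.0
    ala_protist_shift: float = 0.0  # ‰ planted Ala enrichment
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.sampled_year_fraction <= 1.0):
            raise ValueError("sampled_year_fraction must be in (0, 1]")
        for name in ("q_fcl", "source_walk_q", "q_size", "q_ssb", "r_obs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("coupling_fcl_size", "coupling_size_ssb"):
            if not abs(getattr(self, name)) < 1.0:
                raise ValueError(f"|{name}| must be < 1")
        lo, hi = self.specimens_per_year
        if not (1 <= lo <= hi):
            raise ValueError("specimens_per_year must be a nondecreasing positive range")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


@dataclass
class SyntheticDataset:
    """Latent truth plus every observable the pipeline consumes."""

    truth: dict[str, dict[int, float]]
    specimens: list[AAProfile]
    annual_series: dict[str, AnnualSeries]
    community: CommunityMatrix
    sampled_years: list[int]
    break_year: int | None
    scenario: ScenarioConfig


def simulate_latent_walk(
    n_years: int,
    q: float,
    x1: float,
    seed: int | np.random.Generator = 0,
    start_year: int = 1,
) -> dict[int, float]:
    """Random walk x_t = x_{t−1} + w_t, w_t ~ N(0, Q), keyed by year."""
    if n_years < 2:
        raise ValueError("need at least 2 years")
    if q < 0:
        raise ValueError("Q must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(q), size=n_years - 1)
    x = x1 + np.concatenate([[0.0], np.cumsum(steps)])
    return {int(start_year + t): float(v) for t, v in enumerate(x)}


def simulate_aa_profiles(
    fcl_series: Mapping[int, float],
    source_series: Mapping[int, float],
    calib: CalibrationConstants | None = None,
    n_per_year: int | tuple[int, int] = (3, 15),
    noise_scale: float = 1.0,
    missing_years: Sequence[int] = (),
    seed: int | np.random.Generator = 0,
    ala_protist_shift: float = 0.0,
    source_offsets: Mapping[str, float] | None = None,
) -> list[AAProfile]:
    """Forward model: per-specimen amino-acid δ¹⁵N from latent FCL and baseline.

    Source amino acids take the year's baseline (plus an optional per-AA
    offset, default 0); trophic amino acids sit β̄ + TDF̄·(FCL−1) above it,
    using the same pooled uncertainty-weighted β̄/TDF̄ the multi-AA estimator
    applies — so at ``noise_scale=0`` the estimator inverts the forward
    model exactly.  Per-AA noise is N(0, (noise_scale·σ_AA)²) with σ_AA the
    procedural SDs; ``ala_protist_shift`` plants extra Ala enrichment (a
    protistan-pathway signal).
    """
    calib = calib or CalibrationConstants.default()
    for aa in ALL_AAS:
        if aa not in calib.procedural_sd:
            raise ValueError(f"calibration lacks a procedural SD for {aa}")
    offsets = dict.fromkeys(ALL_AAS, 0.0)
    if source_offsets:
        offsets.update(source_offsets)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta, tdf = calib.weighted_beta_tdf()
    missing = set(int(y) for y in missing_years)
    profiles = []
    for year in sorted(fcl_series):
        if year in missing:
            continue
        if year not in source_series:
            raise ValueError(f"source series lacks year {year}")
        fcl = fcl_series[year]
        base = source_series[year]
        if isinstance(n_per_year, tuple):
            n = int(rng.integers(n_per_year[0], n_per_year[1] + 1))
        else:
            n = int(n_per_year)
        for i in range(n):
            d15n = {}
            for aa in SOURCE_AAS:
                sd = noise_scale * calib.procedural_sd[aa]
                d15n[aa] = base + offsets[aa] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            trophic_level = beta + tdf * (fcl - 1.0)
            for aa in TROPHIC_AAS:
                sd = noise_scale * calib.procedural_sd[aa]
                v = base + trophic_level + offsets[aa]
                if aa == "Ala":
                    v += ala_protist_shift
                d15n[aa] = v + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            profiles.append(
                AAProfile(
                    specimen_id=f"Y{year}S{i:02d}",
                    year=int(year),
                    d15n=d15n,
                    station=f"ST{i % 3 + 1}",
                )
            )
    return profiles


_TAXA = [
    "Calanus_pacificus",
    "small_copepods",
    "Metridia_pacifica",
    "Eucalanus_californicus",
    "Pleuromamma_borealis",
    "Oithona_spp",
    "Acartia_tonsa",
    "Clausocalanus_spp",
]
_LOG10_BASE = np.array([2.8, 3.5, 2.2, 1.8, 1.6, 3.0, 2.5, 2.3])
_LOG10_SHIFT = np.array([-1.0, 0.2, -0.4, -0.3, -0.2, 0.0, 0.1, 0.0])


def _simulate_community(
    years: np.ndarray, break_year: int | None, rng: np.random.Generator
) -> CommunityMatrix:
    """Lognormal taxon abundances with an optional planted regime shift."""
    noise = rng.normal(0.0, 0.15, size=(len(years), len(_TAXA)))
    log10 = _LOG10_BASE[None, :] + noise
    if break_year is not None:
        log10[years >= break_year] += _LOG10_SHIFT[None, :]
    return CommunityMatrix(years=years, taxa=list(_TAXA), abundance=10.0**log10)


def simulate_coupled_system(scenario: ScenarioConfig) -> SyntheticDataset:
    """Full synthetic study: coupled latent walks, specimens, series, community.

    The size-ratio walk shares the FCL walk's innovations with a loading
    that targets the configured lag-0 correlation; the SSB walk loads on
    the previous year's size-ratio innovation with the configured (negative)
    lag-1 correlation.  An optional boom-bust step enters as an extra
    innovation at the step year and so propagates through the couplings.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    years = sc.years
    n = sc.n_years

    step = np.zeros(n - 1)
    src_step = np.zeros(n - 1)
    if sc.boom_bust is not None:
        if not years[1] <= sc.boom_bust.year <= years[-1]:
            raise ValueError("boom_bust year outside the simulated window")
        idx = int(sc.boom_bust.year - years[0]) - 1
        step[idx] = sc.boom_bust.delta_fcl
        src_step[idx] = sc.boom_bust.delta_source

    e_fcl = rng.normal(0.0, np.sqrt(sc.q_fcl), n - 1) + step
    r0 = sc.coupling_fcl_size
    e_size = (
        r0 * np.sqrt(sc.q_size / sc.q_fcl) * e_fcl
        + np.sqrt(sc.q_size * (1 - r0**2)) * rng.standard_normal(n - 1)
    )
    r1 = sc.coupling_size_ssb
    e_ssb = np.sqrt(sc.q_ssb * (1 - r1**2)) * rng.standard_normal(n - 1)
    e_ssb[1:] += r1 * np.sqrt(sc.q_ssb / sc.q_size) * e_size[:-1]
    e_src = rng.normal(0.0, np.sqrt(sc.source_walk_q), n - 1) + src_step

    def walk(start: float, innov: np.ndarray) -> np.ndarray:
        return start + np.concatenate([[0.0], np.cumsum(innov)])

    fcl = walk(sc.fcl_start, e_fcl)
    size = walk(0.0, e_size)       # log10 large:small ratio
    ssb = walk(1.0, e_ssb)         # log10 biomass (arbitrary units)
    source = walk(sc.source_start, e_src)

    truth = {
        "fcl": {int(y): float(v) for y, v in zip(years, fcl)},
        "source_d15n": {int(y): float(v) for y, v in zip(years, source)},
        "size_ratio_log10": {int(y): float(v) for y, v in zip(years, size)},
        "ssb_log10": {int(y): float(v) for y, v in zip(years, ssb)},
    }

    n_sampled = max(2, round(sc.sampled_year_fraction * n))
    sampled = np.sort(rng.choice(years, size=n_sampled, replace=False))
    missing = [int(y) for y in years if y not in set(sampled.tolist())]
    specimens = simulate_aa_profiles(
        truth["fcl"],
        truth["source_d15n"],
        n_per_year=sc.specimens_per_year,
        noise_scale=sc.noise_scale,
        missing_years=missing,
        seed=rng,
        ala_protist_shift=sc.ala_protist_shift,
    )

    sd_obs = float(np.sqrt(sc.r_obs))
    yr_range = (int(years[0]), int(years[-1]))

    def observe(latent: np.ndarray, name: str) -> AnnualSeries:
        obs = []
        for y, x in zip(years, latent):
            for i in range(sc.obs_per_year):
                obs.append((int(y), float(x + rng.normal(0.0, sd_obs)), f"r{i}"))
        return AnnualSeries(name=name, observations=obs, year_range=yr_range)

    annual = {
        "size_ratio_log10": observe(size, "size_ratio_log10"),
        "ssb_log10": observe(ssb, "ssb_log10"),
    }

    break_year = sc.boom_bust.year if sc.boom_bust is not None else None
    community = _simulate_community(years, break_year, rng)

    return SyntheticDataset(
        truth=truth,
        specimens=specimens,
        annual_series=annual,
        community=community,
        sampled_years=[int(y) for y in sampled],
        break_year=break_year,
        scenario=sc,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the full fixture set (CSV observations + truth JSON) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["specimens"] = out / "specimens.csv"
    write_specimen_csv(dataset.specimens, paths["specimens"])

    for name, series in dataset.annual_series.items():
        p = out / f"{name}.csv"
        series.to_dataframe().to_csv(p, index=False)
        paths[name] = p

    paths["community"] = out / "community.csv"
    dataset.community.to_dataframe().to_csv(paths["community"], index=False)

    sc = asdict(dataset.scenario)
    if dataset.scenario.boom_bust is not None:
        sc["boom_bust"] = asdict(dataset.scenario.boom_bust)
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "truth": dataset.truth,
                "sampled_years": dataset.sampled_years,
                "break_year": dataset.break_year,
                "scenario": sc,
            },
            fh,
            indent=2,
        )
    return paths
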