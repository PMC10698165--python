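"""End-to-end orchestration: specimens → trophic metrics → state-space fits
→ cross-correlations → community zonation → period contrasts.

Also houses the larval size-ratio constructor (large 10–20 mm : small
5–10 mm counts) and boom/bust period summaries.  Every run writes a
manifest recording input hashes, the seed and the package version, so a
rerun with the same seed is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import CommunityMatrix, bray_curtis, chronological_cluster, log_transform, zscore_series
from .crosscorr import ccf
from .isotope import (
    CalibrationConstants,
    compute_fcl_table,
    filter_standard_length,
    read_specimen_csv,
)
from .ssm import AnnualSeries, SSMConfig, SSMPosterior, fit_ssm, write_posterior

log = logging.getLogger("trophlink")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "size_ratio_series",
    "period_summary",
    "percent_difference",
    "run_pipeline",
]

# Half-open length bins [lower, upper): a 10.0 mm larva is "large", a
# 20.0 mm larva is outside both bins.  Avoids double-counting shared edges.
SMALL_BIN = (5.0, 10.0)
LARGE_BIN = (10.0, 20.0)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _in_bin(length: float, bin_: tuple[float, float]) -> bool:
    return bin_[0] <= length < bin_[1]


def _parse_length_label(label: str) -> tuple[float, float]:
    """A column label is either a point length ('9.5') or a range ('5-10')."""
    s = str(label).strip().removesuffix("mm").strip()
    if "-" in s[1:]:  # allow a leading minus sign to fail later
        lo, hi = s.split("-", 1)
        lo_f, hi_f = float(lo), float(hi)
        if not lo_f < hi_f:
            raise ValueError(f"ill-formed length bin {label!r}")
        return lo_f, hi_f
    v = float(s)
    return v, v


def size_ratio_series(counts: pd.DataFrame, name: str = "size_ratio") -> AnnualSeries:
    """Large (10–20 mm) to small (5–10 mm) larval count ratio per year.

    ``counts`` has a ``year`` column and length-labelled count columns
    (point lengths in mm, or 'lo-hi' ranges that must fall entirely within
    one bin).  Counts are pooled within each year; years whose small-larvae
    count is zero become missing (with a warning), never infinite.
    """
    if "year" not in counts.columns:
        raise ValueError("counts table needs a 'year' column")
    small_cols, large_cols = [], []
    for col in counts.columns:
        if col == "year":
            continue
        lo, hi = _parse_length_label(col)
        in_small = _in_bin(lo, SMALL_BIN) and (lo == hi or hi <= SMALL_BIN[1])
        in_large = _in_bin(lo, LARGE_BIN) and (lo == hi or hi <= LARGE_BIN[1])
        if lo != hi and _in_bin(lo, SMALL_BIN) and hi > SMALL_BIN[1]:
            raise ValueError(f"length bin {col!r} straddles the small/large edge")
        if in_small:
            small_cols.append(col)
        elif in_large:
            large_cols.append(col)
        # lengths outside [5, 20) are simply not part of the ratio
    if np.any(counts.drop(columns="year").to_numpy(dtype=float) < 0):
        raise ValueError("counts must be nonnegative")
    obs = []
    grouped = counts.groupby("year")[small_cols + large_cols].sum()
    for year, row in grouped.iterrows():
        small = float(row[small_cols].sum()) if small_cols else 0.0
        large = float(row[large_cols].sum()) if large_cols else 0.0
        if small == 0:
            warnings.warn(
                f"year {year}: zero small-larvae count; size ratio missing",
                UserWarning,
                stacklevel=2,
            )
            continue
        obs.append((int(year), large / small, None))
    if not obs:
        raise ValueError("no year had a nonzero small-larvae count")
    years = sorted(int(y) for y in counts["year"].unique())
    return AnnualSeries(name=name, observations=obs, year_range=(years[0], years[-1]))


Periods = Mapping[str, Sequence[tuple[int, int]]]


def period_summary(series: Mapping[int, float], periods: Periods) -> pd.DataFrame:
    """Arithmetic mean of annual values within each (possibly multi-interval)
    period.  Intervals within a period must be well-formed and disjoint, and
    each period must contain at least one year of the series."""
    rows = []
    for name, intervals in periods.items():
        yrs: list[int] = []
        seen: set[int] = set()
        for lo, hi in intervals:
            if lo > hi:
                raise ValueError(f"period {name!r}: interval {lo}-{hi} reversed")
            for y in range(lo, hi + 1):
                if y in seen:
                    raise ValueError(f"period {name!r}: year {y} listed twice")
                seen.add(y)
                if y in series:
                    yrs.append(y)
        if not yrs:
            raise ValueError(f"period {name!r} contains no years of the series")
        vals = [series[y] for y in yrs]
        rows.append(
            {"period": name, "n_years": len(yrs), "mean": float(np.mean(vals))}
        )
    return pd.DataFrame(rows)


def percent_difference(summary: pd.DataFrame, a: str, b: str) -> float:
    """(mean_A − mean_B) / mean_B × 100."""
    means = summary.set_index("period")["mean"]
    return float((means[a] - means[b]) / means[b] * 100.0)


@dataclass
class PipelineConfig:
    """Declarative description of a full analysis run."""

    outdir: str | Path
    specimen_csv: str | Path | None = None
    series_csvs: dict[str, str | Path] = field(default_factory=dict)
    community_csv: str | Path | None = None
    ccf_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    periods: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    period_contrast: tuple[str, str] | None = None
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)
    ssm: dict = field(default_factory=dict)        # global SSMConfig overrides
    ssm_per_series: dict[str, dict] = field(default_factory=dict)
    sl_filter: tuple[float, float] | None = None   # standard-length window, mm
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        kwargs: dict = {"outdir": _resolve(raw["outdir"])}
        if raw.get("specimen_csv"):
            kwargs["specimen_csv"] = _resolve(raw["specimen_csv"])
        kwargs["series_csvs"] = {
            k: _resolve(v) for k, v in raw.get("series_csvs", {}).items()
        }
        if raw.get("community_csv"):
            kwargs["community_csv"] = _resolve(raw["community_csv"])
        kwargs["ccf_pairs"] = [
            (p["x"], p["y"], int(p.get("max_lag", 10))) for p in raw.get("ccf_pairs", [])
        ]
        kwargs["periods"] = {
            name: [tuple(iv) for iv in ivs] for name, ivs in raw.get("periods", {}).items()
        }
        if raw.get("period_contrast"):
            kwargs["period_contrast"] = tuple(raw["period_contrast"])
        if raw.get("calibration"):
            kwargs["calibration"] = CalibrationConstants.from_dict(raw)
        kwargs["ssm"] = raw.get("ssm", {})
        kwargs["ssm_per_series"] = raw.get("ssm_per_series", {})
        if raw.get("sl_filter"):
            kwargs["sl_filter"] = tuple(raw["sl_filter"])
        kwargs["seed"] = int(raw.get("seed", 0))
        return cls(**kwargs)


@dataclass
class PipelineReport:
    outdir: Path
    fcl_table: pd.DataFrame | None
    posteriors: dict[str, SSMPosterior]
    ccf_results: dict[str, "object"]
    zonation: "object | None"
    period_summaries: dict[str, pd.DataFrame]
    manifest: dict

    def map_series(self, name: str) -> dict[int, float]:
        return self.posteriors[name].map_mapping()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis graph and write all artifacts.

    Stages: trophic metrics from specimens → per-series state-space fits →
    cross-correlations of MAP series → community zonation → period
    contrasts → manifest.  Any stage failure aborts with a stage-named
    error.  Given the same inputs and seed, outputs are byte-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    outputs: list[str] = []
    posteriors: dict[str, SSMPosterior] = {}
    series_for_ssm: dict[str, AnnualSeries] = {}
    fcl_table = None
    gge = config.calibration.gge

    @_stage("isotope")
    def stage_isotope():
        nonlocal fcl_table
        if config.specimen_csv is None:
            return
        path = Path(config.specimen_csv)
        inputs[str(path)] = _sha256(path)
        profiles = read_specimen_csv(path)
        if config.sl_filter is not None:
            profiles = filter_standard_length(profiles, *config.sl_filter)
        fcl_table = compute_fcl_table(profiles, config.calibration)
        p = outdir / "fcl_table.csv"
        fcl_table.to_csv(p, index=False)
        outputs.append(p.name)
        usable = fcl_table.dropna(subset=["fcl_trp_scr"])
        series_for_ssm["fcl"] = AnnualSeries(
            name="fcl",
            observations=[
                (int(r.year), float(r.fcl_trp_scr), str(r.specimen_id))
                for r in usable.itertuples()
            ],
        )
        log.info("isotope: %d specimens, %d with multi-AA FCL", len(profiles), len(usable))

    @_stage("ssm")
    def stage_ssm():
        for name, path in config.series_csvs.items():
            path = Path(path)
            inputs[str(path)] = _sha256(path)
            series_for_ssm[name] = AnnualSeries.from_csv(path, name=name)
        for i, (name, series) in enumerate(sorted(series_for_ssm.items())):
            overrides = dict(config.ssm)
            overrides.update(config.ssm_per_series.get(name, {}))
            overrides.setdefault("seed", config.seed + i)
            post = fit_ssm(series, SSMConfig(**overrides))
            posteriors[name] = post
            write_posterior(post, outdir / f"ssm_{name}.csv", outdir / f"ssm_{name}.json")
            outputs.extend([f"ssm_{name}.csv", f"ssm_{name}.json"])
            log.info("ssm: %s max R-hat %.3f", name, post.max_rhat())
        if "fcl" in posteriors:
            eff = {
                y: gge ** (m - 1.0) if m >= 1.0 else float("nan")
                for y, m in posteriors["fcl"].map_mapping().items()
            }
            p = outdir / "transfer_efficiency_map.csv"
            pd.DataFrame(
                {"year": list(eff), "transfer_efficiency": list(eff.values())}
            ).to_csv(p, index=False)
            outputs.append(p.name)

    ccf_results: dict[str, object] = {}

    @_stage("ccf")
    def stage_ccf():
        for x_name, y_name, max_lag in config.ccf_pairs:
            for n in (x_name, y_name):
                if n not in posteriors:
                    raise ValueError(f"ccf pair references unfitted series {n!r}")
            res = ccf(
                posteriors[x_name].map_mapping(),
                posteriors[y_name].map_mapping(),
                max_lag=max_lag,
                name_x=x_name,
                name_y=y_name,
            )
            key = f"{x_name}~{y_name}"
            ccf_results[key] = res
            stem = f"ccf_{x_name}__{y_name}"
            res.write(outdir / f"{stem}.csv", outdir / f"{stem}.json")
            outputs.extend([f"{stem}.csv", f"{stem}.json"])

    zonation = None

    @_stage("community")
    def stage_community():
        nonlocal zonation
        if config.community_csv is None:
            return
        path = Path(config.community_csv)
        inputs[str(path)] = _sha256(path)
        matrix = CommunityMatrix.from_csv(path)
        d = bray_curtis(log_transform(matrix))
        zonation = chronological_cluster(d, matrix.years)
        zonation.summary_frame().to_csv(outdir / "merge_heights.csv", index=False)
        with open(outdir / "zonation.json", "w") as fh:
            json.dump(
                {
                    "n_zones": zonation.n_zones,
                    "zone_boundaries": zonation.zone_boundaries,
                    "zones": zonation.zones(zonation.n_zones),
                },
                fh,
                indent=2,
            )
        z = pd.DataFrame(
            {t: zscore_series(matrix.abundance[:, j]) for j, t in enumerate(matrix.taxa)}
        )
        z.insert(0, "year", matrix.years)
        z.to_csv(outdir / "community_zscores.csv", index=False)
        outputs.extend(["merge_heights.csv", "zonation.json", "community_zscores.csv"])

    period_summaries: dict[str, pd.DataFrame] = {}

    @_stage("periods")
    def stage_periods():
        if not config.periods:
            return
        for name, post in posteriors.items():
            series = post.map_mapping()
            if name == "fcl":
                # period contrast the efficiency scale as well
                eff = {y: gge ** (m - 1.0) for y, m in series.items() if m >= 1.0}
                summ = period_summary(eff, config.periods)
                if config.period_contrast:
                    a, b = config.period_contrast
                    summ["pct_vs_" + b] = [
                        percent_difference(summ, p, b) for p in summ["period"]
                    ]
                period_summaries["transfer_efficiency"] = summ
            summ = period_summary(series, config.periods)
            period_summaries[name] = summ
        p = outdir / "period_summaries.csv"
        pd.concat(
            [df.assign(series=name) for name, df in period_summaries.items()]
        ).to_csv(p, index=False)
        outputs.append(p.name)

    stage_isotope()
    stage_ssm()
    stage_ccf()
    stage_community()
    stage_periods()

    manifest = {
        "package": "trophlink",
        "version": __version__,
        "seed": config.seed,
        "inputs_sha256": inputs,
        "outputs": sorted(set(outputs)) + ["manifest.json"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineReport(
        outdir=outdir,
        fcl_table=fcl_table,
        posteriors=posteriors,
        ccf_results=ccf_results,
        zonation=zonation,
        period_summaries=period_summaries,
        manifest=manifest,
    )
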