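"""End-to-end orchestration: simulate -> analyze -> report from one config.

The configuration is a single YAML document with a versioned schema;
unknown keys are rejected (silent typos corrupt science).  Every stage is
a pure function of config + seed: outputs are written under ``out_dir``
and a stage whose outputs already exist is skipped, so partial runs resume
from cached intermediates.  Identical config + seed gives byte-identical
tables.
"""

from __future__ import annotations

import datetime
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import detect_events, event_frequency_mHz, waveform_metrics
from .extraction import DffTrace, RawTrace, compute_f0, neuropil_correct, to_dff
from .imaging import render_neuron_image
from .io import write_image_tiff, write_traces_csv, write_truth_csv, read_traces_csv
from .longitudinal import (
    group_compare,
    growth_rates,
    profile_correlation,
    stage_profiles,
)
from .morphometry import nc_ratio_and_class, soma_area, total_neurite_length
from .presets import build_morph_presets, build_stage_presets
from .simulate import simulate_view
from .spectral import amplitude_spectrum, band_fractions, view_synchrony

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]

_SIMULATE_DEFAULTS = {
    "n_cells": 30,
    "duration_s": 600.0,
    "fs": 5.0,
    "n_images": 8,
    "stage_days": [3, 6, 10, 14, 17, 21, 28],
    "conditions": ["healthy", "toxic"],
    "neuropil_coeff": 0.7,
    "write_images": False,
}
_PARAM_DEFAULTS = {
    "r": 0.7,
    "k": 3.0,
    "n_rest": 5,
    "smooth_window": 3,
    "min_separation": None,
    "cutoff": 0.8,
    "band_edges_mHz": [0.0, 10.0, 100.0, 300.0],
}
_STAGES = ("simulate", "analyze", "report")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    out_dir: Path
    stages: tuple[str, ...] = _STAGES
    simulate: dict = field(default_factory=lambda: dict(_SIMULATE_DEFAULTS))
    params: dict = field(default_factory=lambda: dict(_PARAM_DEFAULTS))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        schema = raw.pop("schema", 1)
        if schema != 1:
            raise ValueError(f"unsupported config schema: {schema}")
        seed = raw.pop("seed", 0)
        out_dir = Path(raw.pop("out_dir", "caosc_run"))
        stages = tuple(raw.pop("stages", _STAGES))
        for s in stages:
            if s not in _STAGES:
                raise ValueError(f"unknown pipeline stage: {s!r}")
        simulate = dict(_SIMULATE_DEFAULTS)
        for key, value in raw.pop("simulate", {}).items():
            if key not in _SIMULATE_DEFAULTS:
                raise ValueError(f"unknown config key: simulate.{key}")
            simulate[key] = value
        params = dict(_PARAM_DEFAULTS)
        for key, value in raw.pop("params", {}).items():
            if key not in _PARAM_DEFAULTS:
                raise ValueError(f"unknown config key: params.{key}")
            params[key] = value
        if raw:
            raise ValueError(f"unknown config key(s): {sorted(raw)}")
        return cls(
            seed=int(seed), out_dir=out_dir, stages=stages,
            simulate=simulate, params=params,
        )


@dataclass
class RunReport:
    """Tables produced by a pipeline run plus provenance."""

    tables: dict[str, pd.DataFrame]
    provenance: dict


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _derived_seed(base: int, *context: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and context ids."""
    ss = np.random.SeedSequence((base, *context))
    return int(ss.generate_state(1)[0] % (2**31))


def _log(msg: str) -> None:
    print(f"[caosc] {msg}", file=sys.stderr)


def _neuropil_trace(
    n: int, fs: float, baseline_F: float, background_F: float, seed: int
) -> np.ndarray:
    """A slow common-background signal emulating neuropil contamination."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    period = rng.uniform(90.0, 150.0)
    return background_F + 0.3 * baseline_F * (
        1.0 + np.sin(2 * np.pi * t / period + phase)
    )


def _stage_simulate(cfg: RunConfig) -> None:
    sim = cfg.simulate
    presets = build_stage_presets()
    morph_presets = build_morph_presets()
    data_dir = cfg.out_dir / "data"
    for di, day in enumerate(sim["stage_days"]):
        for ci, cond in enumerate(sim["conditions"]):
            label = f"DIV{day}"
            stem = f"{label}_{cond}"
            traces_path = data_dir / f"traces_{stem}.csv"
            if traces_path.exists():
                _log(f"simulate: {stem} cached, skipping")
                continue
            preset = presets[(label, cond)]
            view = simulate_view(
                preset,
                n_cells=sim["n_cells"],
                duration_s=sim["duration_s"],
                fs=sim["fs"],
                seed=_derived_seed(cfg.seed, di, ci),
            )
            clean = view.traces
            neuropil = _neuropil_trace(
                clean.shape[1], sim["fs"], preset.baseline_F, preset.background_F,
                _derived_seed(cfg.seed, di, ci, 99),
            )
            measured = clean + sim["neuropil_coeff"] * neuropil
            write_traces_csv(traces_path, measured, sim["fs"], label, cond)
            write_traces_csv(
                data_dir / f"neuropil_{stem}.csv",
                neuropil[None, :], sim["fs"], label, cond,
            )
            write_truth_csv(data_dir / f"truth_{stem}.csv", view)
            if sim["write_images"]:
                img = render_neuron_image(
                    morph_presets[(label, cond)],
                    seed=_derived_seed(cfg.seed, di, ci, 7),
                )
                write_image_tiff(data_dir / f"neuron_{stem}.tif", img)
            _log(f"simulate: wrote {stem}")


def _analyze_view(
    measured: np.ndarray,
    neuropil: np.ndarray,
    fs: float,
    preset,
    params: dict,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell metrics and the view-level synchrony/band summary."""
    r = params["r"]
    edges_hz = tuple(e / 1000.0 for e in params["band_edges_mHz"])
    cell_rows = []
    dffs: list[DffTrace] = []
    band_accum = []
    for c in range(measured.shape[0]):
        raw = RawTrace(measured[c], fs, meta={"cell_id": c})
        if r:
            raw = neuropil_correct(raw, RawTrace(neuropil, fs), r=r)
        f0 = compute_f0(
            RawTrace(raw.values - preset.background_F, fs), n_rest=params["n_rest"]
        )
        dff = to_dff(raw, preset.background_F, f0)
        dff.meta["cell_id"] = c
        table = detect_events(
            dff, k=params["k"], min_separation=params["min_separation"]
        )
        table = waveform_metrics(dff, table)
        spec = amplitude_spectrum(dff)
        bands = band_fractions(spec, edges_hz)  # type: ignore[arg-type]
        band_accum.append(bands)
        cell_rows.append(
            {
                "cell": c,
                "frequency_mHz": event_frequency_mHz(table),
                "amplitude": table.events["amplitude"].mean(),
                "fwhm_s": table.events["fwhm"].mean(),
                "n_events": len(table),
                "threshold": table.threshold_used,
                "band_ultra_slow_pct": bands[0],
                "band_slow_pct": bands[1],
                "band_fast_pct": bands[2],
            }
        )
        dffs.append(dff)
    sync = view_synchrony(dffs)
    bands_mean = np.nanmean(np.array(band_accum, dtype=float), axis=0)
    view_summary = {
        "synchrony": sync.mean_coefficient,
        "band_ultra_slow_pct": bands_mean[0],
        "band_slow_pct": bands_mean[1],
        "band_fast_pct": bands_mean[2],
    }
    return pd.DataFrame(cell_rows), view_summary


def _stage_analyze(cfg: RunConfig) -> None:
    sim = cfg.simulate
    presets = build_stage_presets()
    morph_presets = build_morph_presets()
    data_dir = cfg.out_dir / "data"
    metrics_dir = cfg.out_dir / "metrics"
    metrics_dir.mkdir(parents=True, exist_ok=True)

    cells_path = metrics_dir / "cell_metrics.csv"
    views_path = metrics_dir / "view_metrics.csv"
    morph_path = metrics_dir / "morph_records.csv"
    if cells_path.exists() and views_path.exists() and morph_path.exists():
        _log("analyze: cached, skipping")
        return

    cell_frames, view_rows, morph_rows = [], [], []
    for di, day in enumerate(sim["stage_days"]):
        for ci, cond in enumerate(sim["conditions"]):
            label = f"DIV{day}"
            stem = f"{label}_{cond}"
            measured, fs, _ = read_traces_csv(data_dir / f"traces_{stem}.csv")
            neuropil, _, _ = read_traces_csv(data_dir / f"neuropil_{stem}.csv")
            preset = presets[(label, cond)]
            cells, view = _analyze_view(
                measured, neuropil[0], fs, preset, cfg.params
            )
            cells.insert(0, "div", day)
            cells.insert(1, "condition", cond)
            cell_frames.append(cells)
            view_rows.append({"div": day, "condition": cond, **view})

            mp = morph_presets[(label, cond)]
            for k in range(sim["n_images"]):
                img = render_neuron_image(
                    mp, seed=_derived_seed(cfg.seed, di, ci, 1000 + k)
                )
                ratio, cls = nc_ratio_and_class(
                    img.pixels, img.masks["nucleus"], img.masks["cytosol"],
                    cutoff=cfg.params["cutoff"],
                )
                morph_rows.append(
                    {
                        "div": day,
                        "condition": cond,
                        "image": k,
                        "nc_ratio": ratio,
                        "nuclear_class": cls,
                        "soma_area_um2": soma_area(img.masks["soma"], mp.pixel_size),
                        "neurite_length_um": total_neurite_length(
                            img.masks["neurites"], mp.pixel_size
                        ),
                        "truth_soma_area_um2": img.truth_soma_area,
                        "truth_length_um": img.truth_length,
                        "truth_nc_ratio": img.truth_nc_ratio,
                    }
                )
            _log(f"analyze: {stem} done")

    pd.concat(cell_frames, ignore_index=True).to_csv(cells_path, index=False)
    pd.DataFrame(view_rows).to_csv(views_path, index=False)
    pd.DataFrame(morph_rows).to_csv(morph_path, index=False)


def _stage_report(cfg: RunConfig) -> RunReport:
    metrics_dir = cfg.out_dir / "metrics"
    report_dir = cfg.out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    cells = pd.read_csv(metrics_dir / "cell_metrics.csv")
    views = pd.read_csv(metrics_dir / "view_metrics.csv")
    morph = pd.read_csv(metrics_dir / "morph_records.csv")

    tables: dict[str, pd.DataFrame] = {}
    profiles = {}
    for cond in sorted(cells["condition"].unique()):
        sub = cells[cells["condition"] == cond]
        for metric in ("frequency_mHz", "amplitude", "fwhm_s"):
            prof = stage_profiles(sub, metric)
            profiles[(cond, metric)] = prof
            tables[f"profile_{metric}_{cond}"] = prof.to_frame()
        msub = morph[morph["condition"] == cond]
        for metric in ("soma_area_um2", "neurite_length_um", "nc_ratio"):
            prof = stage_profiles(msub, metric)
            profiles[(cond, metric)] = prof
            tables[f"profile_{metric}_{cond}"] = prof.to_frame()
        vsub = views[views["condition"] == cond]
        tables[f"synchrony_{cond}"] = vsub[["div", "synchrony"]].reset_index(drop=True)

    # growth rates of the healthy morphology curves (first derivative)
    rate_rows = []
    for metric in ("neurite_length_um", "soma_area_um2"):
        mid, rates = growth_rates(profiles[("healthy", metric)])
        for m, rt in zip(mid, rates):
            rate_rows.append({"metric": metric, "mid_div": m, "rate_per_day": rt})
    tables["growth_rates_healthy"] = pd.DataFrame(rate_rows)

    # functional vs morphological profile correlations (healthy condition);
    # meaningful only when at least three stages were simulated
    length_prof = profiles[("healthy", "neurite_length_um")]
    if length_prof.stage_days.size >= 3:
        corr_rows = []
        for metric, name in (
            ("frequency_mHz", "frequency_vs_length"),
            ("amplitude", "amplitude_vs_length"),
        ):
            slope, intercept, r2 = profile_correlation(
                length_prof, profiles[("healthy", metric)]
            )
            corr_rows.append(
                {"pair": name, "slope": slope, "intercept": intercept, "r2": r2}
            )
        tables["profile_correlations"] = pd.DataFrame(corr_rows)

    # late-stage group comparisons, healthy vs toxic
    last_div = int(cells["div"].max())
    comp_rows = []
    for metric, source in (
        ("frequency_mHz", cells),
        ("fwhm_s", cells),
        ("soma_area_um2", morph),
        ("nc_ratio", morph),
    ):
        sub = source[source["div"] == last_div]
        groups = {
            cond: sub[sub["condition"] == cond][metric].dropna().to_numpy()
            for cond in ("healthy", "toxic")
        }
        if any(v.size < 2 for v in groups.values()):
            continue
        cmp_res = group_compare(groups)
        comp_rows.append(
            {
                "metric": metric,
                "div": last_div,
                "test": cmp_res.test,
                "statistic": cmp_res.statistic,
                "p_value": cmp_res.p_value,
                "stars": cmp_res.stars,
            }
        )
    tables[f"comparisons_DIV{last_div}"] = pd.DataFrame(comp_rows)

    for name, df in tables.items():
        df.to_csv(report_dir / f"{name}.csv", index=False)

    provenance = {
        "version": __version__,
        "seed": cfg.seed,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "config": {
            "seed": cfg.seed,
            "out_dir": str(cfg.out_dir),
            "stages": list(cfg.stages),
            "simulate": cfg.simulate,
            "params": cfg.params,
        },
    }
    lines = ["# caosc run report", "", "## Provenance", "```yaml"]
    lines.append(yaml.safe_dump(provenance["config"], sort_keys=True).rstrip())
    lines += ["```", "", "## Tables"]
    for name in sorted(tables):
        lines.append(f"- {name}.csv")
    (report_dir / "report.md").write_text("\n".join(lines) + "\n")
    _log(f"report: wrote {len(tables)} tables to {report_dir}")
    return RunReport(tables=tables, provenance=provenance)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(tables={}, provenance={"seed": config.seed})
    if "simulate" in config.stages:
        _stage_simulate(config)
    if "analyze" in config.stages:
        if not (config.out_dir / "data").exists():
            raise FileNotFoundError(
                "analyze requires simulated data; run the simulate stage first"
            )
        _stage_analyze(config)
    if "report" in config.stages:
        if not (config.out_dir / "metrics").exists():
            raise FileNotFoundError(
                "report requires metrics; run the analyze stage first"
            )
        report = _stage_report(config)
    return report
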