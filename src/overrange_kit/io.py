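"""Trace file I/O, run configuration, and the simulation-estimation sweep.

Traces travel as two-column delimited text (time_s, reading) with a
``#``-prefixed metadata header (label, sample_period, t0); sweeps and
reports are CSV/JSON.  All randomness in a sweep flows from the single
config seed, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .dose_metrics import dose_report
from .errors import ConfigError, InvalidProtocolError, TraceFormatError
from .overranging import direct_overrange
from .scan_model import (
    MIN_SLICE_THICKNESS,
    OverrangeModel,
    ScanProtocol,
    default_layout,
    ground_truth_overrange,
)
from .simulator import DosimeterTrace, SimulationSpec, simulate_scan

__all__ = ["RunConfig", "read_trace", "write_trace", "run_sweep"]

logger = logging.getLogger("overrange_kit")


def write_trace(trace: DosimeterTrace, path: str | Path) -> None:
    """Write a trace as tab-separated (time_s, reading) with a '#' header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# label: {trace.label}\n")
        fh.write(f"# sample_period: {trace.sample_period:.9g}\n")
        fh.write(f"# t0: {trace.t0:.9g}\n")
        for t, y in zip(trace.times, trace.readings):
            fh.write(f"{t:.9g}\t{y:.9g}\n")


def read_trace(path: str | Path) -> DosimeterTrace:
    """Read a trace file written by :func:`write_trace`.

    Non-uniform timestamps raise :class:`TraceFormatError` naming the
    offending data row.  If the header sample_period disagrees with the
    data, a warning is logged and the data-derived period is used.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    readings: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line.lstrip("# ").partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise TraceFormatError(
                    f"expected 2 columns, got {len(parts)}: {line!r}",
                    row_index=len(times),
                )
            times.append(float(parts[0]))
            readings.append(float(parts[1]))
    if len(times) < 2:
        raise TraceFormatError("trace needs at least 2 samples")
    t = np.asarray(times)
    diffs = np.diff(t)
    period = float(np.median(diffs))
    if period <= 0:
        raise TraceFormatError("timestamps must be strictly increasing")
    bad = np.flatnonzero(np.abs(diffs - period) > 1e-6 * max(period, 1.0))
    if bad.size:
        raise TraceFormatError(
            f"non-uniform sampling at data row {int(bad[0]) + 1} "
            f"(dt={diffs[bad[0]]:.6g}, expected {period:.6g})",
            row_index=int(bad[0]) + 1,
        )
    header_period = meta.get("sample_period")
    if header_period is not None and abs(float(header_period) - period) > 1e-9:
        logger.warning(
            "%s: header sample_period %s disagrees with data-derived %.6g; "
            "using the data-derived value",
            path,
            header_period,
            period,
        )
    return DosimeterTrace(
        readings=np.asarray(readings),
        sample_period=period,
        t0=float(t[0]),
        label=meta.get("label", path.stem),
    )


@dataclass
class RunConfig:
    """Configuration for a simulation-estimation sweep.

    Sweep lists default to singletons taken from ``protocol``; every list
    must be non-empty.  ``seed`` drives all randomness and is recorded in
    every output.
    """

    protocol: ScanProtocol = field(default_factory=ScanProtocol)
    pitches: list[float] = field(default_factory=list)
    slice_thicknesses: list[float] = field(default_factory=list)
    rotation_times: list[float] = field(default_factory=list)
    voi_lengths: list[float] = field(default_factory=list)
    noise_sd: float = 0.01
    gantry_ripple: float = 0.0
    seed: int = 0
    outdir: str | None = None
    layout_margin: float = 15.0
    convention: str = "exposure"
    edge_mode: str = "lead"
    threshold_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not self.pitches:
            self.pitches = [self.protocol.pitch]
        if not self.slice_thicknesses:
            self.slice_thicknesses = [self.protocol.slice_thickness]
        if not self.rotation_times:
            self.rotation_times = [self.protocol.rotation_time]
        if not self.voi_lengths:
            self.voi_lengths = [self.protocol.voi_length]
        for name in ("pitches", "slice_thicknesses", "rotation_times", "voi_lengths"):
            vals = getattr(self, name)
            if not vals:
                raise ConfigError(f"sweep list {name!r} must be non-empty")
            if any(v is None for v in vals):
                raise ConfigError(f"sweep list {name!r} contains null entries")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        prot_raw = raw.pop("protocol", {})
        try:
            protocol = ScanProtocol(**prot_raw)
        except (TypeError, InvalidProtocolError) as exc:
            raise ConfigError(f"bad protocol section: {exc}") from exc
        known = {
            "pitches",
            "slice_thicknesses",
            "rotation_times",
            "voi_lengths",
            "noise_sd",
            "gantry_ripple",
            "seed",
            "outdir",
            "layout_margin",
            "convention",
            "edge_mode",
            "threshold_fraction",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "pitches" in raw and raw["pitches"] is not None and len(raw["pitches"]) == 0:
            raise ConfigError("sweep list 'pitches' must be non-empty")
        return cls(protocol=protocol, **{k: v for k, v in raw.items() if v is not None})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)


def run_sweep(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and estimate every sweep combination; return (results, fits).

    One row per (pitch, slice thickness, rotation time, VOI length)
    combination: ground truth, direct estimate, dose report, and the
    per-combination seed.  Combinations whose slice thickness is below
    the scanner minimum for the collimation are skipped with a logged
    warning.  Per-VOI ordinary least-squares fits of estimated length vs
    pitch and measured speed vs pitch are returned as the second table
    (when at least three distinct pitches are present).

    With ``config.outdir`` set, writes ``results.csv``, ``fits.csv`` and
    ``config.json`` there.
    """
    combos = list(
        itertools.product(
            config.pitches,
            config.slice_thicknesses,
            config.rotation_times,
            config.voi_lengths,
        )
    )
    master = np.random.default_rng(config.seed)
    combo_seeds = master.integers(0, 2**31 - 1, size=len(combos))
    logger.info(
        "sweep: %d combinations, threshold=%.2f, edge_mode=%s, convention=%s, seed=%d",
        len(combos),
        config.threshold_fraction,
        config.edge_mode,
        config.convention,
        config.seed,
    )
    rows = []
    for (pitch, st, rot, voi), combo_seed in zip(combos, combo_seeds):
        prot = replace(
            config.protocol,
            pitch=pitch,
            slice_thickness=st,
            rotation_time=rot,
            voi_length=voi,
        )
        min_st = MIN_SLICE_THICKNESS.get(float(prot.collimation))
        if min_st is not None and st < min_st - 1e-9:
            logger.warning(
                "skipping pitch=%.2f st=%.2f rot=%.2f voi=%.0f: slice "
                "thickness below the %.2f mm minimum for %.0f mm collimation",
                pitch, st, rot, voi, min_st, prot.collimation,
            )
            continue
        model = OverrangeModel.for_collimation(prot.collimation)
        layout = default_layout(prot, margin=config.layout_margin)
        spec = SimulationSpec(
            protocol=prot,
            layout=layout,
            model=model,
            noise_sd=config.noise_sd,
            gantry_ripple=config.gantry_ripple,
            seed=int(combo_seed),
        )
        bore, t1, t2, truth = simulate_scan(spec)
        est = direct_overrange(
            bore,
            t1,
            t2,
            layout,
            voi_length=prot.voi_length,
            collimation=prot.collimation,
            convention=config.convention,
            threshold_fraction=config.threshold_fraction,
            edge_mode=config.edge_mode,
        )
        report = dose_report(prot.ctdi_vol, prot.voi_length, max(est.length, 0.0))
        rows.append(
            {
                "pitch": pitch,
                "slice_thickness_mm": st,
                "rotation_time_s": rot,
                "voi_length_mm": voi,
                "seed": int(combo_seed),
                "truth_overrange_mm": truth.overrange_length,
                "est_overrange_mm": est.length,
                "table_speed_mm_s": est.table_speed,
                "beam_on_s": est.beam_on_duration,
                "total_exposed_mm": est.total_exposed_length,
                "uncertainty_mm": est.uncertainty,
                "degenerate": est.degenerate,
                "voi_dlp_mgycm": report.voi_dlp,
                "overrange_dlp_mgycm": report.overrange_dlp,
                "total_dlp_mgycm": report.total_dlp,
                "extra_fraction": report.extra_fraction,
            }
        )
    results = pd.DataFrame(rows)

    fit_rows = []
    if not results.empty:
        for voi, grp in results.groupby("voi_length_mm"):
            if grp["pitch"].nunique() < 3:
                continue
            lf = stats.linregress(grp["pitch"], grp["est_overrange_mm"])
            vf = stats.linregress(grp["pitch"], grp["table_speed_mm_s"])
            fit_rows.append(
                {
                    "voi_length_mm": voi,
                    "length_slope_mm_per_pitch": float(lf.slope),
                    "length_intercept_mm": float(lf.intercept),
                    "length_r2": float(lf.rvalue) ** 2,
                    "speed_slope_mm_s_per_pitch": float(vf.slope),
                    "speed_r2": float(vf.rvalue) ** 2,
                }
            )
    fits = pd.DataFrame(fit_rows)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False, float_format="%.9g")
        fits.to_csv(out / "fits.csv", index=False, float_format="%.9g")
        cfg = asdict(config)
        cfg["protocol"] = asdict(config.protocol)
        (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    return results, fits
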