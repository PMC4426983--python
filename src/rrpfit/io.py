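"""Trace file I/O, run configuration and the end-to-end pipeline.

Traces travel as two-column CSV (time_s, current_pA) with an optional JSON
sidecar (same stem, ``.json``) for stimulus metadata.  Every pipeline output
records the seed and a hash of the configuration so reruns are attributable
and, for the deterministic stages, bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .fitting import FitConfig, FitResult, fit_traces, quality_screen
from .params import ModelParams
from .synthesis import MEPSCKernel, Trace, synthesize_trace

logger = logging.getLogger(__name__)


def write_trace(trace: Trace, path) -> Path:
    """Write a trace as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.t, "current_pA": trace.I})
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {"stim_on": trace.stim_on, "stim_off": trace.stim_off,
            "label": trace.label, "meta": _jsonable(trace.meta)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_trace(path, stim_on: Optional[float] = None,
               stim_off: Optional[float] = None, label: str = "") -> Trace:
    """Read a two-column trace file and validate uniform sampling.

    Accepts CSV with or without a header; a JSON sidecar, when present,
    supplies the stimulus window which explicit arguments override.  Raises
    on non-numeric rows, fewer than two samples, or sampling jitter above
    1e-9 s.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
        if df.shape[1] < 2:
            raise ValueError
        # headerless files parse with numeric-looking column names
        float(df.columns[0])
        df = pd.read_csv(path, comment="#", header=None)
    except (ValueError, TypeError):
        pass
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, current_pA)")
    try:
        t = df.iloc[:, 0].astype(float).to_numpy()
        current = df.iloc[:, 1].astype(float).to_numpy()
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: non-numeric rows: {err}") from err
    if t.size < 2:
        raise ValueError(f"{path}: need at least two rows to establish dt")
    dts = np.diff(t)
    if np.any(dts <= 0) or np.ptp(dts) > 1e-9:
        raise ValueError(f"{path}: non-uniform sampling (jitter > 1e-9 s)")

    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    on = stim_on if stim_on is not None else meta.get("stim_on")
    off = stim_off if stim_off is not None else meta.get("stim_off")
    if on is None or off is None:
        raise ValueError(
            f"{path}: missing stimulus metadata (stim_on/stim_off); "
            "provide a JSON sidecar or explicit arguments"
        )
    return Trace(t=t, I=current, stim_on=float(on), stim_off=float(off),
                 label=label or meta.get("label", ""), meta=meta.get("meta", {}))


@dataclass
class RunConfig:
    """Configuration of a full simulate/fit/analyze/bootstrap run."""

    out_dir: str = "rrpfit_out"
    seed: int = 0
    trace_paths: list[str] = field(default_factory=list)
    n_synthetic: int = 3
    duration: float = 8.0
    noise_sd: float = 10.0
    params: ModelParams = field(default_factory=ModelParams)
    kernel: MEPSCKernel = field(default_factory=MEPSCKernel)
    fit: FitConfig = field(default_factory=lambda: FitConfig(n_starts=3))
    n_bootstrap: int = 10000
    mepsc_charge: float = 1.1e-4

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _jsonable(d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate (if no input traces), fit, analyze and bootstrap stages.

    Writes per-cell summaries and bootstrap JSON under ``config.out_dir``;
    returns the report bundle as a dict.  Deterministic given the seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}

    stage = "simulate"
    try:
        if config.trace_paths:
            traces = [read_trace(p) for p in config.trace_paths]
        else:
            traces = []
            for i in range(config.n_synthetic):
                tr = synthesize_trace(config.params, config.kernel,
                                      noise_sd=config.noise_sd,
                                      seed=config.seed + i,
                                      duration=config.duration,
                                      label=f"synthetic-{i}")
                write_trace(tr, out / f"trace_{i:02d}.csv")
                traces.append(tr)

        stage = "fit"
        fit_cfg = dataclasses.replace(config.fit, seed=config.seed)
        fits: list[FitResult] = []
        for i, tr in enumerate(traces):
            res = fit_traces(tr, config.kernel, fit_cfg)
            res.quality_flags = quality_screen(res, tr, config.kernel, fit_cfg)
            fits.append(res)
            (out / f"fit_{i:02d}.json").write_text(
                json.dumps({**stamp, **_jsonable(res.to_dict())}, indent=2) + "\n")
            vals = {**res.shared, **res.per_trace[0]}
            resid = tr.I - _fit_pred(res, tr, config.kernel)
            pd.DataFrame({"time_s": tr.t, "residual_pA": resid}).to_csv(
                out / f"fit_{i:02d}_residuals.csv", index=False)
            logger.info("fit %d: sse=%.4g rrp=%.4g k2max=%.4g", i, res.sse,
                        res.rrp, vals["k2_max"])

        stage = "analyze"
        rows = []
        for i, (tr, res) in enumerate(zip(traces, fits)):
            vals = {**res.shared, **res.per_trace[0]}
            p = res.params_for(0, t0=tr.stim_on)
            peak = stats.peak_release_rate(p, pulse=tr.stim_off - tr.stim_on)
            rows.append({
                "trace": tr.label or f"trace-{i}",
                "rrp_nC": res.rrp,
                "k1D_nC_per_s": vals["k1D"],
                "k_minus1_per_s": vals["k_minus1"],
                "k2_max_per_s": vals["k2_max"],
                "t_del_s": vals["t_del"],
                "tau_s": vals["tau"],
                "sse_pA2": res.sse,
                "peak_rate_nC_per_s": peak["peak_rate_nC_per_s"],
                "time_to_peak_s": peak["time_to_peak_s"],
                "vesicles": res.rrp / config.mepsc_charge,
                "quality_all_ok": res.quality_flags["all_ok"],
            })
        summary = pd.DataFrame(rows)
        summary.to_csv(out / "summary.csv", index=False)

        stage = "bootstrap"
        boot = {}
        if len(fits) >= 2:
            for col in ("rrp_nC", "k1D_nC_per_s", "k_minus1_per_s", "k2_max_per_s"):
                bs = stats.bootstrap_means(summary[col].to_numpy(),
                                           n_resamples=config.n_bootstrap,
                                           seed=config.seed)
                boot[col] = bs.to_dict()
        (out / "bootstrap.json").write_text(
            json.dumps({**stamp, "bootstrap": boot}, indent=2) + "\n")
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    report = {**stamp, "n_traces": len(traces),
              "summary": rows, "bootstrap": boot,
              "out_dir": str(out)}
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2) + "\n")
    return report


def _fit_pred(res: FitResult, tr: Trace, kernel: MEPSCKernel) -> np.ndarray:
    from .fitting import predict_current

    vals = {**res.shared, **res.per_trace[0]}
    return predict_current(tr.t, tr.stim_on, vals, kernel)
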