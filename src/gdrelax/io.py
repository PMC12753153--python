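"""Text file formats, run configuration, and the analysis pipeline.

All records are plain text: a '#'-prefixed metadata header of ``key: value``
lines followed by whitespace-separated numeric columns.

trace    : time_us, amplitude[, sigma];  header keys: sequence (required on
           write), temperature_K, concentration_uM, field_label
spectrum : field_mT, amplitude;          header keys: mw_freq_GHz,
           temperature_K, seed
series   : concentration_uM, Tm_us, Tm_err_us[, beta, beta_err]

Legacy two-column files without any header are accepted with defaults and a
logged warning.  Malformed headers or non-monotone axes raise a parse error
naming the offending line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .decay_fit import DecayTrace, fit_inversion_recovery, fit_se, fit_sse, select_model
from .edepr import SpectrumGrid
from .mechanism import ConcentrationSeries, fit_concentration

logger = logging.getLogger("gdrelax")

__all__ = [
    "read_trace",
    "write_trace",
    "read_spectrum",
    "write_spectrum",
    "read_series",
    "write_series",
    "load_config",
    "run_pipeline",
    "ParseError",
]


class ParseError(ValueError):
    pass


_TRACE_META_KEYS = ("sequence", "temperature_K", "concentration_uM", "field_label")


def _read_header(path) -> tuple[dict, int]:
    meta: dict = {}
    n_header = 0
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            s = line.strip()
            if not s.startswith("#"):
                break
            n_header += 1
            body = s.lstrip("#").strip()
            if not body or ":" not in body:
                continue
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta, n_header


def _num(meta, key, cast=float):
    if key not in meta or meta[key] in ("", "None"):
        return None
    try:
        return cast(meta[key])
    except ValueError as exc:
        raise ParseError(f"metadata key {key!r} is not numeric: {meta[key]!r}") from exc


def read_trace(path) -> DecayTrace:
    """Read a decay trace; lossless inverse of :func:`write_trace`."""
    path = Path(path)
    meta, n_header = _read_header(path)
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed numeric data: {exc}") from exc
    if data.shape[1] < 2:
        raise ParseError(f"{path}: expected at least 2 columns")
    t, y = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] > 2 else None
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2 + n_header
        raise ParseError(f"{path}: non-monotone time axis at data line {bad}")
    if not meta:
        logger.warning("%s: headerless legacy trace, assuming a Hahn sequence", path)
    if "sequence" not in meta and meta:
        raise ParseError(f"{path}: missing required metadata key 'sequence'")
    extra = {
        k: v for k, v in meta.items() if k not in _TRACE_META_KEYS
    }
    return DecayTrace(
        t,
        y,
        sequence=meta.get("sequence", "hahn"),
        temperature_K=_num(meta, "temperature_K"),
        concentration_uM=_num(meta, "concentration_uM"),
        field_label=meta.get("field_label", ""),
        sigma=sigma,
        meta=extra,
    )


def write_trace(trace: DecayTrace, path) -> None:
    path = Path(path)
    with open(path, "w") as f:
        f.write("# gdrelax-trace v1\n")
        f.write(f"# sequence: {trace.sequence}\n")
        if trace.temperature_K is not None:
            f.write(f"# temperature_K: {trace.temperature_K:.10g}\n")
        if trace.concentration_uM is not None:
            f.write(f"# concentration_uM: {trace.concentration_uM:.10g}\n")
        if trace.field_label:
            f.write(f"# field_label: {trace.field_label}\n")
        cols = "time_us amplitude" + (" sigma" if trace.sigma is not None else "")
        f.write(f"# columns: {cols}\n")
        arr = [trace.time_us, trace.amplitude]
        if trace.sigma is not None:
            arr.append(trace.sigma)
        np.savetxt(f, np.column_stack(arr), fmt="%.17g")


def read_spectrum(path) -> SpectrumGrid:
    path = Path(path)
    meta, _ = _read_header(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ParseError(f"{path}: expected 2 columns")
    md = dict(meta)
    for k in ("mw_freq_GHz", "temperature_K"):
        v = _num(meta, k)
        if v is not None:
            md[k] = v
    seed = _num(meta, "seed", int)
    if seed is not None:
        md["seed"] = seed
    return SpectrumGrid(data[:, 0], data[:, 1], md)


def write_spectrum(spec: SpectrumGrid, path) -> None:
    path = Path(path)
    md = spec.metadata
    with open(path, "w") as f:
        f.write("# gdrelax-spectrum v1\n")
        for k in ("mw_freq_GHz", "temperature_K", "seed"):
            if k in md:
                f.write(f"# {k}: {md[k]}\n")
        f.write("# columns: field_mT amplitude\n")
        np.savetxt(f, np.column_stack([spec.field_mT, spec.amplitude]), fmt="%.10g")


def read_series(path) -> ConcentrationSeries:
    path = Path(path)
    meta, _ = _read_header(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ParseError(f"{path}: expected >= 2 columns")
    return ConcentrationSeries(
        concentration_uM=data[:, 0],
        Tm_us=data[:, 1],
        Tm_err_us=data[:, 2] if data.shape[1] > 2 else None,
        beta=data[:, 3] if data.shape[1] > 3 else None,
        beta_err=data[:, 4] if data.shape[1] > 4 else None,
        label=meta.get("label", ""),
        temperature_K=_num(meta, "temperature_K"),
        field_label=meta.get("field_label", ""),
    )


def write_series(series: ConcentrationSeries, path) -> None:
    path = Path(path)
    cols = [series.concentration_uM, series.Tm_us]
    names = ["concentration_uM", "Tm_us"]
    if series.Tm_err_us is not None:
        cols.append(series.Tm_err_us)
        names.append("Tm_err_us")
    if series.beta is not None:
        cols.append(np.asarray(series.beta, dtype=float))
        names.append("beta")
    if series.beta_err is not None:
        cols.append(np.asarray(series.beta_err, dtype=float))
        names.append("beta_err")
    with open(path, "w") as f:
        f.write("# gdrelax-series v1\n")
        if series.label:
            f.write(f"# label: {series.label}\n")
        if series.temperature_K is not None:
            f.write(f"# temperature_K: {series.temperature_K:.10g}\n")
        f.write(f"# columns: {' '.join(names)}\n")
        np.savetxt(f, np.column_stack(cols), fmt="%.17g")


# ----------------------------------------------------------------------
# configuration and pipeline
# ----------------------------------------------------------------------

_ALLOWED_TOP = {"task", "seed", "output", "trace", "series", "generator", "fit", "bundle"}
_ALLOWED_TASKS = {"fit_decay", "fit_ir", "conc_analysis", "bundle_check"}


def load_config(path) -> dict:
    """Load and validate a YAML run configuration.

    Unknown top-level keys are rejected before anything executes.
    """
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    unknown = set(cfg) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    task = cfg.get("task")
    if task not in _ALLOWED_TASKS:
        raise ValueError(f"config must set task to one of {sorted(_ALLOWED_TASKS)}")
    cfg.setdefault("seed", 0)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: dict, workdir=".") -> dict:
    """Execute a configured generate->fit(->decompose) run; return the report.

    The report carries the seed, a config hash and the package version for
    reproducibility; any stage failure raises with a stage-tagged message.
    """
    workdir = Path(workdir)
    report: dict = {
        "task": cfg["task"],
        "seed": cfg["seed"],
        "config_hash": _config_hash(cfg),
        "version": __version__,
    }
    task = cfg["task"]
    try:
        if task == "fit_decay":
            trace = _resolve_trace(cfg, workdir)
            model = cfg.get("fit", {}).get("model", "auto")
            if model == "se":
                fit = fit_se(trace)
                report["fit"] = _se_dict(fit)
            elif model == "sse":
                fit = fit_sse(trace)
                report["fit"] = _sse_dict(fit)
            elif model == "auto":
                sel = select_model(trace)
                report["selected"] = sel.chosen
                report["delta_aicc"] = sel.delta_aicc
                report["fit"] = _se_dict(sel.se) if sel.chosen == "SE" else _sse_dict(sel.sse)
            else:
                raise ValueError(f"unknown fit model {model!r}")
        elif task == "fit_ir":
            trace = _resolve_trace(cfg, workdir)
            fit = fit_inversion_recovery(trace)
            report["fit"] = dict(T1_us=fit.T1, stretch=fit.stretch, T1_err_us=fit.T1_err,
                                 low_confidence=fit.low_confidence)
        elif task == "conc_analysis":
            series = _resolve_series(cfg, workdir)
            dec = fit_concentration(series)
            report["fit"] = dict(
                slope=dec.slope, slope_err=dec.slope_err,
                intercept=dec.intercept, intercept_err=dec.intercept_err,
                Tm0_us=dec.Tm0_us, Tm0_err_us=dec.Tm0_err_us,
            )
        elif task == "bundle_check":
            report.update(_bundle_check(cfg, workdir))
    except Exception as exc:
        raise RuntimeError(f"stage {task!r} failed: {exc}") from exc

    out = cfg.get("output")
    if out:
        with open(workdir / out, "w") as f:
            json.dump(report, f, indent=1, sort_keys=True)
    return report


def _resolve_trace(cfg, workdir) -> DecayTrace:
    if "trace" in cfg:
        return read_trace(workdir / cfg["trace"])
    gen = cfg.get("generator")
    if gen is None:
        raise ValueError("fit tasks need a 'trace' path or a 'generator' block")
    from .synth import GeneratorSpec, gen_decay

    grid = gen.get("time_us") or list(
        np.arange(gen.get("t_start_us", 0.58), gen.get("t_stop_us", 80.0), gen.get("t_step_us", 0.58))
    )
    spec = GeneratorSpec(
        kind=gen["kind"],
        params=gen["params"],
        time_us=np.asarray(grid, dtype=float),
        noise=gen.get("noise", 0.0),
        seed=int(gen.get("seed", cfg["seed"])),
    )
    return gen_decay(spec)


def _resolve_series(cfg, workdir) -> ConcentrationSeries:
    if "series" in cfg and isinstance(cfg["series"], str):
        return read_series(workdir / cfg["series"])
    gen = cfg.get("generator")
    if gen is None:
        raise ValueError("conc_analysis needs a 'series' path or a 'generator' block")
    from .synth import gen_conc_series

    return gen_conc_series(
        slope=gen["slope"],
        intercept=gen["intercept"],
        concentrations_uM=gen["concentrations_uM"],
        seed=int(gen.get("seed", cfg["seed"])),
        frac_sigma=gen.get("frac_sigma", 0.01),
    )


def _bundle_check(cfg, workdir) -> dict:
    """Regenerate a bundle, push it through the fits, compare to manifest."""
    from .synth import gen_paper_bundle

    bundle_dir = workdir / cfg.get("bundle", {}).get("dir", "bundle")
    manifest = gen_paper_bundle(int(cfg["seed"]), bundle_dir)
    tol = float(cfg.get("bundle", {}).get("tolerance", 0.10))
    checks = []
    ok_all = True
    for fn, truth in manifest["traces"].items():
        trace = read_trace(bundle_dir / fn)
        if truth["kind"] == "se":
            fit = fit_se(trace)
            ok = abs(fit.Tm - truth["Tm"]) / truth["Tm"] < tol
            checks.append(dict(file=fn, param="Tm", fitted=fit.Tm, truth=truth["Tm"], ok=ok))
        elif truth["kind"] == "sse":
            fit = fit_sse(trace)
            ok = (
                abs(fit.Tm_s - truth["Tm_s"]) / truth["Tm_s"] < tol
                and abs(fit.Tm_f - truth["Tm_f"]) / truth["Tm_f"] < tol
            )
            checks.append(dict(file=fn, param="Tm_f/Tm_s", fitted=[fit.Tm_f, fit.Tm_s],
                               truth=[truth["Tm_f"], truth["Tm_s"]], ok=ok))
        elif truth["kind"] == "ir":
            fit = fit_inversion_recovery(trace)
            ok = abs(fit.T1 - truth["T1"]) / truth["T1"] < tol
            checks.append(dict(file=fn, param="T1", fitted=fit.T1, truth=truth["T1"], ok=ok))
        ok_all &= checks[-1]["ok"]
    for fn, truth in manifest["series"].items():
        series = read_series(bundle_dir / fn)
        dec = fit_concentration(series)
        ok = abs(dec.slope - truth["slope"]) / truth["slope"] < 3 * tol
        checks.append(dict(file=fn, param="slope", fitted=dec.slope, truth=truth["slope"], ok=ok))
        ok_all &= ok
    return {"checks": checks, "all_ok": bool(ok_all)}


def _se_dict(fit):
    return dict(model="se", A=fit.A, Tm_us=fit.Tm, beta=fit.beta,
                Tm_err_us=fit.Tm_err, beta_err=fit.beta_err, aicc=fit.aicc)


def _sse_dict(fit):
    return dict(model="sse", A=fit.A, Tm_f_us=fit.Tm_f, beta_f=fit.beta_f,
                Tm_s_us=fit.Tm_s, beta_s=fit.beta_s, aicc=fit.aicc,
                effectively_se=fit.effectively_se)
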