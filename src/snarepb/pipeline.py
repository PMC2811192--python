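"""End-to-end orchestration: YAML run configuration, provenance stamping,
and batched execution of the interaction-energy workflow (structure ->
membranes -> PB solves -> sweeps -> bending -> landscape table)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bending import BendingModel, solve_bending
from .energetics import (DEFAULT_DISTANCE, EnergyCurve, curvature_curve,
                         interaction_energy, scan_composition, scan_distance,
                         scan_orientation)
from .errors import ConfigurationError, SnarePBError
from .membranes import MembraneSpec, build_explicit, build_implicit
from .pb_solver import PBConfig, check_precision
from .structures import align_preferred_orientation, place_at_distance, read_structure
from .synthetic_data import RodSpec, make_benchmark_suite, make_rod, write_fixtures

log = logging.getLogger(__name__)


def load_config(src) -> dict:
    """Load a YAML run configuration (path or mapping)."""
    if isinstance(src, (str, Path)):
        with open(src) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(src)
    cfg.setdefault("seed", 0)
    cfg.setdefault("output_dir", "snarepb_out")
    cfg.setdefault("pb", {})
    cfg.setdefault("tasks", [])
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _pb_config(cfg: dict) -> PBConfig:
    return PBConfig(**cfg.get("pb", {}))


def _resolve_structure(d, cfg):
    if isinstance(d, str):
        d = {"fixture": d}
    if "path" in d:
        s = read_structure(d["path"], d.get("format"))
    elif "rod" in d:
        s = make_rod(RodSpec(**d["rod"]))
    elif "fixture" in d:
        suite = make_benchmark_suite(cfg["seed"])
        fx = suite[d["fixture"]]
        key = d.get("key", "structure")
        s = fx[key]
    else:
        raise ConfigurationError(f"cannot resolve structure from {d!r}")
    if d.get("align", True) and s.anchors:
        s = align_preferred_orientation(s)
    return s


def _resolve_membrane(d, cfg):
    if isinstance(d, str):
        d = {"fixture": d}
    if "fixture" in d:
        spec = make_benchmark_suite(cfg["seed"])[d["fixture"]]["spec"]
    else:
        spec = MembraneSpec(**{k: v for k, v in d.items() if k != "implicit"})
    return build_implicit(spec) if d.get("implicit") else build_explicit(spec)


def _membrane_spec(d, cfg):
    if isinstance(d, str):
        d = {"fixture": d}
    if "fixture" in d:
        return make_benchmark_suite(cfg["seed"])[d["fixture"]]["spec"]
    return MembraneSpec(**d)


def _stamp(obj: dict, cfg: dict) -> dict:
    obj["provenance"] = {"software": f"snarepb {__version__}",
                         "config_hash": config_hash(cfg)}
    return obj


def _write_json(path, obj, cfg):
    with open(path, "w") as fh:
        json.dump(_stamp(obj, cfg), fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return repr(o)


def _write_curve(path_base: Path, curve: EnergyCurve, cfg: dict):
    header = f"# snarepb {__version__} config {config_hash(cfg)}\n"
    with open(path_base.with_suffix(".csv"), "w") as fh:
        fh.write(header)
        curve.to_frame().to_csv(fh, index=False)
    curve.meta["provenance"] = {"software": f"snarepb {__version__}",
                                "config_hash": config_hash(cfg)}
    curve.to_json(str(path_base.with_suffix(".json")))


def run_pipeline(cfg) -> dict:
    """Execute every task in the run configuration; returns the run report.

    Any stage failure aborts the run with the stage name attached.
    """
    cfg = load_config(cfg)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    pb = _pb_config(cfg)
    report = {"tasks": []}
    curves: dict[str, EnergyCurve] = {}

    for i, task in enumerate(cfg["tasks"]):
        kind = task.get("kind")
        name = task.get("name", f"{kind}_{i}")
        log.info("pipeline stage %s (%s)", name, kind)
        try:
            entry = _run_task(kind, name, task, cfg, pb, out, curves)
        except SnarePBError:
            raise
        except Exception as exc:
            raise SnarePBError(f"stage {name!r} ({kind}) failed: {exc}") from exc
        entry.update(kind=kind, name=name)
        report["tasks"].append(entry)

    _write_json(out / "run_report.json", report, cfg)
    return report


def _run_task(kind, name, task, cfg, pb, out: Path, curves) -> dict:
    if kind == "make_fixtures":
        files = write_fixtures(out / "fixtures", cfg["seed"])
        return {"files": files}

    if kind == "interaction":
        s = _resolve_structure(task["structure"], cfg)
        m = _resolve_membrane(task["membrane"], cfg)
        d = task.get("distance", DEFAULT_DISTANCE)
        s = place_at_distance(s, m, d, side=task.get("side", "above"),
                              debye_length=pb.debye_length)
        g = interaction_energy(s, m, pb, task.get("mode"))
        res = {"dG_kJ_per_mol": g, "distance_A": d}
        _write_json(out / f"{name}.json", dict(res), cfg)
        return res

    if kind in ("scan_orientation", "scan_distance"):
        s = _resolve_structure(task["structure"], cfg)
        v = _resolve_membrane(task["v_membrane"], cfg)
        t = _membrane_spec(task["t_membrane"], cfg)
        if kind == "scan_orientation":
            curve = scan_orientation(s, v, t, task["angles"], pb,
                                     task.get("distance", DEFAULT_DISTANCE))
        else:
            curve = scan_distance(s, v, t, task["distances"], pb)
        curves[name] = curve
        _write_curve(out / name, curve, cfg)
        return {"curve": f"{name}.csv", "minimum": curve.minimum("dG_sum")}

    if kind == "scan_composition":
        s = _resolve_structure(task["structure"], cfg)
        spec = _membrane_spec(task["membrane"], cfg)
        curve = scan_composition(s, spec, task["ps_fractions"], pb,
                                 task.get("distance", DEFAULT_DISTANCE))
        curves[name] = curve
        _write_curve(out / name, curve, cfg)
        return {"curve": f"{name}.csv"}

    if kind == "curvature_curve":
        s = _resolve_structure(task["structure"], cfg)
        spec = _membrane_spec(task["membrane"], cfg)
        radii = [float("inf") if r in ("planar", "inf") else float(r)
                 for r in task["radii"]]
        curve = curvature_curve(s, spec, radii, pb,
                                task.get("distance", DEFAULT_DISTANCE))
        curves[name] = curve
        _write_curve(out / name, curve, cfg)
        return {"curve": f"{name}.csv"}

    if kind == "bending_estimate":
        src = task["curve"]
        curve = curves.get(src) or EnergyCurve.from_csv(src, "curvature", "Å")
        model = BendingModel(kappa=task.get("kappa", 20.0),
                             R=task.get("R", 200.0))
        est = solve_bending(curve, model, task.get("N", 1))
        res = asdict(est)
        _write_json(out / f"{name}.json", dict(res), cfg)
        return res

    if kind == "landscape":
        rows = []
        mems = {m.get("name", f"m{j}") if isinstance(m, dict) else m:
                _resolve_membrane(m, cfg) for j, m in enumerate(task["membranes"])}
        for sd in task["structures"]:
            sname = sd.get("name", "complex") if isinstance(sd, dict) else sd
            s = _resolve_structure(sd, cfg)
            for mname, m in mems.items():
                sp = place_at_distance(s, m, task.get("distance", DEFAULT_DISTANCE),
                                       side="above", debye_length=pb.debye_length)
                rows.append({"complex": sname, "membrane": mname,
                             "dG_kJ_per_mol": interaction_energy(sp, m, pb)})
        df = pd.DataFrame(rows)
        header = f"# snarepb {__version__} config {config_hash(cfg)}\n"
        with open(out / f"{name}.csv", "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        return {"rows": rows}

    if kind == "check_precision":
        s = _resolve_structure(task["structure"], cfg)
        m = _resolve_membrane(task["membrane"], cfg)
        s = place_at_distance(s, m, task.get("distance", DEFAULT_DISTANCE),
                              side="above", debye_length=pb.debye_length)
        rep = check_precision(s, m, pb)
        _write_json(out / f"{name}.json", dict(rep), cfg)
        return rep

    raise ConfigurationError(f"unknown task kind {kind!r}")
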