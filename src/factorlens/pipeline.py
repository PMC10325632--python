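"""Multi-stage pipeline runner with a reproducibility manifest.

A run config is a YAML file::

    stages:
      - name: surface            # free label, used in logs and the manifest
        stage: simulate-surface  # one of the registered stage kinds
        params: {name: sagittal-normal, seed: 7, out_triplets: surf.tsv}
      - name: fit
        stage: sr-fit
        params: {triplets: surf.tsv, seed: 7, out: model.json}

Relative paths in ``params`` resolve inside the output directory, so stages
chain naturally.  The manifest records the package and numpy versions, every
stage's parameters, and SHA-256 digests of each stage's declared inputs and
outputs; replaying the same config reproduces identical digests for
deterministic stages.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as flio

log = logging.getLogger("factorlens.pipeline")

# stage kind -> (callable(params, workdir), input path keys, output path keys)
_REGISTRY = {}


def _stage(name, inputs=(), outputs=()):
    def deco(fn):
        _REGISTRY[name] = (fn, tuple(inputs), tuple(outputs))
        return fn
    return deco


class StageError(RuntimeError):
    def __init__(self, stage_name, cause):
        super().__init__(f"stage {stage_name!r} failed: {cause}")
        self.stage_name = stage_name


def _resolve(params: dict, keys, workdir: Path) -> dict:
    out = dict(params)
    for key in keys:
        if key in out and out[key] is not None:
            p = Path(out[key])
            out[key] = str(p if p.is_absolute() else workdir / p)
    return out


@_stage("simulate-surface", outputs=("out_triplets", "out_matrix"))
def _simulate_surface(params, workdir):
    from .simulate import FormulaSpec, formula_surface
    spec = FormulaSpec(name=params["name"],
                       shape=tuple(params.get("shape", (100, 100))),
                       noise_frac=params.get("noise_frac"),
                       noise_sd=params.get("noise_sd", 0.0),
                       seed=int(params["seed"]),
                       with_derivative=bool(params.get("with_derivative", False)))
    matrix, triplets = formula_surface(spec)
    triplets.to_tsv(params["out_triplets"])
    if params.get("out_matrix"):
        flio.save_matrix(matrix, params["out_matrix"])


@_stage("sr-fit", inputs=("triplets",), outputs=("out",))
def _sr_fit(params, workdir):
    from .network import TrainConfig, fit_with_restarts
    from .triplets import TripletDataset
    dataset = TripletDataset.from_tsv(params["triplets"])
    train_set, _ = dataset.split(params.get("train_frac", 0.8), seed=int(params["seed"]))
    cfg = TrainConfig(epochs=int(params.get("epochs", 2000)),
                      lam=float(params.get("lam", 1e-3)),
                      seed=int(params["seed"]))
    net, _ = fit_with_restarts(train_set, depth=int(params.get("depth", 2)),
                               config=cfg, restarts=int(params.get("restarts", 2)))
    flio.save_model(net, params["out"])


@_stage("sr-extract", inputs=("model",), outputs=("out",))
def _sr_extract(params, workdir):
    from .formula import extract_formula
    net = flio.load_model(params["model"])
    extract_formula(net, float(params.get("threshold", 0.01))).to_json(params["out"])


@_stage("sr-eval", inputs=("model", "triplets"), outputs=("out",))
def _sr_eval(params, workdir):
    from .formula import verification_accuracy
    from .triplets import TripletDataset
    net = flio.load_model(params["model"])
    dataset = TripletDataset.from_tsv(params["triplets"])
    _, test_set = dataset.split(params.get("train_frac", 0.8), seed=int(params["seed"]))
    report = verification_accuracy(net, test_set, float(params.get("tau", 0.05)))
    with open(params["out"], "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


@_stage("simulate-timeseries", outputs=("out_dir",))
def _simulate_timeseries(params, workdir):
    from .simulate import PlantedDifferenceSpec, group_timeseries
    edges = tuple((int(p), int(q)) for p, q in params.get("edges", []))
    spec = PlantedDifferenceSpec(
        n_rois=int(params.get("rois", 12)),
        n_frames=int(params.get("frames", 150)),
        n_per_group=int(params.get("per_group", 20)),
        edges=edges, effect_size=float(params.get("effect", 0.0)),
        seed=int(params["seed"]))
    group_a, group_b = group_timeseries(spec)
    out = Path(params["out_dir"])
    for label, group in (("A", group_a), ("B", group_b)):
        gdir = out / f"group{label}"
        gdir.mkdir(parents=True, exist_ok=True)
        for ts in group:
            flio.save_matrix(ts.data, gdir / f"{ts.subject}.tsv")


@_stage("compare", inputs=("group_a", "group_b", "covariates"), outputs=("out_dir",))
def _compare(params, workdir):
    import pandas as pd
    from .connectome import (RoiTimeSeriesSet, build_connectivity,
                             edgewise_group_comparison)
    bins = int(params.get("bins", 16))

    def load_group(d):
        paths = sorted(Path(d).glob("*.tsv"))
        return [build_connectivity(RoiTimeSeriesSet(data=flio.load_matrix(p)),
                                   bins=bins).values
                if params.get("from_timeseries", True) else flio.load_matrix(p)
                for p in paths]

    mats_a = load_group(params["group_a"])
    mats_b = load_group(params["group_b"])
    cov = (pd.read_csv(params["covariates"], sep="\t")
           if params.get("covariates") else None)
    result = edgewise_group_comparison(mats_a, mats_b, covariates=cov,
                                       q_level=float(params.get("fdr", 0.05)))
    out = Path(params["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    result.to_dataframe().to_csv(out / "edges.tsv", sep="\t", index=False)


def run_pipeline(config_path, out_dir) -> dict:
    """Execute the stages of a YAML config; return (and write) the manifest.

    Raises :class:`StageError` naming the failing stage; stages before the
    failure keep their outputs, and the partial manifest is written with the
    failure recorded.
    """
    workdir = Path(out_dir)
    workdir.mkdir(parents=True, exist_ok=True)
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if not config or "stages" not in config:
        raise ValueError(f"{config_path}: config must define a 'stages' list")

    manifest = {
        "factorlens_version": __version__,
        "numpy_version": np.__version__,
        "config": str(config_path),
        "stages": [],
    }
    manifest_path = workdir / "manifest.json"
    try:
        for stage_cfg in config["stages"]:
            kind = stage_cfg.get("stage")
            name = stage_cfg.get("name", kind)
            if kind not in _REGISTRY:
                raise StageError(name, f"unknown stage kind {kind!r}; "
                                       f"known: {sorted(_REGISTRY)}")
            fn, in_keys, out_keys = _REGISTRY[kind]
            params = _resolve(stage_cfg.get("params", {}), in_keys + out_keys, workdir)
            for key in in_keys:
                path = params.get(key)
                if path and not Path(path).exists():
                    raise StageError(name, f"missing input --{key.replace('_', '-')}: {path}")
            record = {"name": name, "stage": kind, "params": params,
                      "inputs": {}, "outputs": {}}
            for key in in_keys:
                if params.get(key) and Path(params[key]).is_file():
                    record["inputs"][key] = flio.sha256_of(params[key])
            t0 = time.time()
            try:
                fn(params, workdir)
            except StageError:
                raise
            except Exception as err:  # noqa: BLE001 - report the failing stage
                log.error("[%s] failed: %s", name, err)
                record["status"] = "failed"
                record["error"] = str(err)
                manifest["stages"].append(record)
                raise StageError(name, err) from err
            for key in out_keys:
                target = params.get(key)
                if not target:
                    continue
                p = Path(target)
                if p.is_file():
                    record["outputs"][key] = flio.sha256_of(p)
                elif p.is_dir():
                    record["outputs"][key] = {
                        f.name: flio.sha256_of(f)
                        for f in sorted(p.rglob("*")) if f.is_file()}
            record["status"] = "ok"
            record["seconds"] = round(time.time() - t0, 3)
            manifest["stages"].append(record)
            log.info("[%s] ok (%.1fs)", name, record["seconds"])
    finally:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest
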