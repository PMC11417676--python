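"""YAML-driven stage graph tying the modules into the full training workflow.

A run configuration is a YAML document::

    seed: 1
    outdir: runs/demo
    stages:
      - {name: box, kind: fixtures, generator: pack_solvent_box,
         args: {n_molecules: 112, density: 0.997}}
      - {name: labelled, kind: label, input: box}
      - {name: model, kind: train, input: labelled}
      ...

Each stage writes its outputs under ``outdir/<name>`` plus a manifest
(JSON: stage kind, input hashes, seed, package version), so a rerun with the
same configuration reproduces byte-identical numeric outputs.  A failed stage
is recorded in the manifest and its downstream stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import fixtures
from ._version import __version__
from .active_learning import ALConfig, run_al_phase, bootstrap_dataset
from .analysis import first_shell, rdf
from .md import RestraintSpec, ThermostatSpec, initialize_state, run_md
from .model import FeatureSpec, LinearMLP, fit
from .reference import ClassicalCalculator, label_dataset, nitrile_ion_params, water_ion_params
from .soap import SoapSpec
from .structures import LabeledDataset, read_extxyz, write_extxyz

logger = logging.getLogger(__name__)

_CALCULATORS = {
    "classical-water": lambda: ClassicalCalculator(water_ion_params()),
    "classical-nitrile": lambda: ClassicalCalculator(nitrile_ion_params()),
}


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _get_calculator(spec: dict):
    name = spec.get("calculator", "classical-water")
    if name not in _CALCULATORS:
        raise ValueError(f"unknown calculator {name!r}; options: {sorted(_CALCULATORS)}")
    return _CALCULATORS[name]()


def run_workflow(config_path) -> dict:
    """Execute the stage graph declared in a YAML run configuration.

    Returns a manifest dict (also written to ``outdir/manifest.json``).
    Schema violations raise with the offending keys named; a stage failure
    marks all downstream stages skipped.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        doc = yaml.safe_load(fh)
    unknown = set(doc) - {"seed", "outdir", "stages"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    if "stages" not in doc or not isinstance(doc["stages"], list):
        raise ValueError("config must declare a 'stages' list")
    seed = int(doc.get("seed", 0))
    outdir = Path(doc.get("outdir", "solvshell-run"))
    outdir.mkdir(parents=True, exist_ok=True)

    artifacts: dict = {}
    manifest = {"version": __version__, "seed": seed, "config": str(config_path),
                "config_hash": _hash_file(config_path), "stages": []}
    failed = False
    for stage in doc["stages"]:
        missing = {"name", "kind"} - set(stage)
        if missing:
            raise ValueError(f"stage {stage} is missing keys: {sorted(missing)}")
        record = {"name": stage["name"], "kind": stage["kind"]}
        if failed:
            record["status"] = "skipped"
            manifest["stages"].append(record)
            continue
        try:
            outputs = _run_stage(stage, artifacts, seed, outdir)
            record["status"] = "ok"
            record["outputs"] = outputs
        except Exception as err:  # noqa: BLE001 - recorded, downstream skipped
            logger.error("stage %s failed: %s", stage["name"], err)
            record["status"] = "failed"
            record["error"] = str(err)
            failed = True
        manifest["stages"].append(record)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _run_stage(stage: dict, artifacts: dict, seed: int, outdir: Path) -> list:
    kind = stage["kind"]
    name = stage["name"]
    args = dict(stage.get("args", {}))
    out: list[str] = []

    def _save_configs(configs, fname):
        path = outdir / fname
        write_extxyz(configs, path)
        out.append(str(path))

    if kind == "fixtures":
        import inspect

        gen = getattr(fixtures, stage.get("generator", "pack_solvent_box"))
        if "seed" in inspect.signature(gen).parameters:
            args.setdefault("seed", seed)
        cfg = gen(**args)
        artifacts[name] = [cfg] if not isinstance(cfg, list) else cfg
        _save_configs(artifacts[name], f"{name}.xyz")
    elif kind == "read":
        artifacts[name] = read_extxyz(stage["path"])
    elif kind == "label":
        calc = _get_calculator(stage)
        ds = label_dataset(artifacts[stage["input"]], calc)
        artifacts[name] = ds
        _save_configs(list(ds), f"{name}.xyz")
    elif kind == "train":
        ds = artifacts[stage["input"]]
        if not isinstance(ds, LabeledDataset):
            ds = LabeledDataset(list(ds))
        spec = FeatureSpec(**args.pop("feature_spec", {}))
        model = fit(ds, spec, **args)
        artifacts[name] = model
        path = outdir / f"{name}.json"
        model.save(path)
        out.append(str(path))
    elif kind == "al":
        calc = _get_calculator(stage)
        start = artifacts[stage["start"]][0]
        init = artifacts[stage["input"]]
        soap = SoapSpec(**args.pop("soap", {"species": tuple(calc.elements)}))
        fspec = FeatureSpec(**args.pop("feature_spec", {"species": tuple(calc.elements)}))
        restraints = [RestraintSpec(**r) for r in args.pop("restraints", [])]
        al = ALConfig(soap=soap, feature_spec=fspec, seed=seed,
                      restraints=tuple(restraints), phase=name, **args)
        dataset, model, history = run_al_phase(init, start, al, calc)
        artifacts[name] = dataset
        artifacts[f"{name}:model"] = model
        _save_configs(list(dataset), f"{name}.xyz")
        hpath = outdir / f"{name}_history.csv"
        history.to_csv(hpath, index=False)
        out.append(str(hpath))
    elif kind == "md":
        calc_name = stage.get("calculator")
        calc = artifacts[calc_name] if calc_name in artifacts else _get_calculator(stage)
        start = artifacts[stage["input"]][0]
        thermo = ThermostatSpec(**args.pop("thermostat", {"kind": "csvr"}))
        restraints = [RestraintSpec(**r) for r in args.pop("restraints", [])]
        state = initialize_state(start, thermo.temperature, seed=args.pop("seed", seed))
        res = run_md(state, calc, thermo, restraints, **args)
        artifacts[name] = res.trajectory
        _save_configs(res.trajectory, f"{name}.xyz")
        lpath = outdir / f"{name}_energy.csv"
        res.log.to_csv(lpath, index=False)
        out.append(str(lpath))
    elif kind == "rdf":
        traj = artifacts[stage["input"]]
        result = rdf(traj, stage["center"], stage["partner"], **args)
        artifacts[name] = result
        path = outdir / f"{name}.csv"
        result.to_frame().to_csv(path, index=False)
        out.append(str(path))
        try:
            shell = first_shell(result)
            (outdir / f"{name}_shell.json").write_text(json.dumps(shell))
            out.append(str(outdir / f"{name}_shell.json"))
        except ValueError:
            pass
    else:
        raise ValueError(f"unknown stage kind {kind!r}")
    return out
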