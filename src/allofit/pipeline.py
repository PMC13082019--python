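"""Config-driven orchestration: simulate → normalize → fit → stats → report.

A run is declared as a YAML (or dict) config with a global seed and an
ordered list of stages. Each stage consumes named outputs of earlier stages
and/or files declared in the config — nothing else — and all randomness
flows from the declared seeds, so identical configs reproduce identical
JSON outputs (floating point is serialized at full repr precision; only the
manifest timestamp differs between runs).

Every run emits exactly one ``manifest.json`` capturing the config
snapshot, seeds, package version, SHA-256 hashes of referenced input files,
per-stage status and output paths. A stage failure halts the run with a
stage-attributed error; the manifest records the partial completion.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assay_io import normalize_vehicle_max, read_response_table, write_response_table
from .curves import fit_competition, fit_logistic3, fit_saturation
from .operational import fit_operational
from .stats import GroupSamples, anova_dunnett, welch_t
from .synthetic import SimConfig, preset, simulate_assay

__all__ = ["RunManifest", "ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    """Config schema violation; the message carries a JSON-pointer path."""


class StageError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str
    input_hashes: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "package_version": self.package_version,
            "input_hashes": self.input_hashes,
            "stages": self.stages,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(stage: dict, key: str, ptr: str):
    if key not in stage:
        raise ConfigError(f"missing required key at {ptr}/{key}")
    return stage[key]


_KNOWN_KINDS = {
    "simulate_assay", "read_table", "normalize", "fit_logistic",
    "fit_saturation", "fit_competition", "fit_operational", "welch", "dunnett",
}


def _validate(config: dict) -> None:
    if not isinstance(config, dict):
        raise ConfigError("config root must be a mapping (at /)")
    stages = config.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ConfigError("missing or empty stage list at /stages")
    names = set()
    for i, st in enumerate(stages):
        ptr = f"/stages/{i}"
        if not isinstance(st, dict):
            raise ConfigError(f"stage must be a mapping at {ptr}")
        kind = _require(st, "kind", ptr)
        if kind not in _KNOWN_KINDS:
            raise ConfigError(f"unknown stage kind {kind!r} at {ptr}/kind")
        name = st.get("name", f"stage{i}")
        if name in names:
            raise ConfigError(f"duplicate stage name {name!r} at {ptr}/name")
        names.add(name)


def run_pipeline(config, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the declared stages in order and write all artifacts.

    Parameters
    ----------
    config : dict or path to a YAML file
    out_dir : directory for artifacts (created if absent)
    seed : optional override of the config's global seed
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(config, dict):
        cfg_path = Path(config)
        config = yaml.safe_load(cfg_path.read_text())
    _validate(config)
    run_seed = int(seed if seed is not None else config.get("seed", 0))

    manifest = RunManifest(
        config=config, seed=run_seed, package_version=__version__,
        started=time.time(),
    )
    registry: dict[str, object] = {}

    def emit_json(name: str, payload: dict) -> str:
        p = out / name
        p.write_text(json.dumps(payload, indent=2, default=_jsonify))
        manifest.outputs.append(str(p))
        return str(p)

    for i, st in enumerate(config["stages"]):
        name = st.get("name", f"stage{i}")
        kind = st["kind"]
        record = {"name": name, "kind": kind, "status": "running"}
        manifest.stages.append(record)
        try:
            _run_stage(st, kind, name, run_seed + i, registry, out, manifest, emit_json)
            record["status"] = "completed"
        except Exception as exc:
            record["status"] = "failed"
            record["error"] = str(exc)
            manifest.finished = time.time()
            (out / "manifest.json").write_text(
                json.dumps(manifest.to_dict(), indent=2, default=_jsonify)
            )
            raise StageError(f"stage {name!r} ({kind}) failed: {exc}") from exc

    manifest.finished = time.time()
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, default=_jsonify)
    )
    return manifest


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _get_input(st: dict, registry: dict, ptr: str):
    key = _require(st, "input", ptr)
    if key not in registry:
        raise ConfigError(f"stage input {key!r} not produced by an earlier stage")
    return registry[key]


def _run_stage(st, kind, name, stage_seed, registry, out, manifest, emit_json):
    ptr = f"/stages/{name}"
    if kind == "simulate_assay":
        if "preset" in st:
            cfg = preset(st["preset"], **st.get("overrides", {}))
        else:
            cfg = SimConfig(
                model=_require(st, "model", ptr),
                truth=_require(st, "truth", ptr),
                design=st.get("design", {}),
                noise_sd=float(st.get("noise_sd", 0.0)),
                noise_kind=st.get("noise_kind", "gaussian"),
            )
        cfg.seed = int(st.get("seed", stage_seed))
        data, truth = simulate_assay(cfg)
        registry[name] = data
        csv_path = out / f"{name}.csv"
        write_response_table(data, csv_path)
        manifest.outputs.append(str(csv_path))
        emit_json(f"{name}.truth.json", truth)
    elif kind == "read_table":
        path = Path(_require(st, "path", ptr))
        data = read_response_table(
            path, _require(st, "schema", ptr),
            radioligand_conc=st.get("radioligand_conc"),
            radioligand_kd=st.get("radioligand_kd"),
        )
        manifest.input_hashes[str(path)] = _sha256(path)
        registry[name] = data
    elif kind == "normalize":
        data = _get_input(st, registry, ptr)
        registry[name] = normalize_vehicle_max(data, st.get("reference_ligand"))
    elif kind == "fit_logistic":
        data = _get_input(st, registry, ptr)
        res = fit_logistic3(data, seed=int(st.get("seed", stage_seed)))
        registry[name] = res
        emit_json(f"{name}.fit.json", res.to_dict())
    elif kind == "fit_saturation":
        data = _get_input(st, registry, ptr)
        res = fit_saturation(data, seed=int(st.get("seed", stage_seed)))
        registry[name] = res
        emit_json(f"{name}.fit.json", res.to_dict())
    elif kind == "fit_competition":
        data = _get_input(st, registry, ptr)
        res = fit_competition(
            data, radioligand_kd=st.get("radioligand_kd"),
            seed=int(st.get("seed", stage_seed)),
        )
        registry[name] = res
        emit_json(f"{name}.fit.json", res.to_dict())
    elif kind == "fit_operational":
        data = _get_input(st, registry, ptr)
        constraints = {"emax": st.get("emax", "auto"), "n": st.get("n", 1.0)}
        res = fit_operational(data, constraints, seed=int(st.get("seed", stage_seed)))
        registry[name] = res
        emit_json(f"{name}.fit.json", res.to_dict())
    elif kind == "welch":
        x = np.asarray(_require(st, "x", ptr), float)
        y = np.asarray(_require(st, "y", ptr), float)
        res = welch_t(x, y)
        registry[name] = res
        emit_json(f"{name}.welch.json", {"t": res.t, "df": res.df, "p": res.p})
    elif kind == "dunnett":
        groups = GroupSamples(
            values={k: np.asarray(v, float)
                    for k, v in _require(st, "groups", ptr).items()},
            control_label=_require(st, "control", ptr),
        )
        res = anova_dunnett(groups, seed=int(st.get("seed", stage_seed)))
        registry[name] = res
        emit_json(
            f"{name}.dunnett.json",
            {
                "F": res.f_statistic,
                "F_p": res.f_pvalue,
                "comparisons": [
                    {"label": c.label, "statistic": c.statistic,
                     "p_adjusted": c.p_adjusted}
                    for c in res.comparisons
                ],
            },
        )
    else:  # pragma: no cover - guarded by _validate
        raise ConfigError(f"unknown stage kind {kind!r}")
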