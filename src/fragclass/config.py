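"""Run configuration (YAML) and run manifests.

A run is declared in one YAML file; unknown keys are rejected. Every CLI
run emits a manifest tying outputs to the config hash, input hashes and
seeds, which also powers the `run` subcommand's cache (identical config
=> outputs reused).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import yaml

from .simulate import GenomeConfig, HealthyModel, SimulationConfig, TumorModel

__all__ = ["ConfigError", "load_run_config", "config_hash", "RunManifestWriter"]


class ConfigError(ValueError):
    pass


_SCHEMA = {
    "genome": set(GenomeConfig.__dataclass_fields__),
    "healthy": set(HealthyModel.__dataclass_fields__),
    "tumor": set(TumorModel.__dataclass_fields__),
    "cohort": {
        "n_train_cancer", "n_train_healthy", "n_val_cancer", "n_val_healthy",
        "tf_low", "tf_high",
    },
    "model": {"combination", "k", "grid_budget", "target_specificity"},
    "depth": None,
    "seed": None,
}


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{section}': {sorted(unknown)}")


def load_run_config(path: str | Path) -> dict:
    """Parse + validate the YAML run config; fill in defaults.

    Returns {"sim": SimulationConfig, "cohort": {...}, "model": {...}}.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("root", raw, set(_SCHEMA))
    for sec in ("genome", "healthy", "tumor", "cohort", "model"):
        if sec in raw:
            if not isinstance(raw[sec], dict):
                raise ConfigError(f"'{sec}' must be a mapping")
            _check_keys(sec, raw[sec], _SCHEMA[sec])
    tumor_raw = dict(raw.get("tumor", {}))
    if "cnv_segments" in tumor_raw:
        tumor_raw["cnv_segments"] = tuple(tuple(s) for s in tumor_raw["cnv_segments"])
    sim = SimulationConfig(
        genome=GenomeConfig(**raw.get("genome", {})),
        healthy=HealthyModel(**raw.get("healthy", {})),
        tumor=TumorModel(**tumor_raw),
        depth=float(raw.get("depth", 5.0)),
        seed=int(raw.get("seed", 0)),
    )
    cohort = {
        "n_train_cancer": 119, "n_train_healthy": 112,
        "n_val_cancer": 85, "n_val_healthy": 79,
        "tf_low": 0.05, "tf_high": 0.3,
    }
    cohort.update(raw.get("cohort", {}))
    model = {"combination": "mean", "k": 5, "grid_budget": 1, "target_specificity": 0.95}
    model.update(raw.get("model", {}))
    if model["combination"] not in ("mean", "meta_glm"):
        raise ConfigError(f"model.combination must be mean|meta_glm, got {model['combination']!r}")
    return {"sim": sim, "cohort": cohort, "model": model}


def config_hash(cfg: dict) -> str:
    payload = {
        "sim": asdict(cfg["sim"]),
        "cohort": cfg["cohort"],
        "model": cfg["model"],
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifestWriter:
    """Collects inputs/outputs/seeds for one CLI run and writes
    manifest.json next to the outputs."""

    def __init__(self, out_dir: str | Path, config_digest: str | None = None):
        from . import __version__

        self.out_dir = Path(out_dir)
        self.data = {
            "tool": "fragclass",
            "version": __version__,
            "config_hash": config_digest,
            "inputs": {},
            "outputs": {},
            "seeds": {},
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def add_input(self, path: str | Path) -> None:
        self.data["inputs"][str(path)] = file_hash(path)

    def add_seed(self, name: str, seed: int) -> None:
        self.data["seeds"][name] = int(seed)

    def add_output(self, path: str | Path) -> None:
        self.data["outputs"][str(Path(path).relative_to(self.out_dir))] = file_hash(path)

    def write(self) -> Path:
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.out_dir.mkdir(parents=True, exist_ok=True)
        p = self.out_dir / "manifest.json"
        with open(p, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
        return p


def cached_manifest(out_dir: str | Path, config_digest: str) -> dict | None:
    """Return the existing manifest when the cached outputs are intact."""
    p = Path(out_dir) / "manifest.json"
    if not p.exists():
        return None
    data = json.loads(p.read_text())
    if data.get("config_hash") != config_digest:
        return None
    for rel, digest in data.get("outputs", {}).items():
        f = Path(out_dir) / rel
        if not f.exists() or file_hash(f) != digest:
            return None
    return data
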