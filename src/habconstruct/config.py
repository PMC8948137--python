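"""Run configuration: YAML files, percent parsing, and result writing.

A run configuration is the full model parameterization plus run metadata
(output directory, replicate count, base seed, optional preset name). Every
field defaults to the baseline regime, so an empty config file reproduces
it. Rates may be written either as fractions (0.44) or with an explicit
percent suffix ("44%").
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .experiment import ExperimentResult, SweepResult, SummaryStats
from .params import ConfigurationError, ModelParams

log = logging.getLogger("habconstruct")

_PERCENT_FIELDS = {"delta", "phi", "tau", "dispersal_rate", "mutation_rate"}


@dataclass(frozen=True)
class RunConfig:
    """ModelParams plus run metadata."""

    params: ModelParams = field(default_factory=ModelParams)
    outdir: Path = Path("results")
    n_reps: int | None = None       # None → params.replicates
    base_seed: int | None = None    # None → params.seed
    preset: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return {
            **self.params.to_dict(),
            "outdir": str(self.outdir),
            "n_reps": self.n_reps,
            "base_seed": self.base_seed,
            "preset": self.preset,
            "log_level": self.log_level,
        }


def _coerce(key: str, value: Any) -> Any:
    """Accept '44%' strings for rate-like fields; pass everything else through."""
    if isinstance(value, str) and value.rstrip().endswith("%"):
        if key not in _PERCENT_FIELDS:
            raise ConfigurationError(f"{key!r} does not accept a percentage value")
        try:
            return float(value.rstrip().rstrip("%")) / 100.0
        except ValueError as e:
            raise ConfigurationError(f"cannot parse percentage for {key!r}: {value!r}") from e
    return value


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Merge flag overrides > config file > baseline defaults.

    The file is flat YAML key/value; keys are either ModelParams fields or
    the run-metadata keys (outdir, n_reps, base_seed, preset, log_level).
    Unknown keys and out-of-range values raise ConfigurationError naming
    the key. The fully resolved configuration is echoed to the log.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file must be a mapping: {p}")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})

    meta_keys = {"outdir", "n_reps", "base_seed", "preset", "log_level"}
    param_keys = {f.name for f in fields(ModelParams)}
    unknown = set(raw) - meta_keys - param_keys
    if unknown:
        raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")

    param_dict = {k: _coerce(k, v) for k, v in raw.items() if k in param_keys}
    try:
        params = ModelParams(**param_dict)
    except TypeError as e:
        raise ConfigurationError(str(e)) from e

    cfg = RunConfig(
        params=params,
        outdir=Path(raw.get("outdir", "results")),
        n_reps=raw.get("n_reps"),
        base_seed=raw.get("base_seed"),
        preset=raw.get("preset"),
        log_level=str(raw.get("log_level", "INFO")),
    )
    log.info("resolved configuration: %s", json.dumps(cfg.to_dict(), default=str))
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write the resolved configuration as YAML (round-trips via load_config)."""
    p = Path(path)
    d = cfg.to_dict()
    p.write_text(yaml.safe_dump(d, sort_keys=True))
    return p


def _result_frames(result: ExperimentResult | SweepResult) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    if isinstance(result, ExperimentResult):
        result = SweepResult([result])
    reps = result.replicate_frame()
    aggs = result.aggregate_frame()
    meta = [r.params.to_dict() | {"base_seed": r.base_seed, "seeds": r.seeds}
            for r in result.results]
    return reps, aggs, meta


def write_results(result: ExperimentResult | SweepResult,
                  outdir: str | Path) -> dict[str, Path]:
    """Write replicate and aggregate CSVs plus a JSON metadata sidecar.

    Columns are in stable order; extinct replicates appear with the extinct
    flag set and NaN statistics. Returns the paths written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reps, aggs, meta = _result_frames(result)
    paths = {
        "replicates": out / "replicates.csv",
        "aggregates": out / "aggregates.csv",
        "metadata": out / "metadata.json",
    }
    reps.to_csv(paths["replicates"], index=False)
    aggs.to_csv(paths["aggregates"], index=False)
    paths["metadata"].write_text(json.dumps({"combinations": meta}, indent=2, default=str))
    log.info("wrote results to %s", out)
    return paths


def read_results(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read back what write_results wrote."""
    out = Path(outdir)
    reps = pd.read_csv(out / "replicates.csv")
    aggs = pd.read_csv(out / "aggregates.csv")
    meta = json.loads((out / "metadata.json").read_text())
    return reps, aggs, meta
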