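"""Pipeline configuration: one YAML block drives simulation through maps."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .suitability import DEFAULT_CLASS_EDGES, DEFAULT_DEPTH_CUTOFF
from .synthetic import ClimatologyConfig, ExperimentDesign
from .tpc import DEFAULT_CT_THRESHOLD


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FittingConfig:
    """Knobs of the TPC fitting stage."""

    n_starts: int = 20
    n_boot: int = 199
    ct_threshold: float = DEFAULT_CT_THRESHOLD
    ct_sensitivity: tuple[float, ...] = (0.05, DEFAULT_CT_THRESHOLD, 0.15)
    models: tuple[str, ...] | None = None  # None = full family
    discard_initial: float = 300.0  # seconds dropped per trace
    noise_sd: float = 0.01  # mg O2/L, synthetic optode noise

    def __post_init__(self) -> None:
        if not (0.0 < self.ct_threshold <= 1.0):
            raise ConfigError("ct_threshold must be in (0, 1]")
        if self.n_starts <= 0 or self.n_boot <= 0:
            raise ConfigError("n_starts and n_boot must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs, serializable to YAML."""

    outdir: str = "thermoniche_out"
    seed: int = 1
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    climatology: ClimatologyConfig | None = None  # None: derive from seed
    fitting: FittingConfig = field(default_factory=FittingConfig)
    class_edges: tuple[float, ...] = DEFAULT_CLASS_EDGES
    depth_cutoff: float = DEFAULT_DEPTH_CUTOFF
    scenarios: tuple[str, ...] = ("current", "rcp45", "rcp85")
    write_traces: bool = False  # raw trace CSVs are large; opt in
    render_figures: bool = True

    def resolved_climatology(self) -> ClimatologyConfig:
        if self.climatology is not None:
            return self.climatology
        return ClimatologyConfig(seed=self.seed)

    def to_dict(self) -> dict:
        return _listify(asdict(self))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Unknown top-level keys are rejected; nested blocks (``design``,
    ``climatology``, ``fitting``) accept the corresponding dataclass fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    kwargs: dict = {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, value in raw.items():
        if key == "design":
            value = ExperimentDesign(**_tuplify(value, "temperatures"))
        elif key == "climatology":
            value = (
                ClimatologyConfig(**_tuplify(value, "lat_range", "lon_range"))
                if value is not None
                else None
            )
        elif key == "fitting":
            value = FittingConfig(
                **_tuplify(value, "ct_sensitivity", "models")
            )
        elif key in ("class_edges", "scenarios"):
            value = tuple(value)
        kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def _listify(obj):
    # YAML-safe: tuples become lists (and back via _tuplify on load)
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def _tuplify(block: dict, *keys: str) -> dict:
    block = dict(block)
    for key in keys:
        if key in block and block[key] is not None:
            block[key] = tuple(block[key])
    return block
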