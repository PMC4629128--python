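"""The extraction pipeline engine.

A pipeline is an ordered sequence of named steps drawn from four stages —
preprocessing, segmentation, graph detection (thinning then detection
proper) and graph filtering. Executing a pipeline on an image yields a
:class:`PipelineResult` holding every intermediate product (images, masks,
skeleton, graphs) plus the final extracted graph.

Configurations are plain YAML documents with a schema version, so a tuned
pipeline can be saved and reused::

    schema_version: 1
    steps:
      - {stage: segmentation, name: otsu, params: {}}
      - {stage: graph_detection, name: guo_hall, params: {}}
      - {stage: graph_detection, name: detect_graph, params: {}}
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from . import graph_detection, graph_filters, preprocessing, segmentation, thinning  # noqa: F401  (step registration)
from .errors import ConfigurationError
from .graph import SpatialGraph
from .images import as_raster
from .registry import STAGE_RANK, get_step
from .thinning import Skeleton

__all__ = [
    "PipelineStep",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "load_config",
    "save_config",
]

SCHEMA_VERSION = 1

#: ordering of kinds inside the graph_detection stage
_KIND_RANK = {"thin": 0, "detect": 1}


@dataclass(frozen=True)
class PipelineStep:
    stage: str
    name: str
    params: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """An ordered, validated list of pipeline steps."""

    steps: list[PipelineStep] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        last_rank = -1
        seen_segmentation = seen_detect = seen_thin = False
        for step in self.steps:
            sd = get_step(step.name)
            if sd.stage != step.stage:
                raise ConfigurationError(
                    f"step {step.name!r} belongs to stage {sd.stage!r}, "
                    f"config says {step.stage!r}"
                )
            rank = 10 * STAGE_RANK[sd.stage] + _KIND_RANK.get(sd.kind, 0)
            if rank < last_rank:
                raise ConfigurationError(
                    f"step {step.name!r} ({sd.stage}) appears after a later stage"
                )
            last_rank = rank
            if sd.stage == "segmentation":
                if seen_segmentation:
                    raise ConfigurationError("more than one segmentation step")
                seen_segmentation = True
            if sd.kind == "thin":
                if seen_thin:
                    raise ConfigurationError("more than one thinning step")
                seen_thin = True
            if sd.kind == "detect":
                if seen_detect:
                    raise ConfigurationError("more than one graph detection step")
                seen_detect = True
            unknown = set(step.params) - set(sd.params)
            if unknown:
                raise ConfigurationError(
                    f"step {step.name!r}: unknown parameters {sorted(unknown)}"
                )

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "steps": [
                {"stage": s.stage, "name": s.name, "params": dict(s.params)}
                for s in self.steps
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict) or "steps" not in data:
            raise ConfigurationError("config must be a mapping with a 'steps' list")
        version = data.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigurationError(f"unsupported schema_version {version!r}")
        steps = []
        for i, raw in enumerate(data["steps"]):
            try:
                steps.append(
                    PipelineStep(
                        stage=raw["stage"],
                        name=raw["name"],
                        params=dict(raw.get("params") or {}),
                    )
                )
            except (KeyError, TypeError) as exc:
                raise ConfigurationError(f"steps[{i}]: malformed entry ({exc})") from exc
        return cls(steps=steps)

    @classmethod
    def from_names(cls, names, params: dict | None = None) -> "PipelineConfig":
        """Convenience constructor from step names; ``params`` maps step
        name to its parameter overrides."""
        params = params or {}
        return cls(
            steps=[
                PipelineStep(stage=get_step(n).stage, name=n, params=dict(params.get(n, {})))
                for n in names
            ]
        )


@dataclass
class PipelineResult:
    """All intermediate products of one pipeline execution, in order."""

    intermediates: dict = field(default_factory=dict)
    final_graph: SpatialGraph | None = None

    def record(self, index: int, name: str, value) -> None:
        self.intermediates[f"{index:02d}-{name}"] = value


def run_pipeline(image, config: PipelineConfig) -> PipelineResult:
    """Execute *config* on *image*.

    Steps run in order; each stage's output is captured in the result. The
    final graph is the last graph produced (after any filters). The
    pipeline is deterministic: identical inputs yield identical results.
    """
    config.validate()
    if not any(get_step(s.name).kind == "detect" for s in config.steps):
        raise ConfigurationError("pipeline has no graph detection step")

    current = as_raster(image)
    binary = None
    skeleton: Skeleton | None = None
    graph: SpatialGraph | None = None
    result = PipelineResult()

    for i, step in enumerate(config.steps):
        sd = get_step(step.name)
        if sd.stage == "preprocessing":
            current = sd.func(current, **step.params)
            out = current
        elif sd.stage == "segmentation":
            binary = sd.func(current, **step.params)
            out = binary
        elif sd.kind == "thin":
            if binary is None:
                raise ConfigurationError(
                    f"step {step.name!r} needs a segmentation step before it"
                )
            skeleton = sd.func(binary, **step.params)
            out = skeleton
        elif sd.kind == "detect":
            if skeleton is None:
                raise ConfigurationError(
                    f"step {step.name!r} needs a thinning step before it"
                )
            graph = sd.func(skeleton, binary, **step.params)
            out = graph
        else:  # graph_filtering
            if graph is None:
                raise ConfigurationError(
                    f"filter {step.name!r} needs a graph detection step before it"
                )
            graph = sd.func(graph, **step.params)
            out = graph
        result.record(i, step.name, out)

    result.final_graph = graph
    return result


# -- config serialization --------------------------------------------------


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    """Load a pipeline config; malformed files raise
    :class:`ConfigurationError` with line context where available."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" at line {mark.line + 1}" if mark is not None else ""
            raise ConfigurationError(f"{path}: cannot parse{where}: {exc}") from exc
    return PipelineConfig.from_dict(data)
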