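"""Registry of named pipeline steps.

Every algorithm that can appear in a pipeline registers itself here under a
stage (``preprocessing``, ``segmentation``, ``graph_detection``,
``graph_filtering``). Within ``graph_detection`` the thinning step is
distinguished from graph detection proper by ``kind`` so the engine can
enforce thin-before-detect ordering.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Callable

from .errors import ConfigurationError

STAGES = ("preprocessing", "segmentation", "graph_detection", "graph_filtering")
STAGE_RANK = {s: i for i, s in enumerate(STAGES)}


@dataclass(frozen=True)
class StepDef:
    name: str
    stage: str
    func: Callable
    kind: str = ""  # "thin" or "detect" within graph_detection
    params: dict = field(default_factory=dict)  # name -> default


REGISTRY: dict[str, StepDef] = {}


def register(name: str, stage: str, kind: str = ""):
    """Class of decorator registering *func* as pipeline step *name*.

    Tunable parameters and their defaults are taken from the function
    signature (every keyword argument after the positional data inputs).
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")

    def deco(func):
        sig = inspect.signature(func)
        params = {
            p.name: p.default
            for p in sig.parameters.values()
            if p.default is not inspect.Parameter.empty
        }
        REGISTRY[name] = StepDef(name=name, stage=stage, func=func, kind=kind, params=params)
        return func

    return deco


def get_step(name: str) -> StepDef:
    try:
        return REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown pipeline step {name!r}; known steps: {sorted(REGISTRY)}"
        ) from None
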