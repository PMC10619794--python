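"""Run configuration: condition plan, blocking, detector and LDE settings.

A session's condition plan is an ordered list of half-open time windows
[start, end) with condition names; windows sharing a name (e.g. three
5-minute training bouts) are concatenated at the stride level by the
pipeline. Configurations can be loaded from a flat YAML file mirroring the
dataclass fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .divergence import LdeParams
from .events import EventParams


@dataclass
class RunConfig:
    walking_speed: float | None = None
    #: ordered (condition-name, start-s, end-s) windows, non-overlapping
    condition_plan: list[tuple[str, float, float]] = field(default_factory=list)
    block_size: int = 30
    seed: int = 0
    event_params: EventParams = field(default_factory=EventParams)
    lde_params: LdeParams = field(default_factory=LdeParams)
    #: "condition" computes one divergence exponent per condition on the
    #: concatenated normalized signal; "block" computes one per 30-stride
    #: block and averages; "off" skips the divergence analysis.
    lde_scope: str = "condition"

    def __post_init__(self) -> None:
        if self.block_size < 10:
            raise ValueError("block_size must be >= 10")
        if self.lde_scope not in ("condition", "block", "off"):
            raise ValueError("lde_scope must be 'condition', 'block' or 'off'")
        plan = sorted(self.condition_plan, key=lambda w: w[1])
        for (n1, s1, e1), (n2, s2, e2) in zip(plan, plan[1:]):
            if e1 > s2:
                raise ValueError(
                    f"condition windows overlap: ({n1}, {s1}, {e1}) and "
                    f"({n2}, {s2}, {e2})"
                )
        for name, start, end in plan:
            if end <= start:
                raise ValueError(f"empty condition window ({name}, {start}, {end})")


def load_config(path) -> RunConfig:
    """Read a RunConfig from a flat YAML file.

    Nested keys ``event_params`` and ``lde_params`` map onto the respective
    dataclasses; ``condition_plan`` is a list of [name, start, end] entries.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    known = {f.name for f in fields(RunConfig)}
    for key, value in raw.items():
        if key not in known:
            raise ValueError(f"unknown config key: {key!r}")
        if key == "event_params":
            value = EventParams(**value)
        elif key == "lde_params":
            value = LdeParams(**value)
        elif key == "condition_plan":
            value = [(str(n), float(s), float(e)) for n, s, e in value]
        kwargs[key] = value
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    raw = {
        "walking_speed": config.walking_speed,
        "condition_plan": [list(w) for w in config.condition_plan],
        "block_size": config.block_size,
        "seed": config.seed,
        "event_params": vars(config.event_params),
        "lde_params": vars(config.lde_params),
        "lde_scope": config.lde_scope,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
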