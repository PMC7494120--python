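"""Run configuration: one flat, serializable record of every knob.

All randomness in a run funnels through ``seed``.  ``save``/``load`` use a
flat ``key = value`` text format so a run's resolved configuration can sit
next to its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # preprocessing (both threshold sets from the source protocols are in
    # use in the field; the stability-analysis baseline is the default)
    min_hole_area: int = 21
    min_object_area: int = 101
    # tracing
    shift: float = 0.05  # anti-crossing separation, px
    # diagram construction
    frame_margin: float = 0.5
    merge_collinear: bool = True
    sample_spacing: float = 0.75
    # typing
    n_types: int = 12
    kmeans_restarts: int = 10
    knn_k: int = 3
    normalize_histograms: bool = False
    use_in: bool = True
    use_out: bool = True
    # randomness
    seed: int = 0

    def save(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        kw = {}
        types = {f.name: f.type for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            k, _, v = line.partition("=")
            k, v = k.strip(), v.strip()
            if k not in types:
                raise ValueError(f"unknown config key {k!r}")
            t = types[k]
            if t in ("bool", bool):
                kw[k] = v.lower() in ("1", "true", "yes")
            elif t in ("int", int):
                kw[k] = int(v)
            elif t in ("float", float):
                kw[k] = float(v)
            else:
                kw[k] = v
        return cls(**kw)
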