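"""Serializable run configuration.

A :class:`RunConfig` bundles everything a simulation or analysis run needs —
seed, lead geometry, stimulus program, plant ground truth, controller and
analysis options — and round-trips losslessly through plain dicts (and hence
YAML/JSON via :mod:`ecaploop.io`). Every CLI run echoes its effective config
next to its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cloop import ControllerParams
from .features import DEFAULT_BLANKING_MS, DEFAULT_DETECTION_K
from .iofit import DEFAULT_SMOOTHING
from .synth import GainProcess, GroundTruth, LeadGeometry, StimulusProgram

__all__ = ["AnalysisOptions", "RunConfig"]


@dataclass(frozen=True)
class AnalysisOptions:
    smoothing: float = DEFAULT_SMOOTHING
    detection_k: float = DEFAULT_DETECTION_K
    blanking_ms: float = DEFAULT_BLANKING_MS
    search_window_ms: tuple[float, float] | None = None


@dataclass
class RunConfig:
    seed: int = 0
    geometry: LeadGeometry = field(default_factory=LeadGeometry)
    program: StimulusProgram = field(default_factory=StimulusProgram)
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    controller: ControllerParams = field(default_factory=ControllerParams)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    out: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        cur = d["program"]["current_ma"]
        if isinstance(cur, np.ndarray):
            d["program"]["current_ma"] = cur.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "geometry" in d:
            g = dict(d["geometry"])
            if "contact_labels" in g:
                g["contact_labels"] = tuple(g["contact_labels"])
            d["geometry"] = LeadGeometry(**g)
        if "program" in d:
            p = dict(d["program"])
            if isinstance(p.get("current_ma"), list):
                p["current_ma"] = np.asarray(p["current_ma"], dtype=float)
            d["program"] = StimulusProgram(**p)
        if "ground_truth" in d:
            gt = dict(d["ground_truth"])
            if "gain_process" in gt and isinstance(gt["gain_process"], dict):
                gt["gain_process"] = GainProcess(**gt["gain_process"])
            d["ground_truth"] = GroundTruth(**gt)
        if "controller" in d:
            d["controller"] = ControllerParams(**d["controller"])
        if "analysis" in d:
            a = dict(d["analysis"])
            if isinstance(a.get("search_window_ms"), list):
                a["search_window_ms"] = tuple(a["search_window_ms"])
            d["analysis"] = AnalysisOptions(**a)
        return cls(**d)
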