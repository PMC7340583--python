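"""YAML configuration: `segmentation:` and `classification:` blocks."""

from __future__ import annotations

from pathlib import Path

import yaml

from .quantify import ClassificationParams
from .segmentation import SegmentationParams


def load_config(path) -> dict:
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def segmentation_params(cfg: dict) -> SegmentationParams:
    return SegmentationParams(**cfg.get("segmentation", {}))


def classification_params(cfg: dict) -> ClassificationParams:
    return ClassificationParams(**cfg.get("classification", {}))
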