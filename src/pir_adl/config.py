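"""YAML configuration for the pipeline.

Recognised top-level blocks::

    segmentation: room          # token | room | slots60
    slot_s: 60
    room_clustering:            # every RoomFilterConfig field
      short_window_s: 15
      long_window_s: 300
      activity_threshold: 0.05
      min_gap_s: 300
      edge_keep_s: 10
      min_activity_s: 20
      default_weights: [1.0, 1.0]
      room_weights:
        BATHROOM: [2.0, 1.0]
    classifier:
      algorithm: rf             # nb | svm | rf
      n_trees: 100
      random_seed: 0
"""

from __future__ import annotations

import os

import yaml

from .classification import ClassifierSpec
from .pipeline import PipelineConfig
from .room_segmentation import RoomFilterConfig


def pipeline_from_mapping(doc: dict) -> PipelineConfig:
    room = RoomFilterConfig.from_dict(doc.get("room_clustering", {}))
    return PipelineConfig(
        segmentation=doc.get("segmentation", "room"),
        room=room,
        slot_s=int(doc.get("slot_s", 60)),
    )


def classifier_from_mapping(doc: dict) -> ClassifierSpec:
    block = dict(doc.get("classifier", {}))
    block.setdefault("algorithm", "rf")
    return ClassifierSpec(**block)


def load_config(path: str | os.PathLike) -> tuple[PipelineConfig, ClassifierSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return pipeline_from_mapping(doc), classifier_from_mapping(doc)
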