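"""Pipeline assembly: dataset -> grid -> segments for each method."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classification import slice_fixed_windows
from .home import ConfigurationError, HomeDataset
from .preprocess import preprocess_home
from .room_segmentation import RoomFilterConfig, segment_rooms
from .token_segmentation import segment_tokens

SEGMENTATION_METHODS = ("token", "room", "slots60")


@dataclass(frozen=True)
class PipelineConfig:
    """Which segmentation feeds the classifier, and its parameters."""

    segmentation: str = "room"
    room: RoomFilterConfig = field(default_factory=RoomFilterConfig)
    slot_s: int = 60

    def __post_init__(self) -> None:
        if self.segmentation not in SEGMENTATION_METHODS:
            raise ConfigurationError(
                f"unknown segmentation {self.segmentation!r}; use one of {SEGMENTATION_METHODS}"
            )


def segment_grid(grid: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.segmentation == "token":
        return segment_tokens(grid)
    if cfg.segmentation == "room":
        return segment_rooms(grid, cfg.room)
    return slice_fixed_windows(grid, cfg.slot_s)


def prepare_homes(
    datasets: list[HomeDataset],
    cfg: PipelineConfig,
    grids: list[pd.DataFrame] | None = None,
) -> list[tuple[str, pd.DataFrame, pd.DataFrame]]:
    """Preprocess and segment every home: (home_id, grid, segments) triples.

    Precomputed grids may be passed to share preprocessing between pipeline
    variants.
    """
    if grids is None:
        grids = [preprocess_home(d) for d in datasets]
    return [(d.home_id, g, segment_grid(g, cfg)) for d, g in zip(datasets, grids)]
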