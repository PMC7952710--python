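"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

from .disentanglement import DEFAULT_THRESHOLD
from .pattern_mining import DEFAULT_MAX_ORDER, DEFAULT_MIN_OCCURRENCE
from .tabular_io import EQUAL_WIDTH


@dataclass
class RunConfig:
    """All tunables of one discovery run; serialized into metadata.json.

    threshold     significance cutoff on residuals (two-sided 95% -> 1.96)
    bins/method   numeric-attribute discretization
    min_occurrence  minimum pattern support (entities)
    max_order     cap on pattern order (search depth)
    merge_overlap Jaccard overlap at which entity clusters merge
    """

    input_path: Optional[str] = None
    input_format: str = "csv"  # csv | fasta | lines
    label_column: Optional[str] = None
    missing_marker: str = "?"
    bins: int = 3
    quantization_method: str = EQUAL_WIDTH
    threshold: float = DEFAULT_THRESHOLD
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE
    max_order: int = DEFAULT_MAX_ORDER
    merge_overlap: float = 0.5
    min_class_size: int = 5
    train_fraction: float = 0.8
    repeats: int = 10
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)
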