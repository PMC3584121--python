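"""The common container for extractor output."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class FeatureBlock:
    """A named, ordered feature vector produced by one extractor call.

    ``names`` carry full provenance (method, scheme/property, parameter) so
    concatenated blocks keep globally unique, reproducible feature names.
    """

    method: str
    names: list[str]
    values: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names within a block")

    def __len__(self) -> int:
        return len(self.names)


def concat_blocks(blocks: list[FeatureBlock], method: str | None = None) -> FeatureBlock:
    """Concatenate blocks into one, preserving order and name uniqueness."""
    names = [n for b in blocks for n in b.names]
    values = np.concatenate([b.values for b in blocks]) if blocks else np.empty(0)
    return FeatureBlock(method or "+".join(dict.fromkeys(b.method for b in blocks)), names, values)
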