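"""The unit of training/evaluation data: a residue string with per-residue labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state_model import CLASS_ALPHABET

__all__ = ["LabeledSequence"]


@dataclass
class LabeledSequence:
    id: str
    sequence: str
    labels: str | None = None  # per-residue classes over {M,H,C,E}
    profile: np.ndarray | None = None  # raw 30-column evolutionary profile
    split: str | None = None  # train / valid / test

    def __post_init__(self) -> None:
        if self.labels is not None:
            if len(self.labels) != len(self.sequence):
                raise ValueError(
                    f"{self.id}: label length {len(self.labels)} != sequence length {len(self.sequence)}"
                )
            bad = set(self.labels) - set(CLASS_ALPHABET)
            if bad:
                raise ValueError(f"{self.id}: labels outside {{M,H,C,E}}: {sorted(bad)}")
        if self.profile is not None and self.profile.shape[0] != len(self.sequence):
            raise ValueError(f"{self.id}: profile rows != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)
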