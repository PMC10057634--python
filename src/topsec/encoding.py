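"""Per-residue feature encoding and sliding-window extraction.

Each residue is encoded as a 52-dimensional row::

    [ 20 one-hot | 1 NoSeq | 30 scaled profile | 1 NoSeq ]

The one-hot block indexes the 20 standard amino acids alphabetically
(A=0, C=1, D=2, ... Y=19, i.e. ``ACDEFGHIKLMNPQRSTVWY``).  The profile
block holds evolutionary-profile values squashed into (0, 1) by
``scale_profile_value``; the two NoSeq columns are 0 on real residues and
1 on the padding rows used to complete terminal windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

N_ONEHOT = 20
N_PROFILE = 30
N_FEATURES = N_ONEHOT + 1 + N_PROFILE + 1  # 52
ONEHOT_NOSEQ_COL = N_ONEHOT  # 20
PROFILE_SLICE = slice(N_ONEHOT + 1, N_ONEHOT + 1 + N_PROFILE)  # 21..50
PROFILE_NOSEQ_COL = N_FEATURES - 1  # 51

#: scale constant of the profile squashing sigmoid
PROFILE_SCALE = 2000.0

__all__ = [
    "AMINO_ACIDS",
    "N_FEATURES",
    "FeatureMatrix",
    "ObservationSequence",
    "scale_profile_value",
    "unscale_profile_value",
    "encode_sequence",
    "extract_windows",
    "encode_observations",
]


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (length, 52)

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class ObservationSequence:
    indices: np.ndarray  # (length,), ints in 0..19

    @property
    def length(self) -> int:
        return self.indices.shape[0]


def scale_profile_value(t, scale: float = PROFILE_SCALE):
    """Squash a raw profile value into (0, 1): ``f(t) = 1 / (1 + exp(-t/scale))``.

    Strictly increasing; f(0) = 0.5.  Large-negative sentinels (absent
    profile entries) map to ~0.
    """
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos] / scale))
    e = np.exp(t[~pos] / scale)
    out[~pos] = e / (1.0 + e)
    return out if out.ndim else float(out)


def unscale_profile_value(p, scale: float = PROFILE_SCALE):
    """Inverse of :func:`scale_profile_value` on (0, 1)."""
    p = np.asarray(p, dtype=float)
    out = scale * (np.log(p) - np.log1p(-p))
    return out if out.ndim else float(out)


def encode_sequence(seq: str, profile: np.ndarray | None = None) -> FeatureMatrix:
    """Encode a residue string (plus optional raw 30-column profile) as 52-dim rows.

    With no profile the 30 profile columns are zero.  Raises ``ValueError``
    naming the 1-based position of any non-standard residue.
    """
    L = len(seq)
    values = np.zeros((L, N_FEATURES), dtype=float)
    for i, aa in enumerate(seq):
        j = AA_INDEX.get(aa)
        if j is None:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
        values[i, j] = 1.0
    if profile is not None:
        profile = np.asarray(profile, dtype=float)
        if profile.shape != (L, N_PROFILE):
            raise ValueError(
                f"profile shape {profile.shape} does not match sequence length {L} x {N_PROFILE}"
            )
        values[:, PROFILE_SLICE] = scale_profile_value(profile)
    return FeatureMatrix(values)


def padding_row() -> np.ndarray:
    """The NoSeq row used beyond either terminus: all zero except both NoSeq flags."""
    row = np.zeros(N_FEATURES, dtype=float)
    row[ONEHOT_NOSEQ_COL] = 1.0
    row[PROFILE_NOSEQ_COL] = 1.0
    return row


def extract_windows(fm: FeatureMatrix, window: int = 19) -> np.ndarray:
    """One window per residue, centred on it; shape (length, window, 52).

    Positions past either terminus are filled with NoSeq padding rows.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    half = window // 2
    L = fm.length
    padded = np.vstack([np.tile(padding_row(), (half, 1)), fm.values, np.tile(padding_row(), (half, 1))])
    if L == 0:
        return np.zeros((0, window, N_FEATURES))
    idx = np.arange(L)[:, None] + np.arange(window)[None, :]
    return padded[idx]


def encode_observations(seq: str) -> ObservationSequence:
    """Map residues to integers 0-19 (alphabetical over the standard codes)."""
    idx = np.empty(len(seq), dtype=int)
    for i, aa in enumerate(seq):
        j = AA_INDEX.get(aa)
        if j is None:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
        idx[i] = j
    return ObservationSequence(idx)
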