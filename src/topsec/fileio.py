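"""File formats: FASTA, HH-suite ``.hhm`` profiles, label strings, predictions.

All readers/writers round-trip bit-exactly on fixture data.  Coordinates in
TSV output are 1-based inclusive, matching residue-numbering habits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .dataset import LabeledSequence
from .encoding import AMINO_ACIDS
from .metrics import project_labels, tm_segments
from .synthetic import SyntheticDataset

#: raw-profile sentinel for ``*`` entries (probability ~0 after squashing)
HHM_MINUS_INF = -40000.0

__all__ = [
    "read_fasta",
    "read_labels",
    "parse_hhm",
    "write_hhm",
    "PredictionRecord",
    "write_prediction",
    "read_fasta3line",
    "read_fixture_dataset",
    "dssp_reduce",
]

MIN_LENGTH = 30


def read_fasta(path, allow_nonstandard: bool = False, min_length: int = MIN_LENGTH) -> list[tuple[str, str]]:
    """Parse FASTA into (id, uppercase sequence) pairs.

    By default mirrors the usual corpus filters: sequences containing a
    non-standard residue (e.g. ``X``) or shorter than 30 are rejected with
    a clear message; pass ``allow_nonstandard=True`` to keep them.
    """
    path = Path(path)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(f"{path}:{ln}: malformed FASTA (first record line must start with '>')")
                break
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not allow_nonstandard:
            bad = [i + 1 for i, a in enumerate(seq) if a not in AMINO_ACIDS]
            if bad:
                raise ValueError(
                    f"{rec.id}: non-standard residue {seq[bad[0] - 1]!r} at position {bad[0]} "
                    "(use allow_nonstandard to keep such records)"
                )
            if len(seq) < min_length:
                raise ValueError(f"{rec.id}: length {len(seq)} < {min_length} (use allow_nonstandard to keep)")
        out.append((rec.id, seq))
    return out


def read_labels(path) -> str:
    """Single-line label string over {M,H,C,E}."""
    text = Path(path).read_text().strip()
    bad = set(text) - set("MHCE")
    if bad:
        raise ValueError(f"{path}: unexpected label characters {sorted(bad)}")
    return text


# ---------------------------------------------------------------------------
# HH-suite .hhm profiles (30 columns per residue)
# ---------------------------------------------------------------------------


def write_hhm(path, name: str, seq: str, profile: np.ndarray) -> None:
    """Write a 30-column profile in the HH-suite v3 text layout.

    Per match state: one line with the residue, position and 20 emission
    values, one line with the 10 transition/diversity values; ``*`` encodes
    an absent (minus-infinity) entry.
    """
    profile = np.asarray(profile)
    if profile.shape != (len(seq), 30):
        raise ValueError(f"profile shape {profile.shape} != ({len(seq)}, 30)")

    def cell(v):
        return "*" if v <= HHM_MINUS_INF else str(int(round(v)))

    with open(path, "w") as fh:
        fh.write("HHsearch 1.5\n")
        fh.write(f"NAME  {name}\n")
        fh.write(f"LENG  {len(seq)} match states\n")
        fh.write("#\n")
        fh.write("HMM    " + "\t".join(AMINO_ACIDS) + "\n")
        fh.write("       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D\n")
        for i, aa in enumerate(seq):
            fh.write(f"{aa} {i + 1} " + "\t".join(cell(v) for v in profile[i, :20]) + "\n")
            fh.write("       " + "\t".join(cell(v) for v in profile[i, 20:]) + "\n")
        fh.write("//\n")


def parse_hhm(path) -> tuple[np.ndarray, str]:
    """Parse a ``.hhm`` file into (raw 30-column matrix, embedded sequence).

    ``*`` entries map to a large-negative sentinel that the profile
    squashing sends to ~0.  The returned sequence lets callers cross-check
    the profile against the FASTA record it is supposed to describe.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("HMM"))
    except StopIteration:
        raise ValueError(f"{path}: no HMM block found") from None
    declared = None
    for l in lines:
        if l.startswith("LENG"):
            declared = int(l.split()[1])
            break
    rows, seq = [], []
    i = start + 2  # skip the two HMM header lines

    def val(tok):
        return HHM_MINUS_INF if tok == "*" else float(tok)

    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("//"):
            break
        if not line:
            i += 1
            continue
        parts = lines[i].split()
        if len(parts) != 22:
            raise ValueError(f"{path}: expected 'res pos + 20 values' on line {i + 1}, got {len(parts)} fields")
        if i + 1 >= len(lines):
            raise ValueError(f"{path}: truncated file (missing transition line after line {i + 1})")
        trans = lines[i + 1].split()
        if len(trans) != 10:
            raise ValueError(f"{path}: expected 10 transition values on line {i + 2}, got {len(trans)}")
        seq.append(parts[0])
        rows.append([val(tok) for tok in parts[2:]] + [val(tok) for tok in trans])
        i += 2
    else:
        raise ValueError(f"{path}: truncated file (no terminating '//')")
    if declared is not None and declared != len(rows):
        raise ValueError(f"{path}: header declares {declared} match states, found {len(rows)}")
    return np.array(rows), "".join(seq)


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------


@dataclass
class PredictionRecord:
    id: str
    sequence: str
    q4: str
    scores: np.ndarray | None = None  # (L, 4) per-class scores, column order MHCE

    def __post_init__(self) -> None:
        if len(self.q4) != len(self.sequence):
            raise ValueError(f"{self.id}: label/sequence length mismatch")

    @property
    def q3(self) -> str:
        return project_labels(self.q4, "Q3")

    @property
    def q2(self) -> str:
        return project_labels(self.q4, "Q2")

    @property
    def tm_segment_count(self) -> int:
        return tm_segments(self.q4)


def write_prediction(records: list[PredictionRecord], path, format: str = "tsv") -> None:
    """``fasta3line``: header / sequence / Q4 labels. ``tsv``: one row per residue."""
    if format == "fasta3line":
        with open(path, "w") as fh:
            for r in records:
                fh.write(f">{r.id}\n{r.sequence}\n{r.q4}\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        cols = ["id", "pos", "residue", "q4", "q3", "q2"]
        has_scores = any(r.scores is not None for r in records)
        if has_scores:
            cols += [f"score_{c}" for c in "MHCE"]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            q3, q2 = r.q3, r.q2
            for i, aa in enumerate(r.sequence):
                row = [r.id, str(i + 1), aa, r.q4[i], q3[i], q2[i]]
                if has_scores:
                    row += (
                        [f"{v:.6g}" for v in r.scores[i]] if r.scores is not None else ["", "", "", ""]
                    )
                fh.write("\t".join(row) + "\n")


def read_fasta3line(path) -> list[tuple[str, str, str]]:
    """Read (id, sequence, Q4 labels) triples written by ``fasta3line``."""
    lines = [l.rstrip("\n") for l in Path(path).read_text().splitlines()]
    lines = [l for l in lines if l]
    out = []
    for i in range(0, len(lines), 3):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected header at record {i // 3 + 1}")
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record {lines[i]}")
        out.append((lines[i][1:].split()[0], lines[i + 1], lines[i + 2]))
    return out


# ---------------------------------------------------------------------------
# Fixture datasets (as written by synthetic.write_fixtures)
# ---------------------------------------------------------------------------


def read_fixture_dataset(directory) -> SyntheticDataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    seqs = dict(read_fasta(directory / manifest["fasta"]))
    split_of = {rid: tag for tag, ids in manifest["splits"].items() for rid in ids}
    records = []
    for rid in seqs:
        labels = read_labels(directory / "labels" / f"{rid}.labels")
        profile = None
        hhm = directory / "profiles" / f"{rid}.hhm"
        if hhm.exists():
            profile, pseq = parse_hhm(hhm)
            if pseq != seqs[rid]:
                raise ValueError(f"{rid}: profile sequence disagrees with FASTA")
        records.append(
            LabeledSequence(id=rid, sequence=seqs[rid], labels=labels, profile=profile, split=split_of.get(rid))
        )
    return SyntheticDataset(records=records, seed=manifest.get("seed", 0))


# ---------------------------------------------------------------------------
# Real-data label derivation helper
# ---------------------------------------------------------------------------

_DSSP_3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def dssp_reduce(eight_state: str, tm_mask: str | None = None) -> str:
    """Reduce 8-state DSSP secondary structure to the 4-class alphabet.

    Standard 8-to-3 reduction (H/G/I -> helix, E/B -> strand, rest ->
    coil); residues flagged transmembrane in ``tm_mask`` ('1' characters)
    override to class M, mirroring the convention that the membrane
    annotation takes precedence over DSSP.
    """
    if tm_mask is not None and len(tm_mask) != len(eight_state):
        raise ValueError("tm_mask length mismatch")
    out = []
    for i, s in enumerate(eight_state):
        if tm_mask is not None and tm_mask[i] == "1":
            out.append("M")
        else:
            out.append(_DSSP_3.get(s.upper(), "C"))
    return "".join(out)
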