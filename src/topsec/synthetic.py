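"""Ground-truth-known synthetic corpora for every stage of the pipeline.

A generative class-HMM (known transition matrix ``theta*`` and per-class
residue distributions) stands in for a real membrane-protein corpus: it
produces residue strings, matching 4-class label paths, and pseudo-profiles
that carry label signal the way evolutionary profiles do.  Because the
truth is known, dynamic programs can be checked against enumeration,
transition fitting against ``theta*``, and end-to-end training against the
Bayes-ish accuracy implied by the class-distribution separation.

The default residue distributions mimic membrane biology loosely: the
transmembrane class M is enriched in hydrophobic residues, non-membrane
helix H in charged/polar ones, strand E and coil C in their usual residue
preferences; a ``separation`` knob interpolates between these and the
uniform distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import LabeledSequence
from .encoding import AMINO_ACIDS, PROFILE_SCALE
from .state_model import StateTopology, TransitionModel, build_default_topology, states_to_labels

__all__ = [
    "GenerativeModel",
    "SyntheticDataset",
    "default_generative_model",
    "simulate_dataset",
    "synthesize_profiles",
    "write_fixtures",
    "class_separation_jsd",
]

# residue-index sets enriched per class (alphabet ACDEFGHIKLMNPQRSTVWY)
_CLASS_SETS = {
    "M": [AMINO_ACIDS.index(a) for a in "AFILMVWY"],  # hydrophobic core
    "H": [AMINO_ACIDS.index(a) for a in "DEKNQR"],  # charged / polar helix
    "E": [AMINO_ACIDS.index(a) for a in "CGHST"],
    "C": [AMINO_ACIDS.index(a) for a in "DGNPS"],  # turn/coil formers
}


@dataclass
class GenerativeModel:
    topology: StateTopology
    theta_star: TransitionModel
    class_dists: dict[str, np.ndarray]  # label -> 20-vector over residues
    profile_noise: float = 300.0  # sd of the raw-profile noise, sigmoid-scale units
    seed: int = 0

    def __post_init__(self) -> None:
        for lab, d in self.class_dists.items():
            d = np.asarray(d, dtype=float)
            if abs(d.sum() - 1.0) > 1e-9:
                raise ValueError(f"class {lab!r} distribution not normalized")
            self.class_dists[lab] = d


@dataclass
class SyntheticDataset:
    records: list[LabeledSequence]
    seed: int = 0

    def split(self, tag: str) -> list[LabeledSequence]:
        return [r for r in self.records if r.split == tag]

    def __len__(self) -> int:
        return len(self.records)


def _class_distributions(separation: float) -> dict[str, np.ndarray]:
    dists = {}
    for lab, idx in _CLASS_SETS.items():
        d = np.full(20, (1.0 - separation) / 20.0)
        d[idx] += separation / len(idx)
        dists[lab] = d / d.sum()
    return dists


def class_separation_jsd(class_dists: dict[str, np.ndarray]) -> float:
    """Minimum pairwise Jensen-Shannon divergence (base 2) between classes."""
    labs = sorted(class_dists)
    best = np.inf
    for i, a in enumerate(labs):
        for b in labs[i + 1 :]:
            p, q = class_dists[a], class_dists[b]
            m = (p + q) / 2
            kl = lambda x, y: float(np.sum(np.where(x > 0, x * np.log2(np.where(x > 0, x / y, 1.0)), 0.0)))
            best = min(best, 0.5 * kl(p, m) + 0.5 * kl(q, m))
    return best


def default_generative_model(seed: int = 0, separation: float = 0.8, profile_noise: float = 300.0) -> GenerativeModel:
    """Sticky-segment transition truth + moderately separated class alphabets.

    Interior and coil self-transitions are 0.9 (geometric mean run length 10,
    so segments average >= 5 residues); ``separation`` is the probability
    mass concentrated on each class's enriched residue set.
    """
    t = build_default_topology()
    theta = np.zeros((12, 12))
    n = {s.name: s.id for s in t.states}
    theta[n["Begin"], [n["M.begin"], n["H.begin"], n["E.begin"], n["C"]]] = [0.35, 0.20, 0.10, 0.35]
    for cls, exits in {
        "M": {"H.begin": 0.10, "E.begin": 0.05, "C": 0.80, "End": 0.05},
        "H": {"M.begin": 0.25, "E.begin": 0.10, "C": 0.60, "End": 0.05},
        "E": {"M.begin": 0.10, "H.begin": 0.10, "C": 0.75, "End": 0.05},
    }.items():
        theta[n[f"{cls}.begin"], n[f"{cls}.interior"]] = 1.0
        theta[n[f"{cls}.interior"], [n[f"{cls}.interior"], n[f"{cls}.end"]]] = [0.9, 0.1]
        for dst, p in exits.items():
            theta[n[f"{cls}.end"], n[dst]] = p
    for dst, p in {"C": 0.90, "M.begin": 0.04, "H.begin": 0.03, "E.begin": 0.02, "End": 0.01}.items():
        theta[n["C"], n[dst]] = p
    tm = TransitionModel.from_theta(theta, t)
    return GenerativeModel(
        topology=t,
        theta_star=tm,
        class_dists=_class_distributions(separation),
        profile_noise=profile_noise,
        seed=seed,
    )


def _conditioned_path(rng: np.random.Generator, gm: GenerativeModel, length: int) -> list[int]:
    """Sample a Begin->...->End state path of exactly ``length`` emitting steps.

    Uses backward survival weights b_t(k) = P(End reached after exactly the
    remaining steps | state k), then walks forward with transitions
    re-weighted by them — an exact draw from the path distribution
    conditioned on the total length, with no rejection.
    """
    t, theta = gm.topology, gm.theta_star.theta
    em = t.emitting_ids
    A = theta[np.ix_(em, em)]
    a0 = theta[t.begin_id, em]
    w = theta[em, t.end_id]
    K = em.shape[0]
    b = np.empty((length, K))
    b[-1] = w
    for i in range(length - 2, -1, -1):
        b[i] = A @ b[i + 1]
        s = b[i].sum()
        if s <= 0:
            raise ValueError(f"no path of length {length} exists in this topology")
        b[i] /= s
    p0 = a0 * b[0]
    if p0.sum() <= 0:
        raise ValueError(f"no path of length {length} starts from Begin")
    path = [int(rng.choice(K, p=p0 / p0.sum()))]
    for i in range(1, length):
        p = A[path[-1]] * b[i]
        path.append(int(rng.choice(K, p=p / p.sum())))
    return [int(em[k]) for k in path]


def simulate_dataset(
    gm: GenerativeModel,
    n_sequences: int,
    length_range: tuple[int, int] = (60, 200),
    seed: int = 0,
    with_profiles: bool = False,
) -> SyntheticDataset:
    """Sample labeled sequences from the generative model; 80/10/10 split.

    Each record's length is drawn uniformly from ``length_range`` (min 30,
    mirroring the usual short-chain filter), its state path is sampled
    conditioned on that length, residues come from the class distribution
    of each state, and labels are the path's class projection.
    """
    lo, hi = length_range
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    if lo < 30 or hi < lo:
        raise ValueError(f"length range must satisfy 30 <= lo <= hi, got {length_range}")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_sequences):
        L = int(rng.integers(lo, hi + 1))
        path = _conditioned_path(rng, gm, L)
        labels = states_to_labels(path, gm.topology)
        seq = "".join(
            AMINO_ACIDS[rng.choice(20, p=gm.class_dists[lab])] for lab in labels
        )
        rec = LabeledSequence(id=f"syn{i + 1:04d}", sequence=seq, labels=labels)
        if with_profiles:
            rec.profile = synthesize_profiles(seq, gm, seed=int(seed) * 100003 + i, labels=labels)
        records.append(rec)
    order = rng.permutation(n_sequences)
    n_train = int(round(0.8 * n_sequences))
    n_valid = int(round(0.1 * n_sequences))
    for rank, j in enumerate(order):
        records[j].split = "train" if rank < n_train else ("valid" if rank < n_train + n_valid else "test")
    return SyntheticDataset(records=records, seed=seed)


def synthesize_profiles(seq: str, gm: GenerativeModel, seed: int = 0, labels: str | None = None) -> np.ndarray:
    """Pseudo-evolutionary profile: raw 30-column matrix of integers.

    The first 20 columns are log-odds of a residue/class mixture on the raw
    sigmoid scale (so squashing recovers probabilities in (0, 1)), plus
    Gaussian noise of sd ``gm.profile_noise``; the last 10 columns are pure
    noise.  With noise 0 the row is a deterministic function of the
    (residue, label) pair.
    """
    rng = np.random.default_rng(seed)
    L = len(seq)
    out = np.empty((L, 30))
    for i, aa in enumerate(seq):
        point = np.full(20, 0.1 / 19)
        point[AMINO_ACIDS.index(aa)] = 0.9
        if labels is not None:
            p = 0.6 * gm.class_dists[labels[i]] + 0.4 * point
        else:
            p = point
        p = np.clip(p, 1e-6, 1 - 1e-6)
        out[i, :20] = PROFILE_SCALE * np.log(p / (1 - p))
        out[i, 20:] = 0.0
    if gm.profile_noise > 0:
        out += rng.normal(0.0, gm.profile_noise, size=out.shape)
    return np.rint(out)


def write_fixtures(ds: SyntheticDataset, directory) -> dict:
    """Write FASTA + per-record label/profile files + a JSON manifest.

    Round-trips bit-exactly through :mod:`topsec.fileio` readers.
    """
    from . import fileio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "sequences.fasta"
    with open(fasta, "w") as fh:
        for r in ds.records:
            fh.write(f">{r.id}\n{r.sequence}\n")
    labels_dir = directory / "labels"
    labels_dir.mkdir(exist_ok=True)
    profile_dir = directory / "profiles"
    for r in ds.records:
        (labels_dir / f"{r.id}.labels").write_text(r.labels + "\n")
        if r.profile is not None:
            profile_dir.mkdir(exist_ok=True)
            fileio.write_hhm(profile_dir / f"{r.id}.hhm", r.id, r.sequence, r.profile)
    with open(directory / "reference.fa3", "w") as fh:
        for r in ds.records:
            fh.write(f">{r.id}\n{r.sequence}\n{r.labels}\n")
    manifest = {
        "seed": ds.seed,
        "n_records": len(ds.records),
        "splits": {tag: [r.id for r in ds.split(tag)] for tag in ("train", "valid", "test")},
        "fasta": fasta.name,
        "have_profiles": any(r.profile is not None for r in ds.records),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
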