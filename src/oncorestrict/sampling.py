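"""Cross-sectional sampling: turn simulated trajectories into genotypes.

Each patient contributes one observed genotype.  Sampling time (S.Time) is
either the end of the simulation (``last``) or uniform between the
appearance of the first mutated driver and the end (``unif``).  Sampling
type (S.Type) is single cell (``singleC``: one clone drawn with probability
proportional to its abundance) or whole tumor (``wholeT``: a gene is called
mutated iff the fraction of cells carrying it is at least the detection
threshold, 0.5 or 0.01).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .graphs import GenomeSpec, RestrictionGraph
from .simulate import ModelParams, Trajectory, simulate_until_cancer

SType = Literal["singleC", "wholeT_0.5", "wholeT_0.01"]
STime = Literal["last", "unif"]

_THRESHOLD = {"wholeT_0.5": 0.5, "wholeT_0.01": 0.01}


@dataclass(frozen=True)
class SampleSpec:
    s_time: STime = "last"
    s_type: SType = "singleC"
    n_subjects: int = 100

    def __post_init__(self) -> None:
        if self.s_time not in ("last", "unif"):
            raise ValueError(f"unknown s_time {self.s_time!r}")
        if self.s_type != "singleC" and self.s_type not in _THRESHOLD:
            raise ValueError(f"unknown s_type {self.s_type!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")

    @property
    def threshold(self) -> float | None:
        return _THRESHOLD.get(self.s_type)


@dataclass
class Dataset:
    """Binary subjects-by-genes matrix with provenance metadata."""

    matrix: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("dataset entries must be 0/1")
        if self.matrix.columns.duplicated().any():
            raise ValueError("gene labels must be unique")

    @property
    def gene_labels(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.matrix)

    def frequencies(self) -> pd.Series:
        return self.matrix.mean(axis=0)

    def to_csv(self, path, metadata_path=None) -> None:
        self.matrix.to_csv(path, index=False)
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                json.dump(self.metadata, fh, indent=1, default=str)

    @classmethod
    def from_csv(cls, path, metadata_path=None) -> "Dataset":
        matrix = pd.read_csv(path)
        meta = {}
        if metadata_path is not None:
            with open(metadata_path) as fh:
                meta = json.load(fh)
        return cls(matrix, meta)


def draw_sample_time(
    traj: Trajectory, s_time: STime, rng: np.random.Generator
) -> float:
    """Sampling time: t_end for 'last', uniform over the disease course
    (first mutated driver to end) for 'unif'."""
    if traj.t_first_driver is None:
        raise ValueError("cannot sample a trajectory with no driver mutation")
    if s_time == "last":
        return traj.t_end
    if s_time == "unif":
        return float(rng.uniform(traj.t_first_driver, traj.t_end))
    raise ValueError(f"unknown s_time {s_time!r}")


def observe_genotype(
    state: Sequence[tuple[frozenset[str], int]],
    s_type: SType,
    genes: Sequence[str],
    rng: np.random.Generator,
    threshold: float | None = None,
) -> np.ndarray:
    """One observed 0/1 genotype row from a clone composition."""
    sizes = np.array([n for _, n in state], dtype=float)
    total = sizes.sum()
    if total <= 0:
        raise ValueError("empty clone composition")
    if s_type == "singleC":
        idx = rng.choice(len(state), p=sizes / total)
        chosen = state[idx][0]
        return np.array([1 if g in chosen else 0 for g in genes], dtype=np.int8)
    thr = _THRESHOLD[s_type] if threshold is None else threshold
    fracs = np.zeros(len(genes))
    for genotype, n in state:
        for i, g in enumerate(genes):
            if g in genotype:
                fracs[i] += n
    fracs /= total
    return (fracs >= thr).astype(np.int8)


def subject_seed(master_seed: int, design_key: str, subject: int) -> np.random.SeedSequence:
    """Reproducible per-subject substream from (master seed, design point,
    subject index)."""
    digest = hashlib.sha256(design_key.encode()).digest()
    tag = int.from_bytes(digest[:4], "little")
    return np.random.SeedSequence(
        entropy=master_seed % (2**31), spawn_key=(tag, subject)
    )


def build_dataset(
    graph: RestrictionGraph,
    genome: GenomeSpec,
    params: ModelParams,
    sample: SampleSpec,
    master_seed: int,
    design_key: str = "",
    engine: str = "bnb",
) -> Dataset:
    """Simulate ``n_subjects`` independent patients and sample one genotype
    from each (cross-sectional design).  Reproducible: each subject draws
    from its own seed substream, so any row can be regenerated alone."""
    genes = list(genome.genes)
    rows = np.empty((sample.n_subjects, len(genes)), dtype=np.int8)
    attempts = []
    key = design_key or f"{graph.name}|{params.model}|{params.sh}|{sample}"
    for i in range(sample.n_subjects):
        rng = np.random.default_rng(subject_seed(master_seed, key, i))
        traj = simulate_until_cancer(graph, genome, params, rng, engine=engine)
        t = draw_sample_time(traj, sample.s_time, rng)
        state = traj.state_at(t)
        rows[i] = observe_genotype(state, sample.s_type, genes, rng)
        attempts.append(traj.metadata.get("attempts", 1))
    matrix = pd.DataFrame(rows, columns=genes)
    meta = {
        "true_graph": graph.name,
        "model": params.model,
        "sh": params.sh,
        "s_time": sample.s_time,
        "s_type": sample.s_type,
        "n_subjects": sample.n_subjects,
        "master_seed": master_seed,
        "design_key": key,
        "mean_attempts": float(np.mean(attempts)),
        "driver_labels": list(genome.driver_labels),
        "passenger_labels": list(genome.passenger_labels),
    }
    return Dataset(matrix, meta)
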