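"""Assembly of labeled peptide benchmarks.

A :class:`LabeledDataset` pairs positive and negative peptide sets with an
80/20 train/validation split and a five-fold partition of the training set.
Negatives come either from random fragments of background proteins (the
easy benchmark) or from a candidate pool by greedy minimum-Euclidean-distance
composition matching (the hard, compositionally-similar benchmark).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import aac
from .peptide_io import Peptide, read_fasta, write_fasta


@dataclass
class LabeledDataset:
    """Positive/negative peptides with split and fold assignments.

    ``split`` maps peptide id -> {"train", "validation"}; ``folds`` maps
    training peptide id -> fold index in 1..5.  Both are empty until
    :func:`split_train_validation` / :func:`assign_five_folds` run.
    """

    positives: list[Peptide]
    negatives: list[Peptide]
    split: dict[str, str] = field(default_factory=dict)
    folds: dict[str, int] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        pos_seqs = {p.sequence for p in self.positives}
        neg_seqs = {p.sequence for p in self.negatives}
        overlap = pos_seqs & neg_seqs
        if overlap:
            raise ValueError(
                f"{len(overlap)} sequence(s) appear in both classes"
            )
        self.positives = [p.with_label("positive") for p in self.positives]
        self.negatives = [p.with_label("negative") for p in self.negatives]

    # -- convenience views ------------------------------------------------
    @property
    def all_peptides(self) -> list[Peptide]:
        return self.positives + self.negatives

    def subset(self, which: str) -> tuple[list[Peptide], list[Peptide]]:
        """(positives, negatives) of the train or validation split."""
        if which not in ("train", "validation"):
            raise ValueError(which)
        pos = [p for p in self.positives if self.split.get(p.id) == which]
        neg = [p for p in self.negatives if self.split.get(p.id) == which]
        return pos, neg


def sample_random_negatives(
    background: Sequence[Peptide],
    positives: Sequence[Peptide],
    n: int,
    seed: int,
    max_retries: int = 1000,
) -> list[Peptide]:
    """Draw ``n`` random fragments from background proteins as negatives.

    Each negative is a contiguous fragment of a uniformly chosen background
    protein; its length is drawn uniformly from the multiset of positive
    lengths, so length carries no class signal.  Fragments identical to any
    positive sequence (or to an already drawn negative) are rejected and
    resampled.

    Raises
    ------
    ValueError
        If ``n`` distinct fragments cannot be found within the retry budget,
        e.g. because every background protein is shorter than the shortest
        positive.
    """
    if n == 0:
        return []
    if not background:
        raise ValueError("empty background")
    rng = np.random.default_rng(seed)
    pos_lengths = np.array([len(p) for p in positives])
    pos_seqs = {p.sequence for p in positives}
    if pos_lengths.min() > max(len(b) for b in background):
        raise ValueError("all background proteins shorter than every positive")

    out: list[Peptide] = []
    drawn: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_retries * n:
            raise ValueError(
                f"could not draw {n} distinct negative fragments "
                f"after {attempts} attempts"
            )
        length = int(rng.choice(pos_lengths))
        prot = background[int(rng.integers(len(background)))]
        if len(prot) < length:
            continue
        start = int(rng.integers(len(prot) - length + 1))
        frag = prot.sequence[start : start + length]
        if frag in pos_seqs or frag in drawn:
            continue
        drawn.add(frag)
        out.append(
            Peptide(id=f"neg_{len(out) + 1}", sequence=frag, label="negative")
        )
    return out


def build_similar_negatives(
    positives: Sequence[Peptide], candidate_pool: Sequence[Peptide]
) -> list[Peptide]:
    """Pick, per positive, the unused pool candidate with minimum AAC distance.

    Greedy nearest-neighbour matching in input order, without replacement;
    ties broken by smallest candidate id.  The result is a hard negative set
    compositionally similar to the positives.
    """
    if len(candidate_pool) < len(positives):
        raise ValueError(
            f"candidate pool ({len(candidate_pool)}) smaller than "
            f"positives ({len(positives)})"
        )
    pos_mat = np.vstack([aac(p).values for p in positives])
    pool_mat = np.vstack([aac(c).values for c in candidate_pool])
    dist = cdist(pos_mat, pool_mat)  # Euclidean

    # stable tie-break: candidates ordered by id within equal distance
    pool_ids = [c.id for c in candidate_pool]
    used = np.zeros(len(candidate_pool), dtype=bool)
    chosen: list[Peptide] = []
    for i in range(len(positives)):
        row = dist[i].copy()
        row[used] = np.inf
        best = np.min(row)
        ties = np.flatnonzero(row == best)
        j = min(ties, key=lambda t: pool_ids[t])
        used[j] = True
        chosen.append(candidate_pool[j].with_label("negative"))
    return chosen


def split_train_validation(
    dataset: LabeledDataset, fraction: float = 0.8, seed: int = 0
) -> LabeledDataset:
    """Random stratified 80/20 split: floor(fraction*n) per class to train."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    split: dict[str, str] = {}
    for group in (dataset.positives, dataset.negatives):
        if len(group) < 2:
            raise ValueError("each class needs at least 2 peptides to split")
        n_train = math.floor(fraction * len(group))
        order = rng.permutation(len(group))
        for rank, idx in enumerate(order):
            split[group[idx].id] = "train" if rank < n_train else "validation"
    return replace(dataset, split=split, seed=seed)


def assign_five_folds(dataset: LabeledDataset, seed: int = 0, n_folds: int = 5) -> LabeledDataset:
    """Partition the training split into near-equal class-stratified folds.

    Fold sizes within a class differ by at most 1; every training peptide
    lands in exactly one fold, so each is held out exactly once across the
    five-fold rotation.
    """
    if not dataset.split:
        raise ValueError("run split_train_validation first")
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    for group in dataset.subset("train"):
        if len(group) < n_folds:
            raise ValueError(
                f"need >= {n_folds} training peptides per class, got {len(group)}"
            )
        order = rng.permutation(len(group))
        for rank, idx in enumerate(order):
            folds[group[idx].id] = (rank % n_folds) + 1
    return replace(dataset, folds=folds)


# -- serialization --------------------------------------------------------

def save_dataset(dataset: LabeledDataset, directory: str | Path) -> None:
    """Write pos/neg x train/validation FASTA files plus a fold table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cls, group in (("pos", dataset.positives), ("neg", dataset.negatives)):
        for which in ("train", "validation"):
            members = [p for p in group if dataset.split.get(p.id) == which]
            write_fasta(members, directory / f"{cls}_{which}.fasta")
    rows = [{"id": pid, "fold": f} for pid, f in sorted(dataset.folds.items())]
    pd.DataFrame(rows, columns=["id", "fold"]).to_csv(
        directory / "folds.tsv", sep="\t", index=False
    )


def load_dataset(directory: str | Path) -> LabeledDataset:
    """Load a dataset written by :func:`save_dataset`, losslessly."""
    directory = Path(directory)
    parts: dict[tuple[str, str], list[Peptide]] = {}
    for cls in ("pos", "neg"):
        for which in ("train", "validation"):
            parts[(cls, which)] = read_fasta(
                directory / f"{cls}_{which}.fasta", amidation_tag="amidated"
            )
    split = {
        p.id: which
        for (cls, which), group in parts.items()
        for p in group
    }
    fold_df = pd.read_csv(directory / "folds.tsv", sep="\t")
    folds = dict(zip(fold_df["id"].astype(str), fold_df["fold"].astype(int)))
    return LabeledDataset(
        positives=parts[("pos", "train")] + parts[("pos", "validation")],
        negatives=parts[("neg", "train")] + parts[("neg", "validation")],
        split=split,
        folds=folds,
    )
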