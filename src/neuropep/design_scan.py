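"""In-silico peptide design and protein scanning.

*Design* enumerates all single-point mutants of a peptide (19 substitutions
per position, the identity substitution excluded) and ranks them by model
score, supporting iterative redesign of more active analogs.

*Protein scan* slides a fixed-length window over a protein at stride 1 and
scores every overlapping subsequence, locating putative neuropeptide
regions.  Coordinates in outputs are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import TrainedModel, classify_at_threshold, predict_scores
from .features import encode_dataset
from .peptide_io import AMINO_ACIDS, Peptide

#: Default scan window length (mid-range of the terminus window sizes 5-15).
DEFAULT_WINDOW = 15


def single_mutants(peptide: Peptide) -> list[Peptide]:
    """All 19*L single-point mutants, ids encoding the substitution.

    A mutant id like ``p1_A3K`` means: in peptide ``p1``, the alanine at
    position 3 (1-based) is replaced by lysine.  The original peptide is not
    included; every mutant differs from it at exactly one position.
    """
    seq = peptide.sequence
    mutants: list[Peptide] = []
    for pos, original in enumerate(seq):
        for aa in AMINO_ACIDS:
            if aa == original:
                continue
            mutants.append(
                Peptide(
                    id=f"{peptide.id}_{original}{pos + 1}{aa}",
                    sequence=seq[:pos] + aa + seq[pos + 1 :],
                    c_term_amidated=peptide.c_term_amidated,
                )
            )
    return mutants


def rank_mutants(
    peptide: Peptide, model: TrainedModel, threshold: float = 0.0
) -> pd.DataFrame:
    """Score the original peptide and all single mutants; sort by score desc.

    Columns: id, sequence, mutation, score, class (``neuropeptide`` /
    ``non-neuropeptide`` at the given threshold).  Row count is 19*L + 1.
    """
    mutants = single_mutants(peptide)
    everything = [peptide] + mutants
    matrix, kept, skipped = encode_dataset(everything, model.feature_scheme)
    if skipped:
        raise ValueError(
            f"feature scheme {model.feature_scheme!r} cannot encode: "
            + ", ".join(pid for pid, _ in skipped)
        )
    scores = predict_scores(model, matrix)
    classes = classify_at_threshold(scores, threshold)
    table = pd.DataFrame(
        {
            "id": [p.id for p in kept],
            "sequence": [p.sequence for p in kept],
            "mutation": ["original"] + [p.id.rsplit("_", 1)[-1] for p in kept[1:]],
            "score": scores,
            "class": np.where(classes == 1, "neuropeptide", "non-neuropeptide"),
        }
    )
    return table.sort_values("score", ascending=False, kind="stable").reset_index(
        drop=True
    )


def scan_protein(
    protein: Peptide,
    model: TrainedModel,
    window: int = DEFAULT_WINDOW,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Score every overlapping window of a protein at stride 1.

    Returns the L - w + 1 windows in positional order with 1-based inclusive
    ``start``/``end`` coordinates, model score, class at the threshold, and a
    ``rank`` column (1 = highest score).
    """
    L = len(protein)
    if window > L:
        raise ValueError(f"window {window} exceeds protein length {L}")
    if window < 1:
        raise ValueError("window must be >= 1")
    windows = [
        Peptide(
            id=f"{protein.id}_{i + 1}_{i + window}",
            sequence=protein.sequence[i : i + window],
        )
        for i in range(L - window + 1)
    ]
    matrix, kept, skipped = encode_dataset(windows, model.feature_scheme)
    if skipped:
        raise ValueError(
            f"scheme {model.feature_scheme!r} cannot encode window length {window}"
        )
    scores = predict_scores(model, matrix)
    classes = classify_at_threshold(scores, threshold)
    table = pd.DataFrame(
        {
            "start": np.arange(1, L - window + 2),
            "end": np.arange(window, L + 1),
            "subsequence": [w.sequence for w in kept],
            "score": scores,
            "class": np.where(classes == 1, "neuropeptide", "non-neuropeptide"),
        }
    )
    table["rank"] = (
        table["score"].rank(ascending=False, method="first").astype(int)
    )
    return table
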