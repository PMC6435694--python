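"""Compositional and positional characterization of peptide sets, plus
exclusive-motif discovery.

All summaries are unweighted over peptides (each peptide contributes its own
percent composition regardless of length), matching the convention of
per-residue "percent average composition" comparisons between positive and
negative sets.  Analyses are intended to run on deduplicated sets so that
repeated sequences cannot inflate a residue or motif preference.

The motif miner is a transparent exact-substring enumerator with an explicit
minimum support — a simplification of pattern-mining tools like MERCI, whose
physicochemical alphabets and gapped classes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .features import aac
from .peptide_io import AMINO_ACIDS, Peptide


@dataclass(frozen=True)
class Motif:
    """A contiguous residue pattern exclusive to the positive set."""

    pattern: str
    positive_support: int
    negative_support: int = 0


def mean_composition(peptides: Sequence[Peptide]) -> pd.Series:
    """Unweighted mean of per-peptide AAC, as percent per residue."""
    if not peptides:
        raise ValueError("empty peptide set")
    mat = np.vstack([aac(p).values for p in peptides])
    return pd.Series(mat.mean(axis=0), index=list(AMINO_ACIDS))


def composition_difference(
    set_a: Sequence[Peptide], set_b: Sequence[Peptide]
) -> pd.Series:
    """Per-residue mean-composition difference a - b (percent points)."""
    return mean_composition(set_a) - mean_composition(set_b)


def positional_composition(
    peptides: Sequence[Peptide],
    end: Literal["N", "C"] = "N",
    n_positions: int = 5,
) -> pd.DataFrame:
    """Percent residue usage at the first ``n_positions`` from one terminus.

    Entry (p, r) is the percent of peptides whose p-th residue from the given
    terminus is r; C-terminal position 1 is the last residue.  Peptides
    shorter than ``n_positions`` are skipped.  Each row sums to 100.
    """
    usable = [p for p in peptides if len(p) >= n_positions]
    if not usable:
        raise ValueError(f"no peptides of length >= {n_positions}")
    counts = np.zeros((n_positions, 20))
    aa_idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for p in usable:
        for pos in range(n_positions):
            ch = p.sequence[pos] if end == "N" else p.sequence[-(pos + 1)]
            counts[pos, aa_idx[ch]] += 1
    return pd.DataFrame(
        100.0 * counts / len(usable),
        index=[f"{end}{i + 1}" for i in range(n_positions)],
        columns=list(AMINO_ACIDS),
    )


def positional_preference(
    pos_set: Sequence[Peptide],
    neg_set: Sequence[Peptide],
    end: Literal["N", "C"] = "N",
    n_positions: int = 5,
) -> pd.DataFrame:
    """Positional composition difference positives - negatives (rows sum to 0).

    The row-wise argmax gives the most over-represented residue per position.
    """
    return positional_composition(pos_set, end, n_positions) - positional_composition(
        neg_set, end, n_positions
    )


def preferred_residues(preference: pd.DataFrame) -> list[str]:
    """Top (most positively enriched) residue for each terminus position."""
    return [str(preference.loc[row].idxmax()) for row in preference.index]


def find_exclusive_motifs(
    pos_set: Sequence[Peptide],
    neg_set: Sequence[Peptide],
    min_len: int = 3,
    max_len: int = 6,
    min_support: int = 3,
) -> list[Motif]:
    """Contiguous substrings present in >= ``min_support`` positives and no negative.

    Support counts peptides containing at least one occurrence, not total
    occurrences.  Results are sorted by support (desc), length (desc), then
    lexicographically; a motif wholly contained in a returned longer motif
    with identical support is suppressed (maximality filter).
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    if not pos_set or not neg_set:
        raise ValueError("both sets must be non-empty")

    def substrings(seq: str) -> set[str]:
        return {
            seq[i : i + L]
            for L in range(min_len, max_len + 1)
            for i in range(len(seq) - L + 1)
        }

    support: dict[str, int] = {}
    for p in pos_set:
        for s in substrings(p.sequence):
            support[s] = support.get(s, 0) + 1

    candidates = {s: c for s, c in support.items() if c >= min_support}
    if candidates:
        for n in neg_set:
            neg_subs = substrings(n.sequence)
            for s in neg_subs & candidates.keys():
                del candidates[s]
            if not candidates:
                break

    ordered = sorted(
        candidates.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0])
    )
    kept: list[Motif] = []
    for pattern, cnt in ordered:
        redundant = any(
            pattern in m.pattern and cnt == m.positive_support
            and len(pattern) < len(m.pattern)
            for m in kept
        )
        if not redundant:
            kept.append(Motif(pattern=pattern, positive_support=cnt))
    return kept


def motif_table(motifs: Sequence[Motif]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": m.pattern,
                "positive_support": m.positive_support,
                "negative_support": m.negative_support,
            }
            for m in motifs
        ],
        columns=["motif", "positive_support", "negative_support"],
    )
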