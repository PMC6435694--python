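"""Synthetic peptide benchmarks with controllable class signal.

The generator emulates the statistical structure that separates insect
neuropeptides from background peptides:

* enrichment of the residues C, D, E, F, G, N, S and Y in positives;
* per-position residue preferences at the first five N- and C-terminal
  positions (e.g. A/N favoured at N-terminal position 1, L at C-terminal
  position 1);
* optional short planted motifs (e.g. ``ECC``, ``GPR``) inserted into a
  fraction of positives and, by construction, absent from negatives.

All biases scale with a single ``effect_size``; at ``effect_size = 0`` the
positive and negative distributions are identical (exchangeable), which is
the null benchmark used for calibration.  Every generator takes an explicit
seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import (
    LabeledDataset,
    assign_five_folds,
    build_similar_negatives,
    split_train_validation,
)
from .peptide_io import AMINO_ACIDS, Peptide, deduplicate

#: Residues enriched in natural insect neuropeptides.
DEFAULT_FAVORED = ("C", "D", "E", "F", "G", "N", "S", "Y")

#: Effect size of the strongly separable benchmark (a DS2-like regime where
#: composition models reach ~97% accuracy); the default 1.0 is the moderate,
#: DS1-like regime (~90%).
STRONG_EFFECT = 2.0

#: Per-position preferred residues, N-terminal positions 1-5.
DEFAULT_N_TERM_PREF: dict[int, dict[str, float]] = {
    1: {"A": 0.15, "N": 0.15},
    2: {"F": 0.25},
    3: {"D": 0.25},
    4: {"S": 0.25},
    5: {"I": 0.25},
}

#: Per-position preferred residues, C-terminal positions 1-5 (1 = last residue).
DEFAULT_C_TERM_PREF: dict[int, dict[str, float]] = {
    1: {"L": 0.25},
    2: {"F": 0.25},
    3: {"N": 0.25},
    4: {"G": 0.25},
    5: {"L": 0.25},
}


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of the positive-class signal.

    ``enrichment`` is the sampling-weight multiplier of each favoured
    residue relative to the 12 others; positional biases are probabilities
    of overriding a terminus position with its preferred residue; motif
    insertion probabilities are per peptide.  ``effect_size`` scales all
    three kinds of bias; 0 collapses positives onto the background.
    """

    favored_residues: tuple[str, ...] = DEFAULT_FAVORED
    enrichment: float = 2.5
    n_term_pref: dict = field(default_factory=lambda: dict(DEFAULT_N_TERM_PREF))
    c_term_pref: dict = field(default_factory=lambda: dict(DEFAULT_C_TERM_PREF))
    planted_motifs: tuple[tuple[str, float], ...] = ()
    length_range: tuple[int, int] = (5, 80)
    effect_size: float = 1.0
    c_term_amidated: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")
        if not 0 <= self.effect_size:
            raise ValueError("effect_size must be >= 0")
        for _, prob in self.planted_motifs:
            if not 0 <= prob <= 1:
                raise ValueError("motif insertion probability must be in [0,1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("bad length_range")


def _draw_length(rng: np.random.Generator, length_range: tuple[int, int]) -> int:
    lo, hi = length_range
    return int(rng.integers(lo, hi + 1))


def generate_background_peptides(
    n: int,
    length_range: tuple[int, int] = (5, 80),
    seed: int = 0,
    id_prefix: str = "bg",
) -> list[Peptide]:
    """i.i.d.-uniform random peptides, lengths uniform over the range."""
    rng = np.random.default_rng(seed)
    out = []
    letters = np.array(list(AMINO_ACIDS))
    for i in range(n):
        L = _draw_length(rng, length_range)
        seq = "".join(rng.choice(letters, size=L))
        out.append(Peptide(id=f"{id_prefix}_{i + 1}", sequence=seq))
    return out


def _residue_weights(spec: SignalSpec) -> np.ndarray:
    # effect_size interpolates each favoured residue's weight between 1 and
    # the full enrichment factor
    weights = np.ones(20)
    for r in spec.favored_residues:
        weights[AMINO_ACIDS.index(r)] = 1.0 + spec.effect_size * (spec.enrichment - 1.0)
    return weights / weights.sum()


def _apply_positional_bias(
    seq: list[str],
    prefs: dict[int, dict[str, float]],
    from_c: bool,
    effect: float,
    rng: np.random.Generator,
) -> None:
    L = len(seq)
    for pos, residue_bias in prefs.items():
        if pos > L:
            continue
        idx = L - pos if from_c else pos - 1
        residues = list(residue_bias)
        probs = np.array([residue_bias[r] for r in residues]) * effect
        total = probs.sum()
        if total <= 0:
            continue
        u = rng.random()
        if u < min(total, 1.0):
            # choose among the preferred residues proportionally to their bias
            pick = rng.choice(len(residues), p=probs / total)
            seq[idx] = residues[pick]


def generate_signal_peptides(
    n: int, spec: SignalSpec, id_prefix: str = "pos"
) -> list[Peptide]:
    """Positive-class peptides under a :class:`SignalSpec`.

    Residues are drawn i.i.d. from the enriched composition, then the first
    five positions from each terminus are stochastically overridden by their
    preferred residues, then each planted motif is inserted (overwriting a
    random window) with its stated probability.
    """
    rng = np.random.default_rng(spec.seed)
    weights = _residue_weights(spec)
    letters = np.array(list(AMINO_ACIDS))
    out = []
    for i in range(n):
        L = _draw_length(rng, spec.length_range)
        seq = list(rng.choice(letters, size=L, p=weights))
        _apply_positional_bias(seq, spec.n_term_pref, False, spec.effect_size, rng)
        _apply_positional_bias(seq, spec.c_term_pref, True, spec.effect_size, rng)
        for motif, prob in spec.planted_motifs:
            if len(motif) <= L and rng.random() < prob * spec.effect_size:
                start = int(rng.integers(L - len(motif) + 1))
                seq[start : start + len(motif)] = list(motif)
        out.append(
            Peptide(
                id=f"{id_prefix}_{i + 1}",
                sequence="".join(seq),
                c_term_amidated=spec.c_term_amidated,
            )
        )
    return out


def _motif_free_background(
    n: int,
    spec: SignalSpec,
    seed: int,
    id_prefix: str,
    forbidden: Optional[set[str]] = None,
) -> list[Peptide]:
    """Background peptides containing no planted motif and no forbidden sequence.

    Resampling keeps planted motifs exclusive to the positive set, which the
    motif-recovery analyses rely on.
    """
    motifs = [m for m, _ in spec.planted_motifs]
    forbidden = forbidden or set()
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    out: list[Peptide] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * max(n, 1):
            raise ValueError("could not generate enough motif-free negatives")
        L = _draw_length(rng, spec.length_range)
        seq = "".join(rng.choice(letters, size=L))
        if any(m in seq for m in motifs) or seq in forbidden:
            continue
        out.append(
            Peptide(
                id=f"{id_prefix}_{len(out) + 1}",
                sequence=seq,
                c_term_amidated=spec.c_term_amidated,
            )
        )
    return out


def generate_benchmark(
    n_pos: int,
    n_neg: int,
    spec: SignalSpec,
    hard_negatives: bool = False,
    seed: int = 0,
    pool_factor: int = 5,
) -> LabeledDataset:
    """A full labeled benchmark: generate, deduplicate, split 80/20, fold 5x.

    Negatives are uniform-background peptides; with ``hard_negatives`` they
    are instead selected from an oversampled background pool (``pool_factor``
    times larger) by greedy minimum-AAC-Euclidean-distance matching to the
    positives, which makes the two classes compositionally similar.
    """
    rng = np.random.default_rng(seed)
    pos_seed, neg_seed, split_seed, fold_seed = (
        int(rng.integers(2**31)) for _ in range(4)
    )
    positives = deduplicate(
        generate_signal_peptides(n_pos, SignalSpec(**{**spec.__dict__, "seed": pos_seed}))
    )
    pos_seqs = {p.sequence for p in positives}
    if hard_negatives:
        if n_neg > n_pos:
            raise ValueError("hard_negatives needs n_neg <= n_pos")
        pool = _motif_free_background(
            pool_factor * n_neg, spec, neg_seed, "pool", forbidden=pos_seqs
        )
        negatives = build_similar_negatives(positives[:n_neg], pool)
    else:
        negatives = _motif_free_background(
            n_neg, spec, neg_seed, "neg", forbidden=pos_seqs
        )
    negatives = deduplicate(negatives)
    ds = LabeledDataset(positives=positives, negatives=negatives, seed=seed)
    ds = split_train_validation(ds, fraction=0.8, seed=split_seed)
    return assign_five_folds(ds, seed=fold_seed)
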