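"""Fixed-length numeric encodings of peptides.

Four encoder families are provided:

* **AAC** — amino-acid composition: ``Comp(i) = 100 * R_i / N`` for each of
  the 20 residues; a 20-dim percent vector summing to 100.
* **DPC** — dipeptide composition: percent frequency of each ordered residue
  pair over the ``N - 1`` overlapping length-2 windows; 400-dim, sums to 100.
* **Split/terminus composition** — AAC or DPC computed on the first/last *k*
  residues (N5..C15) or the joined ``NkCk`` 2k-mer.
* **Binary profiles** — one-hot encoding of the first/last *k* positions,
  20 bits per position in alphabetical residue order (A -> (1,0,...,0),
  Y -> (0,...,0,1)).

Feature order is strict alphabetical one-letter order everywhere so vectors
are bit-comparable across runs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .peptide_io import AMINO_ACIDS, Peptide

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: The 400 ordered dipeptides AA, AC, ..., YW, YY.
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)
DP_INDEX = {dp: i for i, dp in enumerate(DIPEPTIDES)}


@dataclass(frozen=True)
class FeatureVector:
    """A named, ordered numeric encoding of one peptide under one scheme."""

    scheme: str
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values length mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.labels), name=self.scheme)


def aac(peptide: Peptide) -> FeatureVector:
    """Amino-acid percent composition, 20-dim: ``Comp(i) = 100 * R_i / N``."""
    return _aac_of(peptide.sequence, scheme="aac")


def _aac_of(seq: str, scheme: str) -> FeatureVector:
    if not seq:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = np.zeros(20)
    for ch in seq:
        counts[AA_INDEX[ch]] += 1
    values = 100.0 * counts / len(seq)
    return FeatureVector(scheme=scheme, labels=tuple(AMINO_ACIDS), values=values)


def dpc(peptide: Peptide) -> FeatureVector:
    """Dipeptide percent composition, 400-dim.

    ``fraction(d) = 100 * count(d) / (N - 1)`` over the ``N - 1`` overlapping
    length-2 windows.  Requires length >= 2.
    """
    return _dpc_of(peptide.sequence, scheme="dpc")


def _dpc_of(seq: str, scheme: str) -> FeatureVector:
    if len(seq) < 2:
        raise ValueError("dipeptide composition needs length >= 2")
    counts = np.zeros(400)
    for i in range(len(seq) - 1):
        counts[DP_INDEX[seq[i : i + 2]]] += 1
    values = 100.0 * counts / (len(seq) - 1)
    return FeatureVector(scheme=scheme, labels=DIPEPTIDES, values=values)


def terminus_subsequence(
    peptide: Peptide,
    end: Literal["N", "C"] = "N",
    k: int = 5,
    join: bool = False,
) -> str:
    """Extract the first/last ``k`` residues, or their joined ``NkCk`` 2k-mer.

    The C-terminal subsequence is reported in N->C order (the last ``k``
    residues as written).  ``join=True`` concatenates first-k + last-k; for
    ``k <= L < 2k`` the two windows overlap and the joined string still has
    length 2k.

    Raises
    ------
    ValueError
        If the peptide is shorter than ``k``.
    """
    seq = peptide.sequence
    if len(seq) < k:
        raise ValueError(
            f"{peptide.id}: length {len(seq)} < terminus window k={k}"
        )
    if join:
        return seq[:k] + seq[-k:]
    return seq[:k] if end == "N" else seq[-k:]


def split_composition(
    peptide: Peptide,
    end: Literal["N", "C"] = "N",
    k: int = 5,
    join: bool = False,
    order: Literal["aac", "dpc"] = "aac",
) -> FeatureVector:
    """AAC (20-dim) or DPC (400-dim) of a terminus subsequence.

    The joined NkCk composition is the composition of the joined 2k-mer, not
    a concatenation of two per-terminus vectors.
    """
    sub = terminus_subsequence(peptide, end=end, k=k, join=join)
    tag = f"N{k}C{k}" if join else f"{end}{k}"
    scheme = f"{order}_{tag}"
    if order == "aac":
        return _aac_of(sub, scheme=scheme)
    if order == "dpc":
        return _dpc_of(sub, scheme=scheme)
    raise ValueError(f"unknown composition order {order!r}")


_END_SPEC_RE = re.compile(r"^(?:(N|C)(\d+)|N(\d+)C(\d+))$")


def _parse_end_spec(end_spec: str) -> tuple[str, int, bool]:
    """Parse N5/C10/N10C10-style window specs -> (end, k, join)."""
    m = _END_SPEC_RE.match(end_spec)
    if not m:
        raise ValueError(f"unknown terminus window spec {end_spec!r}")
    if m.group(1):
        return m.group(1), int(m.group(2)), False
    kn, kc = int(m.group(3)), int(m.group(4))
    if kn != kc:
        raise ValueError(f"asymmetric joined window {end_spec!r} not supported")
    return "N", kn, True


def binary_profile(peptide: Peptide, end_spec: str = "N10C10") -> FeatureVector:
    """One-hot profile of terminus positions: 20 bits per encoded position.

    ``end_spec`` is one of N5/N10/N15/C5/C10/C15 (20k dims) or
    N5C5/N10C10/N15C15 (40k dims).  Each 20-block has exactly one 1, at the
    alphabetical index of the residue at that position.
    """
    end, k, join = _parse_end_spec(end_spec)
    sub = terminus_subsequence(peptide, end=end, k=k, join=join)
    values = np.zeros(20 * len(sub))
    labels = []
    for pos, ch in enumerate(sub):
        values[20 * pos + AA_INDEX[ch]] = 1.0
        labels.extend(f"p{pos + 1}_{aa}" for aa in AMINO_ACIDS)
    return FeatureVector(
        scheme=f"binary_{end_spec}", labels=tuple(labels), values=values
    )


# scheme name -> encoder; split/binary schemes are resolved dynamically
_SIMPLE_ENCODERS: dict[str, Callable[[Peptide], FeatureVector]] = {
    "aac": aac,
    "dpc": dpc,
}


def get_encoder(scheme: str) -> Callable[[Peptide], FeatureVector]:
    """Resolve a scheme name (aac, dpc, aac_N5, dpc_N10C10, binary_N10C10...)."""
    if scheme in _SIMPLE_ENCODERS:
        return _SIMPLE_ENCODERS[scheme]
    if scheme.startswith("binary_"):
        end_spec = scheme[len("binary_") :]
        _parse_end_spec(end_spec)  # validate eagerly
        return lambda p: binary_profile(p, end_spec=end_spec)
    for order in ("aac", "dpc"):
        prefix = order + "_"
        if scheme.startswith(prefix):
            end, k, join = _parse_end_spec(scheme[len(prefix) :])
            return lambda p: split_composition(p, end=end, k=k, join=join, order=order)
    raise ValueError(f"unknown feature scheme {scheme!r}")


def encode_dataset(
    peptides: Sequence[Peptide], scheme: str
) -> tuple[pd.DataFrame, list[Peptide], list[tuple[str, str]]]:
    """Encode a peptide list uniformly under one scheme.

    Returns ``(matrix, kept, skipped)``: a DataFrame indexed by peptide id
    whose rows align with ``kept``, and a list of ``(id, reason)`` pairs for
    peptides the scheme cannot encode (too short for the window).  Skipped
    peptides are reported with a warning, never silently dropped.
    """
    encoder = get_encoder(scheme)
    rows, kept, skipped = [], [], []
    labels: tuple[str, ...] | None = None
    for p in peptides:
        try:
            fv = encoder(p)
        except ValueError as exc:
            skipped.append((p.id, str(exc)))
            continue
        if labels is None:
            labels = fv.labels
        rows.append(fv.values)
        kept.append(p)
    if skipped:
        warnings.warn(
            f"scheme {scheme!r}: skipped {len(skipped)} peptide(s) "
            f"(e.g. {skipped[0][1]})"
        )
    matrix = pd.DataFrame(
        np.asarray(rows) if rows else np.empty((0, len(labels or ()))),
        index=[p.id for p in kept],
        columns=list(labels) if labels else [],
    )
    return matrix, kept, skipped


def export_matrix(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a feature matrix as headered delimited text, id column first."""
    matrix.to_csv(path, sep=sep, index_label="id")
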