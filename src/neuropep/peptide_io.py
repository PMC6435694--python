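"""Reading, validating, deduplicating and writing peptide sequences in FASTA.

Peptides are short (typically 5-80 aa) sequences over the 20 natural amino
acids.  Records carrying non-natural residue codes (B, J, O, U, Z, X) are
rejected or skipped depending on the ``strict`` flag.  A token in the FASTA
description line (e.g. ``amidated``) may mark C-terminal amidation, the
post-translational modification that distinguishes modified neuropeptides.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("neuropep")

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 natural amino acids, alphabetical by one-letter code."""

AA_SET = frozenset(AMINO_ACIDS)

#: Degenerate / non-natural one-letter codes that disqualify a peptide.
NON_NATURAL = frozenset("BJOUZX")


class FastaParseError(ValueError):
    """Structurally malformed FASTA input (e.g. sequence before a header)."""


class PeptideValidationError(ValueError):
    """A sequence contains characters outside the 20-letter alphabet."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide or protein sequence.

    Attributes
    ----------
    id : str
        Non-empty identifier, unique within a collection.
    sequence : str
        Uppercase sequence over the 20 natural amino acids.
    c_term_amidated : bool
        Whether the C-terminus carries an amide modification.
    label : str or None
        Optional class label, ``"positive"`` or ``"negative"``.
    """

    id: str
    sequence: str
    c_term_amidated: bool = False
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PeptideValidationError("peptide id must be non-empty")
        if not self.sequence:
            raise PeptideValidationError(f"{self.id}: empty sequence")
        bad = sorted(set(self.sequence) - AA_SET)
        if bad:
            raise PeptideValidationError(
                f"{self.id}: invalid residues {', '.join(bad)} "
                f"(allowed: the 20 natural amino acids)"
            )
        if self.label not in (None, "positive", "negative"):
            raise PeptideValidationError(f"{self.id}: bad label {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: Optional[str]) -> "Peptide":
        return replace(self, label=label)


def _open_maybe(path_or_stream: Union[str, Path, TextIO]) -> TextIO:
    if isinstance(path_or_stream, (str, Path)):
        return open(path_or_stream)
    return path_or_stream


def read_fasta(
    path_or_stream: Union[str, Path, TextIO],
    amidation_tag: Optional[str] = None,
    strict: bool = True,
    label: Optional[str] = None,
) -> list[Peptide]:
    """Read peptides from multi-record FASTA.

    Sequences are uppercased.  If ``amidation_tag`` is given, records whose
    description line contains that token get ``c_term_amidated=True``.
    Records failing validation raise (``strict=True``) or are skipped with a
    warning (``strict=False``) — never silently dropped.  Duplicate ids get a
    numeric suffix, with a warning.

    Raises
    ------
    FastaParseError
        If sequence text precedes the first ``>`` header; the offending line
        number is named.
    PeptideValidationError
        In strict mode, for any record with residues outside the alphabet.
    """
    handle = _open_maybe(path_or_stream)
    text = handle.read()
    if isinstance(path_or_stream, (str, Path)):
        handle.close()

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            break
        raise FastaParseError(
            f"line {lineno}: sequence data before first FASTA header"
        )

    peptides: list[Peptide] = []
    seen_ids: dict[str, int] = {}
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        pid = record.id
        if pid in seen_ids:
            seen_ids[pid] += 1
            new_id = f"{pid}_{seen_ids[pid]}"
            warnings.warn(f"duplicate FASTA id {pid!r} renamed to {new_id!r}")
            pid = new_id
        else:
            seen_ids[pid] = 1
        amidated = bool(
            amidation_tag and amidation_tag in record.description
        )
        try:
            pep = Peptide(
                id=pid,
                sequence=str(record.seq).upper(),
                c_term_amidated=amidated,
                label=label,
            )
        except PeptideValidationError as exc:
            if strict:
                raise
            warnings.warn(f"skipping record {pid!r}: {exc}")
            continue
        peptides.append(pep)
    return peptides


def write_fasta(
    peptides: Iterable[Peptide],
    path_or_stream: Union[str, Path, TextIO],
    amidation_tag: str = "amidated",
) -> None:
    """Write peptides as FASTA; amidated records get the tag in the description."""
    records = []
    for p in peptides:
        desc = amidation_tag if p.c_term_amidated else ""
        records.append(SeqRecord(Seq(p.sequence), id=p.id, description=desc))
    if isinstance(path_or_stream, (str, Path)):
        with open(path_or_stream, "w") as fh:
            SeqIO.write(records, fh, "fasta-2line")
    else:
        SeqIO.write(records, path_or_stream, "fasta-2line")


def deduplicate(peptides: list[Peptide]) -> list[Peptide]:
    """Drop exact duplicate sequences, keeping first occurrences in order.

    Only 100%-identical sequences are removed; peptides differing by even a
    single residue are both kept.  No similarity clustering is performed.
    """
    seen: set[str] = set()
    out: list[Peptide] = []
    for p in peptides:
        if p.sequence in seen:
            continue
        seen.add(p.sequence)
        out.append(p)
    if len(out) < len(peptides):
        logger.info("deduplicate: removed %d duplicate sequences", len(peptides) - len(out))
    return out
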