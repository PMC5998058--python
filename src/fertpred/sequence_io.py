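"""FASTA reading/writing, sequence validation, and six-frame ORF translation.

Input proteins must use the 20 canonical one-letter codes; transcripts are
translated through a six-frame longest-ORF search (a deliberately simple
stand-in for nucleotide-composition-aware ORF callers such as TransDecoder).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

from ._tables import AMINO_ACIDS

_CANONICAL = set(AMINO_ACIDS)
_NT = set("ACGT")


class FastaParseError(ValueError):
    """Raised when a FASTA record is structurally malformed."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein record: FASTA id plus canonical residue string."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class NucleotideSequence:
    """A transcript record over {A, C, G, T} (U already mapped to T)."""

    id: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Rejection:
    id: str
    reason: str


def read_fasta(
    path: str | os.PathLike,
    alphabet: Literal["protein", "nucleotide"] = "protein",
) -> list[ProteinSequence] | list[NucleotideSequence]:
    """Read a FASTA file into sequence records, order preserved.

    Residues are uppercased; trailing ``*`` terminators are stripped from
    proteins; ``U`` is mapped to ``T`` in nucleotide mode.  Alphabet
    *validation* is left to :func:`validate_and_filter` (protein) or the ORF
    translator (nucleotide) so that filtering stays a reported decision, not
    a parse failure; structural problems (a record with an empty body) raise
    :class:`FastaParseError`.
    """
    records = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if alphabet == "protein":
            seq = seq.rstrip("*")
            if not seq:
                raise FastaParseError(f"record {rec.id!r} has an empty sequence body")
            records.append(ProteinSequence(id=rec.id, residues=seq))
        else:
            seq = seq.replace("U", "T")
            if not seq:
                raise FastaParseError(f"record {rec.id!r} has an empty sequence body")
            records.append(NucleotideSequence(id=rec.id, bases=seq))
    return records


def write_fasta(seqs: Iterable[ProteinSequence | NucleotideSequence],
                path: str | os.PathLike, width: int = 60) -> None:
    """Write records to FASTA, wrapping lines at ``width`` characters."""
    with open(path, "w") as fh:
        for s in seqs:
            body = s.residues if isinstance(s, ProteinSequence) else s.bases
            fh.write(f">{s.id}\n")
            for i in range(0, len(body), width):
                fh.write(body[i:i + width] + "\n")


def validate_and_filter(
    seqs: Iterable[ProteinSequence],
    min_len: int = 60,
    max_len: int = 6000,
) -> tuple[list[ProteinSequence], list[Rejection]]:
    """Partition proteins into kept / rejected under the benchmark filters.

    A sequence is kept iff ``min_len < L < max_len`` (strict on both sides)
    and every residue is one of the 20 canonical letters.  Rejections carry a
    reason code: ``too_short``, ``too_long`` or ``non_canonical`` (length
    checked first).
    """
    kept: list[ProteinSequence] = []
    rejected: list[Rejection] = []
    for s in seqs:
        n = len(s.residues)
        if n <= min_len:
            rejected.append(Rejection(s.id, "too_short"))
        elif n >= max_len:
            rejected.append(Rejection(s.id, "too_long"))
        elif not _CANONICAL.issuperset(s.residues):
            rejected.append(Rejection(s.id, "non_canonical"))
        else:
            kept.append(s)
    return kept, rejected


def write_rejection_report(rejections: Iterable[Rejection],
                           path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id\treason\n")
        for r in rejections:
            fh.write(f"{r.id}\t{r.reason}\n")


def reverse_complement(nt: NucleotideSequence) -> NucleotideSequence:
    return NucleotideSequence(id=nt.id, bases=str(Seq(nt.bases).reverse_complement()))


def translate_longest_orf(
    nt: NucleotideSequence,
    min_aa: int = 60,
    require_atg: bool = False,
) -> ProteinSequence | None:
    """Translate the longest open reading frame over all six frames.

    Scans the three forward and three reverse-complement frames under the
    standard genetic code.  An ORF is a maximal stop-free codon run; with
    ``require_atg`` it must begin at an ATG (the translated region then
    starts at that methionine).  Returns ``None`` when no ORF reaches
    ``min_aa`` amino acids.  Ties on length are broken by frame index (0-2
    forward then 3-5 reverse) and then by start position.

    Records containing bases outside {A, C, G, T} yield ``None`` (the caller
    reports them as rejected rather than crashing).
    """
    if not _NT.issuperset(nt.bases):
        return None
    best: tuple[int, int, int, str] | None = None  # (-len, frame, start, aa)
    fwd = nt.bases
    rev = str(Seq(fwd).reverse_complement())
    for frame in range(6):
        strand = fwd if frame < 3 else rev
        off = frame % 3
        n_codons = (len(strand) - off) // 3
        if n_codons <= 0:
            continue
        aa = str(Seq(strand[off:off + 3 * n_codons]).translate())
        start = 0
        for chunk in aa.split("*"):
            run = chunk
            run_start = start
            if require_atg:
                m = run.find("M")
                if m < 0:
                    run = ""
                else:
                    run = run[m:]
                    run_start += m
            if run:
                cand = (-len(run), frame, run_start, run)
                if best is None or cand < best:
                    best = cand
            start += len(chunk) + 1
    if best is None or -best[0] < min_aa:
        return None
    return ProteinSequence(id=nt.id, residues=best[3])
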