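"""Sequence containers, FASTA I/O, global alignment, and assembly summary stats.

Every other stage of the toolkit builds on the primitives here: typed
protein/transcript records, affine-gap Needleman-Wunsch alignment under a
configurable scoring scheme, percent identity under explicit denominator
conventions, and the N10/N20/N50 + GC summary used to describe a de novo
transcript assembly.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
GAP = "-"

IdentityConvention = Literal["exclude_terminal_gaps", "all_columns"]


@dataclass
class ProteinRecord:
    """An identified amino-acid sequence with a species tag.

    ``residues`` uses one-letter codes over the 20 standard residues plus
    'X' (unknown). Lowercase input is normalised on load by :func:`read_fasta`.
    """

    id: str
    residues: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.residues:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein record {self.id!r} contains non-amino-acid symbols: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TranscriptRecord:
    """An assembled nucleotide transcript (A/C/G/T/N)."""

    id: str
    bases: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript record id must be non-empty")
        if not self.bases:
            raise ValueError(f"transcript record {self.id!r} has an empty sequence")
        bad = set(self.bases) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValueError(
                f"transcript record {self.id!r} contains non-nucleotide symbols: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both given as costs >= 0).

    The default (BLOSUM62, open 10, extend 1) replaces the BLAST/ClustalX
    default settings with an explicit, reproducible global alignment. 'X'
    scores 0 against everything, including itself.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError(
                f"require gap_open >= gap_extend >= 0, got "
                f"open={self.gap_open}, extend={self.gap_extend}"
            )


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment of a query against a subject.

    The aligned strings are equal-length rows over the residue alphabet plus
    '-'; stripping gaps recovers the input sequences. ``identity`` is the
    fraction of matching columns under the default denominator convention
    (columns excluding terminal gaps).
    """

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    @property
    def n_matches(self) -> int:
        return sum(
            1
            for q, s in zip(self.aligned_query, self.aligned_subject)
            if q == s and q != GAP
        )

    @property
    def identity(self) -> float:
        return percent_identity(self) / 100.0

    def core_span(self) -> tuple[int, int]:
        """Half-open column range once terminal-gap columns are trimmed."""
        both = [
            i
            for i, (q, s) in enumerate(zip(self.aligned_query, self.aligned_subject))
            if q != GAP and s != GAP
        ]
        if not both:
            return (0, 0)
        return (both[0], both[-1] + 1)


def _first_token(header: str) -> str:
    return header.split()[0]


def read_fasta(
    path: str | Path, kind: Literal["protein", "transcript"] = "protein", species: str = ""
) -> list[ProteinRecord] | list[TranscriptRecord]:
    """Read a multi-record FASTA file into typed records.

    Record order is preserved; the id is the first whitespace-delimited header
    token (so ``>L_16562_c0_g1_i1 some note`` yields id ``L_16562_c0_g1_i1``);
    sequences are uppercased. Duplicate ids and empty files are errors.
    """
    path = Path(path)
    cls = ProteinRecord if kind == "protein" else TranscriptRecord
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = _first_token(rec.description) if rec.description else rec.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r} in {path}")
        seen.add(rid)
        desc = rec.description[len(rid) :].strip() if rec.description else ""
        seq = str(rec.seq).upper()
        if kind == "protein":
            records.append(cls(id=rid, residues=seq, species=species, description=desc))
        else:
            records.append(cls(id=rid, bases=seq, species=species, description=desc))
    if not records:
        raise ValueError(f"FASTA file {path} contains no records")
    return records


def write_fasta(
    records: Iterable[ProteinRecord | TranscriptRecord], path: str | Path, width: int = 60
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.residues if isinstance(rec, ProteinRecord) else rec.bases
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@functools.lru_cache(maxsize=8)
def _aligner_for(scheme: ScoringScheme) -> PairwiseAligner:
    matrix = substitution_matrices.load(scheme.matrix_name)
    if "X" in matrix.alphabet:
        matrix = matrix.copy()
        x = matrix.alphabet.index("X")
        for i in range(len(matrix.alphabet)):
            matrix[x, i] = 0.0
            matrix[i, x] = 0.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -float(scheme.gap_open)
    aligner.extend_gap_score = -float(scheme.gap_extend)
    return aligner


def global_align(
    a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme | None = None
) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch, affine-gap) alignment of two proteins.

    Deterministic: among co-optimal alignments the aligner's canonical first
    traceback is returned, so identical inputs always give identical output.
    """
    scheme = scheme or ScoringScheme()
    aligner = _aligner_for(scheme)
    aln = aligner.align(a.residues, b.residues)[0]
    return PairwiseAlignment(
        query_id=a.id,
        subject_id=b.id,
        aligned_query=str(aln[0]),
        aligned_subject=str(aln[1]),
        score=float(aln.score),
    )


def percent_identity(
    aln: PairwiseAlignment, convention: IdentityConvention = "exclude_terminal_gaps"
) -> float:
    """Percent identity of an alignment: 100 x matches / denominator.

    ``exclude_terminal_gaps`` (default): the denominator is the number of
    alignment columns after trimming columns of terminal gap runs; internal
    gaps still count as mismatches. ``all_columns``: every column counts.
    """
    if convention == "all_columns":
        denom = aln.n_columns
        matches = aln.n_matches
    elif convention == "exclude_terminal_gaps":
        lo, hi = aln.core_span()
        denom = hi - lo
        matches = sum(
            1
            for q, s in zip(aln.aligned_query[lo:hi], aln.aligned_subject[lo:hi])
            if q == s and q != GAP
        )
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown identity convention {convention!r}")
    if denom == 0:
        raise ValueError(
            f"alignment {aln.query_id} vs {aln.subject_id} has a zero-length "
            f"denominator under convention {convention!r}"
        )
    return 100.0 * matches / denom


@dataclass(frozen=True)
class TranscriptSummary:
    """Assembly-level summary in the style of a de novo transcriptome report."""

    n_transcripts: int
    total_bases: int
    gc_percent: float
    n10: int
    n20: int
    n50: int

    def to_tsv(self) -> str:
        rows = [
            ("Total transcripts", self.n_transcripts),
            ("Total assembled bases", self.total_bases),
            ("GC (%)", round(self.gc_percent, 1)),
            ("N10 (nts)", self.n10),
            ("N20 (nts)", self.n20),
            ("N50 (nts)", self.n50),
        ]
        return "statistic\tvalue\n" + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def _nx(lengths_desc: Sequence[int], total: int, x: float) -> int:
    """Smallest length L (scanning descending) whose cumulative sum covers x% of total."""
    threshold = total * x / 100.0
    acc = 0
    for length in lengths_desc:
        acc += length
        if acc >= threshold:
            return length
    return lengths_desc[-1]


def transcript_summary_stats(records: Sequence[TranscriptRecord]) -> TranscriptSummary:
    """Count, total bases, GC%, and N10/N20/N50 for a set of transcripts."""
    if not records:
        raise ValueError("transcript_summary_stats requires at least one record")
    lengths = sorted((len(r) for r in records), reverse=True)
    total = sum(lengths)
    gc = sum(r.bases.count("G") + r.bases.count("C") for r in records)
    return TranscriptSummary(
        n_transcripts=len(records),
        total_bases=total,
        gc_percent=100.0 * gc / total,
        n10=_nx(lengths, total, 10),
        n20=_nx(lengths, total, 20),
        n50=_nx(lengths, total, 50),
    )
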