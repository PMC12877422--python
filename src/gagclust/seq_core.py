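"""Protein sequence records, FASTA I/O, filtering, and pairwise alignment.

This module is the substrate for everything downstream: greedy family
clustering, the strain-conservation screen and the synthetic-data generator
all consume :class:`SequenceRecord` collections and the identity/coverage
numbers produced by :func:`global_align` / :func:`local_align`.

Alignment semantics
-------------------
Alignments are exact dynamic-programming alignments (Needleman–Wunsch for
global, Smith–Waterman for local) computed with Biopython's
``PairwiseAligner`` under BLOSUM62 with affine gap penalties (open 11,
extend 1, BLAST convention: a gap of length *k* costs ``11 + k``).  Percent
identity is defined BLAST-like as ``matches / alignment columns`` where
columns are counted between the first and the last aligned residue pair —
internal gaps count as columns, terminal gaps do not.  Query coverage is the
fraction of the query covered by that same span.  The ambiguity residue X is
scored 0 against every residue.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "SequenceRecord",
    "AlignmentResult",
    "AlignmentParams",
    "FastaParseError",
    "FilterReport",
    "read_fasta",
    "write_fasta",
    "filter_records",
    "global_align",
    "local_align",
    "pairwise_identity",
    "default_species_parser",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
# degenerate / rare codes collapsed to X on read; '*' (stop) is stripped
_DEGENERATE = str.maketrans({c: "X" for c in "BZJUO"})


class FastaParseError(ValueError):
    """Raised on structurally malformed FASTA input; names the line number."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence plus the metadata the pipeline keys on.

    ``species`` is the taxon the sequence belongs to (row identity of the
    presence/absence matrices), ``family`` the enzyme-family tag (e.g.
    ``"PL8"``, ``"GH88"``) and ``strain`` an optional strain identifier used
    by the conservation screen.
    """

    id: str
    residues: str
    species: str = ""
    strain: str | None = None
    family: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord.id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentResult:
    """Identity/coverage summary of one pairwise alignment.

    ``aligned_columns`` counts columns between the first and last aligned
    residue pair (internal gaps included, terminal gaps excluded);
    ``identity_pct`` is ``100 * matches / aligned_columns``;
    ``query_coverage_pct`` is the aligned query span over the query length.
    """

    matches: int
    aligned_columns: int
    identity_pct: float
    query_coverage_pct: float
    score: float


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for pairwise alignment.

    Defaults follow BLASTp: BLOSUM62, gap open 11, gap extend 1 (a gap of
    length k costs ``gap_open + k * gap_extend``).  ``identity_mode``
    selects the identity denominator: ``"alignment_columns"`` (default,
    BLAST-like) or ``"shorter_seq"`` (matches over the shorter sequence
    length).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    identity_mode: str = "alignment_columns"

    def __post_init__(self) -> None:
        if self.identity_mode not in ("alignment_columns", "shorter_seq"):
            raise ValueError(f"unknown identity_mode {self.identity_mode!r}")


DEFAULT_PARAMS = AlignmentParams()


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

_OS_RE = re.compile(r"\bOS=(\S+(?:\s+\S+)?)")


def default_species_parser(description: str) -> str:
    """Extract a species name from a FASTA description line.

    Uses the UniProt ``OS=`` field when present, otherwise falls back to the
    first two whitespace tokens of the description (``Genus species``).
    Returns an empty string when nothing can be extracted.
    """
    m = _OS_RE.search(description)
    if m:
        return m.group(1).strip()
    tokens = description.split()
    return " ".join(tokens[:2])


def _validate_fasta_text(text: str) -> None:
    """Structural pre-scan so parse errors can name a line number."""
    header_line = None
    saw_sequence = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header_line is not None and not saw_sequence:
                raise FastaParseError(
                    f"line {header_line}: FASTA header without sequence"
                )
            header_line = lineno
            saw_sequence = False
        else:
            if header_line is None:
                raise FastaParseError(
                    f"line {lineno}: sequence data before any FASTA header"
                )
            cleaned = line.upper().rstrip("*").translate(_DEGENERATE)
            bad = set(cleaned) - _VALID_RESIDUES
            if bad:
                raise FastaParseError(
                    f"line {lineno}: illegal residue characters {sorted(bad)}"
                )
            saw_sequence = True
    if header_line is not None and not saw_sequence:
        raise FastaParseError(f"line {header_line}: FASTA header without sequence")


def read_fasta(
    path: str | Path,
    family: str = "",
    species_parser: Callable[[str], str] = default_species_parser,
    strain: str | None = None,
) -> list[SequenceRecord]:
    """Read a protein FASTA file into :class:`SequenceRecord` objects.

    Residues are upper-cased, trailing stop codons stripped and degenerate
    codes (B, Z, J, U, O) mapped to X.  Entry order is preserved.  Raises
    :class:`FastaParseError` naming the offending line on malformed input.
    """
    text = Path(path).read_text()
    _validate_fasta_text(text)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        description = rec.description[len(rec.id):].strip()
        residues = str(rec.seq).upper().rstrip("*").translate(_DEGENERATE)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                species=species_parser(description),
                strain=strain,
                family=family,
                description=description,
            )
        )
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 80
) -> None:
    """Write records as multi-line FASTA (sequences wrapped at ``width``)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Record filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_records`."""

    n_input: int = 0
    n_fragment: int = 0
    n_multispecies: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_fragment - self.n_multispecies

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rule\tremoved\n")
            fh.write(f"fragment\t{self.n_fragment}\n")
            fh.write(f"multispecies\t{self.n_multispecies}\n")
            fh.write(f"kept\t{self.n_kept}\n")


def filter_records(
    records: Sequence[SequenceRecord],
    drop_fragments: bool = True,
    drop_multispecies: bool = True,
    fragment_marker: str = "(fragment)",
    multispecies_delimiters: Sequence[str] = (";", "/"),
) -> tuple[list[SequenceRecord], FilterReport]:
    """Remove fragment and multispecies entries from a record collection.

    A record is a fragment when its description contains ``fragment_marker``
    (case-insensitive); it is multispecies when its species field names more
    than one taxon (any configured delimiter present, or an NCBI
    ``MULTISPECIES:`` description prefix).
    """
    report = FilterReport(n_input=len(records))
    kept: list[SequenceRecord] = []
    marker = fragment_marker.lower()
    for rec in records:
        if drop_fragments and marker in rec.description.lower():
            report.n_fragment += 1
            continue
        if drop_multispecies and (
            any(d in rec.species for d in multispecies_delimiters)
            or rec.description.upper().startswith("MULTISPECIES:")
        ):
            report.n_multispecies += 1
            continue
        kept.append(rec)
    return kept, report


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float, mode: str) -> PairwiseAligner:
    sub = substitution_matrices.load(matrix)
    if "X" in sub.alphabet:  # neutral ambiguity scoring
        x = sub.alphabet.index("X")
        sub[x, :] = 0.0
        sub[:, x] = 0.0
    aligner = PairwiseAligner()
    aligner.substitution_matrix = sub
    # Biopython charges open_gap_score for the first gap residue; convert
    # from the BLAST convention (gap of length k costs open + k*extend).
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


def _residues(seq: "SequenceRecord | str") -> str:
    return seq.residues if isinstance(seq, SequenceRecord) else seq


def _span_stats(alignment, swapped: bool) -> tuple[int, int, int]:
    """(matches, aligned_columns, query_span) from a Biopython alignment.

    ``swapped`` marks that the caller's query was passed as the aligner's
    second sequence.
    """
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return 0, 0, 0
    target, query = alignment.sequences
    matches = 0
    diag = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        diag += te - ts
        matches += sum(a == b for a, b in zip(target[ts:te], query[qs:qe]))
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    columns = int(t_span + q_span - diag)
    return int(matches), columns, (q_span if swapped else t_span)


def _align(
    query: "SequenceRecord | str",
    subject: "SequenceRecord | str",
    params: AlignmentParams,
    mode: str,
) -> AlignmentResult:
    q, s = _residues(query), _residues(subject)
    if not q or not s:
        raise ValueError("cannot align empty sequences")
    # Canonical argument order makes identity and score exactly symmetric
    # even when co-optimal alignments exist.
    swapped = q > s
    first, second = (s, q) if swapped else (q, s)
    aligner = _aligner(params.matrix, params.gap_open, params.gap_extend, mode)
    try:
        alignment = aligner.align(first, second)[0]
    except IndexError:  # local mode: no alignment with positive score
        return AlignmentResult(
            matches=0, aligned_columns=0, identity_pct=0.0,
            query_coverage_pct=0.0, score=0.0,
        )
    matches, columns, q_span = _span_stats(alignment, swapped)
    if params.identity_mode == "shorter_seq":
        denom = min(len(q), len(s))
        identity = 100.0 * matches / denom
    else:
        identity = 100.0 * matches / columns if columns else 0.0
    identity = float(identity)
    coverage = 100.0 * q_span / len(q)
    return AlignmentResult(
        matches=matches,
        aligned_columns=columns,
        identity_pct=identity,
        query_coverage_pct=coverage,
        score=float(alignment.score),
    )


def global_align(
    query: "SequenceRecord | str",
    subject: "SequenceRecord | str",
    params: AlignmentParams = DEFAULT_PARAMS,
) -> AlignmentResult:
    """Optimal global (Needleman–Wunsch) alignment of two protein sequences."""
    return _align(query, subject, params, "global")


def local_align(
    query: "SequenceRecord | str",
    subject: "SequenceRecord | str",
    params: AlignmentParams = DEFAULT_PARAMS,
) -> AlignmentResult:
    """Highest-scoring local (Smith–Waterman) alignment; coverage is measured
    over the local query span."""
    return _align(query, subject, params, "local")


def pairwise_identity(
    a: "SequenceRecord | str",
    b: "SequenceRecord | str",
    params: AlignmentParams = DEFAULT_PARAMS,
) -> float:
    """Global percent identity between two sequences (symmetric)."""
    return global_align(a, b, params).identity_pct
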