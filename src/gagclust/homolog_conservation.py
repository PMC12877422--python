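"""Strain-level homolog conservation screen.

Each reference (query) protein is searched against every strain proteome by
exact local alignment (Smith–Waterman, BLOSUM62), mimicking a BLASTp
best-hit screen without E-value statistics.  Per (query, strain) only the
top-scoring subject is retained (ties broken by lexicographically smallest
subject id); a hit is *kept* when it passes both the identity and the
query-coverage filter (defaults 60 % and 30 %, chosen to exclude partial or
truncated subjects).  Kept hits define a binary query x strain
presence/absence matrix, summarized per query as the presence fraction and
the mean/SD of identity over strains where the homolog is present.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_core import (
    AlignmentParams,
    DEFAULT_PARAMS,
    SequenceRecord,
    local_align,
    read_fasta,
)

__all__ = [
    "HomologHit",
    "best_hit",
    "presence_matrix",
    "conservation_summary",
    "read_proteome_dir",
    "DEFAULT_MIN_IDENTITY",
    "DEFAULT_MIN_COVERAGE",
]

DEFAULT_MIN_IDENTITY = 60.0
DEFAULT_MIN_COVERAGE = 30.0

HIT_COLUMNS = [
    "query_id",
    "strain_id",
    "subject_id",
    "identity_pct",
    "query_coverage_pct",
    "score",
    "kept",
]


@dataclass(frozen=True)
class HomologHit:
    """Best local-alignment hit of one query in one strain proteome."""

    query_id: str
    strain_id: str
    subject_id: str
    identity_pct: float
    query_coverage_pct: float
    score: float
    kept: bool


def best_hit(
    query: SequenceRecord,
    proteome: Sequence[SequenceRecord],
    strain_id: str = "",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> HomologHit | None:
    """Top-scoring local hit of ``query`` in one proteome, or None.

    Returns None when no subject aligns with positive score.  The returned
    hit carries ``kept = (identity >= min_identity) and (coverage >=
    min_coverage)``.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    best: tuple[float, str, "object"] | None = None
    for subject in sorted(proteome, key=lambda r: r.id):
        res = local_align(query, subject, params)
        if res.score <= 0:
            continue
        if best is None or res.score > best[0]:
            best = (res.score, subject.id, res)
    if best is None:
        return None
    score, subject_id, res = best
    kept = res.identity_pct >= min_identity and res.query_coverage_pct >= min_coverage
    return HomologHit(
        query_id=query.id,
        strain_id=strain_id,
        subject_id=subject_id,
        identity_pct=res.identity_pct,
        query_coverage_pct=res.query_coverage_pct,
        score=score,
        kept=kept,
    )


def presence_matrix(
    queries: Sequence[SequenceRecord],
    proteomes: Mapping[str, Sequence[SequenceRecord]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary query x strain presence matrix plus the full hit table.

    ``proteomes`` maps strain id -> records.  A matrix cell is 1 iff the
    best hit for that (query, strain) passed both filters.
    """
    if not queries:
        raise ValueError("at least one query required")
    if not proteomes:
        raise ValueError("at least one proteome required")
    strain_ids = list(proteomes)
    if len(set(strain_ids)) != len(strain_ids):
        raise ValueError("duplicate strain ids")
    matrix = pd.DataFrame(
        0, index=[q.id for q in queries], columns=strain_ids, dtype=np.int8
    )
    matrix.index.name = "query_id"
    rows: list[HomologHit] = []
    for q in queries:
        for strain, proteome in proteomes.items():
            hit = best_hit(q, proteome, strain, min_identity, min_coverage, params)
            if hit is None:
                continue
            rows.append(hit)
            if hit.kept:
                matrix.loc[q.id, strain] = 1
    hit_table = pd.DataFrame([vars(h) for h in rows], columns=HIT_COLUMNS)
    return matrix, hit_table


def conservation_summary(
    matrix: pd.DataFrame, hit_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-query conservation statistics over the screened strains.

    ``presence_fraction`` is the share of strains with a kept hit;
    ``mean_identity_pct`` / ``identity_sd_pct`` are computed over kept hits
    only (sample SD, n-1 denominator; 0 when a single strain carries the
    homolog; blank when none does).
    """
    n_strains = matrix.shape[1]
    kept = hit_table[hit_table["kept"]]
    rows = []
    for query_id in matrix.index:
        identities = kept.loc[kept["query_id"] == query_id, "identity_pct"]
        n_present = int(matrix.loc[query_id].sum())
        rows.append(
            {
                "query_id": query_id,
                "n_strains": n_strains,
                "n_present": n_present,
                "presence_fraction": n_present / n_strains,
                "mean_identity_pct": identities.mean() if len(identities) else np.nan,
                "identity_sd_pct": (
                    identities.std(ddof=1) if len(identities) > 1
                    else (0.0 if len(identities) == 1 else np.nan)
                ),
            }
        )
    return pd.DataFrame(rows)


def read_proteome_dir(
    directory: str | Path, pattern: str = "*.fasta"
) -> dict[str, list[SequenceRecord]]:
    """Load per-strain proteome FASTA files; the file stem is the strain id."""
    directory = Path(directory)
    proteomes: dict[str, list[SequenceRecord]] = {}
    for path in sorted(directory.glob(pattern)):
        proteomes[path.stem] = read_fasta(path, strain=path.stem)
    if not proteomes:
        raise ValueError(f"no {pattern} files found in {directory}")
    return proteomes
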