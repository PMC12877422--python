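"""End-to-end pipeline: family FASTAs -> species partition -> concordance.

Stages: filter records -> greedy-cluster each family -> presence/absence
matrices over the shared species order -> Jaccard distances -> merge ->
hierarchical clustering -> cut into k groups -> evaluate against phenotype
labels.  Every intermediate is persisted to the output directory together
with a manifest echoing the resolved configuration, so a run can be
reproduced bit-for-bit from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .family_clustering import DEFAULT_SWEEP, greedy_cluster
from .phenotype_concordance import ConcordanceReport, load_labels, majority_vote_map
from .profile_clustering import (
    Partition,
    build_presence_matrix,
    concat_presence_matrices,
    cut_dendrogram,
    hierarchical_cluster,
    jaccard_distances,
    merge_distance_matrices,
)
from .seq_core import AlignmentParams, DEFAULT_PARAMS, read_fasta, filter_records

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

log = logging.getLogger("gagclust")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults mirror the reference analysis regime: 60 % clustering
    identity, threshold sweep 40-80 by 10, k = 10 species groups, average
    linkage, per-family distance averaging, NonCleaver tie rule.
    """

    family_fastas: tuple[str, ...] = ()
    labels_path: str | None = None
    out_dir: str = "gagclust_run"
    threshold_pct: float = 60.0
    sweep: tuple[float, ...] = DEFAULT_SWEEP
    k: int = 10
    linkage: str = "average"
    merge_mode: str = "mean"  # or "concat"
    tie_rule: str = "noncleaver"
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    min_identity: float = 60.0
    min_coverage: float = 30.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    partition: Partition
    report: ConcordanceReport | None
    n_clusters_per_family: dict[str, int]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the clustering pipeline described by ``config``.

    Evaluation is skipped with a warning when no label file is configured;
    clustering outputs are produced regardless.
    """
    if config.merge_mode not in ("mean", "concat"):
        raise ValueError(f"unknown merge mode {config.merge_mode!r}")
    if not config.family_fastas:
        raise ValueError("at least one family FASTA is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
        fh.write("\n")
    params = AlignmentParams()

    log.info("stage=read n_families=%d", len(config.family_fastas))
    families = {}
    for path in config.family_fastas:
        family = Path(path).stem
        records = read_fasta(path, family=family)
        kept, filt = filter_records(records)
        filt.to_tsv(out / f"{family}.filter.tsv")
        if not kept:
            raise ValueError(f"no records left in family {family} after filtering")
        families[family] = kept
        log.info(
            "stage=filter family=%s kept=%d fragment=%d multispecies=%d",
            family, filt.n_kept, filt.n_fragment, filt.n_multispecies,
        )

    canonical_species = sorted({r.species for recs in families.values() for r in recs})

    clusterings = {}
    presence = {}
    for family, records in families.items():
        clustering = greedy_cluster(records, config.threshold_pct, params)
        clustering.to_tsv(out / f"{family}.clusters.tsv")
        clusterings[family] = clustering
        pm = build_presence_matrix(clustering, canonical_species)
        pm.to_tsv(out / f"{family}.presence.tsv")
        presence[family] = pm
        log.info(
            "stage=cluster family=%s threshold=%.0f n_clusters=%d",
            family, config.threshold_pct, clustering.n_clusters,
        )

    if config.merge_mode == "concat":
        merged = jaccard_distances(concat_presence_matrices(list(presence.values())))
    else:
        merged = merge_distance_matrices(
            [jaccard_distances(pm) for pm in presence.values()]
        )
    merged.to_tsv(out / "distance.tsv")

    dendro = hierarchical_cluster(merged, config.linkage)
    dendro.write_newick(out / "dendrogram.nwk")
    partition = cut_dendrogram(dendro, min(config.k, len(merged.species)))
    partition.to_tsv(out / "partition.tsv")
    log.info(
        "stage=partition n_species=%d k=%d", len(merged.species), config.k
    )

    report = None
    if config.labels_path:
        labels = load_labels(config.labels_path)
        report = majority_vote_map(partition, labels, config.tie_rule)
        report.to_tsv(out / "concordance.tsv")
        (out / "concordance.txt").write_text(report.to_text() + "\n")
        log.info(
            "stage=evaluate ari=%.3f accuracy=%.3f", report.ari, report.accuracy
        )
    else:
        log.warning("stage=evaluate skipped=no-label-file")

    return PipelineResult(
        partition=partition,
        report=report,
        n_clusters_per_family={f: c.n_clusters for f, c in clusterings.items()},
    )
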