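"""Agreement between a species partition and degradation phenotype labels.

Phenotype labels are four-valued: ``Cleaver`` / ``NonCleaver`` (clear
experimental evidence for or against hyaluronan degradation), ``Mixed``
(conflicting reports) and ``NA`` (untested).  Mixed/NA species are excluded
before any metric is computed.  Agreement between the partition and the
binary phenotype labeling is quantified with the Hubert–Arabie Adjusted
Rand Index and Normalized Mutual Information, and with a majority-vote
prediction check: each cluster is assigned the phenotype most of its
labeled members carry, every labeled species inherits its cluster's
predicted phenotype, and precision/recall/F1/accuracy are reported with
Cleaver as the positive class.

Clusters with no labeled members are marked ``Unlabeled`` and their species
are excluded from the confusion counts.  Tied clusters are resolved by a
configurable policy (default: predict NonCleaver, the conservative choice
that cannot create false positives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .profile_clustering import Partition

__all__ = [
    "CLEAVER",
    "NONCLEAVER",
    "MIXED",
    "NA",
    "PhenotypeLabels",
    "ConcordanceReport",
    "load_labels",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "majority_vote_map",
]

CLEAVER = "Cleaver"
NONCLEAVER = "NonCleaver"
MIXED = "Mixed"
NA = "NA"

_CANONICAL = {
    "cleaver": CLEAVER,
    "degrader": CLEAVER,
    "noncleaver": NONCLEAVER,
    "non-cleaver": NONCLEAVER,
    "nondegrader": NONCLEAVER,
    "non-degrader": NONCLEAVER,
    "mixed": MIXED,
    "na": NA,
    "nan": NA,
    "": NA,
}

TIE_RULES = ("noncleaver", "cleaver", "exclude")


@dataclass
class PhenotypeLabels:
    """species -> {Cleaver, NonCleaver, Mixed, NA}; unknown species are NA."""

    mapping: dict[str, str]

    def label_of(self, species: str) -> str:
        return self.mapping.get(species, NA)

    def labeled_species(self) -> list[str]:
        return [s for s, l in self.mapping.items() if l in (CLEAVER, NONCLEAVER)]

    def binary_partition(self, species: list[str]) -> Partition:
        return Partition({s: self.label_of(s) for s in species})


@dataclass
class ConcordanceReport:
    """Full evaluation of one partition against phenotype labels."""

    ari: float
    nmi: float
    cluster_label_map: dict[str, str]  # cluster -> Cleaver/NonCleaver/Tie/Unlabeled
    precision: float
    recall: float
    f1: float
    accuracy: float
    n_labeled: int
    n_excluded: int
    n_evaluated: int
    confusion: dict[str, int]  # TP/FP/FN/TN
    tie_rule: str
    predictions: dict[str, str] = field(default_factory=dict)

    def to_flat(self) -> dict[str, float | int | str]:
        flat: dict[str, float | int | str] = {
            "ari": self.ari,
            "nmi": self.nmi,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "n_labeled": self.n_labeled,
            "n_excluded": self.n_excluded,
            "n_evaluated": self.n_evaluated,
            "tie_rule": self.tie_rule,
        }
        flat.update({k: v for k, v in self.confusion.items()})
        return flat

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in self.to_flat().items():
                fh.write(f"{k}\t{v}\n")
            for cluster, label in self.cluster_label_map.items():
                fh.write(f"cluster_label:{cluster}\t{label}\n")

    def to_text(self) -> str:
        lines = [
            f"ARI      {self.ari:.3f}",
            f"NMI      {self.nmi:.3f}",
            f"precision {self.precision:.3f}  recall {self.recall:.3f}  "
            f"F1 {self.f1:.3f}  accuracy {self.accuracy:.3f}",
            f"labeled {self.n_labeled}  excluded (Mixed/NA) {self.n_excluded}  "
            f"evaluated {self.n_evaluated}",
            "confusion "
            + "  ".join(f"{k}={v}" for k, v in self.confusion.items()),
            "cluster labels "
            + "  ".join(f"{c}:{l}" for c, l in self.cluster_label_map.items()),
        ]
        return "\n".join(lines)


def load_labels(path: str | Path) -> PhenotypeLabels:
    """Load a two-column (species, label) delimited table.

    Labels are case-normalized; unknown label strings become NA with a
    warning; duplicate species rows with conflicting labels are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("label file must have two columns: species, label")
    mapping: dict[str, str] = {}
    for species, raw in zip(df.iloc[:, 0], df.iloc[:, 1]):
        species = species.strip()
        key = raw.strip().lower()
        if key in _CANONICAL:
            label = _CANONICAL[key]
        else:
            warnings.warn(f"unknown phenotype label {raw!r} for {species}; using NA")
            label = NA
        if species in mapping and mapping[species] != label:
            raise ValueError(
                f"conflicting labels for {species}: "
                f"{mapping[species]} vs {label}"
            )
        mapping[species] = label
    return PhenotypeLabels(mapping)


def _paired_labels(p: Partition, q: Partition) -> tuple[list[str], list[str]]:
    if set(p.species) != set(q.species):
        raise ValueError("partitions must cover the same species set")
    if len(p.species) < 2:
        raise ValueError("partition comparison requires at least 2 species")
    species = sorted(p.species)
    return [p.assignment[s] for s in species], [q.assignment[s] for s in species]


def adjusted_rand_index(p: Partition, q: Partition) -> float:
    """Hubert–Arabie ARI between two partitions of the same species set."""
    a, b = _paired_labels(p, q)
    if len(set(a)) == 1 and len(set(b)) == 1:
        warnings.warn("both partitions are a single cluster; ARI is degenerate")
    return float(adjusted_rand_score(a, b))


def normalized_mutual_information(
    p: Partition, q: Partition, average_method: str = "arithmetic"
) -> float:
    """NMI between two partitions; normalized by the arithmetic mean of the
    entropies by default (geometric/min/max selectable)."""
    a, b = _paired_labels(p, q)
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


def majority_vote_map(
    partition: Partition,
    labels: PhenotypeLabels,
    tie_rule: str = "noncleaver",
) -> ConcordanceReport:
    """Majority-vote phenotype prediction from cluster membership.

    Mixed/NA species are excluded first; ARI/NMI are computed between the
    partition restricted to labeled species and the binary phenotype
    labeling; the confusion counts cover labeled species in clusters having
    at least one labeled member (and, under ``tie_rule="exclude"``, not
    tied).
    """
    if tie_rule not in TIE_RULES:
        raise ValueError(f"unknown tie rule {tie_rule!r}; choose from {TIE_RULES}")
    labeled = [
        s for s in partition.species
        if labels.label_of(s) in (CLEAVER, NONCLEAVER)
    ]
    n_total = len(partition.species)
    if not labeled:
        raise ValueError("no labeled species remain after Mixed/NA exclusion")

    sub = partition.restricted_to(labeled)
    truth = labels.binary_partition(labeled)
    if len(labeled) >= 2:
        ari = adjusted_rand_index(sub, truth)
        nmi = normalized_mutual_information(sub, truth)
    else:  # single labeled species: agreement metrics are degenerate
        ari = nmi = float("nan")

    cluster_label_map: dict[str, str] = {}
    predicted_of_cluster: dict[str, str | None] = {}
    for cluster in sorted(
        set(partition.assignment.values()),
        key=lambda c: (len(c), c),  # C1, C2, ... C10 in numeric order
    ):
        members = partition.members(cluster)
        n_cleaver = sum(labels.label_of(s) == CLEAVER for s in members)
        n_non = sum(labels.label_of(s) == NONCLEAVER for s in members)
        if n_cleaver + n_non == 0:
            cluster_label_map[cluster] = "Unlabeled"
            predicted_of_cluster[cluster] = None
        elif n_cleaver > n_non:
            cluster_label_map[cluster] = CLEAVER
            predicted_of_cluster[cluster] = CLEAVER
        elif n_non > n_cleaver:
            cluster_label_map[cluster] = NONCLEAVER
            predicted_of_cluster[cluster] = NONCLEAVER
        else:
            cluster_label_map[cluster] = "Tie"
            predicted_of_cluster[cluster] = {
                "noncleaver": NONCLEAVER,
                "cleaver": CLEAVER,
                "exclude": None,
            }[tie_rule]

    tp = fp = fn = tn = 0
    predictions: dict[str, str] = {}
    for s in labeled:
        pred = predicted_of_cluster[partition.assignment[s]]
        if pred is None:
            continue
        predictions[s] = pred
        true = labels.label_of(s)
        if pred == CLEAVER and true == CLEAVER:
            tp += 1
        elif pred == CLEAVER and true == NONCLEAVER:
            fp += 1
        elif pred == NONCLEAVER and true == CLEAVER:
            fn += 1
        else:
            tn += 1
    n_evaluated = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / n_evaluated if n_evaluated else 0.0

    return ConcordanceReport(
        ari=ari,
        nmi=nmi,
        cluster_label_map=cluster_label_map,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        n_labeled=len(labeled),
        n_excluded=n_total - len(labeled),
        n_evaluated=n_evaluated,
        confusion={"TP": tp, "FP": fp, "FN": fn, "TN": tn},
        tie_rule=tie_rule,
        predictions=predictions,
    )
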