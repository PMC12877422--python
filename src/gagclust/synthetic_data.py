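"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure the comparative pipeline
assumes: multi-species enzyme families whose sequences fall into archetype
groups with controlled within-group and between-group percent identity,
species gene content organized in blocks, a degradation phenotype caused by
carrying a designated set of pathway archetypes, strain proteomes diverged
from references at a stated substitution rate, and protein quantification
tables with a known true differentially-expressed set.

Mutations are substitution-only (no indels), which makes realized percent
identity analytically exact: a sequence mutated to a target identity *t*
carries exactly ``round(L * (1 - t/100))`` substituted positions and aligns
back to its source at exactly *t* percent.  Archetype sequences are drawn
uniformly over the 20 amino acids and rejection-sampled until all pairs
within a family stay below the configured between-group identity ceiling.

Species are assigned round-robin to ``n_blocks`` content blocks.  Block 0
carries every designated pathway archetype, the remaining archetypes are
dealt cyclically to the other blocks, so blocks have disjoint archetype
content and block 0 members are the true degraders ("Cleavers").  Emitted
labels flip with probability ``label_noise`` and a configured fraction of
species is relabeled Mixed/NA to mimic the sparsely labeled literature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype_concordance import CLEAVER, MIXED, NA, NONCLEAVER, PhenotypeLabels
from .seq_core import AMINO_ACIDS, SequenceRecord, pairwise_identity, write_fasta

__all__ = [
    "FamilySpec",
    "SimulationConfig",
    "SimulatedDataset",
    "random_protein",
    "mutate_to_identity",
    "simulate_dataset",
    "simulate_strain_proteomes",
    "simulate_quant_table",
]

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class FamilySpec:
    """One synthetic enzyme family.

    ``within_identity_pct`` is the identity of each species' ortholog to its
    archetype; ``between_identity_max_pct`` the ceiling on identity between
    distinct archetypes of the family.
    """

    tag: str
    n_archetypes: int = 5
    within_identity_pct: float = 90.0
    between_identity_max_pct: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.within_identity_pct <= 100:
            raise ValueError("within_identity_pct must be in (0, 100]")
        if not 0 < self.between_identity_max_pct <= 100:
            raise ValueError("between_identity_max_pct must be in (0, 100]")
        if self.within_identity_pct <= self.between_identity_max_pct:
            raise ValueError(
                "within_identity_pct must exceed between_identity_max_pct"
            )
        if self.n_archetypes < 1:
            raise ValueError("n_archetypes must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic multi-species dataset.

    Defaults describe the benchmark regime: 40 species in two content
    blocks, two families of five archetypes at 90 % within / <= 40 % between
    identity, phenotype caused by the first archetype of each family, clean
    labels, proteins of 200 residues.
    """

    n_species: int = 40
    families: tuple[FamilySpec, ...] = (
        FamilySpec("PL8"),
        FamilySpec("GH88"),
    )
    n_blocks: int = 2
    pathway_archetypes: frozenset[tuple[str, int]] = frozenset(
        {("PL8", 0), ("GH88", 0)}
    )
    label_noise: float = 0.0
    mixed_na_fraction: float = 0.0
    protein_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 1 <= self.n_blocks <= self.n_species:
            raise ValueError("n_blocks must be in [1, n_species]")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must be in [0, 1]")
        if not 0 <= self.mixed_na_fraction <= 1:
            raise ValueError("mixed_na_fraction must be in [0, 1]")
        tags = {f.tag for f in self.families}
        if len(tags) != len(self.families):
            raise ValueError("family tags must be unique")
        for fam_tag, idx in self.pathway_archetypes:
            spec = next((f for f in self.families if f.tag == fam_tag), None)
            if spec is None:
                raise ValueError(f"pathway archetype references unknown family {fam_tag}")
            if not 0 <= idx < spec.n_archetypes:
                raise ValueError(f"pathway archetype index {idx} out of range for {fam_tag}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["families"] = [asdict(f) for f in self.families]
        d["pathway_archetypes"] = sorted(self.pathway_archetypes)
        return d


@dataclass
class SimulatedDataset:
    """In-memory synthetic dataset plus its ground truth."""

    config: SimulationConfig
    records: dict[str, list[SequenceRecord]]  # family tag -> records
    archetypes: dict[str, list[str]]  # family tag -> archetype residues
    block_content: dict[int, set[tuple[str, int]]]  # block -> archetype set
    labels: PhenotypeLabels
    truth: pd.DataFrame  # species, block, true_phenotype, emitted_label

    @property
    def species(self) -> list[str]:
        return list(self.truth["species"])

    def write(self, out_dir: str | Path) -> None:
        """Persist family FASTAs, the label TSV, the truth table and a
        manifest echoing the resolved configuration."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for family, records in self.records.items():
            write_fasta(records, out / f"{family}.fasta")
        with open(out / "labels.tsv", "w") as fh:
            fh.write("species\tlabel\n")
            for sp in self.species:
                fh.write(f"{sp}\t{self.labels.label_of(sp)}\n")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2, default=str)
            fh.write("\n")


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Uniform random residue string over the 20 standard amino acids."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_to_identity(
    seq: str, target_identity_pct: float, rng: np.random.Generator
) -> str:
    """Substitute exactly ``round(L * (1 - t/100))`` positions of ``seq``.

    Substitution-only, so the global identity of the mutant to ``seq``
    equals the realized substitution fraction exactly.
    """
    if not 0 < target_identity_pct <= 100:
        raise ValueError("target_identity_pct must be in (0, 100]")
    L = len(seq)
    n_sub = round(L * (1 - target_identity_pct / 100))
    if n_sub == 0:
        return seq
    positions = rng.choice(L, size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _draw_archetypes(
    spec: FamilySpec, length: int, rng: np.random.Generator
) -> list[str]:
    """Rejection-sample mutually dissimilar archetype sequences."""
    archetypes: list[str] = []
    attempts = 0
    while len(archetypes) < spec.n_archetypes:
        candidate = random_protein(length, rng)
        attempts += 1
        if attempts > _MAX_REJECTIONS:
            raise RuntimeError(
                f"could not draw {spec.n_archetypes} archetypes for {spec.tag} "
                f"below {spec.between_identity_max_pct}% mutual identity; "
                "use longer proteins"
            )
        if all(
            pairwise_identity(candidate, a) <= spec.between_identity_max_pct
            for a in archetypes
        ):
            archetypes.append(candidate)
    return archetypes


def _block_content(config: SimulationConfig) -> dict[int, set[tuple[str, int]]]:
    """Deal archetypes to content blocks; block 0 gets the pathway set."""
    content: dict[int, set[tuple[str, int]]] = {
        b: set() for b in range(config.n_blocks)
    }
    for spec in config.families:
        cursor = 0
        for idx in range(spec.n_archetypes):
            key = (spec.tag, idx)
            if key in config.pathway_archetypes:
                content[0].add(key)
            elif config.n_blocks == 1:
                content[0].add(key)
            else:
                content[1 + cursor % (config.n_blocks - 1)].add(key)
                cursor += 1
    return content


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one multi-species dataset under ``config``.

    A species in block *b* emits, for every archetype in that block's
    content, one ortholog mutated to the family's within-group identity.
    Its true phenotype is Cleaver iff the block carries every pathway
    archetype; the emitted label adds the configured noise and Mixed/NA
    censoring.  Byte-identical output for equal seeds.
    """
    rng = np.random.default_rng(config.seed)
    archetypes = {
        spec.tag: _draw_archetypes(spec, config.protein_length, rng)
        for spec in config.families
    }
    content = _block_content(config)
    species_names = [f"Bacteroides sim{i:03d}" for i in range(config.n_species)]
    blocks = [i % config.n_blocks for i in range(config.n_species)]

    true_phenotype = [
        CLEAVER if config.pathway_archetypes <= content[b] else NONCLEAVER
        for b in blocks
    ]

    emitted = list(true_phenotype)
    if config.label_noise > 0:
        flip = rng.random(config.n_species) < config.label_noise
        for i in np.flatnonzero(flip):
            emitted[i] = NONCLEAVER if emitted[i] == CLEAVER else CLEAVER
    n_censored = round(config.mixed_na_fraction * config.n_species)
    censored = rng.choice(config.n_species, size=n_censored, replace=False)
    for j, i in enumerate(sorted(censored)):
        emitted[i] = MIXED if j % 2 == 0 else NA

    within = {spec.tag: spec.within_identity_pct for spec in config.families}
    records: dict[str, list[SequenceRecord]] = {
        spec.tag: [] for spec in config.families
    }
    for i, (sp, b) in enumerate(zip(species_names, blocks)):
        for fam_tag, idx in sorted(content[b]):
            mutant = mutate_to_identity(archetypes[fam_tag][idx], within[fam_tag], rng)
            records[fam_tag].append(
                SequenceRecord(
                    id=f"sim{i:03d}|{fam_tag}a{idx}",
                    residues=mutant,
                    species=sp,
                    family=fam_tag,
                    description=sp,
                )
            )

    truth = pd.DataFrame(
        {
            "species": species_names,
            "block": blocks,
            "true_phenotype": true_phenotype,
            "emitted_label": emitted,
        }
    )
    labels = PhenotypeLabels(dict(zip(species_names, emitted)))
    return SimulatedDataset(
        config=config,
        records=records,
        archetypes=archetypes,
        block_content=content,
        labels=labels,
        truth=truth,
    )


def simulate_strain_proteomes(
    references: Sequence[SequenceRecord],
    n_strains: int,
    identity_pct: float,
    dropout_prob: float,
    rng: np.random.Generator,
    decoys_per_strain: int = 5,
    decoy_length: int | None = None,
) -> tuple[dict[str, list[SequenceRecord]], pd.DataFrame]:
    """Strain proteomes diverged from reference proteins.

    Each strain carries every reference mutated to ``identity_pct`` unless
    dropped with probability ``dropout_prob``, plus random decoy proteins.
    Returns (strain id -> records, truth table with a ``present`` flag per
    (strain, query)).
    """
    if not references:
        raise ValueError("at least one reference protein required")
    if not 0 < identity_pct <= 100:
        raise ValueError("identity_pct must be in (0, 100]")
    if not 0 <= dropout_prob <= 1:
        raise ValueError("dropout_prob must be in [0, 1]")
    if decoy_length is None:
        decoy_length = round(np.mean([len(r.residues) for r in references]))
    proteomes: dict[str, list[SequenceRecord]] = {}
    truth_rows = []
    for s in range(n_strains):
        strain = f"strain{s:03d}"
        members: list[SequenceRecord] = []
        for ref in references:
            present = rng.random() >= dropout_prob
            truth_rows.append(
                {"strain_id": strain, "query_id": ref.id, "present": present}
            )
            if not present:
                continue
            members.append(
                SequenceRecord(
                    id=f"{strain}_{ref.id}",
                    residues=mutate_to_identity(ref.residues, identity_pct, rng),
                    species=ref.species,
                    strain=strain,
                    family=ref.family,
                )
            )
        for d in range(decoys_per_strain):
            members.append(
                SequenceRecord(
                    id=f"{strain}_decoy{d:02d}",
                    residues=random_protein(decoy_length, rng),
                    strain=strain,
                )
            )
        proteomes[strain] = members
    return proteomes, pd.DataFrame(truth_rows)


def simulate_quant_table(
    n_proteins: int,
    n_true_de: int,
    log2fc_effect: float,
    n_replicates: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Protein quantification table with a known true DE set.

    Per protein, ``n_replicates`` log2 intensities are drawn per condition
    from normal distributions with equal means (null proteins) or means
    separated by ``log2fc_effect`` (true DE proteins, alternating sign).
    The reported ``log2fc`` is the difference of condition means and
    ``pvalue`` comes from Welch's two-sample t-test.
    """
    if n_true_de > n_proteins:
        raise ValueError("n_true_de must not exceed n_proteins")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rows = []
    for i in range(n_proteins):
        is_de = i < n_true_de
        direction = 1 if i % 2 == 0 else -1
        base = rng.uniform(20, 30)
        shift = log2fc_effect * direction if is_de else 0.0
        a = rng.normal(base, noise_sd, size=n_replicates)
        b = rng.normal(base + shift, noise_sd, size=n_replicates)
        stat = stats.ttest_ind(b, a, equal_var=False)
        rows.append(
            {
                "protein_id": f"prot{i:05d}",
                "log2fc": float(np.mean(b) - np.mean(a)),
                "pvalue": float(stat.pvalue),
                "true_de": is_de,
                "true_direction": "up" if is_de and direction > 0 else
                                  ("down" if is_de else "none"),
            }
        )
    return pd.DataFrame(rows)
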