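"""Synthetic phage communities with known ground truth.

Real gene-sharing analyses start from a database of phage genomes, each
annotated with the protein families it encodes.  This module fabricates such a
community with a *planted* structure — clusters of genomes sharing core
families, cluster-specific accessory families, per-genome background
singletons, and designated mosaic genomes that draw core families from several
clusters — so that every downstream stage (family clustering, Sig-score
network, Markov clustering, membership) can be tested against a known answer.

The generator also emits protein sequences (per-family ancestors mutated to a
target identity) and whole genome sequences with planted direct terminal
repeats, feeding the sequence-level stages of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "SimConfig",
    "Proteome",
    "PlantedTruth",
    "SequenceSet",
    "generate_community",
    "generate_sequences",
    "generate_genome",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a planted-partition phage community.

    ``n_clusters`` clusters of ``genomes_per_cluster`` genomes each; every
    member of a cluster carries all of that cluster's ``core_families_per_cluster``
    core families, each of its ``accessory_families_per_cluster`` accessory
    families independently with probability ``accessory_carry_prob``, and
    ``background_families_per_genome`` private singleton families.  ``n_mosaic``
    extra genomes draw each cluster's core families with probability given by
    ``mosaic_mixture`` (one proportion per cluster, summing to 1).
    """

    n_clusters: int
    genomes_per_cluster: int
    core_families_per_cluster: int
    accessory_families_per_cluster: int = 0
    accessory_carry_prob: float = 0.5
    background_families_per_genome: int = 0
    n_mosaic: int = 0
    mosaic_mixture: Tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_clusters",
            "genomes_per_cluster",
            "core_families_per_cluster",
            "accessory_families_per_cluster",
            "background_families_per_genome",
            "n_mosaic",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.accessory_carry_prob <= 1.0:
            raise ValueError("accessory_carry_prob must lie in [0, 1]")
        if self.n_mosaic > 0:
            if len(self.mosaic_mixture) != self.n_clusters:
                raise ValueError(
                    "mosaic_mixture must have one proportion per cluster "
                    f"({self.n_clusters}), got {len(self.mosaic_mixture)}"
                )
            if any(p < 0 for p in self.mosaic_mixture):
                raise ValueError("mosaic_mixture proportions must be >= 0")
            if abs(sum(self.mosaic_mixture) - 1.0) > 1e-9:
                raise ValueError(
                    f"mosaic_mixture must sum to 1, got {sum(self.mosaic_mixture)!r}"
                )


@dataclass
class Proteome:
    """One genome: its identifier and the set of protein families it carries."""

    genome_id: str
    families: Set[str] = field(default_factory=set)


@dataclass
class PlantedTruth:
    """Ground truth of a simulated community.

    ``partition`` maps every genome to its cluster (mosaics to their majority
    cluster); ``mosaic_ids`` flags the mosaics; ``family_origin`` maps each
    family to the cluster that owns it, or ``"background"``.
    """

    partition: Dict[str, str]
    mosaic_ids: Set[str]
    family_origin: Dict[str, str]

    def write_tables(self, genome_path: str | Path, family_path: str | Path) -> None:
        with open(genome_path, "w") as fh:
            fh.write("genome_id\tcluster_id\tis_mosaic\n")
            for g in sorted(self.partition):
                fh.write(f"{g}\t{self.partition[g]}\t{int(g in self.mosaic_ids)}\n")
        with open(family_path, "w") as fh:
            fh.write("family_id\torigin\n")
            for f in sorted(self.family_origin):
                fh.write(f"{f}\t{self.family_origin[f]}\n")


def generate_community(config: SimConfig) -> Tuple[List[Proteome], PlantedTruth]:
    """Draw a community of proteomes with a planted cluster structure.

    Deterministic for a given ``config`` (the seed is part of the config).
    Returns the proteomes and the planted truth.  ``n_clusters == 0`` yields
    an empty community.
    """
    rng = np.random.default_rng(config.seed)
    proteomes: List[Proteome] = []
    partition: Dict[str, str] = {}
    mosaic_ids: Set[str] = set()
    family_origin: Dict[str, str] = {}

    core: Dict[str, List[str]] = {}
    accessory: Dict[str, List[str]] = {}
    cluster_ids = [f"C{k + 1}" for k in range(config.n_clusters)]
    for cid in cluster_ids:
        core[cid] = [f"{cid}.core.{i}" for i in range(config.core_families_per_cluster)]
        accessory[cid] = [
            f"{cid}.acc.{i}" for i in range(config.accessory_families_per_cluster)
        ]
        for fam in core[cid] + accessory[cid]:
            family_origin[fam] = cid

    n_background = 0

    def next_background(n: int) -> List[str]:
        nonlocal n_background
        fams = [f"bg.{n_background + i:04d}" for i in range(n)]
        n_background += n
        for fam in fams:
            family_origin[fam] = "background"
        return fams

    for cid in cluster_ids:
        for g in range(config.genomes_per_cluster):
            gid = f"{cid}.g{g + 1:02d}"
            fams = set(core[cid])
            if accessory[cid]:
                keep = rng.random(len(accessory[cid])) < config.accessory_carry_prob
                fams.update(f for f, k in zip(accessory[cid], keep) if k)
            fams.update(next_background(config.background_families_per_genome))
            proteomes.append(Proteome(gid, fams))
            partition[gid] = cid

    if config.n_mosaic > 0 and config.n_clusters > 0:
        mixture = np.asarray(config.mosaic_mixture, dtype=float)
        for m in range(config.n_mosaic):
            gid = f"mosaic.g{m + 1:02d}"
            fams: Set[str] = set()
            counts = np.zeros(config.n_clusters)
            for k, cid in enumerate(cluster_ids):
                if not core[cid]:
                    continue
                keep = rng.random(len(core[cid])) < mixture[k]
                chosen = [f for f, kp in zip(core[cid], keep) if kp]
                fams.update(chosen)
                counts[k] = len(chosen)
            fams.update(next_background(config.background_families_per_genome))
            # majority cluster: largest realized draw, mixture weight breaks ties
            order = sorted(
                range(config.n_clusters),
                key=lambda k: (-counts[k], -mixture[k], k),
            )
            proteomes.append(Proteome(gid, fams))
            partition[gid] = cluster_ids[order[0]]
            mosaic_ids.add(gid)

    return proteomes, PlantedTruth(partition, mosaic_ids, family_origin)


@dataclass
class SequenceSet:
    """Protein sequences emitted for a community, with their true family map."""

    sequences: Dict[str, str]
    family_of: Dict[str, str]
    genome_of: Dict[str, str]

    def write_fasta(self, path: str | Path) -> None:
        """One record per protein, header ``genomeID|proteinID``."""
        with open(path, "w") as fh:
            for pid in sorted(self.sequences):
                fh.write(f">{self.genome_of[pid]}|{pid}\n{self.sequences[pid]}\n")

    def write_family_map(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tfamily_id\n")
            for pid in sorted(self.family_of):
                fh.write(f"{pid}\t{self.family_of[pid]}\n")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each residue with probability ``rate`` by a different one."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_sequences(
    proteomes: Sequence[Proteome],
    target_identity: float = 0.9,
    seed: int = 0,
    min_length: int = 150,
    max_length: int = 400,
) -> SequenceSet:
    """Emit one protein sequence per (genome, family) membership.

    Each family gets a random ancestor (uniform over the 20 standard residues,
    length uniform in [min_length, max_length]); each member sequence is the
    ancestor with point substitutions bringing it to approximately
    ``target_identity`` versus the ancestor.  Two members of the same family
    then share an expected pairwise identity of t^2 + (1-t)^2/19, well above
    the ~1/20 background between unrelated families.
    """
    if not 0.3 <= target_identity <= 1.0:
        raise ValueError(
            f"target_identity must lie in [0.3, 1.0], got {target_identity}"
        )
    rng = np.random.default_rng(seed)
    families = sorted({f for p in proteomes for f in p.families})
    ancestors: Dict[str, str] = {}
    for fam in families:
        length = int(rng.integers(min_length, max_length + 1))
        ancestors[fam] = "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length)
        )
    sequences: Dict[str, str] = {}
    family_of: Dict[str, str] = {}
    genome_of: Dict[str, str] = {}
    rate = 1.0 - target_identity
    for prot in proteomes:
        for j, fam in enumerate(sorted(prot.families)):
            pid = f"{prot.genome_id}.p{j + 1:03d}"
            sequences[pid] = _mutate(rng, ancestors[fam], rate)
            family_of[pid] = fam
            genome_of[pid] = prot.genome_id
    return SequenceSet(sequences, family_of, genome_of)


def generate_genome(
    length: int, dtr_length: int = 0, gc: float = 0.5, seed: int = 0
) -> str:
    """Random linear dsDNA with a planted exact direct terminal repeat.

    Per-base composition: Bernoulli(gc) between {G, C} and {A, T}, each strand
    base equiprobable within its class; the first ``dtr_length`` bases are then
    copied over the last ``dtr_length``, planting an exact terminal repeat.
    """
    if not 0 < gc < 1:
        raise ValueError(f"gc must lie in (0, 1), got {gc}")
    if dtr_length < 0 or dtr_length > length // 2:
        raise ValueError(
            f"dtr_length must lie in [0, length/2] = [0, {length // 2}], got {dtr_length}"
        )
    rng = np.random.default_rng(seed)
    is_gc = rng.random(length) < gc
    pick = rng.integers(0, 2, length)
    bases = np.where(is_gc, np.where(pick == 0, "G", "C"), np.where(pick == 0, "A", "T"))
    seq = bases.tolist()
    if dtr_length:
        seq[length - dtr_length :] = seq[:dtr_length]
    return "".join(seq)


def write_genome_fasta(seq: str, path: str | Path, name: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
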