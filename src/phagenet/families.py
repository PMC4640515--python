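"""Protein-family assignment and the genome x family profile matrix.

Families are built from pairwise similarity evidence: either an external
12-column BLAST tabular file, or the built-in scorer (`score_pairs`), which
seeds candidate pairs on shared 4-mers, aligns them locally and converts the
score to a BLAST-like surrogate E-value via the Karlin-Altschul relation
E = K * m * n * exp(-lambda * S).  Proteins with a qualifying hit to a
reference family adopt it (best hit); the rest are clustered de novo by
single linkage (connected components under the E-value cutoff), singletons
becoming their own families.  The profile matrix records presence/absence of
each family in each genome and is the input to the Sig-score network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .compgen import align_local
from .simulate import AMINO_ACIDS, Proteome

# Karlin-Altschul parameters for gapped BLOSUM62 (BLASTp defaults)
KA_K = 0.041
KA_LAMBDA = 0.267
SEED_K = 4

__all__ = [
    "SimilarityEdge",
    "FamilyAssignment",
    "ProfileMatrix",
    "parse_blast_tab",
    "score_pairs",
    "build_families",
    "build_profile",
    "profile_from_proteomes",
    "read_fasta",
]


@dataclass(frozen=True)
class SimilarityEdge:
    """One pairwise similarity hit (a BLAST tabular row, self-hits removed)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float


@dataclass
class FamilyAssignment:
    """protein -> family map plus per-family size and provenance."""

    family_of: Dict[str, str]
    provenance: Dict[str, str] = field(default_factory=dict)

    @property
    def sizes(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for fam in self.family_of.values():
            out[fam] = out.get(fam, 0) + 1
        return out

    @property
    def n_families(self) -> int:
        return len(set(self.family_of.values()))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tfamily_id\tprovenance\n")
            for pid in sorted(self.family_of):
                fam = self.family_of[pid]
                fh.write(f"{pid}\t{fam}\t{self.provenance.get(fam, 'de novo')}\n")


class ProfileMatrix:
    """Binary genomes x families presence/absence matrix."""

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("profile entries must be 0/1")
        if (values.sum(axis=1) == 0).any():
            empty = data.index[values.sum(axis=1) == 0].tolist()
            raise ValueError(f"genomes with no families: {empty}")
        self.data = data.astype(np.int8)

    @property
    def genomes(self) -> List[str]:
        return list(self.data.index)

    @property
    def families(self) -> List[str]:
        return list(self.data.columns)

    @property
    def n_families(self) -> int:
        return self.data.shape[1]

    def repertoire_sizes(self) -> np.ndarray:
        return self.data.to_numpy().sum(axis=1)

    def shared_counts(self) -> np.ndarray:
        m = self.data.to_numpy()
        return m @ m.T

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="genome_id")

    def write_triplets(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\tfamily_id\tpresent\n")
            rows, cols = np.nonzero(self.data.to_numpy())
            for r, c in zip(rows, cols):
                fh.write(f"{self.data.index[r]}\t{self.data.columns[c]}\t1\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ProfileMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def read_fasta(path: str | Path) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Read protein FASTA with ``genomeID|proteinID`` headers.

    Returns (sequences by protein id, protein id -> genome id).  Headers
    without a ``|`` are treated as bare protein ids with an unknown genome
    equal to the protein id.
    """
    sequences: Dict[str, str] = {}
    genome_of: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                header = line[1:].split()[0]
                if "|" in header:
                    genome, name = header.split("|", 1)
                else:
                    genome = name = header
                genome_of[name] = genome
                chunks = []
            else:
                chunks.append(line)
        if name is not None:
            sequences[name] = "".join(chunks)
    return sequences, genome_of


def parse_blast_tab(path: str | Path) -> List[SimilarityEdge]:
    """Parse 12-column BLAST tabular output (outfmt 6), dropping self-hits.

    Raises ``ValueError`` naming the first line with a wrong column count or
    unparseable numeric field; an empty file yields an empty list with a
    warning.
    """
    edges: List[SimilarityEdge] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                edge = SimilarityEdge(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row: {exc}") from exc
            if edge.query_id == edge.subject_id:
                continue
            edges.append(edge)
    if not edges:
        warnings.warn(f"{path}: no similarity edges parsed", stacklevel=2)
    return edges


def _kmer_candidates(
    sequences: Mapping[str, str], k: int, min_shared: int
) -> List[Tuple[str, str]]:
    """Unordered id pairs sharing >= min_shared distinct exact k-mers.

    A single chance k-mer hit between unrelated sequences is common (for two
    300-mers, P ~ 0.5 at k=4), so candidate pairs must share several distinct
    seeds — homologs at the identities this pipeline targets share dozens.
    """
    index: Dict[str, List[str]] = {}
    for pid, seq in sequences.items():
        for kmer in {seq[i : i + k] for i in range(len(seq) - k + 1)}:
            index.setdefault(kmer, []).append(pid)
    counts: Dict[Tuple[str, str], int] = {}
    for ids in index.values():
        if len(ids) < 2:
            continue
        ids = sorted(ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pair = (ids[i], ids[j])
                counts[pair] = counts.get(pair, 0) + 1
    return sorted(p for p, n in counts.items() if n >= min_shared)


def _clean(seq: str) -> str:
    return "".join(c if c in AMINO_ACIDS else "X" for c in seq.upper())


def score_pairs(
    sequences: Mapping[str, str],
    k: int = SEED_K,
    min_seed_hits: int = 4,
    ka_k: float = KA_K,
    ka_lambda: float = KA_LAMBDA,
) -> List[SimilarityEdge]:
    """All-vs-all similarity scoring with a k-mer prefilter.

    Pairs sharing >= ``min_seed_hits`` distinct ``k``-mers are aligned
    locally (BLOSUM62, affine gaps) and reported symmetrically once per
    unordered pair, with the surrogate E-value E = K*m*n*exp(-lambda*S).
    Residues outside the 20 standard amino acids are mapped to 'X' with a
    warning.
    """
    if len(sequences) < 2:
        raise ValueError("score_pairs needs at least 2 sequences")
    cleaned: Dict[str, str] = {}
    dirty = []
    for pid, seq in sequences.items():
        c = _clean(seq)
        if c != seq.upper():
            dirty.append(pid)
        cleaned[pid] = c
    if dirty:
        warnings.warn(
            f"non-standard residues mapped to 'X' in {len(dirty)} sequence(s)",
            stacklevel=2,
        )
    edges: List[SimilarityEdge] = []
    for qid, sid in _kmer_candidates(cleaned, k, min_seed_hits):
        a, b = cleaned[qid], cleaned[sid]
        res = align_local(a, b)
        if res.alignment_length == 0:
            continue
        evalue = ka_k * len(a) * len(b) * math.exp(-ka_lambda * res.score)
        edges.append(
            SimilarityEdge(
                query_id=qid,
                subject_id=sid,
                percent_identity=res.identity,
                alignment_length=res.alignment_length,
                evalue=evalue,
                bitscore=(ka_lambda * res.score - math.log(ka_k)) / math.log(2),
            )
        )
    return edges


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_families(
    edges: Sequence[SimilarityEdge],
    evalue_threshold: float = 1e-4,
    reference_map: Optional[Mapping[str, str]] = None,
    proteins: Optional[Iterable[str]] = None,
) -> FamilyAssignment:
    """Assign proteins to families from similarity edges.

    Order of precedence mirrors a reference-database-first workflow:

    1. proteins listed in ``reference_map``, or hitting a mapped protein with
       ``evalue < evalue_threshold``, adopt the reference family of their best
       (lowest E-value, then highest bitscore, then lexicographic subject) hit;
    2. remaining proteins are clustered by single linkage over qualifying
       edges (de novo families);
    3. proteins with no qualifying edge become singleton families.

    ``proteins`` optionally supplies the full protein universe so that
    proteins absent from every edge still receive singleton families.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be > 0")
    universe = set(proteins) if proteins is not None else set()
    for e in edges:
        universe.add(e.query_id)
        universe.add(e.subject_id)

    family_of: Dict[str, str] = {}
    provenance: Dict[str, str] = {}

    if reference_map:
        best: Dict[str, Tuple[float, float, str]] = {}
        for pid in universe:
            if pid in reference_map:
                family_of[pid] = reference_map[pid]
                provenance[reference_map[pid]] = "reference"
        for e in edges:
            for qid, sid in ((e.query_id, e.subject_id), (e.subject_id, e.query_id)):
                if qid in family_of or sid not in reference_map:
                    continue
                if e.evalue >= evalue_threshold:
                    continue
                key = (e.evalue, -e.bitscore, sid)
                if qid not in best or key < best[qid]:
                    best[qid] = key
        for qid, (_, _, sid) in best.items():
            family_of[qid] = reference_map[sid]
            provenance[reference_map[sid]] = "reference"

    uf = _UnionFind()
    remaining = universe - set(family_of)
    for pid in remaining:
        uf.find(pid)
    for e in edges:
        if e.evalue >= evalue_threshold:
            continue
        if e.query_id in remaining and e.subject_id in remaining:
            uf.union(e.query_id, e.subject_id)

    components: Dict[str, List[str]] = {}
    for pid in remaining:
        components.setdefault(uf.find(pid), []).append(pid)
    # deterministic naming: order components by their smallest member id
    ordered = sorted(components.values(), key=lambda mem: min(mem))
    width = max(4, len(str(len(ordered))))
    for i, members in enumerate(ordered, start=1):
        fam = f"F{i:0{width}d}"
        provenance[fam] = "de novo"
        for pid in members:
            family_of[pid] = fam
    return FamilyAssignment(family_of, provenance)


def build_profile(
    assignment: FamilyAssignment, genome_of: Mapping[str, str]
) -> ProfileMatrix:
    """Binary genome x family matrix: 1 iff the genome has >= 1 member protein."""
    missing = [p for p in assignment.family_of if p not in genome_of]
    if missing:
        raise ValueError(f"proteins with unknown genome: {sorted(missing)[:5]}")
    genomes = sorted(set(genome_of[p] for p in assignment.family_of))
    fams = sorted(set(assignment.family_of.values()))
    mat = pd.DataFrame(0, index=genomes, columns=fams, dtype=np.int8)
    for pid, fam in assignment.family_of.items():
        mat.loc[genome_of[pid], fam] = 1
    return ProfileMatrix(mat)


def profile_from_proteomes(proteomes: Sequence[Proteome]) -> ProfileMatrix:
    """Profile matrix directly from family-annotated proteomes."""
    genomes = sorted(p.genome_id for p in proteomes)
    fams = sorted({f for p in proteomes for f in p.families})
    mat = pd.DataFrame(0, index=genomes, columns=fams, dtype=np.int8)
    for p in proteomes:
        for f in p.families:
            mat.loc[p.genome_id, f] = 1
    return ProfileMatrix(mat)
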