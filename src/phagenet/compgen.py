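"""Pairwise comparative genomics and small genome utilities.

Covers the ORF-level comparison of a phage genome against its relatives:
local protein alignment (Smith-Waterman scoring, BLOSUM62 with BLASTp-default
affine gaps), reciprocal-best-hit (RBH) ORF pairing, per-genome-pair identity
statistics, GC content, and exact direct-terminal-repeat (DTR) detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "AlignmentResult",
    "GenomeSimilarity",
    "align_local",
    "rbh_pairs",
    "genome_similarity_matrix",
    "gc_content",
    "detect_dtr",
    "translate_orfs",
]

# gap open 11 / extend 1 in BLAST terms: a gap of length k costs 11 + k
_aligner = Align.PairwiseAligner()
_aligner.mode = "local"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -12
_aligner.extend_gap_score = -1

_BLOSUM_ALPHABET = set(_aligner.substitution_matrix.alphabet)


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment summary.

    ``identity`` is percent identities over alignment columns (gap columns
    included in the denominator), the BLAST "pident" convention.  An
    all-negative pair yields the empty alignment: score 0, length 0.
    """

    score: float
    identity: float
    alignment_length: int
    positives: float = 0.0
    query_span: Tuple[int, int] = (0, 0)
    subject_span: Tuple[int, int] = (0, 0)


def _sanitize(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - _BLOSUM_ALPHABET
    if bad:
        seq = "".join(c if c in _BLOSUM_ALPHABET else "X" for c in seq)
    return seq


def align_local(seq_a: str, seq_b: str) -> AlignmentResult:
    """Optimal local alignment of two protein sequences.

    Affine-gap Smith-Waterman under BLOSUM62 with BLASTp-default penalties
    (open 11, extend 1).  Deterministic: of the co-optimal alignments the
    first in Biopython's canonical traceback order is reported.
    """
    a = _sanitize(seq_a, "query")
    b = _sanitize(seq_b, "subject")
    alignments = _aligner.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(score=0.0, identity=0.0, alignment_length=0)
    aln = alignments[0]
    counts = aln.counts()
    matrix = _aligner.substitution_matrix
    positives = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(aln.aligned[0], aln.aligned[1]):
        for qa, sb in zip(a[qs:qe], b[ss:se]):
            if matrix[qa, sb] > 0:
                positives += 1
    aligned_cols = counts.identities + counts.mismatches
    length = aligned_cols + counts.gaps
    qspan = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    sspan = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    return AlignmentResult(
        score=float(aln.score),
        identity=100.0 * counts.identities / length,
        alignment_length=int(length),
        positives=100.0 * positives / length,
        query_span=qspan,
        subject_span=sspan,
    )


@dataclass
class GenomeSimilarity:
    """Identity statistics over the RBH ORF pairs of one genome pair."""

    genome_a: str
    genome_b: str
    pairs: List[Tuple[str, str, float, float, int]]  # orfA, orfB, identity, score, len

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def mean_identity(self) -> float:
        if not self.pairs:
            return 0.0
        return float(np.mean([p[2] for p in self.pairs]))

    @property
    def min_identity(self) -> float:
        return min((p[2] for p in self.pairs), default=0.0)

    @property
    def max_identity(self) -> float:
        return max((p[2] for p in self.pairs), default=0.0)


def rbh_pairs(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    min_identity: float = 0.0,
    min_score: float = 1.0,
) -> List[Tuple[str, str, float, float, int]]:
    """Reciprocal best hits between two ORF sets.

    (a, b) is kept iff b is a's best-scoring hit in B and vice versa; score
    ties break to the lexicographically smaller id, making the pairing
    one-to-one and deterministic.  Returns tuples
    (orfA, orfB, identity%, score, alignment_length).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    results: Dict[Tuple[str, str], AlignmentResult] = {}
    for aid in proteome_a:
        for bid in proteome_b:
            res = align_local(proteome_a[aid], proteome_b[bid])
            if res.score >= min_score and res.identity >= min_identity:
                results[(aid, bid)] = res

    def best(hits: List[Tuple[str, float]]) -> Optional[str]:
        if not hits:
            return None
        return min(hits, key=lambda t: (-t[1], t[0]))[0]

    best_in_b = {
        aid: best([(bid, r.score) for (a, bid), r in results.items() if a == aid])
        for aid in proteome_a
    }
    best_in_a = {
        bid: best([(aid, r.score) for (aid, b), r in results.items() if b == bid])
        for bid in proteome_b
    }
    out = []
    for aid in sorted(proteome_a):
        bid = best_in_b.get(aid)
        if bid is not None and best_in_a.get(bid) == aid:
            r = results[(aid, bid)]
            out.append((aid, bid, r.identity, r.score, r.alignment_length))
    return out


def genome_similarity_matrix(
    proteomes: Mapping[str, Mapping[str, str]],
) -> Dict[Tuple[str, str], GenomeSimilarity]:
    """All-pairs RBH identity statistics over a set of genomes.

    ``proteomes`` maps genome id -> {orf id -> protein sequence}.  The result
    is symmetric; the diagonal pairs every ORF with itself at 100% identity.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least 2 proteomes")
    genomes = sorted(proteomes)
    out: Dict[Tuple[str, str], GenomeSimilarity] = {}
    for i, ga in enumerate(genomes):
        self_pairs = [
            (o, o, 100.0, align_local(s, s).score, len(s))
            for o, s in sorted(proteomes[ga].items())
        ]
        out[(ga, ga)] = GenomeSimilarity(ga, ga, self_pairs)
        for gb in genomes[i + 1 :]:
            pairs = rbh_pairs(proteomes[ga], proteomes[gb])
            out[(ga, gb)] = GenomeSimilarity(ga, gb, pairs)
            out[(gb, ga)] = GenomeSimilarity(
                gb, ga, [(b, a, ident, sc, ln) for (a, b, ident, sc, ln) in pairs]
            )
    return out


def similarity_table(
    matrix: Mapping[Tuple[str, str], GenomeSimilarity],
) -> pd.DataFrame:
    """Square DataFrame of mean RBH identities (diagonal 100)."""
    genomes = sorted({g for g, _ in matrix})
    df = pd.DataFrame(0.0, index=genomes, columns=genomes)
    for (ga, gb), sim in matrix.items():
        df.loc[ga, gb] = sim.mean_identity
    return df


def gc_content(sequence: str) -> float:
    """GC percentage over unambiguous bases, to 2 decimals.

    Ambiguity codes (anything outside ACGT, case-insensitive) are excluded
    from both numerator and denominator.
    """
    if not sequence:
        raise ValueError("sequence is empty")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return round(100.0 * gc / (gc + at), 2)


def detect_dtr(sequence: str, min_len: int = 20) -> int:
    """Length of the longest exact direct terminal repeat.

    Largest L with min_len <= L <= len/2 such that the first L bases equal
    the last L bases; 0 if no such L exists.  Exact matching only.
    """
    n = len(sequence)
    if n < 2 * min_len:
        raise ValueError(f"sequence length {n} < 2*min_len = {2 * min_len}")
    for L in range(n // 2, min_len - 1, -1):
        if sequence[:L] == sequence[n - L :]:
            return L
    return 0


def translate_orfs(
    genome: str, features: Sequence[Tuple[str, int, int, str]]
) -> Dict[str, str]:
    """Translate ORF coordinates to protein sequences (standard code).

    ``features`` are (orf_id, start, end, strand) with 1-based inclusive
    coordinates as in GFF3 and strand '+'/'-'.  The trailing stop is removed;
    an internal stop is a hard failure naming the feature.
    """
    out: Dict[str, str] = {}
    for orf_id, start, end, strand in features:
        sub = Seq(genome[start - 1 : end])
        if strand == "-":
            sub = sub.reverse_complement()
        prot = str(sub.translate())
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            raise ValueError(f"internal stop codon in feature {orf_id}")
        out[orf_id] = prot
    return out


def read_gff3_cds(path: str | Path) -> List[Tuple[str, int, int, str]]:
    """Minimal GFF3 reader returning (id, start, end, strand) for CDS features."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2].lower() != "cds":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            fid = attrs.get("ID", attrs.get("Name", f"cds_{len(feats) + 1}"))
            feats.append((fid, int(cols[3]), int(cols[4]), cols[6]))
    return feats
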