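"""Protein similarity search against a family-labelled reference registry.

Candidate lipolytic proteins are confirmed by searching against a reference
set of family-labelled sequences.  The search is exact affine-gap
Smith-Waterman local alignment (no word-seeded heuristics) — tractable for
the registry sizes this tool handles — with Karlin-Altschul E-values so the
decision semantics downstream (identity / query-coverage / E-value gates)
mirror those of a BLASTp search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "ReferenceSeq",
    "SimilarityHit",
    "smith_waterman",
    "best_hit",
    "all_hits",
    "read_reference_set",
]


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul constants.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST convention).
    Default constants are the published values for gapped BLOSUM62 with
    open/extend 11/1: lambda = 0.267, K = 0.041.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    matrix: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        if self.matrix is None:
            self.matrix = substitution_matrices.load(self.matrix_name)

    @classmethod
    def simple(
        cls,
        match: float,
        mismatch: float,
        gap_open: float,
        gap_extend: float,
        karlin_lambda: float = 0.267,
        karlin_k: float = 0.041,
    ) -> "ScoringScheme":
        """Toy match/mismatch scheme, mainly for tests and small examples."""
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        n = len(alphabet)
        arr = np.full((n, n), float(mismatch))
        np.fill_diagonal(arr, float(match))
        mat = substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)
        return cls(
            matrix_name=f"simple({match},{mismatch})",
            gap_open=gap_open,
            gap_extend=gap_extend,
            karlin_lambda=karlin_lambda,
            karlin_k=karlin_k,
            matrix=mat,
        )

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # Biopython's open_gap_score applies to the first gapped position, so
        # the BLAST-convention cost open + k*extend maps to open+extend / extend.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class ReferenceSeq:
    seq_id: str
    sequence: str
    family_name: str


@dataclass
class SimilarityHit:
    """Best local-alignment match of a query against one reference target."""

    query_id: str
    target_id: str
    target_family: str
    raw_score: float
    e_value: float
    identity: float
    query_coverage: float


def smith_waterman(
    query: str, target: str, scheme: ScoringScheme | None = None
) -> tuple[float, list[tuple[int, int]], float, float]:
    """Optimal affine-gap local alignment of query vs target.

    Returns (raw_score, aligned index pairs, identity, query_coverage).
    Identity is identical residue pairs over aligned residue-pair columns
    (gapped columns excluded from the denominator); query coverage is the
    aligned query span divided by the query length.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()
    alignments = aligner.align(query, target)
    score = float(alignments.score)
    if score <= 0:
        return 0.0, [], 0.0, 0.0
    aln = alignments[0]
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        pairs.extend(zip(range(qs, qe), range(ts, te)))
    if not pairs:
        return score, [], 0.0, 0.0
    n_ident = sum(query[qi] == target[ti] for qi, ti in pairs)
    identity = n_ident / len(pairs)
    q_span = pairs[-1][0] - pairs[0][0] + 1
    coverage = q_span / len(query)
    return score, pairs, identity, coverage


def _evalue(raw_score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    return float(scheme.karlin_k * m * n * np.exp(-scheme.karlin_lambda * raw_score))


def all_hits(
    query_id: str,
    query: str,
    reference_set: Sequence[ReferenceSeq],
    scheme: ScoringScheme | None = None,
) -> list[SimilarityHit]:
    """Score a query against every reference; no E-value filter applied."""
    if not reference_set:
        raise ValueError("empty reference set")
    scheme = scheme or ScoringScheme()
    hits = []
    for ref in reference_set:
        raw, _pairs, ident, cov = smith_waterman(query, ref.sequence, scheme)
        ev = _evalue(raw, len(query), len(ref.sequence), scheme)
        hits.append(
            SimilarityHit(
                query_id=query_id,
                target_id=ref.seq_id,
                target_family=ref.family_name,
                raw_score=raw,
                e_value=ev,
                identity=ident,
                query_coverage=cov,
            )
        )
    hits.sort(key=lambda h: (h.e_value, -h.raw_score, h.target_id))
    return hits


def best_hit(
    query_id: str,
    query: str,
    reference_set: Sequence[ReferenceSeq],
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-10,
) -> SimilarityHit | None:
    """Lowest-E-value reference hit, or None if all E-values exceed the cutoff.

    Ties on E-value break by higher raw score, then lexicographic target id.
    """
    hits = all_hits(query_id, query, reference_set, scheme)
    top = hits[0]
    if top.e_value > e_cutoff:
        return None
    return top


def read_reference_set(fasta_path: str | Path, map_path: str | Path) -> list[ReferenceSeq]:
    """Load a reference registry: FASTA sequences + TSV (seq_id, family_name)."""
    from Bio import SeqIO

    fam_map = pd.read_csv(map_path, sep="\t", dtype=str)
    if not {"seq_id", "family_name"} <= set(fam_map.columns):
        raise ValueError("reference map TSV needs columns: seq_id, family_name")
    families = dict(zip(fam_map["seq_id"], fam_map["family_name"]))
    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in families:
            raise ValueError(f"reference {rec.id!r} missing from family map")
        refs.append(ReferenceSeq(rec.id, str(rec.seq).upper(), families[rec.id]))
    if not refs:
        raise ValueError(f"no sequences in {fasta_path}")
    return refs


def hits_to_frame(hits: Sequence[SimilarityHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "qseqid": h.query_id,
                "sseqid": h.target_id,
                "family": h.target_family,
                "score": h.raw_score,
                "evalue": h.e_value,
                "pident": h.identity,
                "qcovs": h.query_coverage,
            }
            for h in hits
        ]
    )
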