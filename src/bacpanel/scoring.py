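"""Homology score providers.

The built-in provider is Smith–Waterman local alignment under BLOSUM62 with
affine gaps (open 11, extend 1, BLAST's convention: a gap of length g costs
11 + g), converted to bits with Karlin–Altschul statistics using the standard
gapped parameters for that scoring system (lambda = 0.267, K = 0.041), and an
e-value against the pairwise search space m*n. It is a deterministic,
dependency-free stand-in for an external aligner; adapters with the same
interface can wrap external tools or precomputed hit tables.
"""

from __future__ import annotations

import math
from functools import lru_cache
from pathlib import Path
from typing import Protocol, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

E_VALUE_FLOOR = 1e-300  # clamp to avoid underflow artifacts in ranking


class ScoreProvider(Protocol):
    """Behavioral contract for homology scorers.

    ``pair_score`` returns (bit_score, e_value) for a query/subject pair; ids
    and sequences are both passed so that sequence-based scorers and
    id-keyed hit tables can implement the same interface. A pair with no
    positive-scoring local alignment gets bit_score 0.0.
    """

    def pair_score(
        self, query_id: str, query_seq: str, subject_id: str, subject_seq: str
    ) -> tuple[float, float]: ...

    def coverage(self, query_seq: str, subject_seq: str) -> float: ...


class LocalAlignmentScorer:
    """Smith–Waterman / BLOSUM62 scorer with bit-score conversion."""

    def __init__(
        self,
        matrix: str = "BLOSUM62",
        gap_open: int = 11,
        gap_extend: int = 1,
        lam: float = 0.267,
        k: float = 0.041,
    ) -> None:
        self.lam = lam
        self.k = k
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(matrix)
        # first residue of a gap costs open+extend, as in BLAST
        aligner.open_gap_score = -(gap_open + gap_extend)
        aligner.extend_gap_score = -gap_extend
        self._aligner = aligner

    @lru_cache(maxsize=200_000)
    def _raw(self, a: str, b: str) -> float:
        return float(self._aligner.score(a, b))

    def raw_score(self, query_seq: str, subject_seq: str) -> float:
        # SW with a symmetric matrix is symmetric; canonicalize for the cache
        if subject_seq < query_seq:
            query_seq, subject_seq = subject_seq, query_seq
        return self._raw(query_seq, subject_seq)

    def bits(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.k)) / math.log(2)

    def pair_score(
        self, query_id: str, query_seq: str, subject_id: str, subject_seq: str
    ) -> tuple[float, float]:
        raw = self.raw_score(query_seq, subject_seq)
        if raw <= 0:
            return 0.0, math.inf
        bit = self.bits(raw)
        e_value = len(query_seq) * len(subject_seq) * 2.0 ** (-bit)
        return bit, max(e_value, E_VALUE_FLOOR)

    def coverage(self, query_seq: str, subject_seq: str) -> float:
        """Fraction of the query covered by the best local alignment."""
        if self.raw_score(query_seq, subject_seq) <= 0:
            return 0.0
        aln = self._aligner.align(query_seq, subject_seq)[0]
        covered = sum(int(e - s) for s, e in aln.aligned[0])
        return covered / len(query_seq)

    def family_score(
        self, query_id: str, query_seq: str, family: Sequence[tuple[str, str]]
    ) -> float:
        """Score a query against a sequence family.

        Default family model: the maximum pairwise bit score over family
        members — a deliberate simplification of a profile model, adequate
        when family members are close homologs. Profile-based providers can
        override.
        """
        return max(
            self.pair_score(fid, fseq, query_id, query_seq)[0]
            for fid, fseq in family
        )


class HitTableProvider:
    """Score provider backed by a precomputed (query, subject, bit, e-value,
    coverage) hit table, so externally computed alignments (e.g. BLAST
    tabular output) can be injected in place of the built-in scorer.

    Pairs absent from the table score 0 bits.
    """

    def __init__(self, hits: pd.DataFrame) -> None:
        required = {"query", "subject", "bit_score", "e_value"}
        missing = required - set(hits.columns)
        if missing:
            raise ValueError(f"hit table missing columns: {sorted(missing)}")
        self._by_pair: dict[tuple[str, str], tuple[float, float, float]] = {}
        for row in hits.itertuples(index=False):
            cov = float(getattr(row, "coverage", 0.0))
            self._by_pair[(str(row.query), str(row.subject))] = (
                float(row.bit_score),
                max(float(row.e_value), E_VALUE_FLOOR),
                cov,
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HitTableProvider":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def pair_score(
        self, query_id: str, query_seq: str, subject_id: str, subject_seq: str
    ) -> tuple[float, float]:
        bit, e_value, _ = self._by_pair.get((query_id, subject_id), (0.0, math.inf, 0.0))
        return bit, e_value

    def coverage(self, query_seq: str, subject_seq: str) -> float:
        return 0.0

    def family_score(
        self, query_id: str, query_seq: str, family: Sequence[tuple[str, str]]
    ) -> float:
        return max(
            self.pair_score(fid, fseq, query_id, query_seq)[0] for fid, fseq in family
        )
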