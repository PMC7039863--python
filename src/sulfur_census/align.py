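"""Pairwise protein alignment helpers shared by clustering, verification and taxonomy.

Two alignment flavours are used:

* semi-global — the shorter sequence is aligned end to end onto the longer
  one (overhangs of the longer sequence are free). This is the basis for the
  identity/coverage test used in gene-catalog clustering.
* local — Smith–Waterman score, used to decide which reference (ratified
  positive vs different-function negative) a candidate gene most closely
  resembles, and to generate taxonomy hits.

Both use BLOSUM62 with affine gaps (open -11, extend -1), the standard
protein-search parameterisation.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

from Bio import Align
from Bio.Align import substitution_matrices

GAP_OPEN = -11.0
GAP_EXTEND = -1.0

# Karlin-Altschul parameters for gapped BLOSUM62 (BLAST defaults); used to
# express raw local scores as bits / crude E-values for taxonomy hit lists.
KA_LAMBDA = 0.267
KA_K = 0.041


@lru_cache(maxsize=None)
def _semiglobal_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aligner.mode = "global"
    # free end gaps on the query row: the shorter sequence floats inside the longer
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


@lru_cache(maxsize=None)
def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aligner.mode = "local"
    return aligner


class IdentityCoverage(NamedTuple):
    identity: float
    coverage: float


def identity_coverage(seq_a: str, seq_b: str) -> IdentityCoverage:
    """Identity over the aligned region and coverage of the shorter sequence.

    The shorter sequence is semi-globally aligned onto the longer one.
    Identity is the fraction of aligned residue pairs that are identical;
    coverage is the fraction of the shorter sequence's residues that are
    aligned to residues of the longer one.
    """
    short, long_ = sorted((seq_a, seq_b), key=len)
    if not short or not long_:
        return IdentityCoverage(0.0, 0.0)
    alignment = _semiglobal_aligner().align(long_, short)[0]
    paired = 0
    identical = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        paired += t1 - t0
        for i in range(t1 - t0):
            if long_[t0 + i] == short[q0 + i]:
                identical += 1
    if paired == 0:
        return IdentityCoverage(0.0, 0.0)
    return IdentityCoverage(identical / paired, paired / len(short))


def local_score(seq_a: str, seq_b: str) -> float:
    """Smith-Waterman BLOSUM62 score (raw units)."""
    if not seq_a or not seq_b:
        return 0.0
    return float(_local_aligner().score(seq_a, seq_b))


def raw_to_bits(raw_score: float) -> float:
    """Convert a raw BLOSUM62 local score to bit units (Karlin-Altschul)."""
    import math

    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def local_evalue(raw_score: float, query_length: int, database_residues: int) -> float:
    """Crude Karlin-Altschul E-value for a raw local alignment score."""
    import math

    return KA_K * query_length * database_residues * math.exp(-KA_LAMBDA * raw_score)
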