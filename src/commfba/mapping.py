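"""Mapping OTU representative 16S sequences onto reference genome 16S genes.

Each OTU sequence is aligned against every reference with an exact local
(Smith–Waterman) alignment under BLASTN-like scoring (match +2, mismatch −3,
gap open 5, gap extend 2; ambiguity code N always scores as a mismatch).
Hits must reach a minimum percent identity (default 97%) and minimum query
coverage (default 95%); among surviving hits only those tied for the maximum
identity are retained, and the assignment is made deterministic by picking
the lexicographically smallest reference id among the tied hits.

Identity follows the BLAST convention: matched columns divided by total
alignment columns, gap columns included.  Query coverage is the aligned query
span divided by the full query length.  Both query orientations are tried
(the reverse complement covers OTUs called on the opposite strand) and the
higher-scoring orientation is kept, preferring forward on ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 97.0
DEFAULT_MIN_COVERAGE = 95.0
IDENTITY_TIE_TOL = 1e-9

_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class AlignmentScoring:
    """BLASTN-style affine scoring; a gap of length L costs open + L*extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class AlignmentStats:
    query_id: str
    reference_id: str
    identity_pct: float
    query_coverage_pct: float
    aligned_length: int
    score: float = 0.0
    strand: str = "+"


@dataclass(frozen=True)
class MappingResult:
    query_id: str
    retained_hits: tuple[AlignmentStats, ...]
    assigned_reference: str | None

    @property
    def mapped(self) -> bool:
        return self.assigned_reference is not None


@lru_cache(maxsize=8)
def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    matrix = np.full((len(_ALPHABET), len(_ALPHABET)), scoring.mismatch)
    for i, letter in enumerate(_ALPHABET):
        if letter != "N":  # N pairs with anything, including N, as mismatch
            matrix[i, i] = scoring.match
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=_ALPHABET, dims=2, data=matrix
    )
    aligner.mode = "local"
    # Biopython charges open_gap_score for the first gap column and
    # extend_gap_score for each further one; BLAST charges open + L*extend.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _check_sequence(seq: str, role: str) -> str:
    if not seq:
        raise ValueError(f"empty {role} sequence")
    seq = seq.upper()
    extra = set(seq) - set(_ALPHABET)
    if extra:
        raise ValueError(f"{role} sequence contains non-ACGTN symbols {sorted(extra)}")
    return seq


def _align_one_orientation(
    query: str, reference: str, scoring: AlignmentScoring
) -> tuple[float, float, float, int]:
    """Return (score, identity_pct, coverage_pct, aligned_length) for one strand."""
    aligner = _make_aligner(scoring)
    alignments = aligner.align(query, reference)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0, 0.0, 0.0, 0
    aln = alignments[0]
    columns = aln.length
    # count matches ourselves so that N==N stays a mismatch
    matches = 0
    blocks_q, blocks_r = aln.aligned
    for (qs, qe), (rs, re) in zip(blocks_q, blocks_r):
        for qc, rc in zip(query[qs:qe], reference[rs:re]):
            if qc == rc and qc != "N":
                matches += 1
    identity = 100.0 * matches / columns if columns else 0.0
    q_span = int(blocks_q[-1][1] - blocks_q[0][0])
    coverage = 100.0 * q_span / len(query)
    return float(aln.score), identity, coverage, int(columns)


def align_pair(
    query: str,
    reference: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    query_id: str = "",
    reference_id: str = "",
) -> AlignmentStats:
    """Locally align a query against a reference, trying both orientations.

    The orientation with the higher alignment score wins (forward on ties).
    """
    query = _check_sequence(query, "query")
    reference = _check_sequence(reference, "reference")
    fwd = _align_one_orientation(query, reference, scoring)
    rev_query = str(Seq(query).reverse_complement())
    rev = _align_one_orientation(rev_query, reference, scoring)
    if rev[0] > fwd[0]:
        score, identity, coverage, length = rev
        strand = "-"
    else:
        score, identity, coverage, length = fwd
        strand = "+"
    return AlignmentStats(
        query_id=query_id,
        reference_id=reference_id,
        identity_pct=identity,
        query_coverage_pct=coverage,
        aligned_length=length,
        score=score,
        strand=strand,
    )


def map_otu(
    query: tuple[str, str],
    references: list[tuple[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> MappingResult:
    """Map one OTU record against all references with identity/coverage filters.

    Hits below either threshold are discarded; among survivors only the hits
    tied (within 1e-9) for maximum identity are retained and the
    lexicographically smallest reference id is assigned.
    """
    if not references:
        raise ValueError("reference list is empty")
    query_id, query_seq = query
    hits = []
    for ref_id, ref_seq in references:
        stats = align_pair(
            query_seq, ref_seq, scoring, query_id=query_id, reference_id=ref_id
        )
        if (
            stats.identity_pct >= min_identity
            and stats.query_coverage_pct >= min_coverage
        ):
            hits.append(stats)
    if not hits:
        return MappingResult(query_id, (), None)
    best = max(h.identity_pct for h in hits)
    retained = sorted(
        (h for h in hits if best - h.identity_pct <= IDENTITY_TIE_TOL),
        key=lambda h: h.reference_id,
    )
    if len(retained) > 1:
        logger.warning(
            "OTU %s: %d references tied at identity %.4f%%; assigning %s",
            query_id,
            len(retained),
            best,
            retained[0].reference_id,
        )
    return MappingResult(query_id, tuple(retained), retained[0].reference_id)


def map_all(
    otus: list[tuple[str, str]],
    references: list[tuple[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> dict[str, MappingResult]:
    """Map every OTU; the result map includes unmapped entries."""
    ids = [otu_id for otu_id, _ in otus]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate OTU ids: {dupes}")
    return {
        otu_id: map_otu((otu_id, seq), references, min_identity, min_coverage, scoring)
        for otu_id, seq in otus
    }


def mapping_summary(results: dict[str, MappingResult]) -> pd.DataFrame:
    """Flatten mapping results into the summary table written by the pipeline."""
    rows = []
    for otu_id, res in results.items():
        if res.mapped:
            top = res.retained_hits[0]
            rows.append(
                (
                    otu_id,
                    res.assigned_reference,
                    round(top.identity_pct, 6),
                    round(top.query_coverage_pct, 6),
                    len(res.retained_hits),
                    "mapped",
                )
            )
        else:
            rows.append((otu_id, "", float("nan"), float("nan"), 0, "unmapped"))
    return pd.DataFrame(
        rows,
        columns=[
            "otu_id",
            "assigned_reference",
            "identity_pct",
            "query_coverage_pct",
            "n_tied_hits",
            "status",
        ],
    )
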