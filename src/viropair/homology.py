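"""Pairwise nucleotide local alignment with E-value scoring.

Stands in for BLASTN wherever the analysis applies a homology threshold:
host-read screening (E < 1e-5), cross-virome comparison (E < 1e-10), and
intra-virome virus clustering (E < 1e-20 over >= 50% of the shorter contig).

Two alignment engines sit behind :func:`local_align`:

* an exact affine-gap Smith-Waterman (Bio.Align.PairwiseAligner) when both
  sequences are short (<= ``dp_max``), and
* a seed-and-extend path for longer sequences: shared canonical k-mers
  nominate diagonals, and on each diagonal the optimal gapless local segment
  is found by Kadane's maximum-subarray scan.  This is exact for
  substitution-only homology, which is the regime the stringent thresholds
  target.

E-values follow the ungapped Karlin-Altschul formula E = K*m*n*exp(-lambda*S)
with the per-pair search space m*n.  lambda is solved from the scoring matrix
and uniform base composition, so E is monotone decreasing in the raw score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from scipy.optimize import brentq

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte encoding used by the vectorised match/mismatch scans
_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_ENC[ord("N")] = 4


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _karlin_lambda(match: float, mismatch: float) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base frequencies."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-9, 10.0)


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scores and Karlin-Altschul constants.

    The defaults (+2/-3, gap open -5, extend -2) are stringent
    BLASTN-like nucleotide scores; ``karlin_lambda`` is derived from them
    at construction unless supplied.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    karlin_lambda: float | None = None
    karlin_K: float = 0.1

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.karlin_lambda is None:
            object.__setattr__(
                self, "karlin_lambda", _karlin_lambda(self.match, self.mismatch)
            )

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.karlin_K * m * n * math.exp(-self.karlin_lambda * score)


DEFAULT_SCORING = ScoringParams()


@dataclass
class HomologyHit:
    """Best local alignment between a query and a subject sequence.

    Coordinates are 1-based inclusive (BLAST convention); a minus-strand
    hit has ``sstart > send``.
    """

    query_id: str
    subject_id: str
    score: float
    identity: float
    length: int
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    e_value: float

    @property
    def mismatches(self) -> int:
        return self.length - round(self.identity * self.length)

    def bitscore(self, scoring: ScoringParams = DEFAULT_SCORING) -> float:
        return (scoring.karlin_lambda * self.score - math.log(scoring.karlin_K)) / math.log(2)


# ---------------------------------------------------------------------------
# exact DP path (short sequences)
# ---------------------------------------------------------------------------


def _make_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _dp_align_oriented(
    a: str, b: str, scoring: ScoringParams
) -> tuple[float, int, int, int, int, int, int] | None:
    """Best local alignment of a vs b (as given); returns
    (score, matches, aln_len, qstart0, qend0, sstart0, send0) or None."""
    aligner = _make_aligner(scoring)
    score = aligner.score(a, b)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(a, b)))
    qblocks, sblocks = aln.aligned
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        qa = np.frombuffer(a[qs:qe].encode(), dtype=np.uint8)
        sa = np.frombuffer(b[ss:se].encode(), dtype=np.uint8)
        matches += int((qa == sa).sum())
        aligned_cols += qe - qs
    # gap columns between consecutive blocks
    gaps = 0
    for i in range(1, len(qblocks)):
        gaps += (qblocks[i][0] - qblocks[i - 1][1]) + (sblocks[i][0] - sblocks[i - 1][1])
    aln_len = aligned_cols + gaps
    return (
        float(aln.score),
        matches,
        aln_len,
        int(qblocks[0][0]),
        int(qblocks[-1][1]) - 1,
        int(sblocks[0][0]),
        int(sblocks[-1][1]) - 1,
    )


# ---------------------------------------------------------------------------
# seed-and-extend path (long sequences)
# ---------------------------------------------------------------------------

SEED_K = 21
_MAX_SEED_OCCUPANCY = 64
_MAX_DIAGONALS = 32


def kmer_positions(seq: str, k: int = SEED_K) -> dict[str, list[int]]:
    """Positions of every k-mer in ``seq`` (forward orientation)."""
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i : i + k], []).append(i)
    return out


def _best_segment_on_diagonal(
    ea: np.ndarray, eb: np.ndarray, diag: int, scoring: ScoringParams
) -> tuple[float, int, int, int] | None:
    """Optimal gapless local segment on diagonal ``diag`` (a_pos - b_pos).

    Returns (score, a_start, length, matches) or None.
    """
    a0 = max(0, diag)
    b0 = a0 - diag
    n = min(len(ea) - a0, len(eb) - b0)
    if n <= 0:
        return None
    eq = ea[a0 : a0 + n] == eb[b0 : b0 + n]
    # N never matches anything, including another N
    eq &= ea[a0 : a0 + n] != 4
    scores = np.where(eq, scoring.match, scoring.mismatch)
    # Kadane with segment tracking
    best = 0.0
    best_start = best_end = -1
    cur = 0.0
    cur_start = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = float(s)
            cur_start = i
        else:
            cur += float(s)
        if cur > best:
            best = cur
            best_start, best_end = cur_start, i
    if best <= 0:
        return None
    matches = int(eq[best_start : best_end + 1].sum())
    return best, a0 + best_start, best_end - best_start + 1, matches


def _seed_extend_oriented(
    a: str,
    b: str,
    scoring: ScoringParams,
    a_index: Mapping[str, list[int]] | None = None,
) -> tuple[float, int, int, int, int] | None:
    """Best gapless hit of a vs b via shared-k-mer diagonals.

    Returns (score, a_start0, b_start0, length, matches) or None.
    """
    if len(a) < SEED_K or len(b) < SEED_K:
        return None
    index = a_index if a_index is not None else kmer_positions(a)
    diag_hits: dict[int, int] = {}
    for i in range(len(b) - SEED_K + 1):
        positions = index.get(b[i : i + SEED_K])
        if not positions or len(positions) > _MAX_SEED_OCCUPANCY:
            continue
        for p in positions:
            d = p - i
            diag_hits[d] = diag_hits.get(d, 0) + 1
    if not diag_hits:
        return None
    ea, eb = _encode(a), _encode(b)
    diagonals = sorted(diag_hits, key=lambda d: (-diag_hits[d], d))[:_MAX_DIAGONALS]
    best: tuple[float, int, int, int, int] | None = None
    for d in diagonals:
        seg = _best_segment_on_diagonal(ea, eb, d, scoring)
        if seg is None:
            continue
        score, a_start, length, matches = seg
        if best is None or score > best[0]:
            best = (score, a_start, a_start - d, length, matches)
    return best


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def local_align(
    a: str,
    b: str,
    scoring: ScoringParams = DEFAULT_SCORING,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    dp_max: int = 1000,
    a_index: Mapping[str, list[int]] | None = None,
) -> HomologyHit | None:
    """Best-scoring local alignment of ``a`` against both strands of ``b``.

    Uses exact affine-gap DP when both sequences are <= ``dp_max`` nt,
    seed-and-extend otherwise.  Returns None when no positive-scoring
    alignment (or no seed) exists.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    m, n = len(a), len(b)
    use_dp = max(m, n) <= dp_max
    best: HomologyHit | None = None
    for strand, b_or in (("+", b), ("-", revcomp(b))):
        if use_dp:
            res = _dp_align_oriented(a, b_or, scoring)
            if res is None:
                continue
            score, matches, aln_len, qs, qe, ss, se = res
        else:
            res = _seed_extend_oriented(a, b_or, scoring, a_index=a_index)
            if res is None:
                continue
            score, a_start, b_start, length, matches = res
            aln_len = length
            qs, qe = a_start, a_start + length - 1
            ss, se = b_start, b_start + length - 1
        if strand == "-":
            # map oriented-b coordinates back to the original strand
            ss, se = n - 1 - ss, n - 1 - se
        hit = HomologyHit(
            query_id=query_id,
            subject_id=subject_id,
            score=score,
            identity=matches / aln_len,
            length=aln_len,
            qstart=qs + 1,
            qend=qe + 1,
            sstart=ss + 1,
            send=se + 1,
            strand=strand,
            e_value=scoring.evalue(score, m, n),
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def homolog_pairs(
    contigs: Mapping[str, str] | Sequence[tuple[str, str]],
    e_max: float = 1e-20,
    min_cover: float = 0.5,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> list[tuple[str, str, HomologyHit]]:
    """Undirected homolog edges among a set of contigs.

    Edge (i, j) exists iff the best local hit has E < ``e_max`` and the
    alignment spans at least ``min_cover`` of the shorter contig.  Self
    comparisons are excluded; output is symmetric by construction.
    """
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    items = list(contigs.items()) if isinstance(contigs, Mapping) else list(contigs)
    indexes = {cid: kmer_positions(seq) for cid, seq in items if len(seq) >= SEED_K}
    edges: list[tuple[str, str, HomologyHit]] = []
    for i in range(len(items)):
        cid_i, seq_i = items[i]
        for j in range(i + 1, len(items)):
            cid_j, seq_j = items[j]
            hit = local_align(
                seq_i,
                seq_j,
                scoring,
                query_id=cid_i,
                subject_id=cid_j,
                a_index=indexes.get(cid_i),
            )
            if hit is None or hit.e_value >= e_max:
                continue
            if hit.length >= min_cover * min(len(seq_i), len(seq_j)):
                edges.append((cid_i, cid_j, hit))
    return edges


def cross_virome_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    e_max: float = 1e-10,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> list[HomologyHit]:
    """Best hit of each query contig against a subject contig set, E < e_max."""
    hits: list[HomologyHit] = []
    q_indexes = {qid: kmer_positions(seq) for qid, seq in queries.items()}
    for qid, qseq in queries.items():
        best: HomologyHit | None = None
        for sid, sseq in subjects.items():
            hit = local_align(
                qseq, sseq, scoring, query_id=qid, subject_id=sid, a_index=q_indexes[qid]
            )
            if hit is not None and (best is None or hit.e_value < best.e_value):
                best = hit
        if best is not None and best.e_value < e_max:
            hits.append(best)
    return hits
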