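"""Greedy overlap-layout-consensus assembly under stringent overlap criteria.

The assembler honours two thresholds that drive everything downstream:
reads are merged only when they overlap at >= 98% identity over at least
50% of the shorter read's length (for 150 nt reads that floor is 75 nt),
and contigs shorter than 2,000 nt are discarded before any analysis.

Candidate overlaps are nominated by shared canonical k-mers (k=21) and
verified as gapless alignments at the implied offset.  Verified overlaps
are processed longest-first (ties: higher identity, then input order), each
merge placing reads into a common layout frame; inconsistent placements are
skipped, so every read lands in at most one contig.  The consensus is a
per-column majority call, breaking ties by summed base quality and then
alphabetically.  Per-source read support is retained on every contig, which
is what makes co-assembly sharing attribution possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .homology import revcomp
from .read_qc import Read

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_BASES = "ACGT"


@dataclass(frozen=True)
class AssemblyParams:
    min_identity: float = 0.98
    min_overlap_fraction: float = 0.5
    min_contig_len: int = 2000
    seed_kmer: int = 21

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must be in (0, 1]")


@dataclass
class Contig:
    """Assembled consensus with per-source read support and depth profile."""

    id: str
    consensus: str
    support: dict[str, int]
    depth: np.ndarray
    mean_coverage: float
    read_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def total_reads(self) -> int:
        return sum(self.support.values())


def majority_consensus(
    base_counts: Mapping[str, int],
    base_quals: Mapping[str, float] | None = None,
) -> str:
    """Majority-rule base call for one alignment column.

    Ties on count are broken by higher summed quality, then by the
    alphabetically smallest base.
    """
    if not base_counts or sum(base_counts.values()) <= 0:
        raise ValueError("column has no observations")
    quals = base_quals or {}
    return min(
        base_counts,
        key=lambda b: (-base_counts[b], -quals.get(b, 0.0), b),
    )


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class _Overlap:
    i: int
    j: int
    orient: int  # +1 j same strand as i, -1 revcomp
    offset: int  # start of oriented j in i's forward frame
    length: int
    matches: int
    identity: float


def _find_overlaps(
    seqs: list[str], params: AssemblyParams
) -> list[_Overlap]:
    """Nominate read pairs by shared canonical k-mers, verify gaplessly."""
    k = params.seed_kmer
    # canonical k-mer -> list of (read, pos, strand of canonical form)
    index: dict[str, list[tuple[int, int, int]]] = {}
    for ridx, s in enumerate(seqs):
        seen: set[tuple[str, int, int]] = set()
        for p in range(len(s) - k + 1):
            kmer = s[p : p + k]
            rc = revcomp(kmer)
            if kmer <= rc:
                key, strand = kmer, 1
            else:
                key, strand = rc, -1
            index.setdefault(key, []).append((ridx, p, strand))
    enc = [_ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)] for s in seqs]
    enc_rc = [_ENC[np.frombuffer(revcomp(s).encode("ascii"), dtype=np.uint8)] for s in seqs]

    candidates: set[tuple[int, int, int, int]] = set()
    for entries in index.values():
        if len(entries) > 200:  # repeat k-mer; skip to bound work
            continue
        for x in range(len(entries)):
            ri, pi, si = entries[x]
            for y in range(x + 1, len(entries)):
                rj, pj, sj = entries[y]
                if ri == rj:
                    continue
                if ri < rj:
                    a, b, pa, pb, sa, sb = ri, rj, pi, pj, si, sj
                else:
                    a, b, pa, pb, sa, sb = rj, ri, pj, pi, sj, si
                orient = sa * sb
                if orient == 1:
                    off = pa - pb
                else:
                    # oriented b = revcomp(b); canonical kmer at pos pb on b maps
                    # to pos len_b - k - pb on revcomp(b)
                    off = pa - (len(seqs[b]) - k - pb)
                candidates.add((a, b, orient, off))

    overlaps: list[_Overlap] = []
    for (i, j, orient, off) in candidates:
        ei = enc[i]
        ej = enc[j] if orient == 1 else enc_rc[j]
        li, lj = len(ei), len(ej)
        # overlap of [0, li) with [off, off+lj)
        start = max(0, off)
        end = min(li, off + lj)
        ov = end - start
        shorter = min(li, lj)
        if ov < max(params.min_overlap_fraction * shorter, params.seed_kmer):
            continue
        a_seg = ei[start:end]
        b_seg = ej[start - off : end - off]
        matches = int((a_seg == b_seg).sum())
        identity = matches / ov
        if identity >= params.min_identity:
            overlaps.append(_Overlap(i, j, orient, off, ov, matches, identity))
    return overlaps


class _Layouts:
    """Union-find over reads with per-read (strand, offset) poses."""

    def __init__(self, lengths: list[int]):
        self.lengths = lengths
        self.parent = list(range(len(lengths)))
        # members[root] = list of read indices; pose[read] = (strand, offset)
        self.members: dict[int, list[int]] = {i: [i] for i in range(len(lengths))}
        self.pose: list[tuple[int, int]] = [(1, 0) for _ in lengths]

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def _desired_pose(self, ov: _Overlap) -> tuple[int, int]:
        """Pose of read j in i's layout frame, given i's current pose."""
        s_i, o_i = self.pose[ov.i]
        lj = self.lengths[ov.j]
        li = self.lengths[ov.i]
        s_j = s_i * ov.orient
        if s_i == 1:
            o_j = o_i + ov.offset
        else:
            o_j = o_i + li - ov.offset - lj
        return s_j, o_j

    def try_merge(self, ov: _Overlap) -> bool:
        ri, rj = self.find(ov.i), self.find(ov.j)
        s_d, o_d = self._desired_pose(ov)
        if ri == rj:
            return self.pose[ov.j] == (s_d, o_d)
        s_j, o_j = self.pose[ov.j]
        # transform all reads of j's layout into i's frame
        if s_j == s_d:
            delta = o_d - o_j
            updates = [(r, self.pose[r][0], self.pose[r][1] + delta) for r in self.members[rj]]
        else:
            c = o_d + o_j + self.lengths[ov.j] - 1
            updates = [
                (r, -self.pose[r][0], c - self.pose[r][1] - self.lengths[r] + 1)
                for r in self.members[rj]
            ]
        for r, s, o in updates:
            self.pose[r] = (s, o)
        self.parent[rj] = ri
        self.members[ri].extend(self.members.pop(rj))
        return True


def _layout_to_contig(
    contig_id: str,
    member_reads: list[int],
    reads: Sequence[Read],
    layouts: _Layouts,
) -> Contig:
    poses = [layouts.pose[r] for r in member_reads]
    starts = [o for (_, o) in poses]
    shift = -min(starts)
    length = max(o + shift + len(reads[r].seq) for r, (_, o) in zip(member_reads, poses))
    counts = np.zeros((length, 5), dtype=np.int64)
    qsums = np.zeros((length, 5), dtype=np.float64)
    for r, (s, o) in zip(member_reads, poses):
        seq = reads[r].seq if s == 1 else revcomp(reads[r].seq)
        qual = reads[r].qual if s == 1 else reads[r].qual[::-1]
        e = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(float) - 33
        pos = np.arange(len(e)) + o + shift
        np.add.at(counts, (pos, e), 1)
        np.add.at(qsums, (pos, e), q)
    # majority per column among A/C/G/T (ambiguous observations ignored unless
    # they are all there is)
    base_counts = counts[:, :4]
    base_q = qsums[:, :4]
    # order: count desc, qual desc, base asc  -> use lexsort on negatives
    best = np.zeros(length, dtype=np.int64)
    for col in range(length):
        c = base_counts[col]
        if c.sum() == 0:
            best[col] = -1
            continue
        best[col] = min(range(4), key=lambda b: (-c[b], -base_q[col, b], b))
    consensus = "".join("N" if b < 0 else _BASES[b] for b in best)
    depth = counts.sum(axis=1)
    support: dict[str, int] = {}
    for r in member_reads:
        label = reads[r].source
        support[label] = support.get(label, 0) + 1
    total_bases = sum(len(reads[r].seq) for r in member_reads)
    return Contig(
        id=contig_id,
        consensus=consensus,
        support=support,
        depth=depth,
        mean_coverage=total_bases / length,
        read_ids=[reads[r].id for r in member_reads],
    )


def assemble(
    reads: Sequence[Read],
    params: AssemblyParams = AssemblyParams(),
) -> tuple[list[Contig], list[str]]:
    """Greedy overlap assembly.

    Returns (contigs, unassembled read ids).  Contigs carry per-source
    support; reads in single-read layouts are reported as unassembled.
    Deterministic for a fixed input order.
    """
    reads = list(reads)
    if not reads:
        return [], []
    seqs = [r.seq for r in reads]
    overlaps = _find_overlaps(seqs, params)
    overlaps.sort(key=lambda ov: (-ov.length, -ov.identity, ov.i, ov.j))
    layouts = _Layouts([len(s) for s in seqs])
    for ov in overlaps:
        layouts.try_merge(ov)

    contigs: list[Contig] = []
    unassembled: list[str] = []
    roots = sorted(
        {layouts.find(i) for i in range(len(reads))},
        key=lambda r: min(layouts.members[r]),
    )
    cidx = 0
    for root in roots:
        members = sorted(layouts.members[root])
        if len(members) == 1:
            unassembled.append(reads[members[0]].id)
            continue
        contigs.append(_layout_to_contig(f"contig_{cidx:05d}", members, reads, layouts))
        cidx += 1
    return contigs, unassembled


def filter_contigs(contigs: Iterable[Contig], min_len: int = 2000) -> list[Contig]:
    """Keep contigs of length >= ``min_len`` (2,000 nt by default)."""
    return [c for c in contigs if len(c) >= min_len]


def min_accepted_overlap(read_length: int, params: AssemblyParams = AssemblyParams()) -> int:
    """Smallest overlap the parameters accept for reads of ``read_length`` nt."""
    return int(np.ceil(params.min_overlap_fraction * read_length))
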