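"""Mother-infant virus sharing: co-assembly attribution and permutation test.

Two complementary measurements of whether a mother's milk virome and her
infant's stool virome carry the same viruses:

* **Co-assembly attribution** — pool the reads of both samples, assemble
  them jointly, and classify each retained contig by the origin of its
  supporting reads: milk-only, stool-only, or shared (reads from both).

* **Homolog sharing with a permutation test** — the statistic is the
  fraction of contigs sampled from one sample (1,000 draws by default) that
  have at least one stringent homolog (E < 1e-20 over >= 50% of the shorter
  contig) in the partner sample.  An empirical null is built by recomputing
  the statistic between milk and stool contigs of *different* pairs
  (10,000 iterations by default); the p-value is the fraction of null draws
  at or above the observed value, displayed as "< 1/N" when none reach it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import AssemblyParams, Contig, assemble, filter_contigs
from .homology import DEFAULT_SCORING, ScoringParams, kmer_positions, local_align
from .read_qc import Read


@dataclass
class AttributionResult:
    """Per-pair contig attribution: counts and fractions by source class."""

    counts: dict[str, int]  # keys: each source label + "shared"
    fractions: dict[str, float]
    per_contig: dict[str, dict[str, int]]  # contig id -> support by source
    n_contigs: int


def attribute_coassembly(
    reads_by_source: Mapping[str, Sequence[Read]],
    params: AssemblyParams = AssemblyParams(),
    min_reads_each: int = 1,
) -> tuple[AttributionResult, list[Contig]]:
    """Co-assemble two labeled read sets and attribute each contig.

    A contig is *shared* when every source contributes at least
    ``min_reads_each`` reads; otherwise it belongs to its single
    contributing source.  Only contigs passing the length filter count.
    """
    labels = sorted(reads_by_source)
    if len(labels) != 2:
        raise ValueError("attribution requires exactly two labeled read sets")
    if min_reads_each < 1:
        raise ValueError("min_reads_each must be >= 1")
    for label in labels:
        if len(reads_by_source[label]) == 0:
            raise ValueError(f"source {label!r} has zero reads")
    pooled: list[Read] = []
    for label in labels:
        for r in reads_by_source[label]:
            pooled.append(Read(r.id, r.seq, r.qual, source=label))
    contigs, _ = assemble(pooled, params)
    contigs = filter_contigs(contigs, params.min_contig_len)
    counts = {labels[0]: 0, labels[1]: 0, "shared": 0}
    per_contig: dict[str, dict[str, int]] = {}
    for c in contigs:
        per_contig[c.id] = dict(c.support)
        if all(c.support.get(lbl, 0) >= min_reads_each for lbl in labels):
            counts["shared"] += 1
        else:
            owner = max(labels, key=lambda lbl: c.support.get(lbl, 0))
            counts[owner] += 1
    n = len(contigs)
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return AttributionResult(counts, fractions, per_contig, n), contigs


@dataclass(frozen=True)
class PermutationParams:
    n_iterations: int = 10_000
    n_sampled_contigs: int = 1_000
    e_max: float = 1e-20
    min_cover: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_sampled_contigs < 1:
            raise ValueError("n_iterations and n_sampled_contigs must be >= 1")


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    n_iterations: int
    p_value: float
    exceed_count: int

    @property
    def p_display(self) -> str:
        if self.exceed_count == 0:
            return f"< {1 / self.n_iterations:g}"
        return f"{self.p_value:g}"


class _HomologCache:
    """Memoized 'contig has a stringent homolog in sample S' lookups."""

    def __init__(
        self,
        viromes: Mapping[str, Mapping[str, str]],
        e_max: float,
        min_cover: float,
        scoring: ScoringParams,
    ):
        self.viromes = {s: dict(c) for s, c in viromes.items()}
        self.e_max = e_max
        self.min_cover = min_cover
        self.scoring = scoring
        self._kmers: dict[tuple[str, str], dict] = {}
        self._flags: dict[tuple[str, str], np.ndarray] = {}

    def _index(self, sample: str, cid: str) -> dict:
        key = (sample, cid)
        if key not in self._kmers:
            self._kmers[key] = kmer_positions(self.viromes[sample][cid])
        return self._kmers[key]

    def has_homolog_flags(self, sample_a: str, sample_b: str) -> np.ndarray:
        """Boolean flag per contig of ``sample_a`` (sorted id order):
        does it have a qualifying homolog among ``sample_b``'s contigs?"""
        key = (sample_a, sample_b)
        if key in self._flags:
            return self._flags[key]
        a_contigs = self.viromes[sample_a]
        b_contigs = self.viromes[sample_b]
        flags = np.zeros(len(a_contigs), dtype=bool)
        for i, aid in enumerate(sorted(a_contigs)):
            aseq = a_contigs[aid]
            for bid, bseq in b_contigs.items():
                if sample_a == sample_b and aid == bid:
                    flags[i] = True
                    break
                hit = local_align(
                    aseq,
                    bseq,
                    self.scoring,
                    query_id=aid,
                    subject_id=bid,
                    a_index=self._index(sample_a, aid),
                )
                if (
                    hit is not None
                    and hit.e_value < self.e_max
                    and hit.length >= self.min_cover * min(len(aseq), len(bseq))
                ):
                    flags[i] = True
                    break
        self._flags[key] = flags
        return flags


def shared_homolog_fraction(
    contigs_a: Mapping[str, str],
    contigs_b: Mapping[str, str],
    params: PermutationParams = PermutationParams(),
    rng: np.random.Generator | None = None,
    scoring: ScoringParams = DEFAULT_SCORING,
    cache: _HomologCache | None = None,
    _cache_key: tuple[str, str] | None = None,
) -> float:
    """Fraction of contigs sampled from A having >= 1 stringent homolog in B.

    ``n_sampled_contigs`` contigs are drawn from A — without replacement
    when A is large enough, with replacement otherwise.
    """
    if not contigs_a or not contigs_b:
        raise ValueError("both contig sets must be non-empty")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if cache is None:
        cache = _HomologCache({"A": contigs_a, "B": contigs_b}, params.e_max,
                              params.min_cover, scoring)
        _cache_key = ("A", "B")
    flags = cache.has_homolog_flags(*_cache_key)
    n = params.n_sampled_contigs
    replace = len(flags) < n
    idx = rng.choice(len(flags), size=n, replace=replace)
    return float(flags[idx].mean())


def permutation_test(
    pairs: Mapping[str, Mapping[str, Mapping[str, str]]],
    target_pair: str,
    params: PermutationParams = PermutationParams(),
    rng: np.random.Generator | None = None,
    scoring: ScoringParams = DEFAULT_SCORING,
    cache: _HomologCache | None = None,
) -> PermutationResult:
    """Permutation test of within-pair vs between-pair homolog sharing.

    ``pairs`` maps pair id -> {"milk": contigs, "stool": contigs}.  The
    observed statistic is the milk->stool shared-homolog fraction of the
    target pair; each null iteration draws a random (milk_i, stool_j)
    combination with i != j and recomputes the statistic with fresh contig
    sampling.  p = #(null >= observed) / n_iterations.
    """
    pair_ids = sorted(pairs)
    if len(pair_ids) < 3:
        raise ValueError("permutation test requires >= 3 pairs")
    if target_pair not in pairs:
        raise ValueError(f"unknown target pair {target_pair!r}")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if cache is None:
        viromes = {
            f"{p}:{site}": contigs
            for p, sites in pairs.items()
            for site, contigs in sites.items()
        }
        cache = _HomologCache(viromes, params.e_max, params.min_cover, scoring)

    def frac(milk_pair: str, stool_pair: str) -> float:
        a_key = f"{milk_pair}:milk"
        b_key = f"{stool_pair}:stool"
        return shared_homolog_fraction(
            cache.viromes[a_key],
            cache.viromes[b_key],
            params,
            rng,
            scoring,
            cache=cache,
            _cache_key=(a_key, b_key),
        )

    observed = frac(target_pair, target_pair)
    cross = [(i, j) for i in pair_ids for j in pair_ids if i != j]
    null = np.empty(params.n_iterations)
    for it in range(params.n_iterations):
        i, j = cross[int(rng.integers(len(cross)))]
        null[it] = frac(i, j)
    exceed = int((null >= observed).sum())
    return PermutationResult(
        observed=observed,
        null=null,
        n_iterations=params.n_iterations,
        p_value=exceed / params.n_iterations,
        exceed_count=exceed,
    )


def within_between_table(
    pairs: Mapping[str, Mapping[str, Mapping[str, str]]],
    params: PermutationParams = PermutationParams(),
    n_reps: int = 30,
    rng: np.random.Generator | None = None,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> pd.DataFrame:
    """Per-pair within/between sharing summary with permutation p-values.

    Within = mean +/- SD over ``n_reps`` resampled evaluations of the
    shared-homolog fraction inside the pair (milk->stool and stool->milk
    averaged); between = the same over random cross-pair combinations.
    Percentages, shaped like a per-pair summary table.
    """
    pair_ids = sorted(pairs)
    if len(pair_ids) < 3:
        raise ValueError("need >= 3 pairs")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    viromes = {
        f"{p}:{site}": contigs
        for p, sites in pairs.items()
        for site, contigs in sites.items()
    }
    cache = _HomologCache(viromes, params.e_max, params.min_cover, scoring)

    def frac(a_key: str, b_key: str) -> float:
        return shared_homolog_fraction(
            cache.viromes[a_key], cache.viromes[b_key], params, rng, scoring,
            cache=cache, _cache_key=(a_key, b_key),
        )

    cross = [(i, j) for i in pair_ids for j in pair_ids if i != j]
    rows = []
    for p in pair_ids:
        within = np.array([
            0.5 * (frac(f"{p}:milk", f"{p}:stool") + frac(f"{p}:stool", f"{p}:milk"))
            for _ in range(n_reps)
        ])
        between = np.empty(n_reps)
        for r in range(n_reps):
            i, j = cross[int(rng.integers(len(cross)))]
            between[r] = 0.5 * (
                frac(f"{i}:milk", f"{j}:stool") + frac(f"{j}:stool", f"{i}:milk")
            )
        perm = permutation_test(pairs, p, params, rng, scoring, cache=cache)
        rows.append({
            "pair": p,
            "within_mean_pct": 100 * within.mean(),
            "within_sd_pct": 100 * within.std(ddof=1),
            "between_mean_pct": 100 * between.mean(),
            "between_sd_pct": 100 * between.std(ddof=1),
            "p_value": perm.p_value,
            "p_display": perm.p_display,
        })
    return pd.DataFrame(rows)
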