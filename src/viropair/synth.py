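"""Synthetic paired viromes with known ground truth.

Emulates the study design this package analyses: mother-infant pairs, each
contributing a "milk" and an "infant stool" viral community.  Genomes are
drawn from a shared pool; a planted fraction of each infant community is
also present in the paired milk community, and a background fraction is
drawn from a cosmopolitan sub-pool common to all samples, so cross-pair
sharing exists at a controlled low level.  Reads are 150 nt single-end with
substitution errors and Phred+33-style qualities; optional host-contaminant
reads exercise the host screen.

All randomness flows from one ``numpy.random.Generator`` derived from the
config seed, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .homology import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: families sampled for genome labels, with (weight, is_phage); roughly 95%
#: phage as observed in milk/infant-stool viromes
_FAMILY_POOL: list[tuple[str, float, bool]] = [
    ("Siphoviridae", 0.45, True),
    ("Myoviridae", 0.30, True),
    ("Podoviridae", 0.15, True),
    ("Microviridae", 0.05, True),
    ("Anelloviridae", 0.03, False),
    ("Herpesviridae", 0.02, False),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the paired-virome simulation.

    Defaults mirror the study design: 10 mother-infant pairs, 150 nt reads,
    skewed (lognormal sigma=1.5) phage abundances, ~30% of each infant
    community shared with the paired milk community and ~2% background
    sharing across pairs.  ``genomes_per_sample`` = 20 is a free choice (the
    per-sample virome richness is not pinned down by the study); read depth
    defaults to a desk-scale 20,000 rather than the study's millions.
    """

    n_genomes_pool: int = 400
    genome_length_range: tuple[int, int] = (3000, 40000)
    gc_target: float = 0.45
    n_pairs: int = 10
    genomes_per_sample: int = 20
    shared_fraction: float = 0.3
    background_shared_fraction: float = 0.02
    abundance_model: str = "lognormal"
    abundance_sigma: float = 1.5
    n_reads_per_sample: int = 20000
    read_length: int = 150
    substitution_error_rate: float = 0.001
    host_contamination_fraction: float = 0.0
    paired_end: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.genome_length_range
        if not 0 < lo <= hi:
            raise ValueError("genome_length_range must be a positive interval")
        if lo < 2 * self.read_length:
            raise ValueError("genome length lower bound must be >= 2 * read_length")
        for name in ("shared_fraction", "background_shared_fraction", "gc_target",
                     "substitution_error_rate", "host_contamination_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be strictly inside (0, 1)")
        if self.genomes_per_sample > self.n_genomes_pool:
            raise ValueError("genomes_per_sample exceeds n_genomes_pool")
        if self.abundance_model not in ("lognormal", "powerlaw"):
            raise ValueError("abundance_model must be 'lognormal' or 'powerlaw'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class GenomeRecord:
    id: str
    seq: str
    family: str
    is_phage: bool


@dataclass
class SimulatedRead:
    id: str
    seq: str
    qual: str
    source_genome: str  # genome id, or "host"
    position: int  # 0-based start on the forward strand of the source
    strand: str


@dataclass
class GroundTruth:
    """Everything needed to score downstream stages against the truth."""

    catalogue: dict[str, GenomeRecord]
    communities: dict[str, dict[str, float]]  # sample -> genome id -> abundance
    read_map: dict[str, SimulatedRead] = field(default_factory=dict)

    def shared_genomes(self, sample_a: str, sample_b: str) -> set[str]:
        return set(self.communities[sample_a]) & set(self.communities[sample_b])

    def true_spectrum(self, sample: str, reads: list[SimulatedRead]) -> dict[str, int]:
        """Read counts per source genome for one sample's reads."""
        spectrum: dict[str, int] = {}
        for r in reads:
            spectrum[r.source_genome] = spectrum.get(r.source_genome, 0) + 1
        return spectrum


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def generate_genomes(
    n: int,
    length_range: tuple[int, int] = (3000, 40000),
    gc_target: float = 0.45,
    rng: np.random.Generator | int = 0,
) -> dict[str, GenomeRecord]:
    """Generate ``n`` random viral genomes with family labels.

    Lengths are uniform over ``length_range``; each base is G/C with
    probability ``gc_target`` independently, so per-genome GC is binomial
    around the target.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ValueError("length_range must be a positive interval")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must be in (0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    fam_names = [f[0] for f in _FAMILY_POOL]
    fam_w = np.array([f[1] for f in _FAMILY_POOL])
    fam_w = fam_w / fam_w.sum()
    fam_phage = {f[0]: f[2] for f in _FAMILY_POOL}
    catalogue: dict[str, GenomeRecord] = {}
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        family = fam_names[int(rng.choice(len(fam_names), p=fam_w))]
        gid = f"genome_{i:04d}"
        catalogue[gid] = GenomeRecord(
            id=gid,
            seq=_random_seq(rng, length, gc_target),
            family=family,
            is_phage=fam_phage[family],
        )
    return catalogue


def _abundances(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    if config.abundance_model == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    else:  # powerlaw: rank-abundance ~ 1/rank, shuffled
        raw = 1.0 / (np.arange(n) + 1.0)
        rng.shuffle(raw)
    return raw / raw.sum()


def generate_pair_communities(
    catalogue: Mapping[str, GenomeRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, float]]:
    """Per-sample genome presence/abundance tables for every pair.

    Sample labels are ``pair{p}_milk`` and ``pair{p}_stool``.  Each stool
    community shares exactly ``round(shared_fraction * genomes_per_sample)``
    genomes with its paired milk community.  A background fraction of every
    community is drawn from a cosmopolitan sub-pool shared across pairs;
    remaining genomes are unique to one sample.
    """
    if rng is None:
        rng = config.rng()
    gps = config.genomes_per_sample
    ids = sorted(catalogue)
    if gps > len(ids):
        raise ValueError("genomes_per_sample exceeds catalogue size")
    n_bg = round(config.background_shared_fraction * gps)
    n_shared = round(config.shared_fraction * gps)
    bg_pool_size = max(2 * gps, 1) if n_bg else 0
    bg_pool = ids[:bg_pool_size]
    private = ids[bg_pool_size:]
    n_samples = 2 * config.n_pairs
    needed = n_samples * (gps - n_bg) - config.n_pairs * n_shared
    if needed > len(private):
        raise ValueError(
            f"catalogue too small: need {needed} private genomes, have {len(private)}"
        )
    private_iter = iter(rng.permutation(private))

    communities: dict[str, dict[str, float]] = {}
    for p in range(config.n_pairs):
        milk_bg = list(rng.choice(bg_pool, size=n_bg, replace=False)) if n_bg else []
        milk_private = [next(private_iter) for _ in range(gps - n_bg)]
        milk = milk_bg + milk_private
        stool_shared = list(rng.choice(milk, size=n_shared, replace=False))
        stool_bg = list(rng.choice(bg_pool, size=n_bg, replace=False)) if n_bg else []
        # avoid double-counting a genome picked both as shared and background
        stool_bg = [g for g in stool_bg if g not in stool_shared]
        n_private = gps - n_shared - len(stool_bg)
        stool_private = [next(private_iter) for _ in range(n_private)]
        stool = stool_shared + stool_bg + stool_private
        for label, genomes in ((f"pair{p}_milk", milk), (f"pair{p}_stool", stool)):
            ab = _abundances(rng, len(genomes), config)
            communities[label] = {g: float(a) for g, a in zip(genomes, ab)}
    return communities


_QUAL_HI = np.arange(35, 41)
_QUAL_LO = np.arange(8, 21)


def simulate_reads(
    community: Mapping[str, float],
    catalogue: Mapping[str, GenomeRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample: str = "sample",
    host_seq: str | None = None,
) -> tuple[list[SimulatedRead], dict[str, SimulatedRead]]:
    """Simulate single-end reads from one community.

    Reads are allotted to genomes multinomially by abundance; start positions
    and strands are uniform.  Substitutions occur at
    ``substitution_error_rate`` per base; erroneous bases carry low Phred
    scores and correct bases high ones, so the quality string is consistent
    with the planted errors.  When ``host_contamination_fraction`` > 0 a
    corresponding share of reads is drawn from ``host_seq`` instead.

    Returns the reads and a read_id -> truth record map.
    """
    if not community:
        raise ValueError("community is empty")
    if config.n_reads_per_sample < 0:
        raise ValueError("n_reads_per_sample must be >= 0")
    if rng is None:
        rng = config.rng()
    n_total = config.n_reads_per_sample
    n_host = round(config.host_contamination_fraction * n_total)
    if n_host and host_seq is None:
        raise ValueError("host_contamination_fraction > 0 requires host_seq")
    gids = sorted(community)
    probs = np.array([community[g] for g in gids], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(n_total - n_host, probs)
    L = config.read_length
    reads: list[SimulatedRead] = []
    read_map: dict[str, SimulatedRead] = {}
    idx = 0

    def _emit(source_id: str, seq_pool: str) -> None:
        nonlocal idx
        start = int(rng.integers(0, len(seq_pool) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = seq_pool[start : start + L]
        if strand == "-":
            frag = revcomp(frag)
        base_arr = np.frombuffer(frag.encode("ascii"), dtype=np.uint8).copy()
        err = rng.random(L) < config.substitution_error_rate
        if err.any():
            for pos in np.flatnonzero(err):
                cur = chr(base_arr[pos])
                alternatives = [b for b in "ACGT" if b != cur]
                base_arr[pos] = ord(alternatives[int(rng.integers(3))])
        quals = rng.choice(_QUAL_HI, size=L)
        if err.any():
            quals[err] = rng.choice(_QUAL_LO, size=int(err.sum()))
        qual_str = "".join(chr(q + 33) for q in quals)
        rid = f"{sample}_read_{idx:07d}"
        rec = SimulatedRead(
            id=rid,
            seq=base_arr.tobytes().decode("ascii"),
            qual=qual_str,
            source_genome=source_id,
            position=start,
            strand=strand,
        )
        reads.append(rec)
        read_map[rid] = rec
        idx += 1

    for gid, c in zip(gids, counts):
        genome = catalogue[gid].seq
        for _ in range(int(c)):
            _emit(gid, genome)
    for _ in range(n_host):
        _emit("host", host_seq)
    return reads, read_map


def simulate_pair_study(
    config: SimulationConfig,
    host_seq: str | None = None,
) -> tuple[dict[str, list[SimulatedRead]], GroundTruth]:
    """Full simulation: catalogue, communities, reads for every sample."""
    rng = config.rng()
    catalogue = generate_genomes(
        config.n_genomes_pool, config.genome_length_range, config.gc_target, rng
    )
    if host_seq is None and config.host_contamination_fraction > 0:
        host_seq = _random_seq(rng, 20000, 0.41)
    communities = generate_pair_communities(catalogue, config, rng)
    truth = GroundTruth(catalogue=dict(catalogue), communities=communities)
    reads_by_sample: dict[str, list[SimulatedRead]] = {}
    for sample, community in communities.items():
        reads, rmap = simulate_reads(
            community, catalogue, config, rng, sample=sample, host_seq=host_seq
        )
        reads_by_sample[sample] = reads
        truth.read_map.update(rmap)
    return reads_by_sample, truth


def community_contigs(
    communities: Mapping[str, Mapping[str, float]],
    catalogue: Mapping[str, GenomeRecord],
    max_contig_len: int = 6000,
) -> dict[str, dict[str, str]]:
    """Deterministic contig sets per sample, one contig per present genome.

    A fast stand-in for read simulation + assembly when only contig-level
    statistics (homolog sharing, permutation tests, beta diversity) are under
    study: each genome contributes its leading segment (capped at
    ``max_contig_len``), identically in every sample carrying it, so two
    samples share homologous contigs exactly when they share genomes.
    """
    out: dict[str, dict[str, str]] = {}
    for sample, comm in communities.items():
        out[sample] = {
            f"{sample}|{gid}": catalogue[gid].seq[:max_contig_len] for gid in sorted(comm)
        }
    return out


def generate_hit_table(
    contig_families: Mapping[str, str | None],
    rng: np.random.Generator | int = 0,
    n_decoys: int = 2,
    decoy_families: tuple[str, ...] = ("Inoviridae", "Phycodnaviridae"),
) -> tuple[list[list], dict[str, str]]:
    """Synthetic 12-column hit records standing in for a TBLASTX search.

    ``contig_families`` maps contig id -> truth family (None for a contig
    that should remain unassigned).  The best hit of an assigned contig
    carries the truth family at E < 1e-20; decoy hits to other families sit
    at weaker E-values (> 1e-20).  Returns (rows, subject -> family map).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rows: list[list] = []
    subject_family: dict[str, str] = {}
    counter = 0
    for cid in sorted(contig_families):
        family = contig_families[cid]
        if family is not None:
            sid = f"ref|{counter:05d}"
            counter += 1
            subject_family[sid] = family
            e = 10.0 ** -float(rng.uniform(25, 60))
            length = int(rng.integers(300, 1500))
            ident = float(rng.uniform(0.85, 1.0))
            rows.append(
                [cid, sid, round(100 * ident, 2), length,
                 int(length * (1 - ident)), 0, 1, length, 1, length, e,
                 round(2.0 * length * ident, 1)]
            )
        for _ in range(n_decoys):
            sid = f"ref|{counter:05d}"
            counter += 1
            subject_family[sid] = decoy_families[int(rng.integers(len(decoy_families)))]
            e = 10.0 ** -float(rng.uniform(3, 19))
            length = int(rng.integers(50, 300))
            rows.append(
                [cid, sid, round(float(rng.uniform(70, 90)), 2), length,
                 int(length * 0.2), 1, 1, length, 1, length, e, round(length * 1.0, 1)]
            )
    return rows, subject_family
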