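"""Homologous Virus Diversity Index (HVDI).

Assemblers split one virus across several contigs whenever coverage dips or
repeats confuse the layout, so a raw contig spectrum overstates richness.
The HVDI corrects for this within each sample: contigs are nodes, an edge
joins two contigs whose best local alignment has E < 1e-20 and spans at
least half of the shorter contig, and each connected component of that
homology graph is treated as one virus.  Read counts of member contigs are
pooled into a per-virus abundance, and the Shannon index
H = -sum p_i ln p_i of the pooled spectrum is the HVDI.  Isolated contigs
count as singular viruses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import entropy as _scipy_entropy

from .homology import DEFAULT_SCORING, ScoringParams, homolog_pairs


@dataclass
class VirusClusterSpectrum:
    """Virus-cluster -> pooled read count, with contig provenance."""

    counts: dict[str, int]
    provenance: dict[str, list[str]]

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_clusters(self) -> int:
        return len(self.counts)


def build_virus_clusters(
    contig_ids: Iterable[str],
    edges: Iterable[tuple[str, str] | tuple[str, str, object]],
) -> list[set[str]]:
    """Connected components of the intra-sample homology graph.

    Nodes with no edges form singleton clusters.  Components are returned
    sorted by their lexicographically smallest member for determinism.
    """
    g = nx.Graph()
    g.add_nodes_from(contig_ids)
    for e in edges:
        u, v = e[0], e[1]
        if u not in g or v not in g:
            raise ValueError(f"edge ({u}, {v}) references unknown contig")
        g.add_edge(u, v)
    return sorted(nx.connected_components(g), key=lambda c: min(c))


def collapse_spectrum(
    clusters: Sequence[set[str]],
    contig_counts: Mapping[str, int],
) -> VirusClusterSpectrum:
    """Pool member-contig read counts into one count per virus cluster."""
    counts: dict[str, int] = {}
    provenance: dict[str, list[str]] = {}
    for k, members in enumerate(clusters):
        for m in members:
            c = contig_counts[m]
            if c < 0:
                raise ValueError(f"negative read count for contig {m}")
        cid = f"virus_{k:04d}"
        counts[cid] = sum(contig_counts[m] for m in members)
        provenance[cid] = sorted(members)
    return VirusClusterSpectrum(counts=counts, provenance=provenance)


def shannon(spectrum: Mapping[str, int] | Sequence[float], base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i of a count spectrum (nats by default)."""
    values = list(spectrum.values()) if isinstance(spectrum, Mapping) else list(spectrum)
    total = sum(values)
    if not values or total <= 0:
        raise ValueError("spectrum must contain positive total counts")
    return float(_scipy_entropy(values, base=base))


@dataclass
class HvdiResult:
    hvdi: float
    spectrum: VirusClusterSpectrum
    n_clusters: int
    n_contigs: int
    total_reads: int


def hvdi(
    contigs: Mapping[str, str],
    contig_counts: Mapping[str, int],
    e_max: float = 1e-20,
    min_cover: float = 0.5,
    scoring: ScoringParams = DEFAULT_SCORING,
    base: float | None = None,
) -> HvdiResult:
    """Full HVDI for one sample.

    ``contigs`` maps contig id -> consensus sequence (already length
    filtered); ``contig_counts`` maps contig id -> reads assigned by the
    assembler.  Composes homolog search, clustering, spectrum collapse and
    the Shannon index; also reports the cluster count as a genotype
    richness proxy.
    """
    missing = set(contigs) - set(contig_counts)
    if missing:
        raise ValueError(f"contigs without read counts: {sorted(missing)[:3]}...")
    edges = homolog_pairs(contigs, e_max=e_max, min_cover=min_cover, scoring=scoring)
    clusters = build_virus_clusters(contigs.keys(), edges)
    spectrum = collapse_spectrum(clusters, contig_counts)
    return HvdiResult(
        hvdi=shannon(spectrum.counts, base=base),
        spectrum=spectrum,
        n_clusters=spectrum.n_clusters,
        n_contigs=len(contigs),
        total_reads=spectrum.total_reads,
    )
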