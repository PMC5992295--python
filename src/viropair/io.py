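"""Readers, writers, run configuration and the pipeline orchestrator.

FASTA/FASTQ go through Bio.SeqIO (Phred+33 qualities, sequences normalized
to upper case).  Homology hits travel in the 12-column tabular dialect
(query, subject, %identity, aln length, mismatches, gap opens, qstart,
qend, sstart, send, evalue, bitscore) with 1-based inclusive coordinates
and minus-strand hits encoded by sstart > send.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import assembly as asm
from . import community as comm
from . import sharing as sh
from . import synth
from .hvdi import hvdi as _hvdi
from .homology import HomologyHit, DEFAULT_SCORING
from .read_qc import QCParams, Read, qc_pipeline

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# sequence formats
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: uppercase sequence}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path, source: str = "") -> list[Read]:
    """FASTQ (Phred+33) -> Read list; malformed records raise with the id."""
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            reads.append(
                Read(
                    rec.id,
                    str(rec.seq).upper(),
                    "".join(chr(q + 33) for q in quals),
                    source=source,
                )
            )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ near record {len(reads) + 1}: {exc}")
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# 12-column hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_hits(hits: Iterable[HomologyHit | Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            if isinstance(h, HomologyHit):
                row = [
                    h.query_id, h.subject_id, f"{100 * h.identity:.2f}", h.length,
                    h.mismatches, 0, h.qstart, h.qend, h.sstart, h.send,
                    f"{h.e_value:.3g}", f"{h.bitscore():.1f}",
                ]
            else:
                row = list(h)
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_hits(path: str | Path) -> tuple[list[HomologyHit], int]:
    """Parse a 12-column hit table; returns (hits, skipped row count)."""
    hits: list[HomologyHit] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                skipped += 1
                continue
            try:
                sstart, send = int(parts[8]), int(parts[9])
                hits.append(
                    HomologyHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        score=float(parts[11]),
                        identity=float(parts[2]) / 100.0,
                        length=int(parts[3]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=sstart,
                        send=send,
                        strand="-" if sstart > send else "+",
                        e_value=float(parts[10]),
                    )
                )
            except ValueError:
                skipped += 1
    if skipped:
        logger.warning("read_hits(%s): skipped %d malformed rows", path, skipped)
    return hits, skipped


def hits_to_rows(hits: Iterable[HomologyHit]) -> list[list]:
    rows = []
    for h in hits:
        rows.append([
            h.query_id, h.subject_id, round(100 * h.identity, 2), h.length,
            h.mismatches, 0, h.qstart, h.qend, h.sstart, h.send, h.e_value,
            round(h.bitscore(), 1),
        ])
    return rows


# ---------------------------------------------------------------------------
# run configuration / manifest
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = {"simulation", "qc", "assembly", "permutation", "thresholds",
                    "out_dir", "seed", "log_level"}


@dataclass
class RunConfig:
    """Validated parameters for the end-to-end pipeline."""

    simulation: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    qc: QCParams = field(default_factory=QCParams)
    assembly: asm.AssemblyParams = field(default_factory=asm.AssemblyParams)
    permutation: sh.PermutationParams = field(default_factory=sh.PermutationParams)
    beta_e_max: float = 1e-10
    taxonomy_e_max: float = 1e-20
    out_dir: str = "viropair_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "simulation" in raw:
            kwargs["simulation"] = synth.SimulationConfig(**{
                **raw["simulation"],
                **({"genome_length_range": tuple(raw["simulation"]["genome_length_range"])}
                   if "genome_length_range" in raw["simulation"] else {}),
            })
        if "qc" in raw:
            kwargs["qc"] = QCParams(**raw["qc"])
        if "assembly" in raw:
            kwargs["assembly"] = asm.AssemblyParams(**raw["assembly"])
        if "permutation" in raw:
            kwargs["permutation"] = sh.PermutationParams(**raw["permutation"])
        thresholds = raw.get("thresholds", {})
        for key in thresholds:
            if key not in ("beta_e_max", "taxonomy_e_max"):
                raise ValueError(f"unknown threshold {key!r}")
        kwargs.update(thresholds)
        for key in ("out_dir", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        cfg = cls(**kwargs)
        if cfg.beta_e_max <= 0 or cfg.taxonomy_e_max <= 0:
            raise ValueError("thresholds must be positive")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "simulation": asdict(self.simulation),
                "qc": asdict(self.qc),
                "assembly": asdict(self.assembly),
                "permutation": asdict(self.permutation),
                "thresholds": {"beta_e_max": self.beta_e_max,
                               "taxonomy_e_max": self.taxonomy_e_max},
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _atomic_write_json(obj, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
    os.replace(tmp, path)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> QC -> assemble -> HVDI -> sharing -> beta diversity.

    Persists per-stage artifacts under ``config.out_dir`` and writes a run
    manifest (config hash, runtimes, outputs) at the end.  Returns a
    summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": [],
    }
    t0 = time.time()
    sim = config.simulation
    reads_by_sample, truth = synth.simulate_pair_study(sim)
    manifest["stages"]["simulate"] = round(time.time() - t0, 3)

    rng = np.random.default_rng(config.seed)
    summary: dict = {"samples": {}}
    viromes: dict[str, dict[str, str]] = {}
    contig_counts_by_sample: dict[str, dict[str, int]] = {}
    t0 = time.time()
    for sample, sreads in reads_by_sample.items():
        reads = [Read(r.id, r.seq, r.qual, source=sample) for r in sreads]
        kept, report = qc_pipeline(reads, config.qc)
        contigs, _ = asm.assemble(kept, config.assembly)
        contigs = asm.filter_contigs(contigs, config.assembly.min_contig_len)
        viromes[sample] = {c.id: c.consensus for c in contigs}
        contig_counts_by_sample[sample] = {c.id: c.total_reads for c in contigs}
        write_fasta(viromes[sample], out / f"{sample}.contigs.fasta")
        manifest["outputs"].append(f"{sample}.contigs.fasta")
        summary["samples"][sample] = {
            "qc": report.as_dict(),
            "n_contigs": len(contigs),
        }
    manifest["stages"]["qc_assembly"] = round(time.time() - t0, 3)

    t0 = time.time()
    hvdi_table = {}
    for sample in viromes:
        if viromes[sample]:
            res = _hvdi(viromes[sample], contig_counts_by_sample[sample])
            hvdi_table[sample] = {"hvdi": res.hvdi, "clusters": res.n_clusters,
                                  "reads": res.total_reads}
    _atomic_write_json(hvdi_table, out / "hvdi.json")
    manifest["outputs"].append("hvdi.json")
    summary["hvdi"] = hvdi_table
    manifest["stages"]["hvdi"] = round(time.time() - t0, 3)

    t0 = time.time()
    pairs = {}
    for p in range(sim.n_pairs):
        milk, stool = f"pair{p}_milk", f"pair{p}_stool"
        if viromes.get(milk) and viromes.get(stool):
            pairs[f"pair{p}"] = {"milk": viromes[milk], "stool": viromes[stool]}
    if len(pairs) >= 3:
        table = sh.within_between_table(
            pairs, config.permutation, rng=rng
        )
        table.to_csv(out / "sharing_table.tsv", sep="\t", index=False)
        manifest["outputs"].append("sharing_table.tsv")
        summary["sharing_table"] = table.to_dict(orient="records")
    manifest["stages"]["sharing"] = round(time.time() - t0, 3)

    t0 = time.time()
    nonempty = {s: v for s, v in viromes.items() if v}
    if len(nonempty) >= 2:
        features = comm.build_feature_table(nonempty, e_max=config.beta_e_max)
        dm = comm.bray_curtis(features)
        ord_res = comm.pcoa(dm, k=2)
        features.to_csv(out / "feature_table.tsv", sep="\t")
        dm.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
        ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        manifest["outputs"] += ["feature_table.tsv", "bray_curtis.tsv",
                                "pcoa_coordinates.tsv"]
        summary["pcoa_proportion_explained"] = ord_res.proportion_explained.tolist()
    manifest["stages"]["beta_diversity"] = round(time.time() - t0, 3)

    _atomic_write_json(manifest, out / "manifest.json")
    _atomic_write_json(summary, out / "summary.json")
    return summary
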