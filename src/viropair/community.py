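"""Inter-virome community analysis: beta diversity, taxonomy, group stats, GC.

Beta diversity follows the cross-database comparison design: for every
ordered sample pair (i, j) the feature is the fraction of sample i's
contigs with at least one hit in sample j at E < 1e-10; the resulting
per-sample feature vectors feed Bray-Curtis dissimilarity and classical
PCoA.  Taxonomy assigns each contig the viral family of its best tabular
hit below E = 1e-20, with a packaged family -> phage/eukaryotic category
table.  Group comparisons use two-tailed t-tests or the Mann-Whitney U
test (exact for small samples).
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy import stats as sps

from .homology import DEFAULT_SCORING, ScoringParams, cross_virome_hits

logger = logging.getLogger(__name__)


def family_categories() -> dict[str, str]:
    """Packaged family -> {phage, eukaryotic} lookup (editable TSV)."""
    text = (
        importlib.resources.files("viropair")
        .joinpath("data/family_categories.tsv")
        .read_text()
    )
    out: dict[str, str] = {}
    for line in text.strip().splitlines()[1:]:
        family, category = line.split("\t")
        out[family] = category
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def build_feature_table(
    viromes: Mapping[str, Mapping[str, str]],
    e_max: float = 1e-10,
    scoring: ScoringParams = DEFAULT_SCORING,
    binary: bool = False,
) -> pd.DataFrame:
    """Cross-virome hit-fraction features.

    Cell (i, j) is the fraction of sample i's contigs with >= 1 hit among
    sample j's contigs at E < ``e_max`` (presence/absence of any sharing
    when ``binary``).  Samples with zero contigs yield all-zero rows (and a
    zero diagonal) with a warning.
    """
    samples = sorted(viromes)
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    mat = pd.DataFrame(0.0, index=samples, columns=samples)
    for i in samples:
        qi = viromes[i]
        if not qi:
            warnings.warn(f"sample {i!r} has zero contigs; row left at 0")
            continue
        for j in samples:
            if i == j:
                mat.loc[i, j] = 1.0
                continue
            hits = cross_virome_hits(qi, viromes[j], e_max=e_max, scoring=scoring)
            frac = len({h.query_id for h in hits}) / len(qi)
            mat.loc[i, j] = float(frac > 0) if binary else frac
    return mat


@dataclass
class DistanceMatrix:
    data: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        d = self.data
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("distance matrix must be square and symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)


def bray_curtis(features: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y) on rows.

    A pair of all-zero rows has no defined dissimilarity; it is set to 0
    with a warning.
    """
    x = features.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("features must be nonnegative")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            if denom == 0:
                warnings.warn(
                    f"samples {features.index[i]!r} and {features.index[j]!r} are "
                    "both empty; Bray-Curtis set to 0"
                )
                val = 0.0
            else:
                val = np.abs(x[i] - x[j]).sum() / denom
            d[i, j] = d[j, i] = val
    return DistanceMatrix(d, list(features.index))


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalue_magnitude: float


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical (Torgerson) principal coordinates analysis.

    Double-centers -0.5 * D^2, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues.  Negative eigenvalues
    are dropped; their summed magnitude is reported.  ``k`` is truncated to
    the number of positive eigenvalues with a warning when it exceeds it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = dm.data
    n = d.shape[0]
    b = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(evals[0]), 1.0))
    pos = evals > tol
    neg_mag = float(-evals[evals < -tol].sum())
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating k={k}")
        k = max(n_pos, 1) if n_pos else 0
    evals_pos = evals[pos][:k] if n_pos else np.array([])
    coords = (
        evecs[:, pos][:, :k] * np.sqrt(evals_pos)
        if n_pos
        else np.zeros((n, 0))
    )
    total = evals[pos].sum() if n_pos else 1.0
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=dm.labels, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=evals[pos] if n_pos else np.array([]),
        proportion_explained=(evals[pos] / total) if n_pos else np.array([]),
        negative_eigenvalue_magnitude=neg_mag,
    )


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyAssignment:
    assignments: dict[str, str]  # contig id -> family or "unassigned"
    categories: dict[str, str]  # contig id -> phage/eukaryotic/unassigned
    abundance: pd.DataFrame  # per-sample family percentages (of assigned)


def assign_taxonomy(
    hits: Sequence[Sequence],
    subject_families: Mapping[str, str],
    e_max: float = 1e-20,
    contig_samples: Mapping[str, str] | None = None,
    contig_ids: Sequence[str] | None = None,
) -> TaxonomyAssignment:
    """Best-hit family assignment from 12-column tabular hit records.

    The best hit per contig is the lowest E-value (ties: highest bitscore,
    then first record); contigs whose best hit is at or above ``e_max`` are
    "unassigned".  ``contig_samples`` optionally maps contigs to samples
    for the per-sample family-abundance rollup (percent of assigned
    contigs); ``contig_ids`` may list contigs with no hits at all.
    """
    best: dict[str, tuple[float, float, int, str]] = {}
    skipped = 0
    for order, row in enumerate(hits):
        if len(row) != 12:
            skipped += 1
            continue
        try:
            qid, sid = str(row[0]), str(row[1])
            e, bits = float(row[10]), float(row[11])
        except (TypeError, ValueError):
            skipped += 1
            continue
        key = (e, -bits, order)
        if qid not in best or key < (best[qid][0], -best[qid][1], best[qid][2]):
            best[qid] = (e, bits, order, sid)
    if skipped:
        logger.warning("assign_taxonomy: skipped %d malformed hit rows", skipped)

    cats = family_categories()
    assignments: dict[str, str] = {}
    categories: dict[str, str] = {}
    all_ids = set(best) | set(contig_ids or [])
    for cid in sorted(all_ids):
        if cid in best and best[cid][0] < e_max:
            fam = subject_families.get(best[cid][3], "unassigned")
        else:
            fam = "unassigned"
        assignments[cid] = fam
        categories[cid] = cats.get(fam, "unassigned") if fam != "unassigned" else "unassigned"

    sample_of = contig_samples or {cid: "all" for cid in assignments}
    rows: dict[str, dict[str, int]] = {}
    for cid, fam in assignments.items():
        if fam == "unassigned":
            continue
        s = sample_of.get(cid, "all")
        rows.setdefault(s, {})[fam] = rows.get(s, {}).get(fam, 0) + 1
    abundance = pd.DataFrame(rows).T.fillna(0.0).sort_index()
    if not abundance.empty:
        abundance = abundance.div(abundance.sum(axis=1), axis=0) * 100.0
    return TaxonomyAssignment(assignments, categories, abundance)


# ---------------------------------------------------------------------------
# group statistics & GC
# ---------------------------------------------------------------------------


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "t_two_tailed",
) -> tuple[float, float]:
    """Two-sample comparison; returns (statistic, two-sided p).

    ``t_two_tailed``: Welch-free two-sample t-test (equal-variance, the
    classic form).  ``mann_whitney``: exact when the combined sample size
    is <= 20, normal approximation with tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method == "t_two_tailed":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test requires >= 2 values per group")
        if np.array_equal(a, b):
            return 0.0, 1.0
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return float(t), float(p)
    if method == "mann_whitney":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("Mann-Whitney requires >= 1 value per group")
        mode = "exact" if len(a) + len(b) <= 20 else "asymptotic"
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=mode)
        return float(u), float(p)
    raise ValueError(f"unknown method {method!r}")


def gc_content(seq: str) -> float:
    """(G + C) / length of a nucleotide sequence."""
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def gc_summary(contigs_by_sample: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Per-sample median and quartiles of contig GC fraction."""
    rows = []
    for sample in sorted(contigs_by_sample):
        gcs = [gc_content(s) for s in contigs_by_sample[sample].values()]
        if not gcs:
            rows.append({"sample": sample, "n_contigs": 0, "gc_median": np.nan,
                         "gc_q1": np.nan, "gc_q3": np.nan})
            continue
        q1, med, q3 = np.percentile(gcs, [25, 50, 75])
        rows.append({"sample": sample, "n_contigs": len(gcs), "gc_median": med,
                     "gc_q1": q1, "gc_q3": q3})
    return pd.DataFrame(rows).set_index("sample")
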