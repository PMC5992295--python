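"""Beta diversity, taxonomy parsing, group statistics, GC summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from viropair.community import (
    DistanceMatrix,
    assign_taxonomy,
    bray_curtis,
    build_feature_table,
    compare_groups,
    family_categories,
    gc_content,
    gc_summary,
    pcoa,
)
from viropair.synth import generate_hit_table

from conftest import random_seq


class TestFeatureTable:
    def test_identical_samples_all_ones(self, rng):
        contigs = {f"c{i}": random_seq(rng, 2500) for i in range(3)}
        t = build_feature_table({"s1": dict(contigs), "s2": dict(contigs)})
        assert (t.to_numpy() == 1.0).all()

    def test_disjoint_samples_zero_off_diagonal(self, rng):
        t = build_feature_table({
            "s1": {f"a{i}": random_seq(rng, 2400) for i in range(3)},
            "s2": {f"b{i}": random_seq(rng, 2400) for i in range(3)},
        })
        assert t.loc["s1", "s2"] == 0.0 and t.loc["s2", "s1"] == 0.0
        assert t.loc["s1", "s1"] == 1.0

    def test_half_shared_near_half(self, rng):
        genomes = [random_seq(rng, 2500) for _ in range(4)]
        s1 = {f"a{i}": g for i, g in enumerate(genomes)}
        s2 = {f"b{i}": genomes[i] if i < 2 else random_seq(rng, 2500) for i in range(4)}
        t = build_feature_table({"s1": s1, "s2": s2})
        assert t.loc["s1", "s2"] == 0.5

    def test_empty_sample_warns_zero_row(self, rng):
        with pytest.warns(UserWarning):
            t = build_feature_table({
                "full": {"c": random_seq(rng, 2400)},
                "empty": {},
            })
        assert t.loc["empty"].sum() == 0.0


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        f = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert bray_curtis(f).data[0, 1] == 0.0

    def test_disjoint_support_one(self):
        f = pd.DataFrame([[1.0, 0.0], [0.0, 3.0]], index=["a", "b"])
        assert bray_curtis(f).data[0, 1] == 1.0

    def test_worked_example(self):
        f = pd.DataFrame([[1, 2, 3], [2, 1, 3]], index=["a", "b"], dtype=float)
        assert math.isclose(bray_curtis(f).data[0, 1], 2 / 12)

    def test_matrix_axioms_fuzz(self, rng):
        f = pd.DataFrame(rng.random((6, 8)), index=[f"s{i}" for i in range(6)])
        dm = bray_curtis(f)
        d = dm.data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_negative_features_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[-1.0, 0.0], [0.0, 1.0]]))

    def test_two_empty_rows_warn(self):
        f = pd.DataFrame([[0.0, 0.0], [0.0, 0.0]], index=["a", "b"])
        with pytest.warns(UserWarning):
            dm = bray_curtis(f)
        assert dm.data[0, 1] == 0.0


class TestPcoa:
    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(d, ["a", "b", "c"]), k=2)
        coords = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert math.isclose(np.linalg.norm(coords[i] - coords[j]), 1.0,
                                    abs_tol=1e-9)

    def test_roundtrip_on_euclidean_input(self, rng):
        pts = rng.random((6, 2)) * 10
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix(d, [f"s{i}" for i in range(6)]), k=2)
        coords = res.coordinates.to_numpy()
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.abs(d2 - d).max() < 1e-6

    def test_two_points(self):
        res = pcoa(DistanceMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]), ["a", "b"]), k=1)
        coords = res.coordinates.to_numpy().ravel()
        assert np.allclose(sorted(coords), [-0.25, 0.25])

    def test_matches_skbio_reference(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.random((5, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ours = pcoa(DistanceMatrix(d, list("abcde")), k=3)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, list("abcde")))
        ref = theirs.samples.to_numpy()[:, :3]
        got = ours.coordinates.to_numpy()
        # axes defined up to sign
        for ax in range(3):
            assert np.allclose(got[:, ax], ref[:, ax], atol=1e-8) or np.allclose(
                got[:, ax], -ref[:, ax], atol=1e-8
            )

    def test_k_truncated_with_warning(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning):
            res = pcoa(DistanceMatrix(d, ["a", "b"]), k=5)
        assert res.coordinates.shape[1] == 1

    def test_centered_and_sorted(self, rng):
        pts = rng.random((5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix(d, list("abcde")), k=2)
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)
        e = res.eigenvalues
        assert (np.diff(e) <= 1e-12).all()


class TestTaxonomy:
    def test_best_hit_assignment_and_category(self):
        rows, fam_map = generate_hit_table(
            {"c1": "Siphoviridae", "c2": "Herpesviridae"}, rng=4
        )
        res = assign_taxonomy(rows, fam_map)
        assert res.assignments["c1"] == "Siphoviridae"
        assert res.categories["c1"] == "phage"
        assert res.assignments["c2"] == "Herpesviridae"
        assert res.categories["c2"] == "eukaryotic"

    def test_weak_hits_stay_unassigned(self):
        rows = [["c", "s1", 90.0, 100, 10, 0, 1, 100, 1, 100, 1e-15, 120.0]]
        res = assign_taxonomy(rows, {"s1": "Myoviridae"})
        assert res.assignments["c"] == "unassigned"

    def test_threshold_is_strict(self):
        rows = [["c", "s1", 90.0, 100, 10, 0, 1, 100, 1, 100, 1e-20, 120.0]]
        res = assign_taxonomy(rows, {"s1": "Myoviridae"})
        assert res.assignments["c"] == "unassigned"  # E < 1e-20 required

    def test_ties_broken_by_bitscore(self):
        rows = [
            ["c", "lo", 90.0, 100, 10, 0, 1, 100, 1, 100, 1e-30, 100.0],
            ["c", "hi", 90.0, 100, 10, 0, 1, 100, 1, 100, 1e-30, 200.0],
        ]
        res = assign_taxonomy(rows, {"lo": "Myoviridae", "hi": "Siphoviridae"})
        assert res.assignments["c"] == "Siphoviridae"

    def test_malformed_rows_skipped(self):
        rows = [
            ["c", "s1", 90.0, 100, 10, 0, 1, 100, 1, 100, 1e-30, 100.0],
            ["c", "bad_row"],
        ]
        res = assign_taxonomy(rows, {"s1": "Podoviridae"})
        assert res.assignments["c"] == "Podoviridae"

    def test_fixture_accuracy_100_pct(self, rng):
        families = ["Siphoviridae", "Myoviridae", "Podoviridae", "Herpesviridae"]
        truth = {f"c{i:03d}": families[i % 4] for i in range(100)}
        rows, fam_map = generate_hit_table(truth, rng=8)
        res = assign_taxonomy(rows, fam_map)
        assert all(res.assignments[c] == truth[c] for c in truth)

    def test_abundance_sums_to_100(self):
        truth = {f"c{i}": ("Siphoviridae" if i % 2 else "Myoviridae") for i in range(10)}
        rows, fam_map = generate_hit_table(truth, rng=9)
        res = assign_taxonomy(rows, fam_map)
        assert np.allclose(res.abundance.sum(axis=1), 100.0)

    def test_category_table_loads(self):
        cats = family_categories()
        assert cats["Siphoviridae"] == "phage"
        assert cats["Herpesviridae"] == "eukaryotic"


class TestCompareGroups:
    def test_identical_groups_t(self):
        t, p = compare_groups([1, 2, 3], [1, 2, 3], "t_two_tailed")
        assert t == 0.0 and p == 1.0

    def test_mann_whitney_exact_small_sample(self):
        u, p = compare_groups([1, 2, 3], [4, 5, 6], "mann_whitney")
        assert u == 0.0
        assert math.isclose(p, 0.1)  # 2 * 1/C(6,3)

    def test_t_sign_flips_p_unchanged(self):
        t1, p1 = compare_groups([1, 2, 3], [4, 5, 6], "t_two_tailed")
        t2, p2 = compare_groups([4, 5, 6], [1, 2, 3], "t_two_tailed")
        assert t1 == -t2 and p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0], "mann_whitney")
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0], "t_two_tailed")

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], [3, 4], "anova")


class TestGC:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("GATC", 0.5)])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == expected

    def test_gc_summary_quartiles(self):
        contigs = {"s": {"a": "GGCC", "b": "GATC", "c": "ATAT"}}
        tbl = gc_summary(contigs)
        assert tbl.loc["s", "gc_median"] == 0.5
        assert tbl.loc["s", "n_contigs"] == 3

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")
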