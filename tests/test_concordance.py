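"""Genetic distance, Mantel test, NMDS and Ward bootstrap clustering."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from dinolipid.concordance import (
    ClusterTree,
    DistanceMatrix,
    concordance_report,
    mantel,
    nmds,
    p_distance,
    ward_bootstrap,
)
from dinolipid.multivariate import ParetoScaler
from dinolipid.synthetic import SyntheticDesign, gen_alignment, gen_feature_table

from conftest import SUITE_SEED


def _dm(points: np.ndarray, labels=None) -> DistanceMatrix:
    labels = labels or [f"t{i}" for i in range(len(points))]
    return DistanceMatrix(labels, squareform(pdist(points)))


class TestPDistance:
    def test_identical_sequences_zero(self):
        dm = p_distance([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert dm.D[0, 1] == 0.0

    def test_hand_counted_mismatches(self):
        dm = p_distance([("a", "ACGTACGTAC"), ("b", "ACGTACGTTT")])
        assert dm.D[0, 1] == pytest.approx(0.2)

    def test_gap_sites_excluded_pairwise(self):
        dm = p_distance([("a", "ACG-A"), ("b", "ACGTA")])
        assert dm.D[0, 1] == 0.0  # 0 mismatches over 4 compared sites

    def test_all_gap_pair_rejected_with_names(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            p_distance([("a", "----"), ("b", "ACGT"), ("c", "ACGT")])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance([("a", "ACGT"), ("b", "ACG")])

    def test_triangle_inequality_on_gap_free_alignments(self):
        rng = np.random.default_rng(SUITE_SEED)
        bases = np.array(list("ACGT"))
        seqs = [("t%d" % i, "".join(rng.choice(bases, 60))) for i in range(6)]
        dm = p_distance(seqs)
        for i, j, k in itertools.permutations(range(6), 3):
            assert dm.D[i, j] <= dm.D[i, k] + dm.D[k, j] + 1e-12

    def test_fasta_round_trip(self, tmp_path):
        from dinolipid.synthetic import write_fasta

        recs, Dtrue = gen_alignment(SyntheticDesign(seed=SUITE_SEED))
        path = tmp_path / "aln.fasta"
        write_fasta(recs, path)
        dm = p_distance(path)
        assert np.allclose(dm.D, Dtrue, atol=1e-12)


class TestMantel:
    def test_self_correlation_one(self):
        d = _dm(np.random.default_rng(0).normal(size=(6, 2)))
        r, p = mantel(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.01

    def test_affine_invariance(self):
        d1 = _dm(np.random.default_rng(1).normal(size=(6, 2)))
        D2 = 3.0 * d1.D + 2.0
        np.fill_diagonal(D2, 0.0)
        r, _ = mantel(d1, DistanceMatrix(d1.labels, D2), n_perm=9, seed=0)
        assert r == pytest.approx(1.0)

    def test_label_mismatch_rejected(self):
        d1 = _dm(np.random.default_rng(2).normal(size=(5, 2)))
        d2 = _dm(np.random.default_rng(3).normal(size=(5, 2)), labels=list("vwxyz"))
        with pytest.raises(ValueError):
            mantel(d1, d2)

    def test_exact_p_matches_independent_enumeration(self):
        """4-taxon partial concordance: p over all 24 permutations."""
        rng = np.random.default_rng(SUITE_SEED)
        P = rng.normal(size=(4, 2))
        d1 = _dm(P)
        d2 = _dm(P + 0.7 * rng.normal(size=(4, 2)))
        r_obs, p = mantel(d1, d2, exact=True)

        iu = np.triu_indices(4, k=1)

        def corr(perm):
            M = d2.D[np.ix_(perm, perm)]
            return np.corrcoef(d1.D[iu], M[iu])[0, 1]

        rs = [corr(perm) for perm in itertools.permutations(range(4))]
        expected = np.mean([r >= r_obs - 1e-12 for r in rs])
        assert p == pytest.approx(expected, abs=1e-12)

    def test_exact_agrees_with_permutation_mode(self):
        rng = np.random.default_rng(SUITE_SEED + 1)
        P = rng.normal(size=(5, 2))
        d1 = _dm(P)
        d2 = _dm(P + 0.8 * rng.normal(size=(5, 2)))
        _, p_exact = mantel(d1, d2, exact=True)
        _, p_perm = mantel(d1, d2, n_perm=10000, seed=3, exact=False)
        # Monte-Carlo error ~ 3·sqrt(p(1-p)/n_perm)
        assert abs(p_perm - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / 10000) + 1e-3

    def test_r_agrees_with_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(SUITE_SEED + 2)
        P = rng.normal(size=(7, 3))
        d1 = _dm(P)
        d2 = _dm(P + rng.normal(size=(7, 3)))
        r_ours, _ = mantel(d1, d2, n_perm=9, seed=0, exact=False)
        r_ref, _, _ = sk_mantel(
            skbio.DistanceMatrix(d1.D, d1.labels),
            skbio.DistanceMatrix(d2.D, d2.labels),
            method="pearson",
            permutations=0,
        )
        assert r_ours == pytest.approx(float(r_ref), abs=1e-10)


class TestNmds:
    def test_perfectly_embeddable_distances_near_zero_stress(self):
        rng = np.random.default_rng(SUITE_SEED)
        D = _dm(rng.normal(size=(8, 2)))
        res = nmds(D, k=2, seed=0)
        assert res.stress < 1e-3

    def test_stress_weakly_decreases_with_dimension(self):
        rng = np.random.default_rng(SUITE_SEED + 1)
        D = _dm(rng.normal(size=(9, 5)))
        s2 = nmds(D, k=2, seed=0).stress
        s3 = nmds(D, k=3, seed=0).stress
        assert s3 <= s2 + 1e-6

    def test_stress_invariant_to_similarity_transforms_of_input_points(self):
        rng = np.random.default_rng(SUITE_SEED + 2)
        P = rng.normal(size=(7, 2))
        theta = 0.9
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        s1 = nmds(_dm(P), k=2, seed=0).stress
        s2 = nmds(_dm(3.0 * P @ R + 5.0), k=2, seed=0).stress
        assert s1 == pytest.approx(s2, abs=1e-4)

    def test_two_cluster_structure_recovered(self):
        """Planted clusters embed at low stress with separation preserved."""
        rng = np.random.default_rng(SUITE_SEED + 3)
        pts = np.vstack(
            [rng.normal(0, 0.3, size=(5, 4)), rng.normal(4, 0.3, size=(5, 4))]
        )
        res = nmds(_dm(pts), k=2, seed=0)
        assert res.stress < 0.2
        a, b = res.coordinates[:5], res.coordinates[5:]
        within = max(np.linalg.norm(a - a.mean(0), axis=1).max(),
                     np.linalg.norm(b - b.mean(0), axis=1).max())
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        assert between > 2 * within

    def test_shepard_pairs_exported(self):
        D = _dm(np.random.default_rng(4).normal(size=(6, 2)))
        res = nmds(D, k=2, seed=0)
        assert res.shepard.shape == (15, 3)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nmds(_dm(np.random.default_rng(5).normal(size=(3, 2))), k=2)


class TestWardBootstrap:
    def test_planted_two_group_bipartition_supported(self, preprocessed):
        X, groups, _, table = preprocessed
        tree = ward_bootstrap(X, labels=table.samples, B=1000, seed=SUITE_SEED)
        bp = frozenset(np.array(table.samples)[groups.to_numpy() == "group1"])
        support = tree.support.get(bp, tree.support.get(frozenset(table.samples) - bp))
        assert support is not None and support >= 0.95

    def test_no_bootstrap_gives_tree_without_support(self, preprocessed):
        X, _, _, table = preprocessed
        tree = ward_bootstrap(X, labels=table.samples, B=0)
        assert tree.support == {}
        assert tree.linkage.shape == (len(table.samples) - 1, 4)

    def test_duplicated_profiles_merge_first_at_zero_height(self):
        rng = np.random.default_rng(SUITE_SEED)
        X = rng.normal(size=(4, 6))
        X[1] = X[0]
        tree = ward_bootstrap(X, labels=list("abcd"), B=0)
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-10)

    def test_constant_profile_rejected_naming_taxon(self):
        X = np.vstack([np.ones(5), np.random.default_rng(1).normal(size=(3, 5))])
        with pytest.raises(ValueError, match="flat"):
            ward_bootstrap(X, labels=["flat", "b", "c", "d"], B=0)

    def test_support_invariant_to_variable_order(self, preprocessed):
        X, _, _, table = preprocessed
        rng = np.random.default_rng(SUITE_SEED)
        t1 = ward_bootstrap(X, labels=table.samples, B=0)
        t2 = ward_bootstrap(
            X[:, rng.permutation(X.shape[1])], labels=table.samples, B=0
        )
        assert set(map(frozenset, t1.bipartitions())) == set(
            map(frozenset, t2.bipartitions())
        )

    def test_newick_export_parses(self, preprocessed):
        from io import StringIO

        from Bio import Phylo

        X, _, _, table = preprocessed
        tree = ward_bootstrap(X, labels=table.samples, B=50, seed=0)
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(table.samples)


class TestConcordanceReport:
    def test_planted_concordance_detected(self):
        """Lipid groups concordant with the two-clade alignment: r > 0, small p."""
        design = SyntheticDesign(seed=SUITE_SEED)
        table, _ = gen_feature_table(design)
        recs, _ = gen_alignment(design)
        rep = concordance_report(
            table, recs, lipid_classes=["DGDG"], n_perm=999, B=100, seed=SUITE_SEED
        )
        e = rep["DGDG"]
        assert e["mantel_r"] > 0.5
        assert e["mantel_p"] <= 0.01
        assert e["nmds"].stress < 0.2
        assert len(e["leave_one_out"]) == len(table.samples)

    def test_too_few_shared_taxa_refused(self):
        design = SyntheticDesign(seed=SUITE_SEED, n_group1=1, n_group2=2)
        table, _ = gen_feature_table(design)
        recs, _ = gen_alignment(design)
        with pytest.raises(ValueError, match="4"):
            concordance_report(table, recs)
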