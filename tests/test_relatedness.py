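"""GRM/FRM construction, cutoff filtering, and relationship-matrix IO."""

import numpy as np
import pytest

import heritkit as hk
from heritkit.errors import ConfigError, DataError, PedigreeError
from heritkit.genio import GenotypeMatrix
from tests.conftest import make_pedigree


class TestAlleleFrequencies:
    def test_hand_count(self):
        G = GenotypeMatrix(["a", "b", "c"], ["v"], np.array([[0], [1], [2]], dtype=np.int8))
        assert hk.allele_frequencies(G)[0] == 0.5

    def test_all_alt(self):
        G = GenotypeMatrix(["a", "b"], ["v"], np.full((2, 1), 2, dtype=np.int8))
        assert hk.allele_frequencies(G)[0] == 1.0

    def test_missing_shrinks_denominator(self):
        # codes 0, 2, missing -> 2 alt alleles over 4 observed
        G = GenotypeMatrix(["a", "b", "c"], ["v"], np.array([[0], [2], [-1]], dtype=np.int8))
        assert hk.allele_frequencies(G)[0] == 0.5

    def test_all_missing_snp_rejected(self):
        G = GenotypeMatrix(["a"], ["v"], np.array([[-1]], dtype=np.int8))
        with pytest.raises(DataError):
            hk.allele_frequencies(G)


class TestGrm:
    def test_hand_cross_product(self):
        """codes (0,2) and (2,2) at p=0.5: standardized (-1.41, 1.41) and
        (1.41, 1.41) -> off-diagonal (-2 + 2)/2 = 0."""
        G = GenotypeMatrix(["a", "b"], ["v1", "v2"],
                           np.array([[0, 2], [2, 2]], dtype=np.int8))
        K = hk.compute_grm(G, freqs=np.array([0.5, 0.5]))
        assert K.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_rows_match_simple_diagonal(self):
        rng = np.random.default_rng(0)
        codes = rng.binomial(2, 0.3, size=(1, 50)).astype(np.int8)
        codes = np.vstack([codes, codes])
        G = GenotypeMatrix(["a", "a_dup"], [f"v{j}" for j in range(50)], codes)
        K = hk.compute_grm(G, freqs=np.full(50, 0.3))
        assert K.matrix[0, 1] == pytest.approx(K.matrix[0, 0], abs=1e-12)

    def test_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.5, 5000)
        codes = rng.binomial(2, p, size=(50, 5000)).astype(np.int8)
        G = GenotypeMatrix([f"s{i}" for i in range(50)], [f"v{j}" for j in range(5000)], codes)
        K = hk.compute_grm(G, freqs=p)
        assert np.diag(K.matrix).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_frequency_rejected(self):
        G = GenotypeMatrix(["a", "b"], ["v"], np.zeros((2, 1), dtype=np.int8))
        with pytest.raises(DataError, match="v"):
            hk.compute_grm(G)

    def test_missing_pairwise_averaging(self):
        """With one missing call, the pair entry averages over the jointly
        observed SNP only (hand-computed)."""
        codes = np.array([[0, 2], [2, -1]], dtype=np.int8)
        G = GenotypeMatrix(["a", "b"], ["v1", "v2"], codes)
        K = hk.compute_grm(G, freqs=np.array([0.5, 0.5]))
        # only v1 jointly observed: (-sqrt2)(sqrt2)/1 = -2
        assert K.matrix[0, 1] == pytest.approx(-2.0)
        assert K.meta["pair_counts"][0, 1] == 1

    def test_pair_mean_tracks_r(self):
        cfg = hk.SimConfig(n_pairs=300, n_snps=3000, r=0.5, seed=21)
        G = hk.simulate_related_pairs(cfg)
        K = hk.compute_grm(G)
        within = K.matrix[np.arange(0, 600, 2), np.arange(1, 600, 2)]
        se = within.std(ddof=1) / np.sqrt(len(within))
        assert within.mean() == pytest.approx(0.5, abs=3 * se)
        across = K.matrix[np.arange(0, 600, 2), np.roll(np.arange(1, 600, 2), 1)]
        assert abs(across.mean()) < 3 * across.std(ddof=1) / np.sqrt(len(across))

    def test_grm_converges_to_frm_for_full_sibs(self):
        """Expected GRM between r=0.5 pair members equals the FRM value 0.5."""
        cfg = hk.SimConfig(n_pairs=1000, n_snps=4000, r=0.5, seed=22)
        G = hk.simulate_related_pairs(cfg)
        K = hk.compute_grm(G)
        within = K.matrix[np.arange(0, 2000, 2), np.arange(1, 2000, 2)]
        # r = 0.5 pairs play the role of full sibs; build the matching pedigree
        sib_rows = []
        for i in range(1000):
            sib_rows.append((f"f{i}", f"pa{i}", "0", "0", "1", "."))
            sib_rows.append((f"f{i}", f"ma{i}", "0", "0", "2", "."))
            sib_rows.append((f"f{i}", f"p{i}_1", f"pa{i}", f"ma{i}", "0", "."))
            sib_rows.append((f"f{i}", f"p{i}_2", f"pa{i}", f"ma{i}", "0", "."))
        ped = make_pedigree(sib_rows)
        frm = hk.pedigree_frm(ped, sparse=False)
        ids = list(ped.ids)
        i1, i2 = ids.index("p0_1"), ids.index("p0_2")
        assert frm.matrix[i1, i2] == 0.5
        assert within.mean() == pytest.approx(
            0.5, abs=3 * within.std(ddof=1) / np.sqrt(len(within))
        )


class TestFrm:
    def test_textbook_relationships(self, nuclear_family):
        K = hk.pedigree_frm(nuclear_family, sparse=False)
        ids = list(nuclear_family.ids)

        def entry(a, b):
            return K.matrix[ids.index(a), ids.index(b)]

        assert entry("dad", "kid") == 0.5  # parent-offspring
        assert entry("dad", "aunt") == 0.5  # full sibs
        assert entry("gpa", "kid") == 0.25  # grandparent-grandchild
        assert entry("aunt", "kid") == 0.25  # avuncular
        assert entry("mom", "dad") == 0.0  # spouses unrelated
        assert entry("kid", "kid") == 1.0  # outbred diagonal

    def test_inbreeding_on_diagonal(self):
        # offspring of a parent-offspring mating: f = 1/4
        ped = make_pedigree(
            [
                ("f", "a", "0", "0", "1", "."),
                ("f", "b", "0", "0", "2", "."),
                ("f", "c", "a", "b", "2", "."),
                ("f", "d", "a", "c", "0", "."),
            ]
        )
        K = hk.pedigree_frm(ped, sparse=False)
        assert K.matrix[3, 3] == pytest.approx(1.25)

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(PedigreeError):
            make_pedigree(
                [
                    ("f", "a", "b", "0", "1", "."),
                    ("f", "b", "a", "0", "2", "."),
                ]
            )

    def test_psd_for_random_pedigrees(self, rng):
        """FRM is a covariance structure: eigenvalues bounded below by ~0."""
        for trial in range(5):
            rows = []
            for fam in range(10):
                k = rng.integers(1, 4)
                rows.append((f"f{fam}", f"f{fam}_p1", "0", "0", "1", "."))
                rows.append((f"f{fam}", f"f{fam}_p2", "0", "0", "2", "."))
                for j in range(k):
                    rows.append((f"f{fam}", f"f{fam}_c{j}", f"f{fam}_p1", f"f{fam}_p2", "0", "."))
                if k >= 1 and rng.random() < 0.5:  # grandchild via c0 and in-law
                    rows.append((f"f{fam}", f"f{fam}_il", "0", "0", "0", "."))
                    rows.append((f"f{fam}", f"f{fam}_g", f"f{fam}_c0", f"f{fam}_il", "0", "."))
            K = hk.pedigree_frm(make_pedigree(rows), sparse=False)
            assert np.linalg.eigvalsh(K.matrix).min() >= -1e-8

    def test_mz_representative_selection(self):
        y, ped = hk.simulate_twin_cohort(3, 2, 0.5, 0.2, 0.0, 0.3, seed=0)
        kept = hk.select_mz_representatives(ped, seed=1)
        assert len(kept) == 10 - 3  # one member of each MZ pair dropped
        kept2 = hk.select_mz_representatives(ped, seed=1)
        assert (kept == kept2).all()


class TestCutoff:
    @staticmethod
    def component(mat, ids=None):
        n = len(mat)
        ids = ids or [f"s{i}" for i in range(n)]
        return hk.CovarianceComponent("grm", np.array(ids, dtype=object), np.asarray(mat, float))

    def test_all_below_cutoff_everyone_kept(self):
        mat = np.eye(4) + 0.01
        kept = hk.grm_cutoff_filter(self.component(mat), cutoff=0.025)
        assert len(kept) == 4

    def test_single_close_pair_loses_one_member(self):
        mat = np.eye(4)
        mat[0, 1] = mat[1, 0] = 0.5
        kept = hk.grm_cutoff_filter(self.component(mat), cutoff=0.025)
        assert len(kept) == 3
        assert len({"s0", "s1"} & set(kept)) == 1

    def test_clique_keeps_exactly_one(self):
        mat = np.eye(3) * 1.0
        mat[~np.eye(3, dtype=bool)] = 0.5
        kept = hk.grm_cutoff_filter(self.component(mat), cutoff=0.025)
        assert len(kept) == 1

    def test_postcondition_on_random_matrices(self, rng):
        for _ in range(10):
            n = 30
            raw = rng.normal(0, 0.03, size=(n, n))
            mat = (raw + raw.T) / 2
            np.fill_diagonal(mat, 1.0)
            K = self.component(mat)
            kept = hk.grm_cutoff_filter(K, cutoff=0.025)
            pos = [list(K.sample_ids).index(s) for s in kept]
            sub = mat[np.ix_(pos, pos)].copy()
            np.fill_diagonal(sub, 0.0)
            assert sub.max() <= 0.025

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ConfigError):
            hk.grm_cutoff_filter(self.component(np.eye(2)), cutoff=-0.1)

    def test_deterministic(self, rng):
        raw = rng.normal(0, 0.05, size=(20, 20))
        mat = (raw + raw.T) / 2
        np.fill_diagonal(mat, 1.0)
        K = self.component(mat)
        assert (hk.grm_cutoff_filter(K) == hk.grm_cutoff_filter(K)).all()


class TestGrmIO:
    def test_tsv_round_trip(self, rng, tmp_path):
        raw = rng.normal(size=(5, 5))
        mat = (raw + raw.T) / 2
        K = TestCutoff.component(mat)
        hk.write_grm_tsv(K, tmp_path / "k.tsv")
        back = hk.read_grm_tsv(tmp_path / "k.tsv")
        assert np.allclose(back.matrix, K.matrix, atol=1e-9)
        assert list(back.sample_ids) == list(K.sample_ids)

    def test_gcta_binary_round_trip(self, rng, tmp_path):
        raw = rng.normal(size=(6, 6)).astype(np.float32)
        mat = ((raw + raw.T) / 2).astype(float)
        K = TestCutoff.component(mat)
        hk.write_grm_gcta(K, tmp_path / "k")
        back = hk.read_grm_gcta(tmp_path / "k")
        assert np.allclose(back.matrix, K.matrix, atol=1e-6)
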