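import numpy as np
import pytest

from hicnets.domains import DomainInteractionMatrix
from hicnets.transnet import (
    ChromPairMatrix,
    bootstrap_shuffle,
    chrom_pair_matrix,
    dr_bootstrap,
    dr_score,
    rss_elbow,
    sign_run_lengths,
)

from conftest import make_domain


def trans_net(values, c1="chr1", c2="chr2"):
    rows = [make_domain(c1, i * 10, i * 10 + 10) for i in range(values.shape[0])]
    cols = [make_domain(c2, j * 10, j * 10 + 10) for j in range(values.shape[1])]
    return DomainInteractionMatrix(rows, cols, values, "trans")


class TestChromPairMatrix:
    def test_single_pair_arithmetic(self):
        net = trans_net(np.full((2, 3), 2.0))
        cpm = chrom_pair_matrix(
            {("chr1", "chr2"): net}, {"chr1": 100, "chr2": 200}
        )
        assert cpm.values[("chr1", "chr2")] == pytest.approx(12.0 / (100 * 200))

    def test_linearity(self, rng):
        v = rng.random((3, 4))
        lengths = {"chr1": 50, "chr2": 70}
        a = chrom_pair_matrix({("chr1", "chr2"): trans_net(v)}, lengths)
        b = chrom_pair_matrix({("chr1", "chr2"): trans_net(2 * v)}, lengths)
        assert b.values[("chr1", "chr2")] == pytest.approx(
            2 * a.values[("chr1", "chr2")]
        )

    def test_missing_pair_rejected(self):
        with pytest.raises(KeyError, match="chr1.*chr2"):
            chrom_pair_matrix({}, {"chr1": 10, "chr2": 10})

    def test_boosted_chromosome_has_largest_row(self, small_genome):
        cpm = chrom_pair_matrix(small_genome.trans, small_genome.chrom_lengths)
        arr = cpm.to_frame()
        assert set(arr.index) == set(small_genome.chrom_lengths)


class TestRssElbow:
    @staticmethod
    def planted_two_clusters(rng, n=10, sep=10.0):
        centers = np.array([0.0, sep])
        assign = np.array([0] * (n // 2) + [1] * (n - n // 2))
        X = centers[assign][:, None] + rng.normal(0, 0.5, (n, n))
        X = 0.5 * (X + X.T)
        np.fill_diagonal(X, 0)
        chroms = [f"chr{i}" for i in range(1, n + 1)]
        vals = {
            (chroms[i], chroms[j]): abs(X[i, j])
            for i in range(n)
            for j in range(i + 1, n)
        }
        return ChromPairMatrix(chroms, vals)

    def test_rss_zero_at_k_equals_rows(self, rng):
        cpm = self.planted_two_clusters(rng, n=6)
        res = rss_elbow(cpm, k_max=5)
        # RSS decreases and hits ~0 when every row is its own cluster
        full = rss_elbow(cpm, k_max=5)
        assert full.rss == sorted(full.rss, reverse=True)
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=6, n_init=5, random_state=0).fit(cpm.to_array())
        assert km.inertia_ == pytest.approx(0.0, abs=1e-9)

    def test_planted_two_clusters_elbow(self, rng):
        cpm = self.planted_two_clusters(rng, n=10, sep=10.0)
        res = rss_elbow(cpm, k_max=6)
        assert res.elbow_k == 2
        assert res.has_clusters

    def test_unstructured_matrix_no_evident_clusters(self, rng):
        # all chromosomes interact alike (small jitter): one global network
        n = 10
        X = 1.0 + rng.normal(0, 0.02, (n, n))
        X = 0.5 * (X + X.T)
        chroms = [f"chr{i}" for i in range(n)]
        vals = {
            (chroms[i], chroms[j]): X[i, j]
            for i in range(n)
            for j in range(i + 1, n)
        }
        res = rss_elbow(ChromPairMatrix(chroms, vals), k_max=6)
        assert not res.has_clusters
        assert res.verdict == "no evident clusters"

    def test_invalid_k_range(self, rng):
        cpm = self.planted_two_clusters(rng, n=5)
        with pytest.raises(ValueError):
            rss_elbow(cpm, k_max=7)


class TestDRScore:
    def test_constant_rows_zero_profile(self):
        with pytest.raises(ValueError):
            # DR identically zero -> sign runs undefined
            dr_score(trans_net(np.ones((3, 2))))

    def test_direct_arithmetic(self):
        v = np.array([[2.0, 0], [1.0, 0], [0.0, 0]])
        # S = [2, 1, 0] -> <S>=1, DR=[1, 0, -1], sigma=sqrt(2/3)
        prof = dr_score(trans_net(v))
        assert prof.mean_S == pytest.approx(1.0)
        assert np.allclose(prof.DR, [1.0, 0.0, -1.0])
        assert prof.sigma == pytest.approx(np.sqrt(2 / 3))

    def test_mean_dr_exactly_zero(self, small_genome):
        for net in small_genome.trans.values():
            prof = dr_score(net)
            assert abs(prof.DR.mean()) < 1e-9
            assert sum(prof.run_lengths) + prof.runs.n_zeros == len(prof.DR)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            dr_score(trans_net(np.zeros((3, 3))))


class TestBootstrapShuffle:
    def test_multiset_preserved_and_reproducible(self, rng):
        net = trans_net(rng.random((6, 5)))
        s1 = bootstrap_shuffle(net, seed=3)
        s2 = bootstrap_shuffle(net, seed=3)
        s3 = bootstrap_shuffle(net, seed=4)
        assert np.array_equal(np.sort(s1.values.ravel()), np.sort(net.values.ravel()))
        assert np.array_equal(s1.values, s2.values)
        assert not np.array_equal(s1.values, s3.values)

    def test_cis_shuffle_stays_symmetric(self, small_genome):
        net = next(iter(small_genome.cis.values()))
        s = bootstrap_shuffle(net, seed=0)
        assert np.allclose(s.values, s.values.T)
        assert np.array_equal(
            np.sort(s.pool()), np.sort(net.pool())
        )

    def test_shuffle_preserves_exponential_scale(self, small_genome):
        """The null keeps the global intensity distribution (same fitted I0)."""
        from hicnets.networks import fit_exponential

        net = next(iter(small_genome.trans.values()))
        f0 = fit_exponential(net.pool())
        f1 = fit_exponential(bootstrap_shuffle(net, seed=1).pool())
        assert f1.I0 == pytest.approx(f0.I0, rel=1e-9)  # same multiset, same fit


class TestSignRuns:
    def test_direct_count(self):
        runs = sign_run_lengths([0.5, 0.1, -0.2, -0.4, -0.1])
        assert runs.run_lengths == [2, 3]
        assert runs.mean_run == 2.5

    def test_alternating(self):
        runs = sign_run_lengths([1, -1, 1, -1])
        assert runs.run_lengths == [1, 1, 1, 1]
        assert runs.mean_run == 1.0

    def test_zeros_break_runs(self):
        runs = sign_run_lengths([1, 1, 0, 1, -1])
        assert runs.run_lengths == [2, 1, 1]
        assert runs.n_zeros == 1
        assert sum(runs.run_lengths) + runs.n_zeros == 5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sign_run_lengths(np.zeros(5))

    @pytest.mark.parametrize("p", [0.3, 0.5, 0.7])
    def test_iid_closed_form_mean_run(self, p):
        """For i.i.d. signs with P(+)=p the mean run length tends to 1/(2p(1-p))."""
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            signs = np.where(rng.random(5000) < p, 1.0, -1.0)
            means.append(sign_run_lengths(signs).mean_run)
        expected = 1.0 / (2 * p * (1 - p))
        assert np.mean(means) == pytest.approx(expected, rel=0.05)

    def test_exponential_decay_fit_on_geometric_runs(self, rng):
        signs = np.where(rng.random(20000) < 0.5, 1.0, -1.0)
        runs = sign_run_lengths(signs)
        # geometric run sizes: log-counts fall linearly, scale 1/ln 2
        assert runs.decay_scale == pytest.approx(1 / np.log(2), rel=0.15)


class TestPlantedBands:
    def test_banded_sigma_and_runs_exceed_bootstrap(self, banded_genome):
        """Banded trans maps beat the shuffled null on sigma and run length."""
        for net in banded_genome.trans.values():
            prof = dr_score(net)
            null = dr_bootstrap(net, replicates=30, seed=5)
            assert prof.sigma > null["sigma_rand"]
            assert prof.mean_run > null["mean_run_rand"]
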