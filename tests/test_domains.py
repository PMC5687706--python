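import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicnets.domains import (
    assign_subcompartments,
    build_interaction_matrices,
    cis_trans_ratio,
    domain_interaction,
    filter_internal_domains,
)
from hicnets.io import ContactMatrix, GenomicInterval

from conftest import make_domain


def brute_force_filter(domains):
    """All-pairs containment oracle (after duplicate collapse)."""
    uniq = sorted(set(domains), key=lambda d: d.sort_key())
    out = []
    for d in uniq:
        contained = any(
            o is not d
            and o.sort_key() != d.sort_key()
            and o.interval.contains(d.interval)
            for o in uniq
        )
        if not contained:
            out.append(d)
    return out


class TestFilterInternal:
    def test_disjoint_kept(self):
        ds = [make_domain("chr1", 0, 10), make_domain("chr1", 20, 30)]
        assert filter_internal_domains(ds) == ds

    def test_contained_removed(self):
        outer = make_domain("chr1", 0, 100_000)
        inner = make_domain("chr1", 20_000, 80_000)
        assert filter_internal_domains([inner, outer]) == [outer]

    def test_nested_chain_with_disjoint(self):
        a = make_domain("chr1", 0, 100)
        b = make_domain("chr1", 10, 90)
        c = make_domain("chr1", 20, 80)
        d = make_domain("chr2", 0, 50)
        kept = filter_internal_domains([c, d, b, a])
        assert kept == brute_force_filter([a, b, c, d]) == [a, d]

    def test_duplicates_collapse_and_shared_edge_containment(self):
        a = make_domain("chr1", 0, 100)
        dup = make_domain("chr1", 0, 100)
        edge = make_domain("chr1", 0, 60)  # same start, shorter: internal
        kept, report = filter_internal_domains([a, dup, edge], return_report=True)
        assert kept == [a]
        assert report["n_duplicates"] == 1 and report["n_internal"] == 1

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 30),
                st.integers(1, 30),
            ),
            max_size=12,
        ),
        st.randoms(use_true_random=False),
    )
    def test_matches_brute_force_idempotent_order_free(self, raw, rnd):
        ds = [make_domain(c, s, s + l) for c, s, l in raw]
        shuffled = list(ds)
        rnd.shuffle(shuffled)
        kept = filter_internal_domains(shuffled)
        assert kept == brute_force_filter(ds)
        assert filter_internal_domains(kept) == kept  # idempotent
        assert len(kept) <= len(ds)


class TestAssignSubcompartments:
    ann = [
        (GenomicInterval("chr1", 0, 200_000), "A1"),
        (GenomicInterval("chr1", 200_000, 300_000), "B1"),
    ]

    def test_unique_overlap_both_modes(self):
        d = [make_domain("chr1", 10_000, 50_000)]
        for mode in ("single", "majority"):
            labeled, _ = assign_subcompartments(d, self.ann, mode)
            assert labeled[0].subcompartment == "A1"

    def test_majority_by_overlap_bp(self):
        # 150 kb on A1, 50 kb on B1
        d = [make_domain("chr1", 50_000, 250_000)]
        single, _ = assign_subcompartments(d, self.ann, "single")
        assert single[0].subcompartment is None
        major, _ = assign_subcompartments(d, self.ann, "majority")
        assert major[0].subcompartment == "A1"

    def test_majority_tie_unassigned_and_reported(self):
        d = [make_domain("chr1", 150_000, 250_000)]  # 50 kb each side
        labeled, report = assign_subcompartments(d, self.ann, "majority")
        assert labeled[0].subcompartment is None
        assert report["n_ties"] == 1

    def test_no_overlap_counted(self):
        d = [make_domain("chr2", 0, 10_000)]
        labeled, report = assign_subcompartments(d, self.ann)
        assert labeled[0].subcompartment is None
        assert report["n_no_overlap"] == 1
        assert report["fraction_assigned"] == 0.0

    def test_conflicting_annotation_rejected(self):
        bad = self.ann + [(GenomicInterval("chr1", 100_000, 250_000), "B3")]
        with pytest.raises(ValueError, match="overlap"):
            assign_subcompartments([make_domain("chr1", 0, 1000)], bad)


def brute_force_interaction(matrix, a, b):
    """Direct double-loop oracle for I(a,b) with the bin-midpoint rule."""
    arr = matrix.toarray()
    bs = matrix.bin_size
    total = 0.0
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            mid_i, mid_j = (i + 0.5) * bs, (j + 0.5) * bs
            if a.start <= mid_i < a.end and b.start <= mid_j < b.end:
                total += arr[i, j]
    return total / (a.length * b.length)


class TestDomainInteraction:
    def test_worked_example(self):
        arr = np.zeros((4, 4))
        arr[0, 2], arr[0, 3], arr[1, 2], arr[1, 3] = 1, 2, 3, 4
        arr = arr + arr.T
        m = ContactMatrix("chr1", "chr1", 10_000, arr)
        a = make_domain("chr1", 0, 20_000)
        b = make_domain("chr1", 20_000, 40_000)
        assert domain_interaction(m, a, b) == pytest.approx(2.5e-8, rel=1e-12)

    def test_zero_matrix(self):
        m = ContactMatrix("chr1", "chr1", 100, np.zeros((5, 5)))
        a, b = make_domain("chr1", 0, 200), make_domain("chr1", 300, 500)
        assert domain_interaction(m, a, b) == 0.0

    def test_symmetry_on_random_matrices(self, rng):
        arr = rng.random((10, 10))
        arr = arr + arr.T
        m = ContactMatrix("chr1", "chr1", 100, arr)
        a, b = make_domain("chr1", 0, 300), make_domain("chr1", 500, 900)
        assert domain_interaction(m, a, b) == pytest.approx(
            domain_interaction(m, b, a), rel=1e-12
        )

    def test_outside_extent_rejected(self):
        m = ContactMatrix("chr1", "chr1", 100, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="extent"):
            domain_interaction(
                m, make_domain("chr1", 0, 200), make_domain("chr1", 200, 800)
            )

    def test_matches_brute_force_oracle(self, rng):
        """I(a,b) equals the double-loop sum on random 50x50 matrices."""
        arr = rng.random((50, 50))
        arr = arr + arr.T
        m = ContactMatrix("chr1", "chr1", 1000, arr)
        for _ in range(10):
            s1, s2 = sorted(rng.integers(0, 49, size=2) * 1000)
            a = make_domain("chr1", int(s1), int(s1 + rng.integers(1, 5) * 1000))
            b = make_domain("chr1", int(s2), int(s2 + rng.integers(1, 5) * 1000))
            if a.end > 50_000 or b.end > 50_000:
                continue
            assert domain_interaction(m, a, b) == pytest.approx(
                brute_force_interaction(m, a, b), abs=1e-12
            )


class TestBuildInteractionMatrices:
    def make_inputs(self, rng):
        doms = [
            make_domain("chr1", 0, 2000),
            make_domain("chr1", 2000, 5000),
            make_domain("chr1", 5000, 6000),
            make_domain("chr2", 0, 3000),
            make_domain("chr2", 3000, 4000),
        ]
        a1 = rng.random((6, 6))
        a1 = a1 + a1.T
        a2 = rng.random((4, 4))
        a2 = a2 + a2.T
        t = rng.random((6, 4))
        mats = {
            ("chr1", "chr1"): ContactMatrix("chr1", "chr1", 1000, a1),
            ("chr2", "chr2"): ContactMatrix("chr2", "chr2", 1000, a2),
            ("chr1", "chr2"): ContactMatrix("chr1", "chr2", 1000, t),
        }
        return doms, mats

    def test_counts_and_oracle_equivalence(self, rng):
        doms, mats = self.make_inputs(rng)
        cis, trans = build_interaction_matrices(mats, doms)
        assert set(cis) == {"chr1", "chr2"} and set(trans) == {("chr1", "chr2")}
        assert cis["chr1"].values.shape == (3, 3)
        assert trans[("chr1", "chr2")].values.shape == (3, 2)
        # per-pair values match direct calls
        net = cis["chr1"]
        for i, a in enumerate(net.domains_row):
            for j, b in enumerate(net.domains_col):
                if i == j:
                    assert net.values[i, j] == 0.0
                else:
                    assert net.values[i, j] == pytest.approx(
                        domain_interaction(mats[("chr1", "chr1")], a, b), rel=1e-9
                    )
        tnet = trans[("chr1", "chr2")]
        for i, a in enumerate(tnet.domains_row):
            for j, b in enumerate(tnet.domains_col):
                assert tnet.values[i, j] == pytest.approx(
                    domain_interaction(mats[("chr1", "chr2")], a, b), rel=1e-9
                )

    def test_missing_pair_reported(self, rng):
        doms, mats = self.make_inputs(rng)
        del mats[("chr1", "chr2")]
        with pytest.raises(KeyError, match="chr1.*chr2"):
            build_interaction_matrices(mats, doms)

    def test_partition_conservation(self, rng):
        """Domains tiling the chromosome conserve the total matrix mass."""
        doms, mats = self.make_inputs(rng)
        cis, _ = build_interaction_matrices(mats, doms)
        net = cis["chr1"]
        L = np.array([d.length for d in net.domains_row], dtype=float)
        total = (net.values * np.outer(L, L)).sum()
        arr = mats[("chr1", "chr1")].toarray()
        # subtract the intra-domain (diagonal-block) mass explicitly
        blocks = [(0, 2), (2, 5), (5, 6)]
        intra = sum(arr[s:e, s:e].sum() for s, e in blocks)
        assert total == pytest.approx(arr.sum() - intra, rel=1e-9)


class TestCisTransRatio:
    def test_direct_arithmetic(self):
        assert cis_trans_ratio([8.5e-6], [1.0e-8]) == pytest.approx(850.0)

    def test_identity(self):
        assert cis_trans_ratio([1, 2, 3], [1, 2, 3]) == 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            cis_trans_ratio([], [1.0])
        with pytest.raises(ValueError):
            cis_trans_ratio([1.0], [0.0])
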