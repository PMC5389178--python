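"""Coverage filtering, Spearman age correlation, q-values, directionality."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiclock import SampleMeta, classify_directionality, correct_q, filter_sites, \
    shared_tissue_count, spearman_age
from epiclock.io_rrbs import CpGSite
from epiclock.screening import CorrelationResult, estimate_pi0, spearman_test
from conftest import make_matrix


# ---------------------------------------------------------------------------
# filter_sites

class TestFilterSites:
    def test_mean_coverage_bounds(self):
        m = make_matrix([[0, 0], [1, 1], [10, 10]], [[150, 150], [1, 1], [20, 20]])
        out = filter_sites(m)
        assert out.n_sites == 1 and out.sites[0].pos == 120

    def test_ninety_percent_rule(self):
        total = np.full((1, 10), 10)
        total[0, :2] = 4  # covered >=5x in 8/10 samples -> removed
        m = make_matrix(np.zeros_like(total), total)
        out = filter_sites(m)
        assert out.n_sites == 0
        total[0, 1] = 10  # 9/10 -> kept
        m = make_matrix(np.zeros_like(total), total)
        out = filter_sites(m)
        assert out.n_sites == 1
        # the low-coverage cell was blanked
        assert out.total.iloc[0, 0] == 0

    def test_random_matrix_vs_brute_force(self, rng):
        from conftest import random_matrix
        m = random_matrix(rng, n_sites=60, n_samples=12, max_cov=120)
        out = filter_sites(m)
        surviving = set()
        for s in m.sites:
            tot = m.total.loc[(s.chrom, s.pos)].to_numpy().astype(float)
            if tot.mean() < 2 or tot.mean() > 100:
                continue
            defined = (tot >= 5).sum()
            if defined / len(tot) >= 0.9:
                surviving.add(s)
        assert set(out.sites) == surviving

    def test_invalid_thresholds(self, rng):
        from conftest import random_matrix
        m = random_matrix(rng)
        with pytest.raises(ValueError):
            filter_sites(m, min_mean_cov=10, max_mean_cov=2)
        with pytest.raises(ValueError):
            filter_sites(m, min_frac_covered=0.0)


# ---------------------------------------------------------------------------
# Spearman

def brute_force_spearman(x, y):
    """Average-rank correlation computed from first principles."""
    def avg_rank(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            eq = np.sum(v == vi)
            r[i] = less + (eq + 1) / 2.0
        return r
    rx, ry = avg_rank(x), avg_rank(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_test([0.1, 0.2, 0.3, 0.4], [0, 98, 189, 287])
        assert rho == pytest.approx(1.0)
        rho_r, _ = spearman_test([0.4, 0.3, 0.2, 0.1], [0, 98, 189, 287])
        assert rho_r == pytest.approx(-1.0)

    def test_ties_match_brute_force(self):
        rho, _ = spearman_test([0.1, 0.1, 0.3], [7, 14, 21])
        assert rho == pytest.approx(brute_force_spearman([0.1, 0.1, 0.3], [7, 14, 21]))

    def test_random_vectors_match_brute_force(self, rng):
        for _ in range(200):
            n = rng.integers(3, 12)
            x = rng.integers(0, 6, size=n).astype(float)  # ties likely
            y = rng.normal(size=n)
            rho, _ = spearman_test(x, y)
            expected = brute_force_spearman(x, y)
            if np.isnan(expected):
                assert np.isnan(rho)
            else:
                assert rho == pytest.approx(expected, abs=1e-12)

    def test_exact_small_n_p_equals_enumeration(self, rng):
        """Permutation p for n=5 equals a from-scratch enumeration."""
        x = np.array([0.1, 0.5, 0.2, 0.9, 0.3])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho_obs, p = spearman_test(x, y)
        rhos = [brute_force_spearman(x, perm) for perm in itertools.permutations(y)]
        expected = np.mean([abs(r) >= abs(rho_obs) - 1e-12 for r in rhos])
        assert p == pytest.approx(expected)

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.random(8)
        y = rng.random(8)
        rho0, p0 = spearman_test(x, y)
        rho1, p1 = spearman_test(np.exp(3 * x), y ** 3 + 5 * y)
        assert rho1 == pytest.approx(rho0)
        assert p1 == pytest.approx(p0)

    def test_constant_input_is_missing(self):
        rho, p = spearman_test([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)


class TestSpearmanAge:
    def _meta(self):
        meta = []
        for i, (age, tissue) in enumerate([(0, "liver"), (4, "liver"), (14, "liver"), (30, "liver"),
                                           (0, "lung"), (14, "lung"), (27, "lung")]):
            meta.append(SampleMeta(f"s{i + 1}", float(age), tissue=tissue))
        return meta

    def test_ages_used_in_days(self):
        meta = self._meta()
        frac = np.array([[0.1, 0.2, 0.3, 0.4, 0.15, 0.25, 0.35]])
        total = np.full_like(frac, 10, dtype=int)
        m = make_matrix((frac * 10).astype(int), total,
                        samples=[x.sample_id for x in meta])
        res = spearman_age(m, meta, tissue="all")
        assert len(res) == 1
        assert res[0].n_used == 7
        # oracle on the realized (count-derived) fractions, ages in days
        ages_days = [x.age_days for x in meta]
        realized = m.fraction.to_numpy()[0]
        assert res[0].rho == pytest.approx(brute_force_spearman(realized, ages_days))

    def test_tissue_specific_min_samples(self):
        meta = self._meta()
        frac = np.array([[0.1, 0.2, 0.3, 0.4, 0.15, 0.25, 0.35]])
        total = np.full_like(frac, 10, dtype=int)
        m = make_matrix((frac * 10).astype(int), total, samples=[x.sample_id for x in meta])
        assert len(spearman_age(m, meta, tissue="liver")) == 1   # n=4 passes
        assert spearman_age(m, meta, tissue="lung") == []        # n=3 < 4
        with pytest.raises(ValueError, match="unknown tissue"):
            spearman_age(m, meta, tissue="kidney")

    def test_missing_cells_excluded(self):
        meta = self._meta()
        total = np.full((1, 7), 10)
        total[0, 0] = 0  # newborn liver missing
        meth = (np.array([[0.1, 0.2, 0.3, 0.4, 0.15, 0.25, 0.35]]) * total).astype(int)
        m = make_matrix(meth, total, samples=[x.sample_id for x in meta])
        res = spearman_age(m, meta, tissue="all")
        assert res[0].n_used == 6


# ---------------------------------------------------------------------------
# q-values

class TestCorrectQ:
    def test_all_ones(self):
        assert list(correct_q([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    def test_bh_hand_computation_with_pi0_one(self):
        q = correct_q([0.01, 0.02, 0.03, 0.8], pi0=1.0)
        assert list(np.round(q, 10)) == [0.04, 0.04, 0.04, 0.8]

    def test_matches_statsmodels_bh_at_pi0_one(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(1e-6, 1.0, size=200)
        q = correct_q(p, pi0=1.0)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
                    min_size=2, max_size=60))
    def test_monotone_in_p(self, ps):
        q = correct_q(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)
        assert np.all((np.asarray(q) >= 0) & (np.asarray(q) <= 1))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            correct_q([0.0, 0.5])
        with pytest.raises(ValueError):
            correct_q([0.5, 1.2])

    def test_pi0_smoother_sane_on_uniform_and_enriched(self, rng):
        uniform = rng.uniform(size=2000)
        assert 0.7 < estimate_pi0(uniform) <= 1.0
        enriched = np.concatenate([rng.uniform(size=1000), rng.uniform(0, 1e-4, size=1000)])
        assert estimate_pi0(enriched) < 0.8


# ---------------------------------------------------------------------------
# directionality and tissue sharing

def _cr(site, rho, p, tissue="all"):
    return CorrelationResult(site, rho, p, None, 10, tissue)


class TestDirectionality:
    s1, s2, s3 = CpGSite("chr1", 1), CpGSite("chr1", 2), CpGSite("chr1", 3)

    def test_examples(self):
        labels = classify_directionality(
            [_cr(self.s1, 0.8, 0.01), _cr(self.s2, 0.8, 0.01)],
            [_cr(self.s1, 0.7, 0.2), _cr(self.s2, -0.6, 0.2)])
        assert labels[self.s1] == "concordant_positive"
        assert labels[self.s2] == "reversed"

    def test_site_in_one_list_gets_no_label(self):
        labels = classify_directionality([_cr(self.s1, 0.8, 0.01)], [_cr(self.s2, 0.7, 0.01)])
        assert labels == {}

    def test_random_tables_vs_brute_force(self, rng):
        sites = [CpGSite("chr1", i + 1) for i in range(50)]
        a = [_cr(s, float(rng.uniform(-1, 1)), float(rng.uniform(0.001, 1))) for s in sites]
        b = [_cr(s, float(rng.uniform(-1, 1)), float(rng.uniform(0.001, 1))) for s in sites]
        labels = classify_directionality(a, b)
        for ra, rb in zip(a, b):
            sa, sb = np.sign(ra.rho), np.sign(rb.rho)
            if sa == sb and sa != 0 and (ra.p_value < 0.05 or rb.p_value < 0.05):
                expect = "concordant_positive" if sa > 0 else "concordant_negative"
            elif sa * sb < 0:
                expect = "reversed"
            else:
                expect = "unstable"
            assert labels[ra.site] == expect


class TestSharedTissueCount:
    def test_examples_and_brute_force(self, rng):
        sites = [CpGSite("chr1", i + 1) for i in range(20)]
        per_tissue = {
            t: [_cr(s, 0.5, float(rng.uniform(0.001, 1)), t) for s in sites]
            for t in ("liver", "lung", "heart", "cortex")
        }
        counts = shared_tissue_count(per_tissue, threshold_p=0.05)
        for s in sites:
            expect = sum(1 for t in per_tissue
                         for r in per_tissue[t] if r.site == s and r.p_value < 0.05)
            assert counts[s] == expect
        assert set(counts.values()) <= set(range(5))

    def test_needs_two_tissues(self):
        with pytest.raises(ValueError):
            shared_tissue_count({"liver": []})
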