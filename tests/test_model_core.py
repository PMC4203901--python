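import numpy as np
import pytest

from _oracles import posterior_by_enumeration
from conftest import make_column
from pilecall.error_models import (
    BASE_INDEX,
    base_call_distribution,
    build_error_matrix,
    phred_to_error_prob,
)
from pilecall.model_core import (
    DIPLOID_GENOTYPES,
    GenotypeCaller,
    ParameterError,
    ReferencePrior,
    build_genotype_prior,
    cap_depth,
    genotype_posterior,
    marginal_genotype_prior,
    sample_distribution,
    solve_alt_allele_prob,
)


class TestAltAlleleProb:
    def test_zero_snp_rate_gives_zero(self):
        assert solve_alt_allele_prob(0.0) == 0.0

    def test_default_snp_rate_gives_known_percentage(self):
        # 0.1% SNP rate -> p = 0.0333% under the Hardy-Weinberg split
        assert solve_alt_allele_prob(0.001) * 100 == pytest.approx(0.0333, abs=5e-5)

    @pytest.mark.parametrize("mu", [1e-5, 0.001, 0.01, 0.3])
    def test_root_verified_by_numeric_solver(self, mu):
        from scipy.optimize import brentq

        p = solve_alt_allele_prob(mu)
        assert 3 * p + 3 * p * p == pytest.approx(mu, abs=1e-12)
        assert p == pytest.approx(brentq(lambda x: 3 * x + 3 * x * x - mu, 0, 1), abs=1e-12)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ParameterError):
            solve_alt_allele_prob(-0.1)


class TestGenotypePrior:
    def test_haploid_row(self):
        m = build_genotype_prior("haploid", 0.001).matrix
        np.testing.assert_allclose(m[0], [0.999] + [0.001 / 3] * 3, rtol=1e-12)

    def test_diploid_zero_rate_is_point_mass_on_homref(self):
        m = build_genotype_prior("diploid", 0.0).matrix
        for h, ref in enumerate("ACGT"):
            expected = np.zeros(10)
            expected[DIPLOID_GENOTYPES.index(ref + ref)] = 1.0
            np.testing.assert_array_equal(m[h], expected)

    def test_diploid_row_hardy_weinberg_masses(self):
        prior = build_genotype_prior("diploid", 0.001)
        p = prior.alt_allele_prob
        row = prior.matrix[0]  # reference A
        assert row[DIPLOID_GENOTYPES.index("AA")] == pytest.approx(0.999, rel=1e-9)
        for het in ("AC", "AG", "AT"):
            assert row[DIPLOID_GENOTYPES.index(het)] == pytest.approx(
                p * (1 - p), rel=1e-9
            )
        for hom_alt in ("CC", "GG", "TT", "CG", "CT", "GT"):
            assert row[DIPLOID_GENOTYPES.index(hom_alt)] == pytest.approx(
                p * p, rel=1e-9
            )

    @pytest.mark.parametrize("ploidy", ["haploid", "diploid"])
    @pytest.mark.parametrize("mu", [0.0, 1e-4, 0.001, 0.05])
    def test_rows_sum_to_one(self, ploidy, mu):
        m = build_genotype_prior(ploidy, mu).matrix
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_off_homozygote_mass_equals_snp_rate(self):
        prior = build_genotype_prior("diploid", 0.001)
        off = 1.0 - prior.matrix[0, DIPLOID_GENOTYPES.index("AA")]
        assert off == pytest.approx(0.001, rel=1e-9)


class TestSampleDistribution:
    @pytest.mark.parametrize(
        "genotype,expected",
        [
            ("AA", [1, 0, 0, 0]),
            ("AC", [0.5, 0.5, 0, 0]),
            ("T", [0, 0, 0, 1]),
            ("GT", [0, 0, 0.5, 0.5]),
        ],
    )
    def test_allele_sampling(self, genotype, expected):
        np.testing.assert_array_equal(sample_distribution(genotype), expected)


def _call_dists(reads):
    return [
        base_call_distribution(b, phred_to_error_prob(q)) for b, q in reads
    ]


class TestGenotypePosterior:
    def test_zero_reads_returns_prior_exactly(self, diploid_prior):
        ref_prior = ReferencePrior.flat()
        post = genotype_posterior(np.empty((0, 4)), ref_prior, diploid_prior)
        expected = marginal_genotype_prior(diploid_prior, ref_prior)
        np.testing.assert_allclose(post, expected, atol=1e-15)

    def test_haploid_single_read_matches_enumeration(self, haploid_prior):
        # tau = delta = 0, observed reference A, one A read at Q20
        sub = build_error_matrix(0.0)
        calls = _call_dists([("A", 20)])
        likes = np.array([sub.entries @ c for c in calls])
        post = genotype_posterior(
            likes, ReferencePrior.observed("A"), haploid_prior, ref_base="A"
        )
        oracle = posterior_by_enumeration(
            calls, sub.entries, [1, 0, 0, 0], haploid_prior.matrix, "haploid"
        )
        np.testing.assert_allclose(post, oracle, atol=1e-12)

    def test_diploid_discordant_reads_against_enumeration(self, diploid_prior):
        # with only two discordant reads the 0.1% SNP-rate prior still
        # dominates (the enumeration oracle confirms MAP = AA); balanced
        # evidence from several reads is needed to call the heterozygote
        sub = build_error_matrix(0.002)
        calls = _call_dists([("A", 40), ("C", 40)])
        likes = np.array([sub.entries @ c for c in calls])
        post = genotype_posterior(likes, ReferencePrior.flat(), diploid_prior)
        oracle = posterior_by_enumeration(
            calls, sub.entries, np.full(4, 0.25), diploid_prior.matrix, "diploid"
        )
        np.testing.assert_allclose(post, oracle, atol=1e-12)
        # AA and CC tie by symmetry and split nearly all the mass; AC does
        # not come close to either
        assert DIPLOID_GENOTYPES[int(np.argmax(post))] in ("AA", "CC")
        ac = post[DIPLOID_GENOTYPES.index("AC")]
        assert ac < 0.1 and post.max() > 0.45

    def test_diploid_balanced_reads_call_heterozygote(self, diploid_prior):
        sub = build_error_matrix(0.002)
        calls = _call_dists([("A", 40), ("C", 40)] * 4)
        likes = np.array([sub.entries @ c for c in calls])
        post = genotype_posterior(likes, ReferencePrior.flat(), diploid_prior)
        assert DIPLOID_GENOTYPES[int(np.argmax(post))] == "AC"

    @pytest.mark.parametrize("ploidy", ["haploid", "diploid"])
    @pytest.mark.parametrize("observed_ref", [False, True])
    def test_matches_full_joint_enumeration_randomized(self, rng, ploidy, observed_ref):
        from pilecall.error_models import build_damage_matrix

        prior = build_genotype_prior(ploidy, 0.001)
        for _ in range(100):
            sub = build_damage_matrix(rng.uniform(0, 0.3), rng.uniform(0, 0.3))
            n = int(rng.integers(0, 4))
            reads = [
                ("ACGT"[rng.integers(4)], int(rng.integers(0, 60))) for _ in range(n)
            ]
            calls = _call_dists(reads)
            likes = (
                np.array([sub.entries @ c for c in calls])
                if calls
                else np.empty((0, 4))
            )
            if observed_ref:
                ref = "ACGT"[rng.integers(4)]
                ref_prior = ReferencePrior.observed(ref)
                ref_probs = np.eye(4)[BASE_INDEX[ref]]
            else:
                ref = None
                ref_prior = ReferencePrior.flat()
                ref_probs = np.full(4, 0.25)
            post = genotype_posterior(likes, ref_prior, prior, ref_base=ref)
            oracle = posterior_by_enumeration(
                calls, sub.entries, ref_probs, prior.matrix, ploidy
            )
            np.testing.assert_allclose(post, oracle, atol=1e-12)
            assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_concordant_read_never_decreases_supported_homozygote(self, diploid_prior):
        sub = build_error_matrix(0.002)
        like = sub.entries @ base_call_distribution("C", phred_to_error_prob(25))
        cc = DIPLOID_GENOTYPES.index("CC")
        prev = 0.0
        for n in range(0, 20):
            likes = np.tile(like, (n, 1)) if n else np.empty((0, 4))
            post = genotype_posterior(likes, ReferencePrior.flat(), diploid_prior)
            assert post[cc] >= prev - 1e-15
            prev = post[cc]

    def test_prior_dominates_single_read_at_tiny_snp_rate(self):
        # snp_rate -> 0 with an observed reference: one read cannot flip the call
        prior = build_genotype_prior("diploid", 1e-12)
        sub = build_error_matrix(0.002)
        for q in (10, 25, 40):
            like = sub.entries @ base_call_distribution("T", phred_to_error_prob(q))
            post = genotype_posterior(
                like[None, :], ReferencePrior.observed("A"), prior, ref_base="A"
            )
            assert DIPLOID_GENOTYPES[int(np.argmax(post))] == "AA"

    def test_posterior_equivariant_under_base_relabelling(self, rng):
        # relabelling bases by a permutation (with a permutation-consistent
        # error matrix) permutes the posterior identically
        from pilecall.error_models import SubstitutionMatrix

        prior = build_genotype_prior("haploid", 0.001)
        raw = rng.uniform(0.5, 1.0, size=(4, 4)) + 3 * np.eye(4)
        entries = raw / raw.sum(axis=1, keepdims=True)
        sub = SubstitutionMatrix(entries)
        reads = [("A", 30), ("C", 22), ("A", 35)]
        calls = _call_dists(reads)
        likes = np.array([sub.entries @ c for c in calls])
        post = genotype_posterior(likes, ReferencePrior.flat(), prior)
        perm = rng.permutation(4)
        sub_p = SubstitutionMatrix(entries[np.ix_(perm, perm)])
        inv = np.argsort(perm)
        calls_p = [c[perm] for c in calls]
        likes_p = np.array([sub_p.entries @ c for c in calls_p])
        post_p = genotype_posterior(likes_p, ReferencePrior.flat(), prior)
        np.testing.assert_allclose(post_p, post[perm], atol=1e-12)


class TestCapDepth:
    def test_below_cap_returned_unchanged_in_order(self):
        reads = list(range(5))
        assert cap_depth(reads, 10, seed=1) == reads

    def test_subset_deterministic_for_fixed_seed(self):
        reads = list(range(60))
        a = cap_depth(reads, 5, seed=42)
        b = cap_depth(reads, 5, seed=42)
        assert a == b and len(a) == 5
        assert a == sorted(a)  # original relative order preserved
        assert cap_depth(reads, 5, seed=43) != a  # different seed, different subset

    def test_cap_equal_to_depth_keeps_all(self):
        reads = list(range(60))
        assert cap_depth(reads, 60, seed=0) == reads


class TestGenotypeCaller:
    def test_caller_matches_direct_posterior(self, make_caller, diploid_prior):
        caller = make_caller("diploid")
        col = make_column(["A", "C", "A"], [40, 38, 12], ref="A")
        call = caller.call_column(col)
        sub = build_error_matrix(0.002)
        likes = np.array(
            [
                sub.entries @ base_call_distribution(o.base, phred_to_error_prob(
                    min(o.base_quality, o.map_quality)))
                for o in col.observations
            ]
        )
        expected = genotype_posterior(likes, ReferencePrior.flat(), diploid_prior)
        np.testing.assert_allclose(call.posterior, expected, atol=1e-12)
        assert call.map_genotype == DIPLOID_GENOTYPES[int(np.argmax(expected))]
        assert call.depth_used == 3

    def test_phred_quality_definition(self, make_caller):
        caller = make_caller("haploid")
        col = make_column(["G"] * 4, [30] * 4, ref="G")
        call = caller.call_column(col)
        p = call.posterior[int(np.argmax(call.posterior))]
        assert call.phred_quality == pytest.approx(-10 * np.log10(1 - p))

    def test_certain_call_hits_phred_cap(self, make_caller):
        caller = make_caller("haploid", use_reference=True)
        col = make_column(["G"] * 60, [60] * 60, ref="G")
        assert caller.call_column(col).phred_quality == 9999.0

    def test_depth_capping_applied(self, make_caller):
        caller = make_caller("haploid", max_depth=10, seed=7)
        col = make_column(["A"] * 30, [30] * 30, ref="A")
        assert caller.call_column(col).depth_used == 10
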