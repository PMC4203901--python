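"""Generative model of genotypes and exact posterior inference.

The model describes one genomic position.  A reference nucleotide H (known
or latent with a flat prior) conditions a genotype G through a prior that
encodes the expected SNP rate.  Each of the n reads covering the position
samples one allele S_i from the genotype, which is observed as a read base
R_i through a substitution/damage matrix, itself observed through the
sequencer signal summarised by the quality score.  The joint factorises as

    P(H) * P(G|H) * prod_i P(S_i|G) * P(R_i|S_i) * P(I_i|R_i)

and the genotype posterior P(G | data, H) is obtained exactly by summing
out S_i and R_i per read and normalising over genotypes.  All per-position
arithmetic is done in natural-log space with a log-sum-exp reduction, since
products over tens of reads underflow double precision.

Haploid genotypes are the four bases; diploid genotypes are the ten
unordered pairs, ordered lexicographically (``AA, AC, ..., TT``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .error_models import (
    BASE_INDEX,
    BASES,
    DEFAULT_ERROR_CAP,
    ParameterError,
    SubstitutionMatrix,
    base_call_distribution,
    effective_quality,
    phred_to_error_prob,
)

HAPLOID_GENOTYPES: tuple[str, ...] = tuple(BASES)
DIPLOID_GENOTYPES: tuple[str, ...] = (
    "AA", "AC", "AG", "AT", "CC", "CG", "CT", "GG", "GT", "TT",
)

#: Default prior SNP rate (0.1%).
DEFAULT_SNP_RATE = 0.001
#: Maximum Phred-scaled posterior quality reported.
PHRED_CAP = 9999.0
#: Highest Phred score representable in the usual ASCII encodings.
MAX_QUALITY = 93


def genotype_alphabet(ploidy: str) -> tuple[str, ...]:
    if ploidy == "haploid":
        return HAPLOID_GENOTYPES
    if ploidy == "diploid":
        return DIPLOID_GENOTYPES
    raise ParameterError(f"unknown ploidy {ploidy!r}")


def solve_alt_allele_prob(snp_rate: float) -> float:
    """Per-draw probability p of picking an alternative allele.

    Under Hardy-Weinberg equilibrium the three single-alternative
    genotypes each have probability p(1-p) and the six double-alternative
    genotypes p**2, so the total off-homozygote mass is

        3*p*(1-p) + 6*p**2 = 3*p + 3*p**2 = snp_rate.

    Solving the quadratic 3p**2 + 3p - snp_rate = 0 for its positive root
    gives p; at the default SNP rate of 0.1% this is p = 0.0333%.
    """
    if not 0.0 <= snp_rate < 1.0:
        raise ParameterError(f"snp_rate must be in [0, 1), got {snp_rate}")
    p = (-3.0 + math.sqrt(9.0 + 12.0 * snp_rate)) / 6.0
    if not 0.0 <= p < 1.0:
        raise ParameterError(f"no valid root for snp_rate {snp_rate}")
    return p


@dataclass(frozen=True)
class ReferencePrior:
    """Prior P(H) over the reference nucleotide.

    ``flat`` puts 0.25 on each base (reference ignored), ``observed`` is a
    point mass on the base seen in the reference, and ``custom`` is any
    user-supplied distribution.
    """

    mode: str
    probs: np.ndarray

    @classmethod
    def flat(cls) -> "ReferencePrior":
        return cls("flat", np.full(4, 0.25))

    @classmethod
    def observed(cls, base: str) -> "ReferencePrior":
        probs = np.zeros(4)
        probs[BASE_INDEX[base]] = 1.0
        return cls("observed", probs)

    @classmethod
    def custom(cls, probs: Sequence[float]) -> "ReferencePrior":
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
            raise ParameterError("custom reference prior must be a length-4 distribution")
        return cls("custom", probs)


@dataclass(frozen=True)
class GenotypePrior:
    """Conditional distribution P(G|H) as a row-stochastic matrix.

    Rows are indexed by the reference base H; columns by the genotype
    alphabet of the active ploidy (4 haploid, 10 diploid).  ``alt_allele_prob``
    is the Hardy-Weinberg per-draw probability p (diploid only, else 0).
    """

    ploidy: str
    snp_rate: float
    matrix: np.ndarray
    alt_allele_prob: float

    @property
    def genotypes(self) -> tuple[str, ...]:
        return genotype_alphabet(self.ploidy)


def build_genotype_prior(
    ploidy: str, snp_rate: float = DEFAULT_SNP_RATE
) -> GenotypePrior:
    """Build P(G|H) for the given ploidy and expected SNP rate.

    Haploid: the reference base keeps 1 - snp_rate and each other base gets
    snp_rate/3.  Diploid: the homozygous-reference genotype keeps
    1 - snp_rate; the three heterozygotes carrying one alternative allele
    get p(1-p) each and the six genotypes carrying two alternative alleles
    get p**2 each, with p from :func:`solve_alt_allele_prob` so the rows
    sum to one exactly.
    """
    if not 0.0 <= snp_rate < 1.0:
        raise ParameterError(f"snp_rate must be in [0, 1), got {snp_rate}")
    genotypes = genotype_alphabet(ploidy)
    if ploidy == "haploid":
        matrix = np.full((4, 4), snp_rate / 3.0)
        np.fill_diagonal(matrix, 1.0 - snp_rate)
        return GenotypePrior(ploidy, snp_rate, matrix, 0.0)
    p = solve_alt_allele_prob(snp_rate)
    matrix = np.empty((4, 10))
    for h, ref in enumerate(BASES):
        for g, geno in enumerate(genotypes):
            n_alt = (geno[0] != ref) + (geno[1] != ref)
            if n_alt == 0:
                matrix[h, g] = 1.0 - snp_rate
            elif n_alt == 1:
                matrix[h, g] = p * (1.0 - p)
            else:
                matrix[h, g] = p * p
        # the Hardy-Weinberg split makes the off-homozygote mass equal the
        # SNP rate analytically; remove only floating-point residue
        matrix[h] /= matrix[h].sum()
    return GenotypePrior(ploidy, snp_rate, matrix, p)


def sample_distribution(genotype: str) -> np.ndarray:
    """P(S|G): distribution of the sampled allele given the genotype.

    Haploid genotypes (single base) map to a point mass; a diploid
    homozygote aa maps to a point mass on a; a heterozygote ab puts 0.5 on
    each of its two alleles.
    """
    probs = np.zeros(4)
    if len(genotype) == 1:
        probs[BASE_INDEX[genotype]] = 1.0
    elif len(genotype) == 2:
        for allele in genotype:
            probs[BASE_INDEX[allele]] += 0.5
    else:
        raise ParameterError(f"bad genotype {genotype!r}")
    return probs


def sample_matrix(ploidy: str) -> np.ndarray:
    """Stacked P(S|G) rows for the whole genotype alphabet, shape (G, 4)."""
    return np.stack([sample_distribution(g) for g in genotype_alphabet(ploidy)])


def marginal_genotype_prior(
    gt_prior: GenotypePrior, ref_prior: ReferencePrior, ref_base: str | None = None
) -> np.ndarray:
    """Effective prior over genotypes for one position.

    In observed mode with a known reference base this is simply the
    corresponding row of P(G|H).  Otherwise H is summed out analytically:
    prior(g) = sum_h P(H=h) P(G=g|H=h).  Positions where the reference is
    N fall back to the flat marginal.
    """
    if ref_prior.mode == "observed" and ref_base is not None and ref_base in BASE_INDEX:
        return gt_prior.matrix[BASE_INDEX[ref_base]].copy()
    probs = ref_prior.probs if ref_prior.mode != "observed" else np.full(4, 0.25)
    return probs @ gt_prior.matrix


@dataclass
class GenotypeCall:
    """MAP genotype call at one position with its full posterior."""

    chrom: str
    pos: int  # 1-based
    ref_base: str  # 'N' if unknown
    posterior: np.ndarray
    map_genotype: str
    phred_quality: float
    depth_used: int
    mean_mapq: float
    base_counts: np.ndarray  # counts of used read bases over ACGT
    ploidy: str


def _phred_from_posterior(p_map: float) -> float:
    miss = 1.0 - p_map
    if miss <= 0.0:
        return PHRED_CAP
    return min(-10.0 * math.log10(miss), PHRED_CAP)


def genotype_posterior(
    likelihoods: np.ndarray,
    ref_prior: ReferencePrior,
    gt_prior: GenotypePrior,
    ref_base: str | None = None,
) -> np.ndarray:
    """Exact genotype posterior from per-read likelihood vectors.

    ``likelihoods`` has one row per read: the length-4 vector
    L_i[s] = P(observation_i | S_i = s) produced by composing the base-call
    distribution with the substitution matrix.  Per read, the sampled
    allele is summed out against P(S|G); the per-genotype log terms are
    accumulated and combined with the (marginal) genotype prior; the
    result is normalised with log-sum-exp.  Zero reads are allowed and
    return the prior itself.
    """
    likelihoods = np.atleast_2d(np.asarray(likelihoods, dtype=float))
    prior = marginal_genotype_prior(gt_prior, ref_prior, ref_base)
    smat = sample_matrix(gt_prior.ploidy)  # (G, 4)
    with np.errstate(divide="ignore"):
        log_post = np.log(prior)
        if likelihoods.size:
            per_read = likelihoods @ smat.T  # (n, G)
            if np.any(per_read.max(axis=1) <= 0.0):
                raise FloatingPointError(
                    "a read assigns zero likelihood to every genotype"
                )
            log_post = log_post + np.sum(np.log(per_read), axis=0)
    log_post -= log_post.max()
    post = np.exp(log_post)
    return post / post.sum()


def cap_depth(reads: list, max_depth: int, seed: int) -> list:
    """Randomly downsample a position's reads to at most ``max_depth``.

    With ``n <= max_depth`` the input is returned unchanged and in order;
    otherwise a uniform subset of size ``max_depth`` is drawn without
    replacement with a generator seeded by ``seed``, preserving the
    original relative order.  Deterministic for a fixed seed.
    """
    if max_depth < 1:
        raise ParameterError("max_depth must be >= 1")
    if len(reads) <= max_depth:
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=max_depth, replace=False))
    return [reads[i] for i in idx]


class GenotypeCaller:
    """Vectorised caller: precomputes per-(base, quality) genotype terms.

    For every called base b and effective quality q the composed per-read
    likelihood L = A @ call(b, q) depends only on (b, q), so the per-read
    log contribution to each genotype is cached in a (4, MAX_QUALITY+1, G)
    table.  A column's log posterior is then the log prior plus a sum of
    table rows, which keeps whole-genome calling fast without changing the
    exact model.
    """

    def __init__(
        self,
        sub: SubstitutionMatrix,
        gt_prior: GenotypePrior,
        ref_prior: ReferencePrior,
        max_depth: int = 60,
        seed: int = 0,
        error_cap: float = DEFAULT_ERROR_CAP,
    ) -> None:
        self.sub = sub
        self.gt_prior = gt_prior
        self.ref_prior = ref_prior
        self.max_depth = max_depth
        self.error_cap = error_cap
        self._rng = np.random.default_rng(seed)
        smat = sample_matrix(gt_prior.ploidy)  # (G, 4)
        n_g = smat.shape[0]
        table = np.empty((4, MAX_QUALITY + 1, n_g))
        for b in range(4):
            for q in range(MAX_QUALITY + 1):
                call = base_call_distribution(b, phred_to_error_prob(q, error_cap))
                like = sub.entries @ call
                table[b, q] = smat @ like
        self._log_table = np.log(table)
        self._log_prior_cache: dict[str | None, np.ndarray] = {}

    def _log_prior(self, ref_base: str | None) -> np.ndarray:
        key = ref_base if (
            self.ref_prior.mode == "observed" and ref_base in BASE_INDEX
        ) else None
        if key not in self._log_prior_cache:
            prior = marginal_genotype_prior(self.gt_prior, self.ref_prior, key)
            with np.errstate(divide="ignore"):
                self._log_prior_cache[key] = np.log(prior)
        return self._log_prior_cache[key]

    def call_column(self, column) -> GenotypeCall:
        """Call one :class:`~pilecall.pileup_io.PileupColumn`."""
        obs = column.observations
        if len(obs) > self.max_depth:
            idx = np.sort(
                self._rng.choice(len(obs), size=self.max_depth, replace=False)
            )
            obs = [obs[i] for i in idx]
        genotypes = self.gt_prior.genotypes
        log_post = self._log_prior(column.ref).copy()
        counts = np.zeros(4, dtype=int)
        mapqs = []
        for o in obs:
            b = BASE_INDEX[o.base]
            q = min(effective_quality(o.base_quality, o.map_quality), MAX_QUALITY)
            log_post += self._log_table[b, q]
            counts[b] += 1
            mapqs.append(o.map_quality)
        shifted = log_post - log_post.max()
        post = np.exp(shifted)
        post /= post.sum()
        g = int(np.argmax(post))
        return GenotypeCall(
            chrom=column.chrom,
            pos=column.pos,
            ref_base=column.ref,
            posterior=post,
            map_genotype=genotypes[g],
            phred_quality=_phred_from_posterior(float(post[g])),
            depth_used=len(obs),
            mean_mapq=float(np.mean(mapqs)) if mapqs else 0.0,
            base_counts=counts,
            ploidy=self.gt_prior.ploidy,
        )

    def call_columns(self, columns) -> "list[GenotypeCall]":
        return [self.call_column(c) for c in columns]
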