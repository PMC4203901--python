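"""Post-hoc filtering of genotype calls and a simple two-allele indel caller.

A raw all-sites call set contains a record for every covered position; the
high-quality ("QC") subset keeps only variant calls whose Phred-scaled
posterior exceeds a threshold (strictly greater than 30 by default) and
that are supported by a minimum number of reads carrying the alternative
allele (10 by default; 5 is a common relaxation for low-depth data).

Indels are genotyped with a deliberately minimal two-allele reuse of the
diploid machinery: at each column the most frequent indel allele competes
against the reference allele, each read contributing a correctness
probability derived from its effective quality.  The genotype-calling
model itself has no indel channel; this is a pragmatic extension layered
on top of it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .error_models import effective_quality, phred_to_error_prob
from .model_core import GenotypePrior, PHRED_CAP
from .pileup_io import PileupColumn, VcfRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds defining the high-quality (QC) call subset."""

    min_phred: float = 30.0  # strict: a call must score > min_phred
    min_supporting_reads: int = 10
    emit_indels: bool = False

    def __post_init__(self) -> None:
        if self.min_phred < 0:
            raise ValueError("min_phred must be >= 0")
        if self.min_supporting_reads < 1:
            raise ValueError("min_supporting_reads must be >= 1")


def passes_qc(record: VcfRecord, policy: FilterPolicy) -> bool:
    """Whether one variant record enters the QC set.

    Homozygous-reference records are never variants.  Supporting reads are
    those whose called base equals the called non-reference allele (the
    stronger allele for multi-allelic genotypes), taken from the AD field.
    """
    if not record.is_variant:
        return False
    if not record.gq > policy.min_phred:
        return False
    return record.alt_support >= policy.min_supporting_reads


def qc_filter(
    records: Iterable[VcfRecord], policy: FilterPolicy
) -> Iterator[VcfRecord]:
    """Yield the subset of ``records`` passing the QC policy.

    Malformed records (no genotype information) are skipped with a logged
    warning rather than aborting the stream.
    """
    for record in records:
        try:
            if passes_qc(record, policy):
                yield record
        except (IndexError, TypeError, ValueError) as exc:  # malformed record
            logger.warning("skipping malformed record %s:%s (%s)",
                           record.chrom, record.pos, exc)


# ---------------------------------------------------------------------------
# two-allele indel calling


def indel_genotype_posterior(
    support_errs: list[float],
    other_errs: list[float],
    gt_prior: GenotypePrior,
) -> tuple[np.ndarray, int]:
    """Posterior over {hom-ref, het, hom-indel} (diploid) or {ref, indel}
    (haploid) for a two-allele site.

    Each read is reduced to a binary observation: it either carries the
    candidate indel allele or it does not, with per-read correctness
    probability 1 - e from its effective quality.  The prior reuses the
    genotype prior's SNP-rate machinery restricted to the {reference,
    indel} allele pair and renormalised.
    """
    mu = gt_prior.snp_rate
    if gt_prior.ploidy == "haploid":
        prior = np.array([1.0 - mu, mu / 3.0])
        # P(read shows indel | allele): [ref allele, indel allele]
        p_alt = np.array([0.0, 1.0])
    else:
        p = gt_prior.alt_allele_prob
        prior = np.array([1.0 - mu, p * (1.0 - p), p * p])
        p_alt = np.array([0.0, 0.5, 1.0])
    prior = prior / prior.sum()
    with np.errstate(divide="ignore"):
        log_post = np.log(prior)
    for e in support_errs:
        prob = p_alt * (1.0 - e) + (1.0 - p_alt) * e
        log_post += np.log(prob)
    for e in other_errs:
        prob = p_alt * e + (1.0 - p_alt) * (1.0 - e)
        log_post += np.log(prob)
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    return post, int(np.argmax(post))


def call_indels(
    columns: Iterable[PileupColumn],
    policy: FilterPolicy,
    gt_prior: GenotypePrior,
    sample_name: str = "SAMPLE",
) -> Iterator[str]:
    """Yield QC-passing indel VCF record lines from pileup columns.

    At each column the most frequent indel allele (by kind and sequence)
    is genotyped against the reference; the same QC policy as for SNPs is
    applied (posterior Phred > min_phred, supporting reads >= minimum).
    """
    for column in columns:
        if not column.indels:
            continue
        groups: dict[tuple[str, str], list] = {}
        for ind in column.indels:
            groups.setdefault((ind.kind, ind.sequence), []).append(ind)
        (kind, seq), support = max(
            groups.items(), key=lambda kv: (len(kv[1]), kv[0])
        )
        n_support = len(support)
        if n_support < policy.min_supporting_reads:
            continue
        support_errs = [
            phred_to_error_prob(effective_quality(i.base_quality, i.map_quality))
            for i in support
        ]
        supporting_reads = {i.read_index for i in support}
        other_errs = [
            phred_to_error_prob(effective_quality(o.base_quality, o.map_quality))
            for o in column.observations
            if o.read_index not in supporting_reads
        ]
        post, g = indel_genotype_posterior(support_errs, other_errs, gt_prior)
        if g == 0:
            continue
        miss = 1.0 - float(post[g])
        phred = PHRED_CAP if miss <= 0 else min(-10.0 * math.log10(miss), PHRED_CAP)
        if not phred > policy.min_phred:
            continue
        ref_base = column.ref
        if kind == "ins":
            ref_allele, alt_allele = ref_base, ref_base + seq
        else:
            ref_allele, alt_allele = ref_base + seq, ref_base
        if gt_prior.ploidy == "haploid":
            gt = "1"
        else:
            gt = "0/1" if g == 1 else "1/1"
        depth = len(column.observations)
        gq = int(round(min(phred, 99.0)))
        ad = f"{max(depth - n_support, 0)},{n_support}"
        yield (
            f"{column.chrom}\t{column.pos}\t.\t{ref_allele}\t{alt_allele}\t"
            f"{phred:.2f}\t.\tDP={depth}\tGT:DP:GQ:AD\t{gt}:{depth}:{gq}:{ad}"
        )
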