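"""Call-set metrics: SNP rate, hom:het ratio, overlaps, truth comparison.

These are the quantities typically reported when comparing genotypers:
the fraction of positions called variant (SNP rate), the ratio of
homozygous-alternative to heterozygous calls (about 0.8 is expected in
human resequencing data), Venn-style overlaps between call sets from
different methods, and — when simulated ground truth is available —
site-level precision/recall and genotype concordance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .pileup_io import VcfRecord, read_vcf
from .readsim import TruthRecord


@dataclass
class CallSet:
    """A labelled set of variant calls.

    ``variants`` maps a site key to (alt alleles, zygosity).  By default
    the key is (chrom, pos): overlap comparisons between callers are
    position-based, with allele-aware keys available via
    ``allele_aware=True`` in :meth:`from_records`.
    """

    label: str
    variants: dict = field(default_factory=dict)

    @property
    def positions(self) -> set:
        return set(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    @classmethod
    def from_records(
        cls,
        label: str,
        records: Iterable[VcfRecord],
        allele_aware: bool = False,
    ) -> "CallSet":
        variants = {}
        for r in records:
            if not r.is_variant:
                continue
            key = (r.chrom, r.pos, r.called_alts) if allele_aware else (r.chrom, r.pos)
            variants[key] = (r.called_alts, r.zygosity)
        return cls(label, variants)

    @classmethod
    def from_vcf(cls, label: str, path, allele_aware: bool = False) -> "CallSet":
        return cls.from_records(label, read_vcf(path), allele_aware=allele_aware)


def snp_rate(calls: CallSet, n_positions: int) -> float:
    """Number of variant calls divided by the number of positions."""
    if n_positions <= 0:
        raise ValueError("n_positions must be positive")
    return len(calls) / n_positions


def hom_het_ratio(calls: CallSet) -> float:
    """Homozygous-alternative over heterozygous call count.

    Returns NaN (with a warning) when the set contains no heterozygotes.
    """
    n_hom = sum(1 for _, z in calls.variants.values() if z == "hom")
    n_het = len(calls) - n_hom
    if n_het == 0:
        warnings.warn(f"call set {calls.label!r} has no heterozygous calls")
        return math.nan
    return n_hom / n_het


def overlap_matrix(sets: Sequence[CallSet]) -> dict:
    """Venn-cell counts, pairwise overlap fractions and exclusive fractions.

    ``cells`` maps each non-empty label subset (as a sorted tuple) to the
    number of sites found by exactly those sets; ``pairwise`` maps
    (label_a, label_b) to |A ∩ B| / |A|; ``exclusive`` maps each label to
    the fraction of its calls found by no other set.
    """
    if len(sets) < 2:
        raise ValueError("need at least two call sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("call-set labels must be unique")
    membership: dict = {}
    for s in sets:
        for key in s.positions:
            membership.setdefault(key, set()).add(s.label)
    cells: dict[tuple, int] = {}
    for found_by in membership.values():
        cell = tuple(sorted(found_by))
        cells[cell] = cells.get(cell, 0) + 1
    pairwise = {}
    for a, b in itertools.permutations(sets, 2):
        inter = len(a.positions & b.positions)
        pairwise[(a.label, b.label)] = inter / len(a) if len(a) else math.nan
    exclusive = {}
    for s in sets:
        only = cells.get((s.label,), 0)
        exclusive[s.label] = only / len(s) if len(s) else 0.0
    return {"cells": cells, "pairwise": pairwise, "exclusive": exclusive}


@dataclass(frozen=True)
class TruthEvaluation:
    precision: float  # site-level: called variant sites that are true
    recall: float
    concordance: float  # truth sites with matching alleles and zygosity
    n_truth: int
    n_called: int
    true_positives: int


def truth_eval(
    calls: CallSet, truth: Sequence[TruthRecord], chrom: str = "sim"
) -> TruthEvaluation:
    """Compare a call set against simulator ground truth.

    Precision and recall are site-level: a called variant position that is
    a truth position counts as a true positive even if the genotype is
    wrong.  Genotype concordance is the fraction of all truth sites whose
    called alternative alleles and zygosity both match the planted
    genotype (uncalled truth sites count as discordant).
    """
    truth_by_pos = {(chrom, t.pos): t for t in truth}
    tp = sum(1 for key in calls.positions if key[:2] in truth_by_pos)
    n_called = len(calls)
    fp = n_called - tp
    if n_called == 0:
        warnings.warn("empty call set: precision undefined")
        precision = math.nan
    else:
        precision = tp / n_called
    recall = tp / len(truth) if truth else math.nan

    concordant = 0
    call_by_pos = {key[:2]: val for key, val in calls.variants.items()}
    for (c, pos), t in truth_by_pos.items():
        called = call_by_pos.get((c, pos))
        if called is None:
            continue
        alts, zyg = called
        true_alts = tuple(sorted({a for a in t.genotype if a != t.ref}))
        if alts == true_alts and zyg == t.zygosity:
            concordant += 1
    concordance = concordant / len(truth) if truth else math.nan
    return TruthEvaluation(
        precision=precision,
        recall=recall,
        concordance=concordance,
        n_truth=len(truth),
        n_called=n_called,
        true_positives=tp,
    )


def call_set_from_calls(label: str, calls, policy=None) -> CallSet:
    """Build a variant :class:`CallSet` directly from genotype calls.

    ``policy`` is an optional :class:`~pilecall.variant_filter.FilterPolicy`;
    when given, only calls passing its quality and alt-allele-support
    thresholds are included (the QC set).  Without it, every non-reference
    MAP genotype enters the set.
    """
    from .error_models import BASE_INDEX

    variants = {}
    for c in calls:
        alts = tuple(sorted({a for a in c.map_genotype if a != c.ref_base}))
        if not alts:
            continue
        if c.ploidy == "haploid":
            zyg = "hom"
        else:
            zyg = "hom" if c.map_genotype[0] == c.map_genotype[1] else "het"
        if policy is not None:
            if not c.phred_quality > policy.min_phred:
                continue
            support = max(
                int(c.base_counts[BASE_INDEX[a]]) for a in alts if a in BASE_INDEX
            )
            if support < policy.min_supporting_reads:
                continue
        variants[(c.chrom, c.pos)] = (alts, zyg)
    return CallSet(label, variants)


def truth_from_vcf(path) -> list[TruthRecord]:
    """Load planted variants from a truth VCF written by the simulator."""
    records = []
    for r in read_vcf(path):
        alleles = (r.ref,) + r.alts
        geno = "".join(sorted(alleles[a] for a in r.gt_alleles))
        records.append(TruthRecord(r.pos, r.ref, geno, r.zygosity))
    return records
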