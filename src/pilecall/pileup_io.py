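"""Reading `samtools mpileup -s` text and writing/reading VCF.

The pileup dialect is the 7-column form produced with the ``-s`` flag:
chrom, 1-based position, reference base, depth, read bases, base-quality
string and mapping-quality string.  The read-base string uses ``.``/``,``
for reference matches on the forward/reverse strand, letters (case gives
strand) for mismatches, ``^X``/``$`` for read starts/ends, ``+N<seq>`` /
``-N<seq>`` for indels attached to the preceding read, and ``*``/``N`` for
deletion placeholders and ambiguous bases (both skipped, but both consume
a quality character).

VCF output is version 4.2 with one record per covered position (all-sites
mode) or variant positions only.  Reading uses cyvcf2.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .error_models import BASE_INDEX
from .model_core import GenotypeCall

DEFAULT_QUALITY_OFFSET = 33


class PileupParseError(ValueError):
    """Malformed pileup input, carrying the offending line number."""


@dataclass(frozen=True)
class Observation:
    """One aligned read base at a column."""

    base: str  # one of ACGT, uppercased
    reverse: bool  # True if the read maps to the reverse strand
    base_quality: int
    map_quality: int
    read_index: int = 0  # ordinal of the read within the column


@dataclass(frozen=True)
class IndelObservation:
    """One insertion or deletion reported after a read base."""

    kind: str  # 'ins' or 'del'
    sequence: str  # inserted or deleted bases, uppercased
    reverse: bool
    base_quality: int  # qualities of the read the indel is attached to
    map_quality: int
    read_index: int = 0  # ordinal of the carrying read within the column


@dataclass
class PileupColumn:
    """All reads covering one genomic position."""

    chrom: str
    pos: int  # 1-based
    ref: str  # reference base, 'N' if unknown
    depth: int  # declared depth (read events, incl. skipped)
    observations: list[Observation] = field(default_factory=list)
    indels: list[IndelObservation] = field(default_factory=list)
    skipped: int = 0  # N bases, '*' deletion placeholders, ref skips

    def base_counts(self) -> np.ndarray:
        counts = np.zeros(4, dtype=int)
        for o in self.observations:
            counts[BASE_INDEX[o.base]] += 1
        return counts


def parse_pileup_line(
    line: str,
    quality_offset: int = DEFAULT_QUALITY_OFFSET,
    line_number: int | None = None,
) -> PileupColumn:
    """Parse one ``mpileup -s`` line into a :class:`PileupColumn`.

    Both quality strings are index-aligned with the read events in the
    base string (including skipped ones), so no quality character is ever
    silently dropped.
    """

    def fail(msg: str) -> PileupParseError:
        where = f" (line {line_number})" if line_number is not None else ""
        return PileupParseError(f"{msg}{where}: {line.rstrip()!r}")

    fields = line.rstrip("\n").split("\t")
    if len(fields) != 7:
        raise fail(f"expected 7 tab-separated columns, got {len(fields)}")
    chrom, pos_s, ref, depth_s, bases, bquals, mquals = fields
    try:
        pos = int(pos_s)
        depth = int(depth_s)
    except ValueError:
        raise fail("position and depth must be integers") from None
    ref = ref.upper()
    column = PileupColumn(chrom=chrom, pos=pos, ref=ref, depth=depth)
    if depth == 0:
        return column

    events: list[tuple[str, bool, bool]] = []  # (base, reverse, keep)
    pending_indels: list[tuple[str, str, bool, int]] = []  # + event index
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise fail("dangling '^' read-start marker")
            i += 2  # the next char encodes mapping quality; the -s column supersedes it
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            # indel attached to the previous read event
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise fail("indel marker without a length")
            length = int(bases[i + 1 : j])
            seq = bases[j : j + length]
            if len(seq) != length:
                raise fail("indel sequence shorter than its declared length")
            if not events:
                raise fail("indel with no preceding read base")
            kind = "ins" if c == "+" else "del"
            _base, reverse, _keep = events[-1]
            pending_indels.append((kind, seq.upper(), reverse, len(events) - 1))
            i = j + length
            continue
        reverse = c in ",acgtn"
        if c == ".":
            events.append((ref, False, ref in BASE_INDEX))
        elif c == ",":
            events.append((ref, True, ref in BASE_INDEX))
        elif c.upper() in BASE_INDEX:
            events.append((c.upper(), reverse, True))
        elif c in "Nn*<>":
            events.append(("N", reverse, False))
        else:
            raise fail(f"unexpected pileup character {c!r}")
        i += 1

    if len(events) != depth:
        raise fail(f"declared depth {depth} but found {len(events)} read bases")
    if len(bquals) != depth or len(mquals) != depth:
        raise fail(
            f"quality string lengths ({len(bquals)}, {len(mquals)}) do not "
            f"match depth {depth}"
        )

    bq = [ord(c) - quality_offset for c in bquals]
    mq = [ord(c) - quality_offset for c in mquals]
    if min(bq) < 0 or min(mq) < 0:
        raise fail("negative quality after offset subtraction; wrong offset?")

    for k, (base, reverse, keep) in enumerate(events):
        if keep:
            column.observations.append(Observation(base, reverse, bq[k], mq[k], k))
        else:
            column.skipped += 1
    for kind, seq, reverse, k in pending_indels:
        column.indels.append(IndelObservation(kind, seq, reverse, bq[k], mq[k], k))
    return column


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_pileup(
    source, quality_offset: int = DEFAULT_QUALITY_OFFSET
) -> Iterator[PileupColumn]:
    """Iterate pileup columns from a path or an open text handle."""
    handle = _open_text(source) if isinstance(source, (str, bytes)) or hasattr(
        source, "__fspath__"
    ) else source
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            yield parse_pileup_line(line, quality_offset, line_number=lineno)
    finally:
        if handle is not source:
            handle.close()


# ---------------------------------------------------------------------------
# VCF output


def _alt_alleles(call: GenotypeCall) -> tuple[list[str], list[int]]:
    """ALT allele list and per-haplotype allele indices for one call."""
    ref = call.ref_base
    alleles = [ref]
    gt_idx = []
    for allele in call.map_genotype:
        if allele not in alleles:
            alleles.append(allele)
        gt_idx.append(alleles.index(allele))
    return alleles[1:], gt_idx


def format_vcf_record(call: GenotypeCall, sample_name: str = "SAMPLE") -> str:
    alts, gt_idx = _alt_alleles(call)
    alt_field = ",".join(alts) if alts else "."
    qual = f"{call.phred_quality:.2f}"
    gq = int(round(min(call.phred_quality, 99.0)))
    gt = "/".join(str(i) for i in sorted(gt_idx))
    allele_order = [call.ref_base] + alts
    ad = ",".join(
        str(int(call.base_counts[BASE_INDEX[a]])) if a in BASE_INDEX else "0"
        for a in allele_order
    )
    info = f"DP={call.depth_used};MQ={call.mean_mapq:.2f}"
    return (
        f"{call.chrom}\t{call.pos}\t.\t{call.ref_base}\t{alt_field}\t{qual}\t.\t"
        f"{info}\tGT:DP:GQ:AD\t{gt}:{call.depth_used}:{gq}:{ad}"
    )


def vcf_header(
    meta: dict | None = None,
    sample_name: str = "SAMPLE",
    contigs: Sequence[str] = (),
) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=pilecall",
    ]
    if meta:
        params = ",".join(f"{k}={v}" for k, v in sorted(meta.items()))
        lines.append(f"##pilecall_params={params}")
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth used for the call">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality of used reads">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth used">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (Phred posterior)">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read counts per allele">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}",
    ]
    return "\n".join(lines) + "\n"


def write_vcf(
    calls: Iterable[GenotypeCall],
    out,
    meta: dict | None = None,
    variants_only: bool = False,
    sample_name: str = "SAMPLE",
) -> int:
    """Write genotype calls as VCF 4.2; returns the number of records.

    Calls must be sorted by (chrom, pos).  In variants-only mode records
    whose MAP genotype is homozygous-reference are omitted.
    """
    # records are buffered so the header can declare every contig seen
    body: list[str] = []
    contigs: dict[str, None] = {}
    last: tuple[str, int] | None = None
    for call in calls:
        key = (call.chrom, call.pos)
        if last is not None and key[0] == last[0] and key[1] <= last[1]:
            raise ValueError(f"unsorted calls at {key} after {last}")
        last = key
        contigs[call.chrom] = None
        if variants_only and is_homref_genotype(call.map_genotype, call.ref_base):
            continue
        body.append(format_vcf_record(call, sample_name))

    close = False
    if isinstance(out, (str, bytes)) or hasattr(out, "__fspath__"):
        out = _open_text(out, "wt")
        close = True
    try:
        out.write(vcf_header(meta, sample_name, contigs=tuple(contigs)))
        for line in body:
            out.write(line + "\n")
        return len(body)
    finally:
        if close:
            out.close()


def is_homref_genotype(genotype: str, ref: str) -> bool:
    return all(a == ref for a in genotype)


# ---------------------------------------------------------------------------
# VCF input (cyvcf2-backed)


@dataclass(frozen=True)
class VcfRecord:
    """Light projection of a VCF record used by filtering and evaluation."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float
    gt_alleles: tuple[int, ...]  # allele indices, e.g. (0, 1)
    depth: int
    gq: float
    allele_depths: tuple[int, ...]  # per allele, REF first
    line: str

    @property
    def is_variant(self) -> bool:
        return any(a > 0 for a in self.gt_alleles)

    @property
    def zygosity(self) -> str:
        if len(self.gt_alleles) < 2:
            return "hom"
        return "hom" if len(set(self.gt_alleles)) == 1 else "het"

    @property
    def alt_support(self) -> int:
        """Reads supporting the strongest called non-reference allele."""
        support = 0
        for a in set(self.gt_alleles):
            if a > 0 and a < len(self.allele_depths):
                support = max(support, self.allele_depths[a])
        return support

    @property
    def called_alts(self) -> tuple[str, ...]:
        alleles = (self.ref,) + self.alts
        return tuple(sorted({alleles[a] for a in self.gt_alleles if a > 0}))


def read_vcf(path) -> Iterator[VcfRecord]:
    """Read a VCF file into :class:`VcfRecord` projections via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        for v in vcf:
            gt = tuple(int(a) for a in v.genotypes[0][:-1] if a >= 0)
            try:
                gq = float(v.format("GQ")[0][0])
            except (TypeError, KeyError):
                gq = v.QUAL if v.QUAL is not None else 0.0
            try:
                ad = tuple(int(x) for x in np.atleast_1d(v.format("AD")[0]))
            except (TypeError, KeyError):
                ad = ()
            try:
                dp = int(v.format("DP")[0][0])
            except (TypeError, KeyError):
                dp = int(v.INFO.get("DP", 0))
            yield VcfRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                gt_alleles=gt,
                depth=dp,
                gq=gq,
                allele_depths=ad,
                line=str(v).rstrip("\n"),
            )
    finally:
        vcf.close()


def read_vcf_header(path) -> str:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        return vcf.raw_header
    finally:
        vcf.close()
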