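"""Synthetic reference, variant and read simulator with an aDNA damage mode.

The simulator provides ground truth for the genotype caller without any
external dataset.  It draws a random reference of configurable GC content,
plants SNPs at a configurable rate (heterozygous or homozygous-alternative
for diploid genomes), and samples single-end reads uniformly along the
genome with

* a linear Phred quality profile along the read (qualities decay towards
  the 3' end, as on Illumina machines),
* optional cytosine-deamination damage clustered at the read ends:
  C->T at the 5' end and G->A at the 3' end, each with probability
  ``d_max * exp(-lambda * j)`` at distance ``j`` from the respective end,
  applied strand-aware to the read sequence *before* sequencing error, and
* independent per-base sequencing errors at rate ``10**(-q/10)``.

Damage is a property of the template, invisible to the sequencer: the
emitted quality strings encode the intended quality profile, not the
realized errors.  This is exactly the failure mode the damage-aware
substitution matrix targets.

Outputs are FASTA (reference), FASTQ (reads), a truth VCF, and a pileup in
the ``mpileup -s`` dialect with perfectly placed reads and constant
mapping quality, which lets the genotyper be tested in isolation from any
mapper.  All outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .error_models import BASES

_COMPLEMENT = 3  # complement of base index b is 3 - b in ACGT order


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one simulation."""

    genome_length: int = 100_000
    gc_content: float = 0.5
    ploidy: str = "haploid"
    snp_rate: float = 0.001  # fraction of positions mutated
    het_fraction: float = 5.0 / 9.0  # of planted diploid SNPs; hom:het = 0.8
    read_length: int = 36
    mean_depth: float = 27.0
    q_start: int = 40  # Phred at the 5' end of each read
    q_end: int = 30  # Phred at the 3' end
    damage_max: float = 0.0  # terminal deamination probability (d_max)
    damage_lambda: float = 0.3  # exponential decay per position
    map_quality: int = 60  # constant mapping quality in direct-pileup mode
    seed: int = 0
    chrom: str = "sim"

    def __post_init__(self) -> None:
        for name in ("gc_content", "snp_rate", "het_fraction", "damage_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length < self.read_length:
            raise ValueError("genome_length must be >= read_length")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")


@dataclass(frozen=True)
class TruthRecord:
    """Planted variant: position, alleles and zygosity."""

    pos: int  # 1-based
    ref: str
    genotype: str  # e.g. 'T' (haploid), 'AT' or 'TT' (diploid), sorted
    zygosity: str  # 'hom' or 'het'


@dataclass
class SimResult:
    """Arrays describing one simulated experiment."""

    config: SimConfig
    reference: np.ndarray  # (L,) int8 base indices
    haplotypes: np.ndarray  # (ploidy, L) int8
    truth: list[TruthRecord]
    starts: np.ndarray  # (n_reads,) 0-based
    reverse: np.ndarray  # (n_reads,) bool
    read_seq: np.ndarray  # (n_reads, read_length) read-space realized bases
    read_qual: np.ndarray  # (read_length,) Phred profile, read space
    base_counts: np.ndarray = field(default=None)  # (L, 4) bookkeeping

    @property
    def n_reads(self) -> int:
        return len(self.starts)


def simulate_genome(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[TruthRecord]]:
    """Draw a reference and plant variants into individual haplotypes.

    The reference is i.i.d. with P(G) = P(C) = gc/2.  Each position
    carries a variant with probability ``snp_rate``; the alternative
    allele is uniform over the other three bases.  Diploid variants are
    heterozygous (ref/alt) with probability ``het_fraction`` and
    homozygous-alternative otherwise.
    """
    L = config.genome_length
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    reference = rng.choice(4, size=L, p=probs).astype(np.int8)
    n_hap = 1 if config.ploidy == "haploid" else 2
    haplotypes = np.tile(reference, (n_hap, 1))
    truth: list[TruthRecord] = []
    var_pos = np.flatnonzero(rng.random(L) < config.snp_rate)
    for pos in var_pos:
        ref_b = int(reference[pos])
        alt_b = (ref_b + int(rng.integers(1, 4))) % 4
        if config.ploidy == "haploid":
            haplotypes[0, pos] = alt_b
            truth.append(TruthRecord(pos + 1, BASES[ref_b], BASES[alt_b], "hom"))
        else:
            if rng.random() < config.het_fraction:
                hap = int(rng.integers(0, 2))
                haplotypes[hap, pos] = alt_b
                geno = "".join(sorted(BASES[ref_b] + BASES[alt_b]))
                truth.append(TruthRecord(pos + 1, BASES[ref_b], geno, "het"))
            else:
                haplotypes[:, pos] = alt_b
                truth.append(
                    TruthRecord(pos + 1, BASES[ref_b], BASES[alt_b] * 2, "hom")
                )
    return reference, haplotypes, truth


def quality_profile(config: SimConfig) -> np.ndarray:
    """Integer Phred profile along the read, linear from q_start to q_end."""
    rl = config.read_length
    if rl == 1:
        return np.array([config.q_start])
    return np.rint(np.linspace(config.q_start, config.q_end, rl)).astype(int)


def simulate_reads(
    haplotypes: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample reads; returns (starts, reverse, read-space realized bases).

    Read count is ``round(mean_depth * genome_length / read_length)``;
    start positions and strands are uniform; for diploid genomes each read
    draws its haplotype uniformly.  Damage is applied to the read-space
    sequence first, then sequencing errors at the per-position error rate
    implied by the quality profile.
    """
    L = config.genome_length
    rl = config.read_length
    n = int(round(config.mean_depth * L / rl))
    starts = rng.integers(0, L - rl + 1, size=n)
    hap = rng.integers(0, haplotypes.shape[0], size=n)
    reverse = rng.integers(0, 2, size=n).astype(bool)

    idx = starts[:, None] + np.arange(rl)[None, :]
    seq = haplotypes[hap[:, None], idx]  # fragment in reference orientation
    # read space: reverse-strand reads see the reverse complement
    seq = seq.copy()
    seq[reverse] = (_COMPLEMENT - seq[reverse])[:, ::-1]

    j = np.arange(rl)
    if config.damage_max > 0.0:
        p5 = config.damage_max * np.exp(-config.damage_lambda * j)
        p3 = p5[::-1]
        c_hit = (seq == 1) & (rng.random(seq.shape) < p5[None, :])
        seq[c_hit] = 3  # C -> T near the 5' end
        g_hit = (seq == 2) & (rng.random(seq.shape) < p3[None, :])
        seq[g_hit] = 0  # G -> A near the 3' end

    qual = quality_profile(config)
    err_rate = 10.0 ** (-qual / 10.0)
    err = rng.random(seq.shape) < err_rate[None, :]
    shift = rng.integers(1, 4, size=seq.shape)
    seq[err] = (seq[err] + shift[err]) % 4
    return starts, reverse, seq


def simulate(config: SimConfig) -> SimResult:
    """Run the full simulation and tabulate per-position base counts."""
    rng = np.random.default_rng(config.seed)
    reference, haplotypes, truth = simulate_genome(config, rng)
    starts, reverse, read_seq = simulate_reads(haplotypes, config, rng)
    qual = quality_profile(config)

    rl = config.read_length
    # realized bases back in reference orientation, for pileup/bookkeeping
    ref_seq = read_seq.copy()
    ref_seq[reverse] = (_COMPLEMENT - read_seq[reverse])[:, ::-1]
    idx = starts[:, None] + np.arange(rl)[None, :]
    counts = np.zeros((config.genome_length, 4), dtype=np.int64)
    np.add.at(counts, (idx.ravel(), ref_seq.ravel()), 1)

    return SimResult(
        config=config,
        reference=reference,
        haplotypes=haplotypes,
        truth=truth,
        starts=starts,
        reverse=reverse,
        read_seq=read_seq,
        read_qual=qual,
        base_counts=counts,
    )


# ---------------------------------------------------------------------------
# writers


def _indices_to_seq(arr: np.ndarray) -> str:
    return "".join(BASES[b] for b in arr)


def write_fasta(reference: np.ndarray, handle, chrom: str = "sim") -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(_indices_to_seq(reference)), id=chrom, description="")
    seqio_write([record], handle, "fasta")


def write_fastq(result: SimResult, handle) -> None:
    qual_str = "".join(chr(q + 33) for q in result.read_qual)
    for i in range(result.n_reads):
        handle.write(
            f"@read{i}\n{_indices_to_seq(result.read_seq[i])}\n+\n{qual_str}\n"
        )


def write_truth_vcf(result: SimResult, handle) -> None:
    cfg = result.config
    handle.write("##fileformat=VCFv4.2\n##source=pilecall-simulate\n")
    handle.write(f"##contig=<ID={cfg.chrom},length={cfg.genome_length}>\n")
    handle.write(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Planted genotype">\n'
    )
    handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTRUTH\n")
    for t in result.truth:
        alts = sorted({a for a in t.genotype if a != t.ref})
        alleles = [t.ref] + alts
        if cfg.ploidy == "haploid":
            gt = str(alleles.index(t.genotype))
        else:
            gt = "/".join(str(alleles.index(a)) for a in sorted(t.genotype))
        handle.write(
            f"{cfg.chrom}\t{t.pos}\t.\t{t.ref}\t{','.join(alts)}\t.\t.\t.\tGT\t{gt}\n"
        )


def write_pileup(result: SimResult, handle) -> None:
    """Emit an ``mpileup -s`` pileup of perfectly placed reads.

    Bases are reported in reference orientation with '.'/',' for matches
    and case encoding strand; per-base qualities follow the read's quality
    profile (reversed for reverse-strand reads); mapping quality is the
    configured constant.
    """
    cfg = result.config
    rl = cfg.read_length
    n = result.n_reads
    idx = (result.starts[:, None] + np.arange(rl)[None, :]).ravel()
    ref_seq = result.read_seq.copy()
    ref_seq[result.reverse] = (_COMPLEMENT - result.read_seq[result.reverse])[:, ::-1]
    bases = ref_seq.ravel()
    qual = np.tile(result.read_qual, (n, 1))
    qual[result.reverse] = qual[result.reverse][:, ::-1]
    qual = qual.ravel()
    rev = np.repeat(result.reverse, rl)

    order = np.argsort(idx, kind="stable")
    idx, bases, qual, rev = idx[order], bases[order], qual[order], rev[order]

    ref_at = result.reference[idx]
    match = bases == ref_at
    # char codes into '.,ACGTacgt'
    lookup = np.frombuffer(b".,ACGTacgt", dtype=np.uint8)
    code = np.where(match, rev.astype(int), 2 + bases + 4 * rev.astype(int))
    base_str = lookup[code].tobytes().decode("ascii")
    qual_str = (qual + 33).astype(np.uint8).tobytes().decode("latin1")
    mq_char = chr(cfg.map_quality + 33)

    # column boundaries over covered positions
    boundaries = np.flatnonzero(np.diff(idx)) + 1
    col_starts = np.concatenate(([0], boundaries))
    col_ends = np.concatenate((boundaries, [len(idx)]))
    ref_str = _indices_to_seq(result.reference)
    for s, e in zip(col_starts, col_ends):
        pos = int(idx[s])
        d = e - s
        handle.write(
            f"{cfg.chrom}\t{pos + 1}\t{ref_str[pos]}\t{d}\t"
            f"{base_str[s:e]}\t{qual_str[s:e]}\t{mq_char * d}\n"
        )


def config_summary(config: SimConfig) -> dict:
    return asdict(config)
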