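"""Quality-score handling and substitution-error / damage matrices.

Sequencers report a Phred quality for every base call, and mappers report a
Phred mapping quality for every read.  This module turns those scores into
probability distributions over the four nucleotides, and builds the
row-stochastic 4x4 matrices P(observed base R | sampled base S) that model
systematic substitution errors and the cytosine-deamination damage typical
of ancient or formalin-fixed DNA.

Conventions used throughout the package:

* bases are indexed 0..3 in the fixed order ``A, C, G, T``;
* matrices are row-stochastic with rows indexed by the true (sampled) base
  ``S`` and columns by the observed (read) base ``R``;
* an error rate ``tau`` is the total off-diagonal mass per row, split
  non-uniformly: the substitution towards the Watson-Crick complement of
  the sampled base is the rarest and carries 1/3 of the mass of each of the
  other two substitutions (an empirical pattern of mapped mismatches);
* a damage rate ``delta`` adds C->T and G->A mass on top of the error
  matrix, modelling post-mortem deamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Default per-row substitution error rate (0.2%).
DEFAULT_TAU = 0.002
#: Default deamination damage rate (3%) for the ancient-DNA model.
DEFAULT_DELTA = 0.03
#: Cap on the per-base error probability.  Phred 0 decodes to an error
#: probability of 1, which would make a read anti-informative (it would
#: certainly NOT be the called base); capping at 0.75 turns such a base
#: into a flat, uninformative observation instead.
DEFAULT_ERROR_CAP = 0.75

#: For each sampled base, the observed base receiving the smallest
#: off-diagonal probability: the Watson-Crick complement (A->T, C->G,
#: G->C, T->A).
_RAREST_SUBSTITUTION = (3, 2, 1, 0)

_ROW_SUM_TOL = 1e-12


class ParameterError(ValueError):
    """Raised for rate parameters outside their valid range."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Row-stochastic 4x4 matrix P(R|S) over the alphabet ``ACGT``.

    Rows are indexed by the sampled (true) base S, columns by the observed
    read base R.  ``tau`` and ``delta`` record the parameters the matrix
    was built from (both ``None`` for user-supplied matrices).
    """

    entries: np.ndarray
    tau: float | None = None
    delta: float | None = None

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.shape != (4, 4):
            raise ValueError(f"substitution matrix must be 4x4, got {entries.shape}")
        if np.any(entries < 0.0) or np.any(entries > 1.0):
            raise ValueError("substitution matrix entries must lie in [0, 1]")
        if np.any(np.abs(entries.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError("substitution matrix rows must each sum to 1")
        object.__setattr__(self, "entries", entries)

    def __getitem__(self, key):
        return self.entries[key]


def phred_to_error_prob(score: int, cap: float = DEFAULT_ERROR_CAP) -> float:
    """Decode a Phred score into a per-base error probability.

    The Phred convention is ``P(error) = 10**(-score/10)``; the result is
    capped at ``cap`` so that very low scores degrade to an uninformative
    base call rather than an anti-informative one.

    Raises
    ------
    ValueError
        If ``score`` is negative, which almost always indicates a wrong
        ASCII quality offset upstream.
    """
    if score < 0:
        raise ValueError(
            f"negative Phred score {score}: check the quality ASCII offset"
        )
    return min(10.0 ** (-score / 10.0), cap)


def effective_quality(read_q: int, map_q: int) -> int:
    """Effective quality of one read base: ``min(Q_read, Q_map)``.

    A confidently mapped but poorly called base is no more trustworthy than
    its base quality, and a well called base on a dubiously placed read is
    no more trustworthy than its mapping quality, so the smaller of the two
    scores governs the weight of the observation.
    """
    if read_q < 0 or map_q < 0:
        raise ValueError("quality scores must be non-negative")
    return min(read_q, map_q)


def base_call_distribution(called_base: str | int, error_prob: float) -> np.ndarray:
    """Distribution over the four nucleotides implied by one base call.

    Mass ``1 - e`` goes to the called base and ``e/3`` to each alternative,
    i.e. errors are uniform over the other three bases.  Under a flat prior
    over nucleotides this is proportional to the likelihood the sequencer's
    signal assigns to each base, which is all the quality string encodes.
    """
    if not 0.0 <= error_prob <= DEFAULT_ERROR_CAP:
        raise ValueError(f"error_prob {error_prob} outside [0, {DEFAULT_ERROR_CAP}]")
    idx = BASE_INDEX[called_base] if isinstance(called_base, str) else int(called_base)
    probs = np.full(4, error_prob / 3.0)
    probs[idx] = 1.0 - error_prob
    return probs


def build_error_matrix(tau: float = DEFAULT_TAU) -> SubstitutionMatrix:
    """Substitution-error matrix with total off-diagonal row mass ``tau``.

    Each row keeps ``1 - tau`` on the diagonal.  The off-diagonal mass is
    split so that the substitution to the complement base gets ``tau/7``
    and the other two substitutions get ``3*tau/7`` each: the rarest
    substitution is then exactly 1/3 of each of the other two, and
    ``tau/7 + 2 * 3*tau/7 == tau``.
    """
    if not 0.0 <= tau < 1.0:
        raise ParameterError(f"tau must be in [0, 1), got {tau}")
    small = tau / 7.0
    large = 3.0 * tau / 7.0
    entries = np.full((4, 4), large)
    for s, rare in enumerate(_RAREST_SUBSTITUTION):
        entries[s, rare] = small
        entries[s, s] = 1.0 - tau
    return SubstitutionMatrix(entries, tau=tau, delta=0.0)


def build_damage_matrix(
    tau: float = DEFAULT_TAU, delta: float = DEFAULT_DELTA
) -> SubstitutionMatrix:
    """Error matrix with deamination damage added on top.

    Post-mortem deamination converts cytosine to uracil, read as thymine;
    depending on the strand sequenced this shows up as an excess of C->T or
    G->A mismatches.  Given an overall expected damage rate ``delta``, mass
    ``delta`` is moved from C->C to C->T and from G->G to G->A; the other
    rows are untouched and every row stays stochastic.
    """
    if not 0.0 <= delta < 1.0:
        raise ParameterError(f"delta must be in [0, 1), got {delta}")
    if tau + delta >= 1.0:
        raise ParameterError(
            f"tau + delta must be < 1 (got {tau} + {delta}); the diagonal "
            "would become non-positive"
        )
    entries = build_error_matrix(tau).entries.copy()
    c, g, a, t = BASE_INDEX["C"], BASE_INDEX["G"], BASE_INDEX["A"], BASE_INDEX["T"]
    entries[c, t] += delta
    entries[c, c] -= delta
    entries[g, a] += delta
    entries[g, g] -= delta
    return SubstitutionMatrix(entries, tau=tau, delta=delta)


def compose_read_likelihood(sub: SubstitutionMatrix, call: np.ndarray) -> np.ndarray:
    """Per-read likelihood vector L with L[s] = sum_r P(R=r|S=s) * call[r].

    ``call`` is the base-call distribution derived from the effective
    quality; composing it with the substitution matrix sums out the
    unobserved read nucleotide R, leaving the likelihood contribution of
    this read for each possible sampled base S.  With the identity matrix
    (tau = delta = 0) the reported quality scores are trusted completely
    and L equals ``call``.
    """
    call = np.asarray(call, dtype=float)
    if call.shape != (4,):
        raise ValueError("base-call distribution must be a length-4 vector")
    return sub.entries @ call


def write_matrix_file(sub: SubstitutionMatrix, handle) -> None:
    """Write a 4x4 matrix as tab-separated text, rows in ``ACGT`` order."""
    for s in range(4):
        handle.write("\t".join(f"{x:.12g}" for x in sub.entries[s]) + "\n")


def read_matrix_file(handle) -> SubstitutionMatrix:
    """Read a matrix written by :func:`write_matrix_file` (or user-supplied
    in the same format), validating row-stochasticity."""
    rows = []
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(x) for x in line.split()])
    if len(rows) != 4 or any(len(r) != 4 for r in rows):
        raise ValueError("matrix file must contain 4 rows of 4 probabilities")
    return SubstitutionMatrix(np.array(rows))
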