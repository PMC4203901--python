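"""Independent brute-force oracles used by the test suite.

These deliberately avoid the factorised per-read computation the package
uses: the genotype posterior is obtained by explicitly enumerating every
joint assignment of the sampled alleles (s_1..s_n) and read nucleotides
(r_1..r_n), so agreement with the implementation checks the
marginalisation itself.
"""

from __future__ import annotations

import itertools

import numpy as np

from pilecall.model_core import sample_matrix


def posterior_by_enumeration(call_dists, sub_entries, ref_probs, gt_matrix, ploidy):
    """Genotype posterior by explicit enumeration of all (s-vector, r-vector)
    assignments.

    Parameters
    ----------
    call_dists : list of length-4 arrays
        Base-call distribution of each read (from its effective quality).
    sub_entries : (4, 4) array
        Substitution matrix P(R|S).
    ref_probs : length-4 array
        Prior over the reference nucleotide (point mass in observed mode).
    gt_matrix : (4, G) array
        Genotype prior P(G|H).
    ploidy : str
    """
    n = len(call_dists)
    smat = sample_matrix(ploidy)
    n_geno = smat.shape[0]
    combos = np.array(list(itertools.product(range(4), repeat=n)), dtype=int)
    combos = combos.reshape(len(combos), n)  # handles n = 0

    # P(r-vector, signals | s-vector) over all pairs of assignments
    term = np.ones((len(combos), len(combos)))
    for i in range(n):
        m = np.asarray(sub_entries) * np.asarray(call_dists[i])[None, :]
        term *= m[combos[:, i][:, None], combos[None, :, i]]
    sum_over_r = term.sum(axis=1)

    post = np.empty(n_geno)
    ref_probs = np.asarray(ref_probs, dtype=float)
    for g in range(n_geno):
        w = np.ones(len(combos))
        for i in range(n):
            w *= smat[g, combos[:, i]]
        post[g] = float(ref_probs @ gt_matrix[:, g]) * float(w @ sum_over_r)
    return post / post.sum()
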