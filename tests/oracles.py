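"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: AMOVA from
an expanded individual-level distance matrix, nucleotide diversity as the
plain average over all individual pairs, and the TN93 distance evaluated
directly from its closed form.
"""

import math

import numpy as np


def brute_amova_phi_st(ind_a, ind_b, D):
    """Two-group AMOVA ΦST from individual haplotype-index lists, summing
    squared distances over every ordered individual pair."""
    ind = list(ind_a) + list(ind_b)
    na, nb = len(ind_a), len(ind_b)
    N = na + nb
    D2 = np.asarray(D, dtype=float) ** 2
    ssd_tot = sum(D2[ind[i], ind[j]] for i in range(N) for j in range(N)) / (2 * N)
    ssd_w = (
        sum(D2[i, j] for i in ind_a for j in ind_a) / (2 * na)
        + sum(D2[i, j] for i in ind_b for j in ind_b) / (2 * nb)
    )
    ssd_a = ssd_tot - ssd_w
    sigma_w = ssd_w / (N - 2)
    n_c = N - (na * na + nb * nb) / N
    sigma_a = (ssd_a - sigma_w) / n_c
    return sigma_a / (sigma_a + sigma_w)


def brute_pi(individual_seqs):
    """Unbiased nucleotide diversity as the average per-site difference over
    all unordered individual pairs (valid sites only)."""
    n = len(individual_seqs)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = individual_seqs[i], individual_seqs[j]
            pairs = [
                (x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"
            ]
            total += sum(x != y for x, y in pairs) / len(pairs)
    # the plain mean over C(n,2) pairs equals the n/(n-1)-corrected
    # frequency formula, since pair (h,k) occurs c_h·c_k times
    return total / (n * (n - 1) / 2)


def tn93_closed_form(p1, p2, q, gA, gC, gG, gT):
    """TN93 distance evaluated directly from the published closed form."""
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    return (
        -k1 * math.log(1 - p1 / k1 - q / (2 * gR))
        - k2 * math.log(1 - p2 / k2 - q / (2 * gY))
        - k3 * math.log(1 - q / (2 * gR * gY))
    )
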