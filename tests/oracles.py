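"""Independent brute-force oracles.

Each oracle assembles the full covariance matrix entry by entry with
plain Python loops and sums it directly — deliberately naive, so the
vectorized package implementations are checked against an independent
path rather than themselves.
"""

import itertools
import math


def subset_cov(structure, subset):
    """sigma_i sigma_j rho_ij over a subset, as nested lists."""
    pos = {lab: i for i, lab in enumerate(structure.labels)}
    idx = sorted(pos[lab] for lab in subset)
    sd = structure.sd_vector()
    return [
        [sd[i] * sd[j] * structure.R[i, j] for j in idx] for i in idx
    ]


def oracle_alpha(structure, subset):
    cov = subset_cov(structure, subset)
    n = len(cov)
    total = sum(sum(row) for row in cov)
    diag = sum(cov[i][i] for i in range(n))
    return n / (n - 1) * (1 - diag / total)


def oracle_validity(structure, subset):
    pos = {lab: i for i, lab in enumerate(structure.labels)}
    idx = sorted(pos[lab] for lab in subset)
    sd = structure.sd_vector()
    num = sum(sd[i] * structure.r_crit[i] for i in idx)
    cov = subset_cov(structure, subset)
    return num / math.sqrt(sum(sum(row) for row in cov))


def oracle_item_total(structure, subset, item):
    pos = {lab: i for i, lab in enumerate(structure.labels)}
    i = pos[item]
    rest = sorted(pos[lab] for lab in subset if lab != item)
    sd = structure.sd_vector()
    cov_ir = sum(sd[i] * sd[j] * structure.R[i, j] for j in rest)
    var_r = sum(sd[j] * sd[k] * structure.R[j, k] for j in rest for k in rest)
    return cov_ir / math.sqrt(sd[i] ** 2 * var_r)


def oracle_best_deletion(structure, subset, objective_oracle):
    """(best objective value, removed label) over all single deletions."""
    best = None
    for item in subset:
        v = objective_oracle(structure, [x for x in subset if x != item])
        if best is None or v > best[0] + 1e-12:
            best = (v, item)
    return best


def oracle_best_subset(structure, k, objective_oracle):
    """Best size-k subset by exhaustive enumeration with the oracle metric."""
    best = None
    for subset in itertools.combinations(structure.labels, k):
        v = objective_oracle(structure, subset)
        if best is None or v > best[0] + 1e-12:
            best = (v, subset)
    return best
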