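"""Deliberately naive reference implementations used as independent oracles.

Everything here is written as plain double loops / textbook formulas,
independent of the package's vectorized code paths.
"""

import math


def naive_scores(dosage_rows, rare_flags):
    """Per-individual (total, rare, common) mean dosages by double loop."""
    out = []
    for row in dosage_rows:
        tot = rare = common = 0.0
        n_rare = n_common = 0
        for g, is_rare in zip(row, rare_flags):
            tot += g
            if is_rare:
                rare += g
                n_rare += 1
            else:
                common += g
                n_common += 1
        out.append(
            (
                tot / len(row),
                rare / n_rare if n_rare else float("nan"),
                common / n_common if n_common else float("nan"),
            )
        )
    return out


def naive_two_proportion_z(x1, n1, x2, n2):
    p1, p2 = x1 / n1, x2 / n2
    p = (x1 + x2) / (n1 + n2)
    if p == 0 or p == 1:
        return 0.0, 1.0
    z = (p1 - p2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    pval = 2 * (1 - _phi(abs(z)))
    return z, min(pval, 1.0)


def _phi(x):
    return 0.5 * (1 + math.erf(x / math.sqrt(2)))


def naive_bh(pvals):
    """Step-up BH: sort ascending, adj_i = min_{j>=i} m*p_j/j, clamp at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj[i] = running
    return adj


def naive_mannwhitney_u(a, b):
    """U statistic of sample a: #(a_i > b_j) + 0.5 * #(a_i == b_j)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def naive_chi_square(table):
    """Pearson chi-square without continuity correction on a 2x2."""
    (a, b), (c, d) = table
    n = a + b + c + d
    chi2 = 0.0
    for i, row_tot in enumerate((a + b, c + d)):
        for j, col_tot in enumerate((a + c, b + d)):
            obs = table[i][j]
            exp = row_tot * col_tot / n
            chi2 += (obs - exp) ** 2 / exp
    return chi2


def naive_odds_ratio(table):
    (a, b), (c, d) = table
    return (a * d) / (b * c)
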