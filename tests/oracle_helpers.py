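"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own algorithms: the SSR oracle
tests every (start, period) pair directly, and the AMOVA oracle computes
sums of squares and variance components with exact rational arithmetic
from the defining formulas.
"""

from fractions import Fraction
from itertools import combinations


def brute_force_ssrs(seq, thresholds):
    """All qualifying maximal perfect runs, reported at their smallest period.

    Returns a set of (start_1based, end_1based, motif, period, copies).
    """
    seq = seq.upper()
    n = len(seq)
    found = set()
    for period in range(1, 7):
        runs = set()
        for start in range(n - period + 1):
            window = seq[start:start + period]
            if any(c not in "ACGT" for c in window):
                continue
            end = start + period
            while end < n and seq[end] in "ACGT" and seq[end] == seq[end - period]:
                end += 1
            runs.add((start, end))
        # keep only runs not contained in a longer run of the same period
        maximal = {(s, e) for (s, e) in runs
                   if not any((s2 <= s and e <= e2 and (s2, e2) != (s, e))
                              for (s2, e2) in runs)}
        for s, e in maximal:
            copies = (e - s) // period
            if copies < thresholds[period]:
                continue
            run = seq[s:e]
            if min_period(run) != period:
                continue
            found.add((s + 1, s + copies * period, seq[s:s + period], period, copies))
    return found


def min_period(s):
    for p in range(1, len(s)):
        if all(s[i] == s[i - p] for i in range(p, len(s))):
            return p
    return len(s)


def amova_oracle(distances, populations, species):
    """Three-level AMOVA with exact rational arithmetic.

    ``distances[i][j]`` are squared distances between individuals;
    ``populations`` and ``species`` are parallel label lists.  Returns
    (df, ss, variance_components) as tuples of Fractions, strata ordered
    among-species / among-populations-within-species / within-populations.
    """
    n = len(populations)
    d2 = [[Fraction(distances[i][j]) for j in range(n)] for i in range(n)]
    pops = sorted(set(populations))
    groups = sorted(set(species))
    pop_of_group = {p: species[populations.index(p)] for p in pops}

    def ss_within(labels, members_of):
        total = Fraction(0)
        for label in labels:
            idx = members_of[label]
            pair_sum = sum(d2[i][j] for i, j in combinations(idx, 2))
            total += Fraction(pair_sum, len(idx))
        return total

    pop_members = {p: [i for i, q in enumerate(populations) if q == p] for p in pops}
    grp_members = {g: [i for i, q in enumerate(species) if q == g] for g in groups}
    ss_total = Fraction(sum(d2[i][j] for i, j in combinations(range(n), 2)), n)
    ss_wp = ss_within(pops, pop_members)
    ss_wg = ss_within(groups, grp_members)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    G, P = len(groups), len(pops)
    df = (Fraction(G - 1), Fraction(P - G), Fraction(n - P))
    n_p = {p: Fraction(len(pop_members[p])) for p in pops}
    N_g = {g: Fraction(len(grp_members[g])) for g in groups}
    sum_np2_over_ng = sum(
        sum(n_p[p] ** 2 for p in pops if pop_of_group[p] == g) / N_g[g]
        for g in groups)
    ms_wp = Fraction(ss_wp, df[2])
    sigma_c = ms_wp
    if df[1] > 0:
        n_coef = (n - sum_np2_over_ng) / df[1]
        sigma_b = (Fraction(ss_ap, df[1]) - sigma_c) / n_coef
    else:
        sigma_b = Fraction(0)
    n1_coef = (sum_np2_over_ng - sum(v**2 for v in n_p.values()) / n) / df[0]
    n2_coef = (n - sum(v**2 for v in N_g.values()) / n) / df[0]
    sigma_a = (Fraction(ss_ag, df[0]) - sigma_c - n1_coef * sigma_b) / n2_coef
    return df, (ss_ag, ss_ap, ss_wp), (sigma_a, sigma_b, sigma_c)
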