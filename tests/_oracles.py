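"""Independent brute-force oracles used to validate the library.

Everything here deliberately avoids the code paths under test: exact
rational arithmetic with math.comb, explicit permutation enumeration,
hand-built risk tables and cross-product joins.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def enum_hypergeom_upper(k: int, n_marked: int, n_drawn: int, n_total: int) -> float:
    """P(X >= k) by exact enumeration of hypergeometric point masses."""
    total = Fraction(0)
    denom = math.comb(n_total, n_drawn)
    lo = max(k, 0, n_marked + n_drawn - n_total)
    hi = min(n_marked, n_drawn)
    for j in range(lo, hi + 1):
        total += Fraction(math.comb(n_marked, j) * math.comb(n_total - n_marked, n_drawn - j), denom)
    return float(min(total, Fraction(1)))


def bh_step_up(p_values: list[float]) -> list[float]:
    """Literal BH step-up: sort, scale by m/i, enforce monotonicity, unsort."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    scaled = [p_values[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = min(1.0, scaled[i])
    return out


def brute_force_triplets(
    circ_dirs: dict[str, str],
    mirna_dirs: dict[str, str],
    gene_dirs: dict[str, str],
    mc_pairs: set[tuple[str, str]],
    mg_pairs: set[tuple[str, str]],
) -> set[tuple[str, str, str]]:
    """Full cross-product enumeration of sign-consistent ceRNA triplets."""
    out = set()
    for c, m, g in itertools.product(circ_dirs, mirna_dirs, gene_dirs):
        cd, md, gd = circ_dirs[c], mirna_dirs[m], gene_dirs[g]
        if "none" in (cd, md, gd):
            continue
        if (m, c) in mc_pairs and (m, g) in mg_pairs and gd == cd and gd != md:
            out.add((c, m, g))
    return out


def hand_logrank(times_a, events_a, times_b, events_b) -> float:
    """Log-rank chi-square from an explicitly built pooled risk table."""
    records = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in records if e == 1})
    observed_a = expected_a = variance = 0.0
    for t in event_times:
        n_at_risk = sum(1 for tt, _, _ in records if tt >= t)
        n_a = sum(1 for tt, _, grp in records if tt >= t and grp == 0)
        d = sum(1 for tt, e, _ in records if tt == t and e == 1)
        d_a = sum(1 for tt, e, grp in records if tt == t and e == 1 and grp == 0)
        observed_a += d_a
        expected_a += d * n_a / n_at_risk
        if n_at_risk > 1:
            variance += (
                d * (n_a / n_at_risk) * (1 - n_a / n_at_risk) * (n_at_risk - d) / (n_at_risk - 1)
            )
    return (observed_a - expected_a) ** 2 / variance


def rank_average(values) -> list[float]:
    """Average ranks with ties, written out longhand."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho_enum(x, y) -> float:
    rx, ry = rank_average(x), rank_average(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def spearman_exact_p_enum(x, y) -> float:
    """Two-sided permutation p for Spearman rho by full n! enumeration."""
    observed = abs(spearman_rho_enum(x, y))
    count = total = 0
    for perm in itertools.permutations(y):
        if abs(spearman_rho_enum(x, perm)) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total
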