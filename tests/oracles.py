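"""Independent brute-force transcriptions of the zoning and selection rules.

These are written with plain Python loops, sets and dicts — deliberately a
different style from the package's vectorized implementations — and serve as
oracles in equivalence tests on small random instances.
"""

from __future__ import annotations

import math


def oracle_region(xs: list[float], rs: list[float], bx: float, bs: float) -> tuple[int, int]:
    """Literal scan for one candidate's region; positions are 1-based inclusive."""
    n = len(xs)

    def x(j):  # 1-based accessor
        return xs[j - 1]

    # rank crossing: last position whose transferred rank is <= bs
    pi = 0
    j = 1
    while j <= n and rs[j - 1] <= bs:
        pi = j
        j += 1
    if pi < 1:
        pi = 1
    if pi > n:
        pi = n

    if pi + 1 <= n and x(pi + 1) <= bx:
        # Case I: keep adding k until the score reaches bx
        j = pi + 1
        while x(j) < bx and j < n:
            j += 1
        return (pi, j)
    if x(pi) >= bx:
        # Case II: walk left until the score has dropped to bx
        j = pi
        while x(j) > bx and j > 1:
            j -= 1
        hi = pi + 1 if pi + 1 <= n else n
        return (j, hi)
    # in-between: degenerate one-step region
    return (pi, pi + 1 if pi + 1 <= n else n)


def oracle_zone_numbers(regions: list[tuple[int, int]], n: int):
    """Merge-and-number by painting positions; returns (labels, region labels)."""
    # transitive merge via repeated pairwise joins
    groups = [{r} for r in range(len(regions))]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(_overlap(regions[i], regions[j])
                       for i in groups[a] for j in groups[b]):
                    groups[a] |= groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    runs = []  # (lo, hi, group index or None)
    for gi, g in enumerate(groups):
        lo = min(regions[i][0] for i in g)
        hi = max(regions[i][1] for i in g)
        runs.append((lo, hi, gi))
    runs.sort()
    full = []
    pos = 1
    for lo, hi, gi in runs:
        if pos < lo:
            full.append((pos, lo - 1, None))
        full.append((lo, hi, gi))
        pos = hi + 1
    if pos <= n:
        full.append((pos, n, None))
    labels = [0] * n
    group_label = {}
    for num, (lo, hi, gi) in enumerate(full, start=1):
        for q in range(lo, hi + 1):
            labels[q - 1] = num
        if gi is not None:
            group_label[gi] = num
    region_labels = []
    for r in range(len(regions)):
        gi = next(i for i, g in enumerate(groups) if r in g)
        region_labels.append(group_label[gi])
    return labels, region_labels


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return not (a[1] < b[0] or b[1] < a[0])


def oracle_zone_table(t_scores, t_ranks, cand_scores, cand_ranks):
    """Zone labels for unknown objects and candidates, variable by variable."""
    n, m = len(t_scores), len(t_scores[0])
    cn = len(cand_scores)
    a_zones = [[0] * m for _ in range(n)]
    b_zones = [[0] * m for _ in range(cn)]
    for p in range(m):
        order = sorted(range(n), key=lambda i: (t_scores[i][p], i))
        xs = [t_scores[i][p] for i in order]
        rs = [t_ranks[i][p] for i in order]
        regions = [oracle_region(xs, rs, cand_scores[ej][p], cand_ranks[ej][p])
                   for ej in range(cn)]
        labels, cand_labels = oracle_zone_numbers(regions, n)
        for pos, i in enumerate(order):
            a_zones[i][p] = labels[pos]
        for ej in range(cn):
            b_zones[ej][p] = cand_labels[ej]
    return a_zones, b_zones


def oracle_select(m_values, cn: int):
    """Literal transcription of the five-tier cascade; returns (ids, steps)."""
    n_cand = len(m_values)
    n = len(m_values[0])

    # per-candidate nearest sets (ties included at the cn-th smallest value)
    sets = []
    for ej in range(n_cand):
        row = sorted(m_values[ej])
        cut = row[min(cn, n) - 1]
        sets.append({i for i in range(n) if m_values[ej][i] <= cut})
    count = {i: sum(i in s for s in sets) for i in range(n)}
    big = float("inf")
    avg = {}
    for i in range(n):
        vals = [m_values[ej][i] for ej in range(n_cand) if i in sets[ej]]
        avg[i] = sum(vals) / len(vals) if vals else big
    universe = [i for i in range(n) if count[i] >= 1]

    def top(keys, k, smallest):
        if not universe or k <= 0:
            return set()
        ordered = sorted((keys[i] for i in universe), reverse=not smallest)
        cut = ordered[min(k, len(universe)) - 1]
        if smallest:
            return {i for i in universe if keys[i] <= cut}
        return {i for i in universe if keys[i] >= cut}

    third = math.ceil(len(universe) / 3)
    quarter = math.ceil(len(universe) / 4)
    f1 = top(avg, third, True)
    f2 = top(count, third, False)
    f3 = top(avg, quarter, True)
    f4 = top(count, quarter, False)

    min_m = {i: min(m_values[ej][i] for ej in range(n_cand)) for i in range(n)}
    chosen, steps = [], []

    def admit(pred, step):
        for i in range(n):
            if i not in chosen and pred(i):
                chosen.append(i)
                steps.append(step)

    admit(lambda i: min_m[i] == 0, "2.1")
    if len(chosen) < cn:
        admit(lambda i: min_m[i] == 1, "2.2")
        if len(chosen) < cn:
            admit(lambda i: min_m[i] == 2 and i in f1 and i in f2, "2.3")
            if len(chosen) < cn:
                admit(lambda i: min_m[i] == 2 and (i in f1 or i in f2), "2.4")
                if len(chosen) < cn:
                    admit(lambda i: i in f3 and i in f4, "2.5")
    return chosen, steps
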