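"""Independent brute-force oracles used to check the library's statistics.

Everything here is deliberately naive (full enumeration, literal counting)
and shares no code with the implementation it checks.
"""

from itertools import combinations


def prevalence_by_counting(rows: list[str]) -> list[dict[str, float]]:
    """Per-column symbol frequency by literal counting; 'X' cells dropped."""
    width = len(rows[0])
    table = []
    for c in range(width):
        symbols = [r[c] for r in rows if r[c] != "X"]
        table.append({s: symbols.count(s) / len(symbols) for s in set(symbols)})
    return table


def mean_score_by_hand(query: str, table: list[dict[str, float]]) -> float:
    """Mean prevalence of the query's residues, skipping 'X' columns."""
    vals = [table[c].get(query[c], 0.0)
            for c in range(len(query)) if query[c] != "X" and table[c]]
    return sum(vals) / len(vals)


def unique_positions_by_scan(consensus: dict[str, str],
                             amino_acids: str = "ACDEFGHIKLMNPQRSTVWY",
                             ) -> dict[str, list[tuple[int, str]]]:
    """Exhaustive column scan for group-unique consensus residues."""
    out: dict[str, list[tuple[int, str]]] = {g: [] for g in consensus}
    width = len(next(iter(consensus.values())))
    for g, seq in consensus.items():
        for c in range(width):
            res = seq[c]
            if res not in amino_acids:
                continue
            if all(other[c] != res for og, other in consensus.items() if og != g):
                out[g].append((c + 1, res))
    return out


def grid_search_cutoff(labeled: list[tuple[float, bool]],
                       granularity: float = 0.01) -> float:
    """Exhaustive grid search: smallest cutoff with zero false member calls
    and, under that constraint, the fewest false non-member calls."""
    members = [r for r, m in labeled if m]
    nonmembers = [r for r, m in labeled if not m]
    top = max(members + nonmembers)
    best = None
    k = 1
    while k * granularity <= top + 2 * granularity:
        cut = round(k * granularity, 10)
        false_members = sum(1 for r in nonmembers if r >= cut)
        false_nonmembers = sum(1 for r in members if r < cut)
        if false_members == 0:
            if best is None or false_nonmembers < best[1]:
                best = (cut, false_nonmembers)
        k += 1
    assert best is not None
    return best[0]


def exact_mw_p_two_sided(a: list[float], b: list[float]) -> float:
    """Two-sided Mann-Whitney p by enumerating every group assignment.

    Tie-free inputs only.  The p-value is the fraction of assignments whose
    min(U_a, U_b) is at least as extreme as observed.
    """
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n_a = len(a)

    def u_min(xs, ys):
        u = sum(1 for x in xs for y in ys if x > y)
        return min(u, len(xs) * len(ys) - u)

    observed = u_min(a, b)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_min(xs, ys) <= observed:
            count += 1
    return count / total
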