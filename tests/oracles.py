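"""Independent brute-force oracles used by the test suite.

These are deliberately written against the *definitions* (exhaustive
move enumeration, exact rational arithmetic, pair enumeration), not
against the package implementations they check.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction


# ---------------------------------------------------------------------------
# DCJ-indel distance by breadth-first search over genome states
# ---------------------------------------------------------------------------


def _rn(t: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(-x for x in reversed(t))


def _canon_linear(t: tuple[int, ...]) -> tuple[int, ...]:
    return min(t, _rn(t))


def _canon_circular(t: tuple[int, ...]) -> tuple[int, ...]:
    cands = []
    for s in (t, _rn(t)):
        for k in range(len(s)):
            cands.append(s[k:] + s[:k])
    return min(cands)


def _canon_state(chroms) -> tuple:
    out = []
    for kind, t in chroms:
        if not t:
            continue
        out.append((kind, _canon_linear(t) if kind == "L" else _canon_circular(t)))
    return tuple(sorted(out))


def _dcj_results(chroms):
    """All genomes reachable by one DCJ operation."""
    res = []
    n = len(chroms)
    for ci in range(n):
        kind, c = chroms[ci]
        rest = chroms[:ci] + chroms[ci + 1 :]
        L = len(c)
        if kind == "L":
            for i in range(L + 1):
                for j in range(i + 1, L + 1):
                    seg = c[i:j]
                    res.append(rest + [("L", c[:i] + _rn(seg) + c[j:])])  # reversal
                    res.append(rest + [("L", c[:i] + c[j:]), ("C", seg)])  # excision
            for i in range(1, L):
                res.append(rest + [("L", c[:i]), ("L", c[i:])])  # fission
            res.append(rest + [("C", c)])  # circularization
        else:
            for k in range(L):
                res.append(rest + [("L", c[k:] + c[:k])])  # linearization
            for i in range(L):
                for j in range(i + 1, L):
                    seg = c[i:j]
                    res.append(rest + [("C", c[:i] + _rn(seg) + c[j:])])
                    res.append(rest + [("C", seg), ("C", c[j:] + c[:i])])
    for ci in range(n):
        for cj in range(ci + 1, n):
            (k1, c1), (k2, c2) = chroms[ci], chroms[cj]
            rest = [chroms[x] for x in range(n) if x not in (ci, cj)]
            if k1 == "L" and k2 == "L":
                for i in range(len(c1) + 1):
                    for j in range(len(c2) + 1):
                        res.append(rest + [("L", c1[:i] + c2[j:]), ("L", c2[:j] + c1[i:])])
                        res.append(
                            rest + [("L", c1[:i] + _rn(c2[:j])), ("L", _rn(c1[i:]) + c2[j:])]
                        )
            elif k1 == "L" and k2 == "C" or k1 == "C" and k2 == "L":
                lin = c1 if k1 == "L" else c2
                cir = c2 if k2 == "C" else c1
                for i in range(len(lin) + 1):
                    for k in range(len(cir)):
                        rot = cir[k:] + cir[:k]
                        res.append(rest + [("L", lin[:i] + rot + lin[i:])])
                        res.append(rest + [("L", lin[:i] + _rn(rot) + lin[i:])])
            else:
                for k in range(len(c1)):
                    for m in range(len(c2)):
                        r1 = c1[k:] + c1[:k]
                        r2 = c2[m:] + c2[:m]
                        res.append(rest + [("C", r1 + r2)])
                        res.append(rest + [("C", r1 + _rn(r2))])
    return res


def dcj_indel_bfs(a: tuple[int, ...], b: tuple[int, ...], max_depth: int = 12) -> int:
    """Exact DCJ-indel distance between linear signed sequences by BFS.

    Markers are signed integers; magnitudes unique within each sequence.
    One move is a DCJ (cut two adjacencies, rejoin; circular
    intermediates allowed), a deletion of any contiguous block (or whole
    circular chromosome), or an insertion of one block containing any
    arrangement of target markers not currently present.
    """
    set_b = {abs(x) for x in b}

    def insert_blocks(missing: frozenset[int]) -> list[tuple[int, ...]]:
        """Any non-empty arrangement (order and signs) of any subset of the
        missing target-unique markers can be inserted as one block; later
        DCJ operations may split it."""
        blocks = []
        items = sorted(missing)
        for k in range(1, len(items) + 1):
            for sub in itertools.permutations(items, k):
                for signs in itertools.product((1, -1), repeat=k):
                    blocks.append(tuple(s * m for s, m in zip(signs, sub)))
        return blocks
    target = _canon_state([("L", b)])
    start = _canon_state([("L", a)])
    if start == target:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        state, d = frontier.popleft()
        chroms = list(state)
        nexts = _dcj_results(chroms)
        # deletions: any contiguous block (the scenario-minimum model allows
        # deleting shared content and reinserting it later)
        for ci, (kind, t) in enumerate(chroms):
            rest = chroms[:ci] + chroms[ci + 1 :]
            L = len(t)
            if kind == "C":
                nexts.append(rest)  # whole circle
                for i in range(L):
                    for ln in range(1, L):
                        keep = tuple((t + t)[i + ln : i + L])
                        nexts.append(rest + [("C", keep)])
            else:
                for i in range(L):
                    for j in range(i + 1, L + 1):
                        nexts.append(rest + [("L", t[:i] + t[j:])])
        # insertions: any arrangement of target markers not currently present
        present = {abs(x) for _, t in chroms for x in t}
        missing = frozenset(set_b - present)
        for blk in insert_blocks(missing):
            nexts.append(chroms + [("L", blk)])
            nexts.append(chroms + [("C", blk)])
            for ci, (kind, t) in enumerate(chroms):
                rest = chroms[:ci] + chroms[ci + 1 :]
                if kind == "L":
                    for i in range(len(t) + 1):
                        nexts.append(rest + [("L", t[:i] + blk + t[i:])])
                        nexts.append(rest + [("L", t[:i] + _rn(blk) + t[i:])])
                else:
                    for k in range(len(t)):
                        rot = t[k:] + t[:k]
                        nexts.append(rest + [("C", rot + blk)])
                        nexts.append(rest + [("C", rot + _rn(blk))])
        for nx in nexts:
            cs = _canon_state(nx)
            if cs == target:
                return d + 1
            if cs not in seen:
                seen.add(cs)
                frontier.append((cs, d + 1))
        if d + 1 > max_depth:
            raise RuntimeError("BFS depth limit exceeded")
    raise RuntimeError("BFS exhausted without reaching target")


# ---------------------------------------------------------------------------
# Tajima's D by exact rational arithmetic
# ---------------------------------------------------------------------------


def tajimas_d_exact(haplotypes) -> float | None:
    """Tajima's D from a 0/1 haplotype matrix via exact rationals.

    Follows the 1989 formulation symbol by symbol: a1, a2, b1, b2,
    c1, c2, e1, e2; returns None when undefined (S = 0 or n < 4).
    """
    rows = [tuple(r) for r in haplotypes]
    n = len(rows)
    if n < 4:
        return None
    S_cols = [j for j in range(len(rows[0])) if 0 < sum(r[j] for r in rows) < n]
    S = len(S_cols)
    if S == 0:
        return None
    pi = Fraction(0)
    npairs = Fraction(n * (n - 1), 2)
    for i, j in itertools.combinations(range(n), 2):
        diff = sum(1 for k in S_cols if rows[i][k] != rows[j][k])
        pi += Fraction(diff)
    pi /= npairs
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    num = pi - Fraction(S) / a1
    import math

    return float(num) / math.sqrt(float(var))


# ---------------------------------------------------------------------------
# nSL by exhaustive pair enumeration
# ---------------------------------------------------------------------------


def nsl_raw_bruteforce(haplotypes) -> list[float | None]:
    """Unstandardized nSL per site by direct enumeration of haplotype pairs.

    For each pair agreeing at the focal site, L = number of consecutive
    sites (including the focal one) over which the pair is identical,
    extended both ways until the first mismatch or the edge.  Returns
    ln(SL_ancestral / SL_derived) per site, None where a pool has < 2.
    """
    import math

    H = [tuple(r) for r in haplotypes]
    n = len(H)
    S = len(H[0]) if H else 0
    out: list[float | None] = []
    for s in range(S):
        pools = {0: [i for i in range(n) if H[i][s] == 0], 1: [i for i in range(n) if H[i][s] == 1]}
        sl = {}
        for allele, pool in pools.items():
            if len(pool) < 2:
                sl[allele] = None
                continue
            tot = 0
            cnt = 0
            for i, j in itertools.combinations(pool, 2):
                left = s
                while left - 1 >= 0 and H[i][left - 1] == H[j][left - 1]:
                    left -= 1
                right = s
                while right + 1 < S and H[i][right + 1] == H[j][right + 1]:
                    right += 1
                tot += right - left + 1
                cnt += 1
            sl[allele] = tot / cnt
        if sl[0] is None or sl[1] is None:
            out.append(None)
        else:
            out.append(math.log(sl[0] / sl[1]))
    return out
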