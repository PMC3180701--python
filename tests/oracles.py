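"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's enumeration code paths: elementary
modes are found by testing every reaction subset for a one-dimensional,
full-support, sign-feasible nullspace; minimal hitting sets by exhaustive
subset search.  Exponential, therefore only for tiny instances.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import gcd

from flavnet.network import MetabolicNetwork


def rational_nullspace(rows: list[list[Fraction]], n_cols: int) -> list[list[Fraction]]:
    """Basis of the nullspace of a small rational matrix (Gauss-Jordan)."""
    A = [list(r) for r in rows]
    m = len(A)
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        pivot = next((i for i in range(r, m) if A[i][c] != 0), None)
        if pivot is None:
            continue
        A[r], A[pivot] = A[pivot], A[r]
        inv = A[r][c]
        A[r] = [x / inv for x in A[r]]
        for i in range(m):
            if i != r and A[i][c] != 0:
                f = A[i][c]
                A[i] = [x - f * y for x, y in zip(A[i], A[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    free = [c for c in range(n_cols) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * n_cols
        v[fc] = Fraction(1)
        for i, pc in enumerate(pivots):
            v[pc] = -A[i][fc]
        basis.append(v)
    return basis


def _canonical(v: dict[str, Fraction], order: list[str], reversible: set[str]):
    denom = 1
    for x in v.values():
        denom = denom * x.denominator // gcd(denom, x.denominator)
    num = 0
    for x in v.values():
        num = gcd(num, abs(int(x * denom)))
    scale = Fraction(denom, num)
    v = {rid: c * scale for rid, c in v.items()}
    if all(rid in reversible for rid in v):
        first = next(rid for rid in order if rid in v)
        if v[first] < 0:
            v = {rid: -c for rid, c in v.items()}
    return tuple(sorted(v.items()))


def brute_force_ems(network: MetabolicNetwork) -> set[tuple]:
    """All elementary modes by exhaustive support search (canonical form).

    A reaction subset carries an elementary mode iff the balance matrix
    restricted to it has a one-dimensional nullspace whose generator has
    full support and satisfies the irreversibility signs (possibly after a
    global sign flip).
    """
    _, S = network.stoichiometric_matrix()
    n = len(network.reactions)
    order = [r.id for r in network.reactions]
    reversible = {r.id for r in network.reactions if r.reversible}
    irrev_idx = [i for i, r in enumerate(network.reactions) if not r.reversible]
    # bitmask per metabolite of the reactions touching it, for quick pruning
    met_masks = []
    for row in S:
        mask = 0
        for i, x in enumerate(row):
            if x != 0:
                mask |= 1 << i
        met_masks.append(mask)

    found: set[tuple] = set()
    for mask in range(1, 1 << n):
        # a metabolite touched by exactly one selected reaction cannot balance
        if any((mm & mask).bit_count() == 1 for mm in met_masks):
            continue
        cols = [i for i in range(n) if mask >> i & 1]
        sub = [[row[i] for i in cols] for row in S if any(row[i] != 0 for i in cols)]
        basis = rational_nullspace(sub, len(cols))
        if len(basis) != 1:
            continue
        g = basis[0]
        if any(x == 0 for x in g):
            continue
        sel_irrev = [j for j, i in enumerate(cols) if i in set(irrev_idx)]
        if all(g[j] > 0 for j in sel_irrev):
            v = g
        elif all(g[j] < 0 for j in sel_irrev):
            v = [-x for x in g]
        else:
            continue
        found.add(
            _canonical(
                {order[i]: v[j] for j, i in enumerate(cols)}, order, reversible
            )
        )
    return found


def brute_force_minimal_hitting_sets(
    sets: list[frozenset[str]], candidates: frozenset[str]
) -> list[frozenset[str]]:
    """All minimal hitting sets by exhaustive subset search."""
    hitting = []
    items = sorted(candidates)
    for k in range(0, len(items) + 1):
        for combo in combinations(items, k):
            h = frozenset(combo)
            if all(h & s for s in sets):
                if not any(prev <= h for prev in hitting):
                    hitting.append(h)
    return sorted(hitting, key=lambda h: (len(h), tuple(sorted(h))))
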