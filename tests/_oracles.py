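"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's dynamic programs: folding
and duplex energies are found by exhaustive enumeration of structures /
alignments evaluated with a standalone loop-decomposition function, exact
tests by direct probability summation in rational arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction

from srnapipe._energy import (
    MIN_HAIRPIN,
    MULTI_BRANCH,
    MULTI_CLOSE,
    MULTI_UNPAIRED,
    PAIRS,
    STACK,
    bulge_energy,
    hairpin_energy,
    internal_energy,
)

# ---------------------------------------------------------------------------
# secondary-structure enumeration


def enumerate_structures(seq: str):
    """Yield every pseudoknot-free pair set (tuples of (i, j)) for *seq*."""
    n = len(seq)
    memo: dict[tuple[int, int], list[tuple]] = {}

    def rec(i: int, j: int) -> list[tuple]:
        if j - i + 1 < MIN_HAIRPIN + 2:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if seq[i] + seq[k] in PAIRS:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(((i, k),) + left + right)
        memo[key] = out
        return out

    yield from rec(0, n - 1)


def structure_energy(seq: str, pairs, max_loop: int) -> float | None:
    """Loop-decomposition energy of one structure; None if inadmissible."""
    if not pairs:
        return 0.0
    pairs = sorted(pairs)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    total = 0.0
    for (i, j) in pairs:
        # children: pairs directly enclosed by (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            total += hairpin_energy(j - i - 1)
        elif len(children) == 1:
            (a, b) = children[0]
            b1 = a - i - 1
            b2 = j - b - 1
            if b1 == 0 and b2 == 0:
                total += STACK[(seq[i] + seq[j], seq[a] + seq[b])]
            elif b1 == 0 or b2 == 0:
                if max(b1, b2) > max_loop:
                    return None
                total += bulge_energy(b1 + b2)
            else:
                if max(b1, b2) > max_loop:
                    return None
                total += internal_energy(b1 + b2)
        else:
            unpaired = (j - i - 1) - sum(b - a + 1 for a, b in children)
            total += (
                MULTI_CLOSE
                + MULTI_BRANCH * (len(children) + 1)
                + MULTI_UNPAIRED * unpaired
            )
    return total


def fold_bruteforce(seq: str, max_loop: int = 15) -> tuple[float, int]:
    """Minimum (energy, n_pairs) over all admissible structures of *seq*."""
    best = (0.0, 0)
    for pairs in enumerate_structures(seq):
        e = structure_energy(seq, pairs, max_loop)
        if e is None:
            continue
        cand = (e, len(pairs))
        if cand < best:
            best = cand
    return best


# ---------------------------------------------------------------------------
# duplex alignment enumeration


def duplex_bruteforce(mirna: str, target: str, max_asym: int = 15) -> float:
    """Minimum duplex energy by enumerating all monotone pair chains."""
    q = mirna.upper().replace("T", "U")
    tr = target.upper().replace("T", "U")[::-1]
    nq, nt = len(q), len(tr)
    cells = [
        (i, j) for i in range(nq) for j in range(nt) if q[i] + tr[j] in PAIRS
    ]
    best = 0.0

    def rec(i: int, j: int, energy: float) -> None:
        nonlocal best
        if energy < best:
            best = energy
        for i2 in range(i + 1, min(i + 2 + max_asym, nq)):
            g1 = i2 - i - 1
            for j2 in range(j + 1, min(j + 2 + max_asym, nt)):
                if q[i2] + tr[j2] not in PAIRS:
                    continue
                g2 = j2 - j - 1
                if g1 == 0 and g2 == 0:
                    step = STACK[(q[i] + tr[j], q[i2] + tr[j2])]
                elif g1 == 0 or g2 == 0:
                    step = bulge_energy(g1 + g2)
                else:
                    step = internal_energy(g1 + g2)
                rec(i2, j2, energy + step)

    for (i, j) in cells:
        rec(i, j, 0.0)
    return best


# ---------------------------------------------------------------------------
# exact two-library test by rational summation


def two_library_bruteforce(x: int, n1: int, y: int, n2: int) -> float:
    """Minimum-likelihood two-sided binomial p-value in exact arithmetic."""
    n = x + y
    q = Fraction(n2, n1 + n2)
    pmf = [
        Fraction(math.comb(n, k)) * q**k * (1 - q) ** (n - k)
        for k in range(n + 1)
    ]
    p_obs = pmf[y]
    return float(sum(p for p in pmf if p <= p_obs))


# ---------------------------------------------------------------------------
# exact hypergeometric enumeration


def hypergeom_upper_bruteforce(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for kk in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, kk) * math.comb(N - K, n - kk), denom)
    return float(total)
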