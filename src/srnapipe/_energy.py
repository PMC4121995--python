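"""Bundled nearest-neighbor energy parameters.

A single simplified Turner-style parameter set shared by the intramolecular
hairpin folder (:mod:`srnapipe.novel`) and the intermolecular duplex scanner
(:mod:`srnapipe.targets`).  The table is data, not physics: any internally
consistent stabilizing stack table works for the pipeline's decision rules,
and the values below are frozen so results are reproducible.

Conventions
-----------
* Sequences are RNA (``A``, ``C``, ``G``, ``U``); callers normalize T->U.
* A base pair is written as a two-letter string, 5' base first (``"GC"``).
* ``STACK[(p1, p2)]`` is the free energy (kcal/mol) of pair ``p2`` stacked
  on pair ``p1``; for a helix read 5'->3' on the top strand, ``p1`` closes
  the loop outward and ``p2`` is the next pair inward.
* Wobble (G:U) stacks are deliberately uniform and weak (-0.5) so that
  replacing any Watson-Crick pair with a wobble strictly destabilizes a
  helix; all Watson-Crick stacks are <= -0.93.
* Loop penalties are linear in loop size.
"""

from __future__ import annotations

#: Admissible base pairs (Watson-Crick plus G:U wobble).
PAIRS: frozenset[str] = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

_WOBBLE_STACK = -0.5

#: Watson-Crick on Watson-Crick stacking energies, kcal/mol.
_WC_STACK: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("AU", "GC"): -2.24, ("AU", "CG"): -2.08,
    ("UA", "AU"): -1.33, ("UA", "UA"): -0.93, ("UA", "GC"): -2.35, ("UA", "CG"): -2.11,
    ("CG", "AU"): -2.11, ("CG", "UA"): -2.08, ("CG", "GC"): -3.26, ("CG", "CG"): -2.36,
    ("GC", "AU"): -2.35, ("GC", "UA"): -2.24, ("GC", "GC"): -3.42, ("GC", "CG"): -3.26,
}

#: Full stack table over all ordered pairs of admissible pairs.
STACK: dict[tuple[str, str], float] = {}
for _p1 in PAIRS:
    for _p2 in PAIRS:
        if "U" in _p1 and "G" in _p1 and _p1 in ("GU", "UG"):
            STACK[(_p1, _p2)] = _WOBBLE_STACK
        elif _p2 in ("GU", "UG"):
            STACK[(_p1, _p2)] = _WOBBLE_STACK
        else:
            STACK[(_p1, _p2)] = _WC_STACK[(_p1, _p2)]

# Linear loop penalties (kcal/mol).
HAIRPIN_BASE = 5.4      # hairpin loop of minimal size (3 unpaired)
HAIRPIN_SLOPE = 0.1     # per extra unpaired base
BULGE_BASE = 3.8        # bulge of 1 unpaired base
BULGE_SLOPE = 0.3       # per extra unpaired base
INTERNAL_BASE = 4.0     # internal loop of 2 unpaired bases (1+1)
INTERNAL_SLOPE = 0.3    # per extra unpaired base
MULTI_CLOSE = 3.4       # multiloop closing penalty
MULTI_BRANCH = 0.4      # per helix branch (including the closing one)
MULTI_UNPAIRED = 0.1    # per unpaired base inside a multiloop

#: Minimum number of unpaired bases in a hairpin loop.
MIN_HAIRPIN = 3

#: Default cap on the unpaired stretch per side of a bulge/internal loop.
MAX_LOOP = 15


def can_pair(a: str, b: str) -> bool:
    """True if bases *a* and *b* (RNA alphabet) can form an admissible pair."""
    return a + b in PAIRS


def hairpin_energy(size: int) -> float:
    """Penalty of a hairpin loop with *size* unpaired bases (size >= 3)."""
    return HAIRPIN_BASE + HAIRPIN_SLOPE * (size - MIN_HAIRPIN)


def bulge_energy(size: int) -> float:
    """Penalty of a bulge loop with *size* unpaired bases (size >= 1)."""
    return BULGE_BASE + BULGE_SLOPE * (size - 1)


def internal_energy(size: int) -> float:
    """Penalty of an internal loop with *size* total unpaired bases (>= 2)."""
    return INTERNAL_BASE + INTERNAL_SLOPE * (size - 2)


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")
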