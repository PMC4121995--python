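"""Novel miRNA candidate prediction.

Unannotated, genome-mapped tags are extended into candidate precursor
windows, folded with a nearest-neighbor minimum-free-energy dynamic
program, and filtered on three criteria: hairpin stability (MFE strictly
below a threshold, default -20 kcal/mol), placement of the mature tag on
one arm of the hairpin stem, and detectable expression (>= 1 TPM) in both
libraries.

The folding model is deliberately small and fully specified (see
:mod:`srnapipe._energy`): Watson-Crick + G:U pairs, stacking energies,
linear hairpin/bulge/internal-loop penalties, a linear multiloop model, a
minimum hairpin loop of 3, and a cap on the unpaired stretch per side of a
bulge/internal loop.  The dynamic program is exact for this model: for
short sequences it returns the same minimum as exhaustive enumeration of
every pseudoknot-free structure.  Ties are broken toward fewer pairs, then
by a fixed traceback preference, so output is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from ._energy import (
    MAX_LOOP,
    MIN_HAIRPIN,
    MULTI_BRANCH,
    MULTI_CLOSE,
    MULTI_UNPAIRED,
    PAIRS,
    STACK,
    bulge_energy,
    hairpin_energy,
    internal_energy,
    to_rna,
)
from .preprocess import revcomp

__all__ = [
    "FoldResult",
    "PrecursorWindow",
    "HairpinCandidate",
    "fold_mfe",
    "excise_windows",
    "call_novel",
]

_INF = (math.inf, math.inf)


@dataclass(frozen=True)
class FoldResult:
    """Minimum-free-energy secondary structure of one sequence."""

    sequence: str  #: RNA sequence
    structure: str  #: dot-bracket, same length as sequence
    mfe: float  #: kcal/mol, <= 0
    n_pairs: int

    def pair_table(self) -> dict[int, int]:
        """Map each paired position to its partner (both directions)."""
        stack: list[int] = []
        table: dict[int, int] = {}
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                table[i] = j
                table[j] = i
        return table


def fold_mfe(sequence: str, max_loop: int = MAX_LOOP) -> FoldResult:
    """Fold *sequence* to its minimum-free-energy pseudoknot-free structure.

    Parameters
    ----------
    sequence:
        RNA (or DNA; T is read as U) string, 10-300 nt, alphabet ACGU/ACGT.
    max_loop:
        Maximum unpaired stretch per side of a bulge or internal loop; part
        of the energy model (structures exceeding it are inadmissible).

    Returns
    -------
    FoldResult
        With ``mfe <= 0``; an all-dot structure with ``mfe == 0.0`` when no
        stabilizing structure exists.
    """
    s = to_rna(sequence)
    n = len(s)
    if not 10 <= n <= 300:
        raise ValueError(f"sequence length {n} outside supported range 10-300")
    bad = set(s) - {"A", "C", "G", "U"}
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    inf = math.inf
    # pair[i][j]: two-letter pair string if (i, j) can pair at legal span
    pair: list[list[str | None]] = [[None] * n for _ in range(n)]
    for i in range(n):
        si = s[i]
        row = pair[i]
        for j in range(i + MIN_HAIRPIN + 1, n):
            p = si + s[j]
            if p in PAIRS:
                row[j] = p

    # V[i][j]: (energy, n_pairs) of the best structure on s[i..j] with (i,j)
    # paired.  WM[i][j]: best multiloop segment on s[i..j] with >= 1 branch,
    # charging MULTI_UNPAIRED per free base and MULTI_BRANCH per branch.
    V: list[list[tuple[float, int]]] = [[_INF] * n for _ in range(n)]
    WM: list[list[tuple[float, int]]] = [[_INF] * n for _ in range(n)]

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            pij = pair[i][j]
            if pij is not None:
                best = (hairpin_energy(j - i - 1), 1)
                kmax = min(i + 1 + max_loop, j - 2 - MIN_HAIRPIN)
                for k in range(i + 1, kmax + 1):
                    b1 = k - i - 1
                    vrow = V[k]
                    prow = pair[k]
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - max_loop)
                    for l in range(lmin, j):
                        vkl = vrow[l]
                        if vkl[0] == inf:
                            continue
                        b2 = j - 1 - l
                        if b1 == 0 and b2 == 0:
                            e = STACK[(pij, prow[l])] + vkl[0]  # type: ignore[index]
                        elif b1 == 0 or b2 == 0:
                            e = bulge_energy(b1 + b2) + vkl[0]
                        else:
                            e = internal_energy(b1 + b2) + vkl[0]
                        cand = (e, vkl[1] + 1)
                        if cand < best:
                            best = cand
                # multiloop: closing pair + >= 2 branches inside
                if span >= 2 * (MIN_HAIRPIN + 2) + 2:
                    wrow = WM[i + 1]
                    for m in range(i + 2, j - 1):
                        a = wrow[m]
                        if a[0] == inf:
                            continue
                        b = WM[m + 1][j - 1]
                        if b[0] == inf:
                            continue
                        cand = (
                            MULTI_CLOSE + MULTI_BRANCH + a[0] + b[0],
                            a[1] + b[1] + 1,
                        )
                        if cand < best:
                            best = cand
                V[i][j] = best

            # WM over the same cell
            wbest = _INF
            prev = WM[i][j - 1] if j - 1 >= i else _INF
            if prev[0] < inf:
                wbest = (prev[0] + MULTI_UNPAIRED, prev[1])
            for k in range(i, j - MIN_HAIRPIN):
                v = V[k][j]
                if v[0] == inf:
                    continue
                cand = (MULTI_UNPAIRED * (k - i) + v[0] + MULTI_BRANCH, v[1])
                if cand < wbest:
                    wbest = cand
                if k > i:
                    w2 = WM[i][k - 1]
                    if w2[0] < inf:
                        cand = (w2[0] + v[0] + MULTI_BRANCH, w2[1] + v[1])
                        if cand < wbest:
                            wbest = cand
            WM[i][j] = wbest

    # exterior loop: W[j] = best over prefix s[0..j-1]; unpaired is free
    W: list[tuple[float, int]] = [(0.0, 0)] * (n + 1)
    for j in range(n):
        best = W[j]
        for i in range(0, j - MIN_HAIRPIN):
            v = V[i][j]
            if v[0] == inf:
                continue
            w = W[i]
            cand = (w[0] + v[0], w[1] + v[1])
            if cand < best:
                best = cand
        W[j + 1] = best

    struct = ["."] * n

    def tb_v(i: int, j: int) -> None:
        struct[i] = "("
        struct[j] = ")"
        target = V[i][j]
        pij = pair[i][j]
        if target == (hairpin_energy(j - i - 1), 1):
            return
        kmax = min(i + 1 + max_loop, j - 2 - MIN_HAIRPIN)
        for k in range(i + 1, kmax + 1):
            b1 = k - i - 1
            lmin = max(k + MIN_HAIRPIN + 1, j - 1 - max_loop)
            for l in range(lmin, j):
                vkl = V[k][l]
                if vkl[0] == inf:
                    continue
                b2 = j - 1 - l
                if b1 == 0 and b2 == 0:
                    e = STACK[(pij, pair[k][l])] + vkl[0]  # type: ignore[index]
                elif b1 == 0 or b2 == 0:
                    e = bulge_energy(b1 + b2) + vkl[0]
                else:
                    e = internal_energy(b1 + b2) + vkl[0]
                if (e, vkl[1] + 1) == target:
                    tb_v(k, l)
                    return
        for m in range(i + 2, j - 1):
            a = WM[i + 1][m]
            b = WM[m + 1][j - 1]
            if a[0] == inf or b[0] == inf:
                continue
            if (MULTI_CLOSE + MULTI_BRANCH + a[0] + b[0], a[1] + b[1] + 1) == target:
                tb_wm(i + 1, m)
                tb_wm(m + 1, j - 1)
                return
        raise AssertionError("traceback failed in V")  # pragma: no cover

    def tb_wm(i: int, j: int) -> None:
        while True:
            target = WM[i][j]
            if j - 1 >= i:
                prev = WM[i][j - 1]
                if prev[0] < inf and (prev[0] + MULTI_UNPAIRED, prev[1]) == target:
                    j -= 1
                    continue
            for k in range(i, j - MIN_HAIRPIN):
                v = V[k][j]
                if v[0] == inf:
                    continue
                if (MULTI_UNPAIRED * (k - i) + v[0] + MULTI_BRANCH, v[1]) == target:
                    tb_v(k, j)
                    return
                if k > i:
                    w2 = WM[i][k - 1]
                    if w2[0] < inf and (
                        w2[0] + v[0] + MULTI_BRANCH,
                        w2[1] + v[1],
                    ) == target:
                        tb_v(k, j)
                        j = k - 1
                        break
            else:  # pragma: no cover
                raise AssertionError("traceback failed in WM")

    j = n
    while j > 0:
        if W[j] == W[j - 1]:
            j -= 1
            continue
        for i in range(0, j - 1 - MIN_HAIRPIN):
            v = V[i][j - 1]
            if v[0] == inf:
                continue
            if (W[i][0] + v[0], W[i][1] + v[1]) == W[j]:
                tb_v(i, j - 1)
                j = i
                break
        else:  # pragma: no cover
            raise AssertionError("traceback failed in exterior loop")

    mfe, n_pairs = W[n]
    return FoldResult(sequence=s, structure="".join(struct), mfe=mfe, n_pairs=n_pairs)


@dataclass(frozen=True)
class PrecursorWindow:
    """A genomic window around an unannotated tag, oriented to sense."""

    tag: str  #: tag sequence (DNA), as collapsed
    chrom: str
    start: int  #: 0-based, on the reference
    end: int
    strand: str
    sequence: str  #: window sequence (DNA), reverse-complemented for '-'
    tag_offset: int  #: tag start within ``sequence``


@dataclass
class HairpinCandidate:
    """A candidate novel miRNA precursor with its filter flags."""

    window: PrecursorWindow
    fold: FoldResult | None
    arm: str | None  #: '5p' or '3p' when arm placement passes
    tpm_control: float
    tpm_knockdown: float
    mfe_pass: bool | None
    arm_pass: bool | None
    expression_pass: bool

    @property
    def passed(self) -> bool:
        return bool(self.mfe_pass and self.arm_pass and self.expression_pass)


def excise_windows(
    tag_hits: Mapping[str, Sequence],
    genome: Mapping[str, str],
    flank: int = 70,
) -> list[PrecursorWindow]:
    """Cut a precursor-sized window (tag +/- *flank*) around every genome hit.

    Windows on the minus strand are reverse-complemented so the tag always
    reads sense within the returned sequence; clipping at chromosome ends is
    silent.
    """
    windows: list[PrecursorWindow] = []
    for tag in sorted(tag_hits):
        for hit in tag_hits[tag]:
            chrom_seq = genome[hit.chrom]
            start = max(0, hit.start - flank)
            end = min(len(chrom_seq), hit.end + flank)
            seq = chrom_seq[start:end]
            if hit.strand == "-":
                seq = revcomp(seq)
                offset = end - hit.end
            else:
                offset = hit.start - start
            windows.append(
                PrecursorWindow(
                    tag=tag,
                    chrom=hit.chrom,
                    start=start,
                    end=end,
                    strand=hit.strand,
                    sequence=seq,
                    tag_offset=offset,
                )
            )
    return windows


def _arm_placement(fold: FoldResult, offset: int, length: int) -> str | None:
    """Return '5p'/'3p' if the tag sits on one arm of a hairpin stem.

    Requirements: no tag base inside a terminal (hairpin) loop; all paired
    tag bases on the same side of a stem (all '(' or all ')'); and >= 75%
    of tag bases either paired or flanked by paired tag bases (interior
    bulges count as facing the other arm).
    """
    struct = fold.structure
    tag_struct = struct[offset : offset + length]
    n_open = tag_struct.count("(")
    n_close = tag_struct.count(")")
    if n_open and n_close:
        return None
    if n_open + n_close == 0:
        return None

    # hairpin loops: maximal dot runs whose nearest enclosing brackets are
    # '(' on the left and ')' on the right (a terminal loop)
    table = fold.pair_table()
    in_loop = [False] * len(struct)
    i = 0
    while i < len(struct):
        if struct[i] == ".":
            j = i
            while j < len(struct) and struct[j] == ".":
                j += 1
            left = i - 1
            right = j
            if (
                left >= 0
                and right < len(struct)
                and struct[left] == "("
                and struct[right] == ")"
                and table.get(left) == right
            ):
                for k in range(i, j):
                    in_loop[k] = True
            i = j
        else:
            i += 1
    if any(in_loop[offset : offset + length]):
        return None

    paired_pos = [k for k in range(offset, offset + length) if struct[k] in "()"]
    lo, hi = paired_pos[0], paired_pos[-1]
    n_ok = sum(
        1
        for k in range(offset, offset + length)
        if struct[k] in "()" or lo < k < hi
    )
    if n_ok / length < 0.75:
        return None
    return "5p" if n_open else "3p"


def call_novel(
    windows: Iterable[PrecursorWindow],
    tpm_control: Mapping[str, float],
    tpm_knockdown: Mapping[str, float],
    mfe_max: float = -20.0,
    tpm_min: float = 1.0,
    fold_fn: Callable[[str], FoldResult] = fold_mfe,
) -> tuple[list[HairpinCandidate], list[HairpinCandidate]]:
    """Filter precursor windows into novel miRNA candidates.

    Expression is checked first (folding is skipped for tags below the TPM
    floor, and the rejection records the failing flag only).  Passing
    candidates at overlapping loci on the same strand are collapsed to the
    lowest-MFE window.

    Returns ``(passing, rejected)``.
    """
    passing: list[HairpinCandidate] = []
    rejected: list[HairpinCandidate] = []
    for w in windows:
        tc = tpm_control.get(w.tag, 0.0)
        tk = tpm_knockdown.get(w.tag, 0.0)
        expr_ok = min(tc, tk) >= tpm_min
        if not expr_ok:
            rejected.append(
                HairpinCandidate(w, None, None, tc, tk, None, None, False)
            )
            continue
        fold = fold_fn(w.sequence)
        mfe_ok = fold.mfe < mfe_max
        arm = _arm_placement(fold, w.tag_offset, len(w.tag))
        cand = HairpinCandidate(
            w, fold, arm, tc, tk, mfe_ok, arm is not None, True
        )
        (passing if cand.passed else rejected).append(cand)

    # collapse overlapping passing loci to the lowest-MFE window
    passing.sort(key=lambda c: (c.window.chrom, c.window.strand, c.window.start))
    collapsed: list[HairpinCandidate] = []
    for cand in passing:
        if collapsed:
            last = collapsed[-1]
            if (
                last.window.chrom == cand.window.chrom
                and last.window.strand == cand.window.strand
                and cand.window.start < last.window.end
            ):
                assert cand.fold is not None and last.fold is not None
                if cand.fold.mfe < last.fold.mfe:
                    collapsed[-1] = cand
                continue
        collapsed.append(cand)
    return collapsed, rejected
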