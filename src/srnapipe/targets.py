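"""miRNA target prediction by duplex hybridization energy.

Intermolecular-only model: the miRNA and a target window hybridize through
stacked base pairs (Watson-Crick + G:U) interrupted by bounded bulges and
internal loops; neither strand folds on itself.  The dynamic program
returns the global minimum energy over all alignments and target start
positions.  Significance comes from an extreme-value model of
length-normalized energies whose location/scale grow logarithmically with
target length (slopes default to 1.9 and 0.28).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from ._energy import PAIRS, STACK, bulge_energy, internal_energy, to_rna

__all__ = [
    "DuplexAlignment",
    "DuplexHit",
    "EvdParams",
    "duplex_mfe",
    "evd_pvalue",
    "scan_targets",
    "aggregate_targets",
]

#: Maximum unpaired stretch per side between consecutive duplex pairs.
MAX_ASYM = 15


@dataclass(frozen=True)
class DuplexAlignment:
    """Base pairs of one duplex: (miRNA index, target index) tuples."""

    pairs: tuple[tuple[int, int], ...]

    @property
    def target_start(self) -> int:
        return min(j for _, j in self.pairs)

    @property
    def target_end(self) -> int:
        return max(j for _, j in self.pairs) + 1


@dataclass(frozen=True)
class DuplexHit:
    mirna_id: str
    gene_id: str
    position: int  #: 0-based start of the duplex on the target
    duplex_mfe: float
    pvalue: float


@dataclass(frozen=True)
class EvdParams:
    location_slope: float = 1.9
    scale_slope: float = 0.28

    def __post_init__(self) -> None:
        if self.scale_slope <= 0:
            raise ValueError("scale_slope must be positive")


def duplex_mfe(
    mirna: str,
    target_window: str,
    max_asym: int = MAX_ASYM,
    check_lengths: bool = True,
) -> tuple[float, DuplexAlignment | None]:
    """Minimum hybridization energy of *mirna* against *target_window*.

    Both sequences are given 5'->3'; pairing is antiparallel (the miRNA 5'
    end pairs toward the target 3' end).  Returns ``(energy, alignment)``;
    when no base pair is possible the convention is a no-hit:
    ``(0.0, None)``.  *check_lengths* enforces the miRNA-sized query
    contract; disable it to run the DP on shorter sequences.
    """
    q = to_rna(mirna)
    t = to_rna(target_window)
    if check_lengths and not 15 <= len(q) <= 30:
        raise ValueError(f"miRNA length {len(q)} outside supported 15-30")
    if check_lengths and len(t) < len(q):
        raise ValueError("target window shorter than the miRNA")

    # reverse the target so pair indices increase on both strands
    tr = t[::-1]
    nq, nt = len(q), len(tr)
    pairable = [
        [q[i] + tr[j] in PAIRS for j in range(nt)] for i in range(nq)
    ]

    # D[i][j]: best (energy, -n_pairs) of a duplex whose last pair is (i, j)
    D: list[list[tuple[float, int] | None]] = [[None] * nt for _ in range(nq)]
    back: list[list[tuple[int, int] | None]] = [[None] * nt for _ in range(nq)]
    # selection key: energy, then leftmost on the original target, then
    # most-paired (original start of a duplex ending at reversed j is
    # nt - 1 - j)
    best_key: tuple[float, int, int, int] | None = None
    best_cell: tuple[int, int] | None = None
    for i in range(nq):
        for j in range(nt):
            if not pairable[i][j]:
                continue
            cur = (0.0, -1)  # open a new duplex at (i, j)
            origin = None
            p2 = q[i] + tr[j]
            for ip in range(max(0, i - 1 - max_asym), i):
                g1 = i - ip - 1
                for jp in range(max(0, j - 1 - max_asym), j):
                    prev = D[ip][jp]
                    if prev is None:
                        continue
                    g2 = j - jp - 1
                    if g1 == 0 and g2 == 0:
                        step = STACK[(q[ip] + tr[jp], p2)]
                    elif g1 == 0 or g2 == 0:
                        step = bulge_energy(g1 + g2)
                    else:
                        step = internal_energy(g1 + g2)
                    cand = (prev[0] + step, prev[1] - 1)
                    if cand < cur:
                        cur = cand
                        origin = (ip, jp)
            D[i][j] = cur
            back[i][j] = origin
            key = (cur[0], nt - 1 - j, cur[1], i)
            if best_key is None or key < best_key:
                best_key = key
                best_cell = (i, j)

    if best_cell is None:
        return 0.0, None
    bi, bj = best_cell
    energy = D[bi][bj][0]  # type: ignore[index]
    pairs_rev: list[tuple[int, int]] = []
    cell: tuple[int, int] | None = (bi, bj)
    while cell is not None:
        pairs_rev.append(cell)
        cell = back[cell[0]][cell[1]]
    # translate reversed-target indices back to the original orientation
    pairs = tuple(
        sorted((i, nt - 1 - j) for i, j in pairs_rev)
    )
    return energy, DuplexAlignment(pairs=pairs)


def evd_pvalue(
    energy: float,
    mirna_len: int,
    target_len: int,
    params: EvdParams = EvdParams(),
) -> float:
    """Extreme-value p-value for a best-of-many duplex energy.

    The score ``s = -energy`` is referred to a Gumbel distribution whose
    location and scale grow with the search space:
    ``location_slope * log(mirna_len * target_len)`` and
    ``scale_slope * log(mirna_len * target_len)``; the p-value is the
    upper tail ``1 - exp(-exp(-(s - location) / scale))``.
    """
    if mirna_len <= 0 or target_len <= 1:
        raise ValueError("lengths must be positive (target length > 1)")
    if energy > 0:
        raise ValueError("duplex energy must be <= 0")
    s = -energy
    log_mn = math.log(mirna_len * target_len)
    location = params.location_slope * log_mn
    scale = params.scale_slope * log_mn
    z = (s - location) / scale
    try:
        p = -math.expm1(-math.exp(-z))
    except OverflowError:
        p = 1.0
    return min(max(p, 5e-324), 1.0 - 1e-16)


def scan_targets(
    matures: Mapping[str, str],
    utrs: Mapping[str, str],
    params: EvdParams = EvdParams(),
    max_p: float = 0.05,
    max_energy: float | None = None,
) -> list[DuplexHit]:
    """Scan every miRNA against every target sequence.

    Keeps the single best-energy site per (miRNA, gene); a hit is retained
    when its EVD p-value is below *max_p* (or, when *max_energy* is given,
    the p-value layer is disabled and the energy cutoff applies instead).
    """
    hits: list[DuplexHit] = []
    for mid in sorted(matures):
        mseq = matures[mid]
        for gid in sorted(utrs):
            useq = utrs[gid]
            if len(useq) < len(mseq):
                continue
            energy, aln = duplex_mfe(mseq, useq)
            if aln is None:
                continue
            p = evd_pvalue(energy, len(mseq), len(useq), params)
            if max_energy is not None:
                if energy > max_energy:
                    continue
            elif p >= max_p:
                continue
            hits.append(
                DuplexHit(
                    mirna_id=mid,
                    gene_id=gid,
                    position=aln.target_start,
                    duplex_mfe=energy,
                    pvalue=p,
                )
            )
    return hits


def aggregate_targets(
    hits: Iterable[DuplexHit],
    de_status: Mapping[str, str],
    min_mirnas: int = 3,
) -> list[dict]:
    """Per-gene counts of distinct up/down miRNAs targeting it.

    A gene is kept iff strictly more than *min_mirnas* distinct up-regulated
    miRNAs target it, or strictly more than *min_mirnas* down-regulated
    ones.  Each (miRNA, gene) pair counts once regardless of site count.
    """
    per_gene: dict[str, dict[str, set[str]]] = {}
    for h in hits:
        status = de_status.get(h.mirna_id)
        if status not in ("up", "down"):
            continue
        sets = per_gene.setdefault(h.gene_id, {"up": set(), "down": set()})
        sets[status].add(h.mirna_id)
    records = []
    for gene in sorted(per_gene):
        n_up = len(per_gene[gene]["up"])
        n_down = len(per_gene[gene]["down"])
        records.append(
            {
                "gene": gene,
                "n_up_mirnas": n_up,
                "n_down_mirnas": n_down,
                "kept": n_up > min_mirnas or n_down > min_mirnas,
            }
        )
    records.sort(key=lambda r: (-max(r["n_up_mirnas"], r["n_down_mirnas"]), r["gene"]))
    return records
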