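"""Two-library differential expression of miRNA counts.

One library per condition, so significance uses an exact conditional test:
under the null of equal relative abundance, given the combined count
``x + y`` the knockdown count is Binomial(x + y, N2 / (N1 + N2)).  The
two-sided p-value sums every outcome whose probability does not exceed the
observed one (minimum-likelihood rule).  P-values are Benjamini-Hochberg
adjusted, and a miRNA is called up/down when the adjusted p is below alpha
and the TPM fold change is at least ``min_fold``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEResult",
    "tpm",
    "two_library_test",
    "bh_adjust",
    "fold_change",
    "classify",
    "sample_specific",
    "differential_expression",
]


@dataclass
class DEResult:
    mirna_id: str
    count_control: int
    count_knockdown: int
    tpm_control: float
    tpm_knockdown: float
    log2fc: float  #: knockdown over control
    pvalue: float
    adj_pvalue: float
    status: str  #: 'up', 'down' or 'ns'


def tpm(count: int, total_clean: int) -> float:
    """Transcripts (tags) per million: ``count / total_clean * 1e6``."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    if count < 0 or count > total_clean:
        raise ValueError("count must be within [0, total_clean]")
    return count / total_clean * 1e6


def two_library_test(x: int, n1: int, y: int, n2: int) -> float:
    """Exact two-sided test of equal relative abundance in two libraries.

    *x*, *y* are the feature's counts and *n1*, *n2* the library totals.
    Conditional on ``x + y``, ``y ~ Binomial(x + y, n2 / (n1 + n2))`` under
    the null; the two-sided p-value is the sum of binomial probabilities
    not exceeding the observed outcome's probability.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    n = x + y
    if n == 0:
        raise ValueError("x + y must be at least 1")
    q = n2 / (n1 + n2)
    pmf = stats.binom.pmf(np.arange(n + 1), n, q)
    p_obs = pmf[y]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, max(p, 5e-324))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out.tolist()


def fold_change(
    tpm_control: float, tpm_knockdown: float, floor: float = 0.01
) -> float:
    """log2(knockdown / control) with zeros replaced by *floor* first."""
    if tpm_control < 0 or tpm_knockdown < 0:
        raise ValueError("TPMs must be non-negative")
    if tpm_control == 0 and tpm_knockdown == 0:
        raise ValueError("fold change undefined when both TPMs are zero")
    c = tpm_control if tpm_control > 0 else floor
    k = tpm_knockdown if tpm_knockdown > 0 else floor
    return float(np.log2(k / c))


def classify(
    log2fcs: Sequence[float],
    adj_pvalues: Sequence[float],
    alpha: float = 0.01,
    min_fold: float = 2.0,
) -> tuple[list[str], int, int]:
    """Call each row 'up', 'down' or 'ns'.

    'up' iff ``log2fc >= log2(min_fold)`` and ``adj_p < alpha``; 'down'
    symmetric.  Returns ``(statuses, n_up, n_down)``.
    """
    thr = float(np.log2(min_fold))
    statuses: list[str] = []
    for fc, ap in zip(log2fcs, adj_pvalues, strict=True):
        if ap < alpha and fc >= thr:
            statuses.append("up")
        elif ap < alpha and fc <= -thr:
            statuses.append("down")
        else:
            statuses.append("ns")
    return statuses, statuses.count("up"), statuses.count("down")


def sample_specific(
    counts: Mapping[str, tuple[int, int]]
) -> tuple[list[str], list[str]]:
    """IDs expressed (count >= 1) in exactly one library.

    Returns ``(control_only, knockdown_only)``.
    """
    control_only = sorted(k for k, (c, kd) in counts.items() if c >= 1 and kd == 0)
    knockdown_only = sorted(k for k, (c, kd) in counts.items() if c == 0 and kd >= 1)
    return control_only, knockdown_only


def differential_expression(
    counts: Mapping[str, tuple[int, int]],
    total_control: int,
    total_knockdown: int,
    alpha: float = 0.01,
    min_fold: float = 2.0,
    floor: float = 0.01,
) -> pd.DataFrame:
    """Full per-miRNA DE table from raw counts and library totals.

    Features with zero counts in both libraries are dropped (untestable).
    """
    ids = [k for k in counts if sum(counts[k]) > 0]
    rows = []
    for mid in ids:
        x, y = counts[mid]
        tc = tpm(x, total_control)
        tk = tpm(y, total_knockdown)
        rows.append(
            {
                "mirna_id": mid,
                "count_control": x,
                "count_knockdown": y,
                "tpm_control": tc,
                "tpm_knockdown": tk,
                "log2fc": fold_change(tc, tk, floor=floor),
                "pvalue": two_library_test(x, total_control, y, total_knockdown),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "count_control",
            "count_knockdown",
            "tpm_control",
            "tpm_knockdown",
            "log2fc",
            "pvalue",
        ],
    )
    if len(df):
        df["adj_pvalue"] = bh_adjust(df["pvalue"].tolist())
        statuses, _, _ = classify(
            df["log2fc"], df["adj_pvalue"], alpha=alpha, min_fold=min_fold
        )
        df["status"] = statuses
    else:
        df["adj_pvalue"] = []
        df["status"] = []
    return df
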