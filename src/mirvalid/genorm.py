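"""GeNorm reference-gene stability statistics.

For candidate reference genes measured on a linear relative-quantity
scale, the stability M of gene j is the mean over partners k of the
standard deviation across samples of log2(q_j / q_k): a gene that moves
in proportion with its partners has a small M. Genes are ranked by
iteratively discarding the highest-M gene; the pairwise-variation curve
V(n, n+1) — the SD across samples of the log2 ratio of normalization
factors built from the top n versus top n+1 genes — indicates how many
references are needed (V below 0.15 by convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError

V_THRESHOLD = 0.15


@dataclass
class GenormResult:
    m_values: pd.Series
    ranking: list[str]          # most stable first; the final pair shares rank 1
    v_curve: pd.Series          # index n, value V(n, n+1)
    recommended_n: int


def _check_matrix(expr: pd.DataFrame, min_genes: int = 2) -> None:
    if expr.shape[0] < min_genes or expr.shape[1] < 2:
        raise ValidationError(
            f"need >= {min_genes} genes and >= 2 samples, got {expr.shape}"
        )
    if (expr.to_numpy() <= 0).any():
        raise ValidationError(
            "expression quantities must be strictly positive; "
            "apply a pseudocount upstream"
        )


def m_values(expr: pd.DataFrame) -> pd.Series:
    """Per-gene stability M (lower = more stable).

    ``expr`` is a genes x samples DataFrame of positive linear quantities.
    """
    _check_matrix(expr, min_genes=2)
    log = np.log2(expr.to_numpy(dtype=float))
    g = log.shape[0]
    m = np.empty(g)
    for j in range(g):
        ratios = log[j][None, :] - log          # log2(q_j / q_k) for all k
        sds = ratios.std(axis=1, ddof=1)
        m[j] = np.delete(sds, j).mean()
    return pd.Series(m, index=expr.index, name="M")


def rank_by_stability(expr: pd.DataFrame) -> list[str]:
    """Stability ranking by iterative exclusion of the highest-M gene.

    Returns gene IDs from most to least stable; the final two genes are
    indistinguishable by the procedure and are listed first in ID order.
    Ties in M are broken by ID (the later one is excluded first).
    """
    _check_matrix(expr, min_genes=3)
    remaining = expr.copy()
    excluded: list[str] = []
    while remaining.shape[0] > 2:
        m = m_values(remaining)
        # ties (up to floating noise) break by ID: the later one goes first
        tied = m.index[m >= m.max() - 1e-9]
        worst = sorted(tied)[-1]
        excluded.append(worst)
        remaining = remaining.drop(index=worst)
    final_pair = sorted(remaining.index.tolist())
    return final_pair + excluded[::-1]


def pairwise_variation(expr: pd.DataFrame, ranking: list[str],
                       v_threshold: float = V_THRESHOLD
                       ) -> tuple[pd.Series, int]:
    """V(n, n+1) curve over normalization factors of the top-ranked genes.

    NF_n is the per-sample geometric mean of the n most stable genes;
    V(n, n+1) = SD across samples of log2(NF_n / NF_{n+1}). The
    recommended number of references is the smallest n with
    V(n, n+1) strictly below ``v_threshold``; if no n qualifies, all G
    genes are recommended with a warning.
    """
    g = len(ranking)
    if g < 3:
        warnings.warn("fewer than 3 genes: V curve is empty, recommending 2",
                      stacklevel=2)
        return pd.Series(dtype=float, name="V"), 2
    log = np.log2(expr.loc[ranking].to_numpy(dtype=float))
    # cumulative per-sample geometric means on the log scale
    cum = np.cumsum(log, axis=0) / np.arange(1, g + 1)[:, None]
    v = {}
    for n in range(2, g):
        diff = cum[n - 1] - cum[n]              # log2(NF_n / NF_{n+1})
        v[n] = float(np.std(diff, ddof=1))
    v_curve = pd.Series(v, name="V")
    below = [n for n, val in v_curve.items() if val < v_threshold]
    if below:
        recommended = min(below)
    else:
        warnings.warn(
            f"no V(n,n+1) below {v_threshold}; recommending all {g} genes",
            stacklevel=2,
        )
        recommended = g
    return v_curve, recommended


def evaluate(expr: pd.DataFrame, v_threshold: float = V_THRESHOLD) -> GenormResult:
    """Full GeNorm evaluation: M values, ranking and V curve."""
    ranking = rank_by_stability(expr)
    v_curve, recommended = pairwise_variation(expr, ranking, v_threshold)
    return GenormResult(
        m_values=m_values(expr),
        ranking=ranking,
        v_curve=v_curve,
        recommended_n=recommended,
    )


def quantities_from_ct(ct_wide: pd.DataFrame, efficiency: float | dict | None = None
                       ) -> pd.DataFrame:
    """Convert an assays x samples CT matrix to linear relative quantities.

    quantity = E^(-CT) with E = 1 + efficiency fraction per assay; the
    default assumes 100% efficiency (E = 2). ``efficiency`` may be a single
    fraction or a per-assay mapping.
    """
    if efficiency is None:
        base = pd.Series(2.0, index=ct_wide.index)
    elif np.isscalar(efficiency):
        base = pd.Series(1.0 + float(efficiency), index=ct_wide.index)
    else:
        base = pd.Series({a: 1.0 + efficiency.get(a, 1.0) for a in ct_wide.index})
    return pd.DataFrame(
        np.power(base.to_numpy()[:, None], -ct_wide.to_numpy(dtype=float)),
        index=ct_wide.index,
        columns=ct_wide.columns,
    )
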