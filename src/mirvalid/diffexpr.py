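"""Two-group differential expression for miRNA count matrices.

The tests here are deliberately simple, self-contained negative-binomial
procedures: CPM and median-of-ratios normalization, a per-miRNA Wald test
with method-of-moments dispersion, and a label-permutation alternative.
Calls follow the conventional small-RNA thresholds |log2FC| >= 1 at
BH-FDR < 0.01 (both overridable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CASE, CONTROL, GROUP_LABELS, ValidationError

#: default calling thresholds
LFC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.01


@dataclass
class CountMatrix:
    """Nonnegative integer miRNA x sample count matrix with two-group labels.

    Parameters
    ----------
    counts
        DataFrame indexed by miRNA ID with one column per sample.
    groups
        Series mapping sample ID -> "case" / "control", aligned to columns.
    """

    counts: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate miRNA IDs: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dup}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (arr < 0).any():
            raise ValidationError("counts must be nonnegative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integral")
        self.groups = self.groups.reindex(c.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValidationError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - set(GROUP_LABELS)
        if bad:
            raise ValidationError(
                f"unknown group labels {sorted(bad)}; expected {GROUP_LABELS}"
            )
        for g in GROUP_LABELS:
            if (self.groups == g).sum() < 2:
                raise ValidationError(f"need >=2 samples in group '{g}'")

    @property
    def mirna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def group_columns(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count / library size * 1e6, per sample (column).

    Raises on zero-depth samples, naming them.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    libsize = mat.sum(axis=0)
    zero = libsize.index[libsize == 0].tolist()
    if zero:
        raise ValidationError(f"zero-depth sample(s): {zero}")
    return mat / libsize * 1e6


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample s: median over all-positive miRNAs m of
    count[m, s] / geometric-mean-over-samples(count[m, :]).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValidationError(
            "no miRNA has positive counts in every sample; "
            "filter low-abundance miRNAs before normalization"
        )
    sub = arr[allpos]
    geomean = np.exp(np.mean(np.log(sub), axis=1))
    ratios = sub / geomean[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _classify(log2fc: np.ndarray, fdr: np.ndarray,
              lfc_threshold: float, fdr_threshold: float) -> np.ndarray:
    call = np.full(log2fc.shape, "ns", dtype=object)
    sig = fdr < fdr_threshold
    call[sig & (log2fc >= lfc_threshold)] = "up"
    call[sig & (log2fc <= -lfc_threshold)] = "down"
    return call


def _moments_dispersion(x: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Per-miRNA NB dispersion alpha by method of moments within one group.

    Under var = mu + alpha mu^2, alpha = (var - mu) / mu^2, floored so the
    modeled variance never collapses below the Poisson term.
    """
    mu = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(mu > 0, (var - mu) / np.square(mu), 0.0)
    return np.maximum(a, floor)


def _log2fc_stat(norm: np.ndarray, case_idx: np.ndarray, ctrl_idx: np.ndarray,
                 pseudocount: float = 0.5) -> np.ndarray:
    mu_case = norm[:, case_idx].mean(axis=1)
    mu_ctrl = norm[:, ctrl_idx].mean(axis=1)
    return np.log2(mu_case + pseudocount) - np.log2(mu_ctrl + pseudocount)


def test_de(counts: CountMatrix, method: str = "wald", *,
            lfc_threshold: float = LFC_THRESHOLD,
            fdr_threshold: float = FDR_THRESHOLD,
            n_permutations: int = 1000,
            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Two-group differential-expression test.

    Parameters
    ----------
    method
        "wald": per-miRNA NB Wald z on log2FC with delta-method standard
        error and method-of-moments dispersion. "permutation": two-sided
        p from group-label permutations of the same log2FC statistic.
    lfc_threshold, fdr_threshold
        Calling thresholds: call = up/down requires |log2FC| >= lfc_threshold
        and BH-FDR < fdr_threshold.

    Returns
    -------
    DataFrame indexed by miRNA ID with columns
    base_mean, log2fc, p, fdr, call.
    """
    if method not in ("wald", "permutation"):
        raise ValidationError(f"unknown method {method!r}; use wald or permutation")
    sf = size_factors(counts)
    norm = counts.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    grp = counts.groups.to_numpy()
    case_idx = np.flatnonzero(grp == CASE)
    ctrl_idx = np.flatnonzero(grp == CONTROL)

    base_mean = norm.mean(axis=1)
    log2fc = _log2fc_stat(norm, case_idx, ctrl_idx)

    if method == "wald":
        p = _wald_p(norm, case_idx, ctrl_idx, log2fc)
    else:
        if n_permutations < 100:
            warnings.warn(
                f"only {n_permutations} permutations; p-value resolution is poor",
                stacklevel=2,
            )
        rng = np.random.default_rng() if rng is None else rng
        p = _permutation_p(norm, case_idx, ctrl_idx, log2fc, n_permutations, rng)

    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "call": _classify(log2fc, fdr, lfc_threshold, fdr_threshold),
        },
        index=counts.mirna_ids.copy(),
    )


def _wald_p(norm, case_idx, ctrl_idx, log2fc, pseudocount: float = 0.5):
    """Wald test on log2FC: delta-method SE from per-group NB moment
    dispersion, referred to a t distribution with Welch-Satterthwaite
    degrees of freedom (the normal reference is anti-conservative at the
    6-per-group sizes this design uses)."""
    ln2 = np.log(2.0)
    terms, sizes = [], []
    for idx in (case_idx, ctrl_idx):
        x = norm[:, idx]
        mu = x.mean(axis=1)
        alpha = _moments_dispersion(x)
        # delta method: Var(log2(mu+c)) ~= Var(mu) / ((mu+c) ln2)^2, with
        # Var(mu) = (mu + alpha mu^2) / n for an NB group mean
        var_mean = (mu + alpha * mu**2) / len(idx)
        terms.append(var_mean / np.square((mu + pseudocount) * ln2))
        sizes.append(len(idx))
    tc, tk = terms
    se2 = tc + tk
    se = np.sqrt(np.maximum(se2, 1e-24))
    z = log2fc / se
    with np.errstate(divide="ignore", invalid="ignore"):
        df = np.where(
            se2 > 0,
            se2**2 / (tc**2 / (sizes[0] - 1) + tk**2 / (sizes[1] - 1)),
            sizes[0] + sizes[1] - 2,
        )
    df = np.where(np.isfinite(df) & (df >= 1), df, sizes[0] + sizes[1] - 2)
    p = 2.0 * stats.t.sf(np.abs(z), df)
    return np.clip(p, 0.0, 1.0)


def _permutation_p(norm, case_idx, ctrl_idx, observed, n_perm, rng):
    n_samples = norm.shape[1]
    n_case = len(case_idx)
    abs_obs = np.abs(observed)
    exceed = np.zeros(norm.shape[0], dtype=int)
    order = np.arange(n_samples)
    for _ in range(n_perm):
        perm = rng.permutation(order)
        pc, pk = perm[:n_case], perm[n_case:]
        stat = _log2fc_stat(norm, pc, pk)
        exceed += np.abs(stat) >= abs_obs - 1e-12
    return (exceed + 1.0) / (n_perm + 1.0)


def rank_candidates(de: pd.DataFrame, k: int,
                    pathway_weight: dict[str, int] | None = None) -> list[str]:
    """Rank DE-called miRNAs for a validation panel.

    Composite rank = mean of rank(|log2FC| descending) and rank(FDR
    ascending); ties broken by pathway annotation count (descending, when
    provided) then lexicographically by ID. Returns the top-k IDs; if fewer
    than k miRNAs are DE-called, returns all of them with a warning.
    """
    called = de[de["call"] != "ns"]
    if called.empty:
        warnings.warn("no DE-called miRNAs to rank", stacklevel=2)
        return []
    if k > len(called):
        warnings.warn(
            f"requested {k} candidates but only {len(called)} DE-called; "
            "returning all", stacklevel=2,
        )
        k = len(called)
    fc_rank = called["log2fc"].abs().rank(ascending=False, method="average")
    fdr_rank = called["fdr"].rank(ascending=True, method="average")
    composite = (fc_rank + fdr_rank) / 2.0
    ann = pd.Series(
        [0 if pathway_weight is None else pathway_weight.get(m, 0)
         for m in called.index],
        index=called.index,
    )
    order = pd.DataFrame(
        {"composite": composite, "neg_ann": -ann, "id": called.index}
    ).sort_values(["composite", "neg_ann", "id"])
    return order["id"].head(k).tolist()
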