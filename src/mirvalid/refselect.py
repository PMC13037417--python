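"""Multi-step endogenous-normalizer selection from sequencing data.

Candidate qPCR reference miRNAs are picked from a count matrix and its
differential-expression results in four stages:

1. keep miRNAs NOT significantly DE (FDR strictly > 0.05),
2. rank by fold-change proximity to 1 (minimal |log2FC|),
3. keep the 50% of candidates with the lowest coefficient of variation
   of CPM across all samples (both groups pooled),
4. drop anything on a user-supplied exclusion list (e.g. miRNAs with
   prior cancer involvement),

then take the top n (default 3) lowest-CV survivors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError
from .diffexpr import CountMatrix, cpm

FDR_FLOOR = 0.05
CV_RETENTION = 0.5
N_NORMALIZERS = 3


@dataclass
class NormalizerReport:
    """Outcome of the selection pipeline."""

    candidates: list[str]
    n_requested: int
    stage_counts: dict[str, int]
    exclusion_hits: list[str] = field(default_factory=list)
    stability: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "n_requested": self.n_requested,
            "stage_counts": self.stage_counts,
            "exclusion_hits": self.exclusion_hits,
        }


def filter_non_de(de: pd.DataFrame, fdr_floor: float = FDR_FLOOR) -> set[str]:
    """miRNAs that are not significantly DE: FDR strictly greater than the floor."""
    kept = set(de.index[de["fdr"] > fdr_floor])
    if not kept:
        raise ValidationError(
            f"no miRNA has FDR > {fdr_floor}; relax the floor or revisit the DE step"
        )
    return kept


def rank_fc_proximity(de: pd.DataFrame, subset: set[str]) -> list[str]:
    """Order a candidate set by fold-change proximity to 1 (|log2FC| ascending).

    Ties are broken by FDR descending (least evidence of change first),
    then lexicographically by ID.
    """
    if not subset:
        raise ValidationError("candidate subset is empty")
    sub = de.loc[sorted(subset)]
    order = (
        pd.DataFrame(
            {"absfc": sub["log2fc"].abs(), "negfdr": -sub["fdr"], "id": sub.index}
        )
        .sort_values(["absfc", "negfdr", "id"])
    )
    return order["id"].tolist()


def cv_screen(cpm_matrix: pd.DataFrame, subset,
              retention: float = CV_RETENTION) -> pd.DataFrame:
    """Stability table over a candidate set, flagging the lowest-CV half.

    CV = sample standard deviation (n-1) of CPM over ALL samples divided by
    the mean. ceil(m * retention) candidates are retained. Zero-mean rows
    are dropped with a warning.
    """
    ids = [m for m in subset if m in cpm_matrix.index]
    if len(ids) < 2:
        raise ValidationError("CV screen needs at least 2 candidates")
    sub = cpm_matrix.loc[ids]
    mean = sub.mean(axis=1)
    zero = mean.index[mean == 0].tolist()
    if zero:
        warnings.warn(f"zero-mean CPM rows dropped from CV screen: {zero}",
                      stacklevel=2)
        sub = sub.drop(index=zero)
        mean = mean.drop(index=zero)
    sd = sub.std(axis=1, ddof=1)
    cv = sd / mean
    table = pd.DataFrame({"mean_cpm": mean, "sd_cpm": sd, "cv": cv})
    table = table.sort_values(["cv", "mean_cpm"], kind="mergesort")
    n_keep = math.ceil(len(table) * retention)
    table["passed_cv_cut"] = False
    table.iloc[:n_keep, table.columns.get_loc("passed_cv_cut")] = True
    return table


def normalize_id(mirna_id: str) -> str:
    return mirna_id.strip().lower()


def apply_exclusion(subset, exclusion_list) -> tuple[set[str], list[str]]:
    """Remove excluded IDs (case-insensitively); returns (kept, hits)."""
    excl = {normalize_id(x) for x in exclusion_list}
    kept, hits = set(), []
    for m in subset:
        if normalize_id(m) in excl:
            hits.append(m)
        else:
            kept.add(m)
    return kept, sorted(hits)


def select_normalizers(counts: CountMatrix, de: pd.DataFrame,
                       exclusion_list=(), n: int = N_NORMALIZERS, *,
                       fdr_floor: float = FDR_FLOOR,
                       retention: float = CV_RETENTION) -> NormalizerReport:
    """Run the full selection pipeline and report per-stage survivor counts."""
    missing = counts.mirna_ids.difference(de.index)
    if len(missing):
        raise ValidationError(
            f"DE table does not cover the count matrix: missing {list(missing[:5])}"
        )
    non_de = filter_non_de(de, fdr_floor)
    ranked = rank_fc_proximity(de, non_de)
    cpm_matrix = cpm(counts)
    stability = cv_screen(cpm_matrix, ranked, retention)
    survivors = stability.index[stability["passed_cv_cut"]]
    kept, hits = apply_exclusion(survivors, exclusion_list)

    # final pick: lowest CV among survivors not excluded
    final = [m for m in stability.index if m in kept]
    if len(final) < n:
        warnings.warn(
            f"only {len(final)} normalizer candidates survive; requested {n}",
            stacklevel=2,
        )
    picked = final[:n]

    stability = stability.copy()
    stability["fc_proximity"] = de.loc[stability.index, "log2fc"].abs()
    stability["passed_fdr_filter"] = [m in non_de for m in stability.index]
    stability["excluded_by_list"] = [m in set(hits) for m in stability.index]

    return NormalizerReport(
        candidates=picked,
        n_requested=n,
        stage_counts={
            "input": len(de),
            "non_de": len(non_de),
            "cv_screen": int(stability["passed_cv_cut"].sum()),
            "after_exclusion": len(final),
            "selected": len(picked),
        },
        exclusion_hits=hits,
        stability=stability,
    )
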