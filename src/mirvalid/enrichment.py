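"""Target-score filtering and hypergeometric pathway over-representation.

Predicted miRNA target tables (miRDB-export style: mirna_id, gene_symbol,
target_score in 0-100) are filtered at a score cutoff (default >= 60) and
the resulting gene union is tested for over-representation in pathway
gene sets (GMT) with the upper-tail hypergeometric test: with a universe
of N genes of which K belong to the set, drawing n query genes and
observing k in the set gives p = P(X >= k); fold enrichment is
(k/n) / (K/N). FDR across sets is Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .diffexpr import bh_adjust

SCORE_MIN = 60.0
MIN_SET_SIZE = 2
MAX_SET_SIZE = 2000


def _norm_gene(g: str) -> str:
    return g.strip().upper()


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe (symbols upper-cased)."""

    sets: dict[str, set[str]]
    universe: set[str]

    @classmethod
    def from_sets(cls, sets: dict[str, list[str] | set[str]],
                  universe=None) -> "GeneSetCollection":
        norm_sets = {
            name: {_norm_gene(g) for g in genes} for name, genes in sets.items()
        }
        empty = [n for n, s in norm_sets.items() if not s]
        if empty:
            raise ValidationError(f"empty gene sets: {empty}")
        if universe is None:
            warnings.warn(
                "no background universe supplied; defaulting to the union of "
                "all set genes, which differs from a genome background",
                stacklevel=2,
            )
            uni = set().union(*norm_sets.values())
        else:
            uni = {_norm_gene(g) for g in universe}
            for name in list(norm_sets):
                outside = norm_sets[name] - uni
                if outside:
                    warnings.warn(
                        f"set {name!r}: {len(outside)} gene(s) outside the "
                        "universe dropped", stacklevel=2,
                    )
                    norm_sets[name] = norm_sets[name] & uni
            norm_sets = {n: s for n, s in norm_sets.items() if s}
        return cls(sets=norm_sets, universe=uni)

    def size_filtered(self, min_size: int = MIN_SET_SIZE,
                      max_size: int = MAX_SET_SIZE) -> "GeneSetCollection":
        kept = {
            n: s for n, s in self.sets.items() if min_size <= len(s) <= max_size
        }
        return GeneSetCollection(sets=kept, universe=self.universe)


def filter_targets(targets: pd.DataFrame, score_min: float = SCORE_MIN
                   ) -> list[str]:
    """Unique gene symbols from records with target_score >= score_min.

    ``targets`` needs columns mirna_id, gene_symbol, target_score (0-100).
    """
    required = {"mirna_id", "gene_symbol", "target_score"}
    missing = required - set(targets.columns)
    if missing:
        raise ValidationError(f"target table missing columns: {sorted(missing)}")
    scores = targets["target_score"]
    if ((scores < 0) | (scores > 100)).any():
        raise ValidationError("target scores must lie in [0, 100]")
    kept = targets.loc[scores >= score_min, "gene_symbol"].map(_norm_gene)
    genes = sorted(kept.unique())
    if not genes:
        warnings.warn(f"no targets with score >= {score_min}", stacklevel=2)
    return genes


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for a hypergeometric(N, K, n) variable."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_test(query, collection: GeneSetCollection, *,
             min_set_size: int = MIN_SET_SIZE,
             max_set_size: int = MAX_SET_SIZE) -> pd.DataFrame:
    """Over-representation of a query gene list in each gene set.

    Query genes outside the universe are dropped (logged). Returns a
    DataFrame indexed by set name with columns k, n, K, N,
    fold_enrichment, p, fdr, sorted by fdr then fold_enrichment
    (descending).
    """
    if not collection.universe:
        raise ValidationError("empty universe")
    q = {_norm_gene(g) for g in query}
    if not q:
        raise ValidationError("empty query gene list")
    outside = q - collection.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
        q &= collection.universe
    if not q:
        raise ValidationError("no query genes remain inside the universe")

    filtered = collection.size_filtered(min_set_size, max_set_size)
    N = len(collection.universe)
    n = len(q)
    rows = []
    for name in sorted(filtered.sets):
        genes = filtered.sets[name]
        K = len(genes)
        k = len(q & genes)
        fe = (k / n) / (K / N)
        rows.append((name, k, n, K, N, fe, hypergeom_sf(k, N, K, n)))
    table = pd.DataFrame(
        rows, columns=["set", "k", "n", "K", "N", "fold_enrichment", "p"]
    ).set_index("set")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values(["fdr", "fold_enrichment"], ascending=[True, False])
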