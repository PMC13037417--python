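"""Cross-platform and cross-tissue agreement summaries.

Compares signed up/down calls between experiments: validated-set counts
from a classified qPCR result table, signed-overlap (Venn) partitions
between two call sets, and direction concordance between sequencing
log2FC calls and qPCR fold-regulation calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError


@dataclass
class ComparisonReport:
    concordant: list[str]
    discordant: list[str]
    unique_a: list[str]
    unique_b: list[str]

    @property
    def n_shared(self) -> int:
        return len(self.concordant) + len(self.discordant)

    def to_dict(self) -> dict:
        return {
            "concordant": self.concordant,
            "discordant": self.discordant,
            "unique_a": self.unique_a,
            "unique_b": self.unique_b,
            "n_shared": self.n_shared,
        }


def summarize_validation(results: pd.DataFrame) -> tuple[int, int, int]:
    """(n_validated, n_up, n_down) from a table with a ``class`` column."""
    cls = results["class"]
    n_up = int((cls == "up").sum())
    n_down = int((cls == "down").sum())
    return n_up + n_down, n_up, n_down


def _signed_map(calls: pd.Series | dict) -> dict[str, str]:
    if isinstance(calls, pd.Series):
        if calls.index.has_duplicates:
            dup = calls.index[calls.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate IDs in call set: {dup}")
        calls = calls.to_dict()
    bad = {v for v in calls.values() if v not in ("up", "down")}
    if bad:
        raise ValidationError(f"signed calls must be up/down, got {sorted(bad)}")
    return dict(calls)


def overlap_sets(set_a: pd.Series | dict, set_b: pd.Series | dict
                 ) -> ComparisonReport:
    """Partition two signed call sets (ID -> up/down) by overlap and sign.

    Shared IDs split into concordant (same direction) and discordant
    (opposite direction); the remainder populate unique_a / unique_b.
    """
    a = _signed_map(set_a)
    b = _signed_map(set_b)
    shared = sorted(set(a) & set(b))
    concordant = [m for m in shared if a[m] == b[m]]
    discordant = [m for m in shared if a[m] != b[m]]
    return ComparisonReport(
        concordant=concordant,
        discordant=discordant,
        unique_a=sorted(set(a) - set(b)),
        unique_b=sorted(set(b) - set(a)),
    )


def direction_concordance(de: pd.DataFrame, qpcr: pd.DataFrame
                          ) -> tuple[float, pd.DataFrame]:
    """Fraction of jointly significant miRNAs changing in the same direction.

    ``de`` is a DE table (log2fc, call); ``qpcr`` a classified
    quantification table (fold_regulation, class). Only IDs significant on
    BOTH platforms enter the fraction; the per-ID table reports every
    shared ID with its signs.
    """
    shared = de.index.intersection(qpcr.index)
    if shared.empty:
        raise ValidationError("no shared miRNA IDs between DE and qPCR tables")
    table = pd.DataFrame(
        {
            "seq_log2fc": de.loc[shared, "log2fc"],
            "seq_call": de.loc[shared, "call"],
            "qpcr_fold_regulation": qpcr.loc[shared, "fold_regulation"],
            "qpcr_class": qpcr.loc[shared, "class"],
        }
    )
    both = table[(table["seq_call"] != "ns") & (table["qpcr_class"] != "ns")]
    table["jointly_significant"] = table.index.isin(both.index)
    table["concordant"] = table["jointly_significant"] & (
        table["seq_call"] == table["qpcr_class"]
    )
    if both.empty:
        return float("nan"), table
    frac = float(table.loc[both.index, "concordant"].mean())
    return frac, table


def validated_set(de: pd.DataFrame, qpcr: pd.DataFrame) -> list[str]:
    """IDs significant on both platforms with the same direction."""
    _, table = direction_concordance(de, qpcr)
    return sorted(table.index[table["concordant"]])
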