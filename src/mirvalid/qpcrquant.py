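"""ddCT relative quantification and volcano classification for RT-qPCR panels.

Each target's dCT is its CT minus the mean CT of the reference
(endogenous-control) assays in the same sample; ddCT is the case-group
mean dCT minus the control-group mean; fold change is 2^(-ddCT). Fold
regulation is the signed convention used on commercial analysis portals:
equal to fold change when >= 1, otherwise -1/fold change, so magnitudes
are always >= 1 and the sign gives direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CASE, CONTROL, ValidationError

CT_COLUMNS = ["sample_id", "group", "assay_id", "ct", "undetermined"]


@dataclass
class CtTable:
    """Long-format qPCR CT records: (sample_id, group, assay_id, ct, undetermined).

    Replicate rows per (sample, assay) are averaged on construction
    (undetermined replicates are dropped from the average; a pair is
    undetermined only if every replicate is).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in CT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"CT table missing columns: {missing}")
        bad = set(df["group"].unique()) - {CASE, CONTROL}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        det = df[~df["undetermined"].astype(bool)]
        if det["ct"].isna().any():
            raise ValidationError("determined records must carry a CT value")
        # average technical replicates per (sample, assay)
        if df.duplicated(["sample_id", "assay_id"]).any():
            df = (
                df.groupby(["sample_id", "assay_id"], as_index=False)
                .apply(_collapse_replicates, include_groups=False)
                .reset_index(drop=True)
            )
        self.records = df.reset_index(drop=True)

    def groups(self) -> pd.Series:
        return (
            self.records[["sample_id", "group"]]
            .drop_duplicates()
            .set_index("sample_id")["group"]
        )


def _collapse_replicates(block: pd.DataFrame) -> pd.Series:
    det = block[~block["undetermined"].astype(bool)]
    if det.empty:
        return pd.Series(
            {"group": block["group"].iloc[0], "ct": np.nan, "undetermined": True}
        )
    return pd.Series(
        {
            "group": block["group"].iloc[0],
            "ct": det["ct"].mean(),
            "undetermined": False,
        }
    )


@dataclass
class PanelConfig:
    """Assay roles on a custom qPCR plate.

    target_assays are quantified against reference_assays (endogenous
    normalizers); spike/control assays (RNU6, UniSp3/6-style) are recorded
    for QC but excluded from ddCT.
    """

    target_assays: list[str]
    reference_assays: list[str]
    spike_controls: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.reference_assays:
            raise ValidationError("panel needs at least one reference assay")
        overlap = set(self.target_assays) & set(self.reference_assays)
        if overlap:
            raise ValidationError(
                f"assays listed as both target and reference: {sorted(overlap)}"
            )
        for name in ("target_assays", "reference_assays", "spike_controls"):
            vals = getattr(self, name)
            if len(set(vals)) != len(vals):
                raise ValidationError(f"duplicate IDs in {name}")

    def all_quantified(self) -> list[str]:
        return list(self.target_assays) + list(self.reference_assays)


def delta_ct(ct: CtTable, panel: PanelConfig) -> pd.DataFrame:
    """Per-(sample, target) dCT = CT_target - mean(determined reference CTs).

    Samples with no determined reference assay are dropped with a warning
    naming them. Undetermined targets yield missing dCT.
    """
    df = ct.records
    refs = df[
        df["assay_id"].isin(panel.reference_assays) & ~df["undetermined"].astype(bool)
    ]
    ref_mean = refs.groupby("sample_id")["ct"].mean()
    all_samples = df["sample_id"].unique()
    dropped = [s for s in all_samples if s not in ref_mean.index]
    if dropped:
        warnings.warn(
            f"samples without any determined reference CT dropped: {dropped}",
            stacklevel=2,
        )
    targets = df[df["assay_id"].isin(panel.target_assays)].copy()
    targets = targets[targets["sample_id"].isin(ref_mean.index)]
    targets["dct"] = np.where(
        targets["undetermined"].astype(bool),
        np.nan,
        targets["ct"] - targets["sample_id"].map(ref_mean),
    )
    return targets[["sample_id", "group", "assay_id", "dct"]].reset_index(drop=True)


def fold_regulation(fold_change: float) -> float:
    """Signed fold representation: FC if FC >= 1, else -1/FC."""
    if fold_change <= 0:
        raise ValidationError("fold change must be positive")
    return fold_change if fold_change >= 1.0 else -1.0 / fold_change


def fold_change_from_regulation(fr: float) -> float:
    """Inverse of :func:`fold_regulation` on |FR| >= 1."""
    if abs(fr) < 1.0:
        raise ValidationError("fold regulation magnitude must be >= 1")
    return fr if fr >= 1.0 else -1.0 / fr


def ddct_quantify(dct: pd.DataFrame, *, p_on: str = "dct",
                  n_permutations: int = 10000,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-target ddCT quantification with Welch t-test group comparison.

    ddCT = mean(dCT case) - mean(dCT control); FC = 2^(-ddCT); fold
    regulation per the signed convention. p is a two-sided Welch t-test on
    per-sample dCT (default) or on linear 2^(-dCT) quantities
    (``p_on="linear"``); ``p_on="permutation"`` uses label permutations of
    the ddCT statistic. Targets with <2 usable samples in either group get
    missing p and are flagged.
    """
    if p_on not in ("dct", "linear", "permutation"):
        raise ValidationError(f"unknown p_on {p_on!r}")
    rows = []
    for assay, block in dct.groupby("assay_id", sort=True):
        usable = block.dropna(subset=["dct"])
        case = usable.loc[usable["group"] == CASE, "dct"].to_numpy()
        ctrl = usable.loc[usable["group"] == CONTROL, "dct"].to_numpy()
        n_case, n_ctrl = len(case), len(ctrl)
        flagged = n_case < 2 or n_ctrl < 2
        if n_case == 0 or n_ctrl == 0:
            rows.append((assay, np.nan, np.nan, np.nan, np.nan, np.nan,
                         np.nan, n_case, n_ctrl, True))
            continue
        ddct = case.mean() - ctrl.mean()
        fc = float(np.exp2(-ddct))
        fr = fold_regulation(fc)
        if flagged:
            p = np.nan
        elif p_on == "dct":
            p = stats.ttest_ind(case, ctrl, equal_var=False).pvalue
        elif p_on == "linear":
            p = stats.ttest_ind(
                np.exp2(-case), np.exp2(-ctrl), equal_var=False
            ).pvalue
        else:
            rng_ = np.random.default_rng() if rng is None else rng
            pooled = np.concatenate([case, ctrl])
            obs = abs(ddct)
            exceed = 0
            for _ in range(n_permutations):
                perm = rng_.permutation(pooled)
                stat = perm[:n_case].mean() - perm[n_case:].mean()
                exceed += abs(stat) >= obs - 1e-12
            p = (exceed + 1.0) / (n_permutations + 1.0)
        rows.append((assay, case.mean(), ctrl.mean(), ddct, fc, fr, p,
                     n_case, n_ctrl, flagged))
    result = pd.DataFrame(
        rows,
        columns=[
            "assay_id", "dct_case_mean", "dct_control_mean", "ddct",
            "fold_change", "fold_regulation", "p", "n_case", "n_control",
            "flagged",
        ],
    ).set_index("assay_id")
    return result


def classify_volcano(results: pd.DataFrame, fr_cut: float = 2.0,
                     p_cut: float = 0.05) -> pd.DataFrame:
    """Volcano-style classification of quantified targets.

    up: fold_regulation >= fr_cut and p < p_cut; down: fold_regulation <=
    -fr_cut and p < p_cut; everything else (including missing p) ns.
    Returns a copy with a ``class`` column.
    """
    out = results.copy()
    fr = out["fold_regulation"]
    p = out["p"]
    cls = np.full(len(out), "ns", dtype=object)
    sig = p.notna() & (p < p_cut)
    cls[(sig & (fr >= fr_cut)).to_numpy()] = "up"
    cls[(sig & (fr <= -fr_cut)).to_numpy()] = "down"
    out["class"] = cls
    return out
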