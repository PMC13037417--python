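"""Synthetic miRNA-seq count matrices and qPCR CT tables with known truth.

The generator emulates an FFPE small-RNA cohort: negative-binomial counts
with realistic depth variation, a planted differentially expressed subset
with known log2 fold changes, and a planted stable (normalizer-like)
subset with minimal extra-Poisson noise. CT values derive from each
miRNA's relative abundance (its share of the miRNA pool), so they are
depth-independent — qPCR input mass is fixed regardless of sequencing
depth. Every downstream stage can thus be tested for recovery against
the truth table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import CASE, CONTROL, ValidationError
from .diffexpr import CountMatrix
from .qpcrquant import CtTable, PanelConfig


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the splenic arm of the motivating study design: 453
    detected miRNAs, 18 tumor vs 6 control samples, 67/453 differentially
    expressed, libraries of 17-49 million reads.

    Attributes
    ----------
    n_mirnas, n_case, n_control
        Matrix dimensions and group sizes.
    frac_de
        Fraction of miRNAs planted as differentially expressed.
    lfc_range
        (lo, hi) magnitude of planted |log2FC|, lo > 0; signs alternate.
    n_stable
        Number of planted normalizer-like miRNAs (log2FC 0, low dispersion).
    dispersion
        Global NB dispersion alpha (variance mu + alpha mu^2); per-miRNA
        values are drawn log-normally around it.
    lib_size_range
        (lo, hi) of log-uniformly drawn per-sample library sizes.
    ct_noise_sd
        Technical CT noise, cycles.
    ct_offset
        Cycles mapping log2 relative abundance to CT:
        CT = ct_offset - log2(relative abundance).
    ct_limit
        Detection censor: CT above this is flagged undetermined.
    seed
        Seed for all draws.
    """

    n_mirnas: int = 453
    n_case: int = 18
    n_control: int = 6
    frac_de: float = 67 / 453
    lfc_range: tuple[float, float] = (1.0, 4.0)
    n_stable: int = 30
    dispersion: float = 0.15
    lib_size_range: tuple[int, int] = (17_000_000, 49_000_000)
    ct_noise_sd: float = 0.25
    ct_offset: float = 12.0
    ct_limit: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_case, self.n_control) < 1:
            raise ValidationError("n_mirnas, n_case, n_control must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValidationError("frac_de must lie in [0, 1]")
        if self.lfc_range[0] <= 0 or self.lfc_range[1] < self.lfc_range[0]:
            raise ValidationError("lfc_range must satisfy 0 < lo <= hi")
        n_de = int(round(self.frac_de * self.n_mirnas))
        if n_de + self.n_stable > self.n_mirnas:
            raise ValidationError("frac_de*n_mirnas + n_stable exceeds n_mirnas")
        if self.n_stable < 0 or self.dispersion <= 0 or self.ct_noise_sd < 0:
            raise ValidationError("invalid n_stable/dispersion/ct_noise_sd")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ValidationError("lib_size_range must satisfy 0 < lo <= hi")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_mirnas))

    def to_dict(self) -> dict:
        return asdict(self)


#: dispersion planted for stable miRNAs: effectively Poisson
STABLE_DISPERSION = 1e-6


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-sim-{i + 1:04d}" for i in range(n)]


def _sample_frame(config: SimConfig) -> tuple[list[str], np.ndarray]:
    ids = [f"case_{i + 1:02d}" for i in range(config.n_case)] + [
        f"ctrl_{i + 1:02d}" for i in range(config.n_control)
    ]
    groups = np.array([CASE] * config.n_case + [CONTROL] * config.n_control)
    return ids, groups


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a negative-binomial count matrix plus its truth table.

    Base abundances are log-normal; DE miRNAs get group mean ratio exactly
    2^true_log2fc (fold change applied to the case group against a fixed
    control-side denominator, so planted ratios are exact); stable miRNAs
    get identical group means and near-Poisson dispersion. Library sizes
    are log-uniform in ``lib_size_range``.

    Returns
    -------
    (CountMatrix, truth) where truth is a DataFrame indexed by miRNA ID
    with columns true_log2fc, is_de, is_stable, base_mean (expected CPM-
    scale relative abundance x 1e6), dispersion.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_mirnas
    ids = _mirna_ids(n)
    sample_ids, groups = _sample_frame(config)

    # base relative abundance: heavy-tailed log-normal, as in real miRNA pools
    base = np.exp(rng.normal(loc=0.0, scale=2.0, size=n))

    n_de = config.n_de
    is_de = np.zeros(n, dtype=bool)
    is_stable = np.zeros(n, dtype=bool)
    # abundance-stratified planting. DE goes preferentially into the
    # low-abundance half so that planted fold changes do not shift the
    # per-sample totals (which would leak a compositional group effect
    # into every CPM value); stable (normalizer-like) miRNAs go into the
    # abundant half, since a usable endogenous control must be well
    # expressed — at low abundance Poisson noise alone inflates its CV.
    order = np.argsort(base)
    lower, upper = order[: n // 2], order[n // 2:]
    de_pool = np.concatenate([rng.permutation(lower), rng.permutation(upper)])
    de_idx = de_pool[:n_de]
    stable_pool = np.concatenate(
        [rng.permutation(np.setdiff1d(upper, de_idx)),
         rng.permutation(np.setdiff1d(lower, de_idx))[::-1]]
    )
    if config.n_stable > len(stable_pool):
        raise ValidationError("n_stable exceeds available non-DE miRNAs")
    stable_idx = stable_pool[:config.n_stable]
    is_de[de_idx] = True
    is_stable[stable_idx] = True

    lfc = np.zeros(n)
    if n_de:
        mag = rng.uniform(*config.lfc_range, size=n_de)
        sign = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
        lfc[de_idx] = mag * sign

    alpha = config.dispersion * np.exp(rng.normal(0.0, 0.5, size=n))
    alpha[stable_idx] = STABLE_DISPERSION

    total = base.sum()  # control-side pool; case fold changes leave the
    # denominator fixed so planted mean ratios are exactly 2^lfc
    prop_ctrl = base / total
    prop_case = base * np.exp2(lfc) / total

    lo, hi = config.lib_size_range
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sample_ids)))

    mu = np.where(
        (groups == CASE)[None, :], prop_case[:, None], prop_ctrl[:, None]
    ) * libsize[None, :]
    # NB(mean mu, var mu + alpha mu^2): size r = 1/alpha, p = r/(r+mu)
    r = 1.0 / alpha
    p = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p)

    matrix = CountMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(ids, name="mirna_id"), columns=sample_ids
        ),
        groups=pd.Series(groups, index=sample_ids),
    )
    truth = pd.DataFrame(
        {
            "true_log2fc": lfc,
            "is_de": is_de,
            "is_stable": is_stable,
            "base_mean": prop_ctrl * 1e6,
            "dispersion": alpha,
        },
        index=pd.Index(ids, name="mirna_id"),
    )
    return matrix, truth


def simulate_ct(truth: pd.DataFrame, config: SimConfig,
                panel: PanelConfig) -> CtTable:
    """Generate a long-format qPCR CT table from the truth abundances.

    CT = ct_offset - log2(relative abundance) + Normal(0, ct_noise_sd);
    values above ct_limit are flagged undetermined (their CT is censored
    at the limit). Reference assays are expected to come from planted
    stable miRNAs; a non-stable reference triggers a warning so that
    bad-normalizer scenarios remain expressible.
    """
    missing = [a for a in panel.all_quantified() if a not in truth.index]
    if missing:
        raise ValidationError(f"panel assays absent from truth table: {missing}")
    bad_refs = [a for a in panel.reference_assays if not truth.loc[a, "is_stable"]]
    if bad_refs:
        warnings.warn(
            f"reference assays not planted as stable: {bad_refs}", stacklevel=2
        )

    rng = np.random.default_rng(config.seed + 1)
    sample_ids, groups = _sample_frame(config)
    assays = panel.all_quantified()
    base = truth.loc[assays, "base_mean"].to_numpy() / 1e6
    lfc = truth.loc[assays, "true_log2fc"].to_numpy()

    records = []
    for s, g in zip(sample_ids, groups):
        abundance = base * np.exp2(lfc) if g == CASE else base
        ct = config.ct_offset - np.log2(abundance)
        ct = ct + rng.normal(0.0, config.ct_noise_sd, size=len(assays))
        undet = ct > config.ct_limit
        for a, c, u in zip(assays, ct, undet):
            records.append(
                (s, g, a, config.ct_limit if u else float(c), bool(u))
            )
    frame = pd.DataFrame(
        records, columns=["sample_id", "group", "assay_id", "ct", "undetermined"]
    )
    return CtTable(frame)
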