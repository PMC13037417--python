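"""End-to-end seeded pipeline over synthetic data.

Chains the stages of a sequencing-to-qPCR miRNA biomarker study:
simulate counts -> differential expression -> normalizer selection ->
GeNorm stability -> CT simulation for a candidate panel -> ddCT
quantification -> cross-platform concordance -> target filtering and
pathway over-representation. A manifest records inputs, per-stage seeds
and record counts; given the same seed and configuration the run is
bit-reproducible.

Seeding: the global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(entropy=seed, spawn_key=(stage_index,))``
with fixed stage indices, so inserting a new stage never perturbs the
draws of existing ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .core import ValidationError
from .diffexpr import (FDR_THRESHOLD, LFC_THRESHOLD, rank_candidates, test_de)
from .enrichment import (GeneSetCollection, SCORE_MIN, filter_targets, ora_test)
from .genorm import V_THRESHOLD, evaluate, quantities_from_ct
from .qpcrquant import classify_volcano, ddct_quantify, delta_ct, PanelConfig
from .concordance import direction_concordance, summarize_validation
from .refselect import FDR_FLOOR, CV_RETENTION, N_NORMALIZERS, select_normalizers
from .simdata import SimConfig, simulate_counts, simulate_ct

VERSION = "0.1.0"

#: fixed stage indices for seed fan-out (never renumber)
STAGE_INDEX = {
    "simulate": 0,
    "de": 1,
    "select_normalizers": 2,
    "genorm": 3,
    "ddct": 4,
    "compare": 5,
    "enrich": 6,
}


def stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the study's published thresholds."""

    seed: int = 0
    sim: SimConfig | None = None
    de_method: str = "wald"
    lfc_threshold: float = LFC_THRESHOLD        # |log2FC| >= 1
    fdr_threshold: float = FDR_THRESHOLD        # FDR < 0.01
    normalizer_fdr_floor: float = FDR_FLOOR     # FDR > 0.05 to qualify
    cv_retention: float = CV_RETENTION          # keep lowest-CV 50%
    n_normalizers: int = N_NORMALIZERS          # 3
    panel_size: int = 40                        # targets on the custom plate
    fr_cut: float = 2.0                         # volcano fold-regulation cut
    p_cut: float = 0.05                         # volcano p cut
    score_min: float = SCORE_MIN                # target score >= 60
    v_threshold: float = V_THRESHOLD            # GeNorm V < 0.15
    exclusion_list: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", None)
        cfg = cls(**d)
        if sim is not None:
            if "seed" not in sim:
                sim["seed"] = stage_seed(cfg.seed, "simulate")
            if "lfc_range" in sim:
                sim["lfc_range"] = tuple(sim["lfc_range"])
            if "lib_size_range" in sim:
                sim["lib_size_range"] = tuple(sim["lib_size_range"])
            cfg.sim = SimConfig(**sim)
        return cfg

    def resolved_sim(self) -> SimConfig:
        if self.sim is not None:
            return self.sim
        return SimConfig(seed=stage_seed(self.seed, "simulate"))


def simulate_target_table(mirna_ids, seed: int, *, universe_size: int = 6000,
                          targets_per_mirna: int = 100,
                          n_sets: int = 20, planted_sets: int = 3
                          ) -> tuple[pd.DataFrame, dict[str, list[str]], list[str]]:
    """Synthetic miRDB-style target table plus GMT-style gene sets.

    Each miRNA receives ``targets_per_mirna`` predicted targets drawn from
    a symbolic gene universe with scores uniform on [40, 100]. Most gene
    sets are random draws from the universe; ``planted_sets`` of them are
    biased toward high-score predicted targets so that over-representation
    is recoverable.
    """
    rng = np.random.default_rng(seed)
    universe = [f"GENE{i + 1:05d}" for i in range(universe_size)]
    uni = np.array(universe)
    rows = []
    for m in mirna_ids:
        genes = rng.choice(uni, size=targets_per_mirna, replace=False)
        scores = rng.uniform(40.0, 100.0, size=targets_per_mirna)
        rows.extend(zip([m] * targets_per_mirna, genes, scores))
    targets = pd.DataFrame(rows, columns=["mirna_id", "gene_symbol", "target_score"])

    high = targets.loc[targets["target_score"] >= SCORE_MIN, "gene_symbol"].unique()
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(30, 81))
        if i < planted_sets and len(high) >= size // 2:
            enriched = rng.choice(high, size=size // 2, replace=False)
            rest = rng.choice(uni, size=size - size // 2, replace=False)
            members = sorted(set(enriched) | set(rest))
            sets[f"planted_pathway_{i + 1:02d}"] = members
        else:
            sets[f"random_pathway_{i + 1:02d}"] = sorted(
                rng.choice(uni, size=size, replace=False)
            )
    return targets, sets, universe


def run_pipeline(config: RunConfig | dict, out_dir) -> dict:
    """Execute every stage, writing tables and a manifest under ``out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": VERSION,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_INDEX},
        "thresholds": {
            "lfc_threshold": config.lfc_threshold,
            "fdr_threshold": config.fdr_threshold,
            "normalizer_fdr_floor": config.normalizer_fdr_floor,
            "cv_retention": config.cv_retention,
            "target_score_min": config.score_min,
            "volcano_fr_cut": config.fr_cut,
            "volcano_p_cut": config.p_cut,
            "genorm_v_threshold": config.v_threshold,
        },
        "stages": {},
    }

    # -- simulate ---------------------------------------------------------
    sim = config.resolved_sim()
    counts, truth = simulate_counts(sim)
    io.write_count_matrix(counts, out / "counts.tsv", out / "groups.tsv")
    io.write_truth_table(truth, out / "truth.tsv")
    manifest["stages"]["simulate"] = {
        "config": sim.to_dict(),
        "n_mirnas": int(counts.counts.shape[0]),
        "n_samples": int(counts.counts.shape[1]),
    }

    # -- differential expression -----------------------------------------
    de_rng = np.random.default_rng(stage_seed(config.seed, "de"))
    de = test_de(
        counts, config.de_method,
        lfc_threshold=config.lfc_threshold,
        fdr_threshold=config.fdr_threshold,
        rng=de_rng,
    )
    io.write_de_table(de, out / "de.tsv")
    manifest["stages"]["de"] = {
        "method": config.de_method,
        "n_tested": len(de),
        "n_called": int((de["call"] != "ns").sum()),
        "n_up": int((de["call"] == "up").sum()),
        "n_down": int((de["call"] == "down").sum()),
    }

    # -- normalizer selection --------------------------------------------
    report = select_normalizers(
        counts, de, config.exclusion_list, config.n_normalizers,
        fdr_floor=config.normalizer_fdr_floor, retention=config.cv_retention,
    )
    (out / "normalizers.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n"
    )
    if report.stability is not None:
        report.stability.rename_axis("mirna_id").to_csv(
            out / "stability.tsv", sep="\t"
        )
    manifest["stages"]["select_normalizers"] = report.to_dict()

    # -- panel + CT simulation -------------------------------------------
    panel_targets = rank_candidates(de, config.panel_size)
    panel_targets = [m for m in panel_targets if m not in report.candidates]
    panel = PanelConfig(
        target_assays=panel_targets, reference_assays=report.candidates
    )
    ct = simulate_ct(truth, sim, panel)
    io.write_ct_table(ct, out / "ct.tsv")
    manifest["stages"]["ddct"] = {"n_targets": len(panel_targets),
                                  "references": report.candidates}

    # -- GeNorm on the selected references (from simulated CT) ------------
    wide = (
        ct.records[ct.records["assay_id"].isin(panel.reference_assays)]
        .pivot(index="assay_id", columns="sample_id", values="ct")
    )
    gn = evaluate(quantities_from_ct(wide), config.v_threshold)
    manifest["stages"]["genorm"] = {
        "m_values": {k: float(v) for k, v in gn.m_values.items()},
        "ranking": gn.ranking,
        "v_curve": {str(k): float(v) for k, v in gn.v_curve.items()},
        "recommended_n": gn.recommended_n,
    }

    # -- ddCT quantification ----------------------------------------------
    dct = delta_ct(ct, panel)
    qpcr = classify_volcano(ddct_quantify(dct), config.fr_cut, config.p_cut)
    qpcr.rename_axis("mirna_id").to_csv(out / "qpcr.tsv", sep="\t")
    n_validated, n_up, n_down = summarize_validation(qpcr)
    manifest["stages"]["ddct"].update(
        {"n_validated": n_validated, "n_up": n_up, "n_down": n_down}
    )

    # -- concordance -------------------------------------------------------
    frac, table = direction_concordance(de, qpcr)
    table.rename_axis("mirna_id").to_csv(out / "concordance.tsv", sep="\t")
    manifest["stages"]["compare"] = {
        "n_shared": len(table),
        "n_jointly_significant": int(table["jointly_significant"].sum()),
        "direction_concordance": None if np.isnan(frac) else float(frac),
    }

    # -- enrichment on validated, concordant miRNAs ------------------------
    validated = sorted(table.index[table["concordant"]])
    manifest["stages"]["enrich"] = {"n_validated_mirnas": len(validated)}
    if validated:
        targets, sets, universe = simulate_target_table(
            validated, stage_seed(config.seed, "enrich")
        )
        targets.to_csv(out / "targets.tsv", sep="\t", index=False)
        io.write_gmt(sets, out / "pathways.gmt")
        query = filter_targets(targets, config.score_min)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            collection = GeneSetCollection.from_sets(sets, universe)
        enr = ora_test(query, collection)
        enr.to_csv(out / "enrichment.tsv", sep="\t")
        manifest["stages"]["enrich"].update(
            {
                "n_query_genes": len(query),
                "n_sets": len(enr),
                "n_significant_sets": int((enr["fdr"] < 0.05).sum()),
            }
        )

    # -- truth recovery summary -------------------------------------------
    de_called = de.index[de["call"] != "ns"]
    truth_de = truth.index[truth["is_de"]]
    manifest["recovery"] = {
        "de_sensitivity": float(len(set(de_called) & set(truth_de)) / len(truth_de))
        if len(truth_de) else None,
        "de_false_calls": int(len(set(de_called) - set(truth_de))),
        "normalizers_all_planted_stable": bool(
            all(truth.loc[m, "is_stable"] for m in report.candidates)
        ),
        "direction_concordance": manifest["stages"]["compare"][
            "direction_concordance"
        ],
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
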