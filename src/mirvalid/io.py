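"""Readers and writers for the pipeline's table formats.

Canonical dialect: tab-separated, header row, UTF-8, ``.`` decimal.
Every writer round-trips through its reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GROUP_LABELS, ValidationError
from .diffexpr import CountMatrix
from .qpcrquant import CT_COLUMNS, CtTable, PanelConfig


# ---------------------------------------------------------------- counts

def read_count_matrix(counts_path, groups_path) -> CountMatrix:
    """Read a miRNA x sample count TSV plus a sample -> group map TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = "mirna_id"
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{counts_path}: duplicated sample column(s) {dup}")
    groups = read_group_map(groups_path)
    return CountMatrix(counts=counts, groups=groups)


def write_count_matrix(matrix: CountMatrix, counts_path, groups_path) -> None:
    out = matrix.counts.copy()
    out.index.name = "mirna_id"
    out.to_csv(counts_path, sep="\t")
    gm = matrix.groups.rename("group").rename_axis("sample_id")
    gm.to_frame().to_csv(groups_path, sep="\t")


def read_group_map(path) -> pd.Series:
    gm = pd.read_csv(path, sep="\t")
    need = {"sample_id", "group"}
    if not need <= set(gm.columns):
        raise ValidationError(f"{path}: group map needs columns {sorted(need)}")
    if gm["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample IDs in group map")
    bad = set(gm["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValidationError(f"{path}: unknown group labels {sorted(bad)}")
    return gm.set_index("sample_id")["group"]


# ---------------------------------------------------------------- qPCR

def read_ct_table(path) -> CtTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: CT table missing columns {missing}")
    df["undetermined"] = df["undetermined"].astype(bool)
    return CtTable(df)


def write_ct_table(ct: CtTable, path) -> None:
    ct.records.to_csv(path, sep="\t", index=False)


def read_panel(path) -> PanelConfig:
    """Read a panel definition: YAML mapping or role-annotated TSV."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        spec = yaml.safe_load(path.read_text())
        return PanelConfig(
            target_assays=list(spec.get("target_assays", [])),
            reference_assays=list(spec.get("reference_assays", [])),
            spike_controls=list(spec.get("spike_controls", [])),
        )
    df = pd.read_csv(path, sep="\t")
    need = {"mirna_id", "role"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: panel TSV needs columns {sorted(need)}")
    role = df.groupby("role")["mirna_id"].apply(list).to_dict()
    return PanelConfig(
        target_assays=role.get("target", []),
        reference_assays=role.get("reference", []),
        spike_controls=role.get("control", []),
    )


# ---------------------------------------------------------------- generic tables

def read_de_table(path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", index_col="mirna_id")
    need = {"base_mean", "log2fc", "p", "fdr", "call"}
    missing = need - set(de.columns)
    if missing:
        raise ValidationError(f"{path}: DE table missing columns {sorted(missing)}")
    return de


def write_de_table(de: pd.DataFrame, path) -> None:
    out = de.copy()
    out.index.name = "mirna_id"
    out.to_csv(path, sep="\t")


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="mirna_id")


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def read_exclusion_list(path) -> list[str]:
    """One miRNA ID per line; ``#`` starts a comment; blanks ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.append(entry)
    return out


def read_target_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"mirna_id", "gene_symbol", "target_score"}
    missing = need - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: target table missing columns {sorted(missing)}")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{i}: GMT line needs name, description and >=1 gene"
            )
        name = fields[0]
        if name in sets:
            raise ValidationError(f"{path}:{i}: duplicate set name {name!r}")
        sets[name] = [g for g in fields[2:] if g.strip()]
    return sets


def write_gmt(sets: dict[str, list[str] | set[str]], path) -> None:
    lines = [
        "\t".join([name, "", *sorted(set(genes))]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> list[str]:
    return read_exclusion_list(path)


def read_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg
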