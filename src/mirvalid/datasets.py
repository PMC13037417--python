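"""Packaged reference tables from the canine hemangiosarcoma validation study.

Three small TSVs ship with the package: the composition of the custom
RT-qPCR panel (40 targets, 3 candidate endogenous normalizers, 3 spike/
control assays) and the published fold-regulation / p-value tables for
the splenic and cardiac validation experiments (13 significant miRNAs
each). They serve as worked examples and as fixtures for the
classification, summary and overlap operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .qpcrquant import PanelConfig


def _data_path(name: str):
    return resources.files("mirvalid").joinpath("data", name)


def load_reference_panel() -> pd.DataFrame:
    """Custom qPCR plate layout: position, catalog number, miRNA ID, role."""
    with resources.as_file(_data_path("qpcr_panel.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def reference_panel_config() -> PanelConfig:
    """The plate layout as a PanelConfig (targets / references / controls)."""
    df = load_reference_panel()
    role = df.groupby("role")["mirna_id"].apply(list).to_dict()
    return PanelConfig(
        target_assays=role.get("target", []),
        reference_assays=role.get("reference", []),
        spike_controls=role.get("control", []),
    )


def _load_validation(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        df = pd.read_csv(p, sep="\t")
    return df.rename(columns={"p_value": "p"}).set_index("mirna_id")


def load_splenic_validation() -> pd.DataFrame:
    """Published splenic fold regulation and p-values (13 significant miRNAs)."""
    return _load_validation("splenic_qpcr_validation.tsv")


def load_cardiac_validation() -> pd.DataFrame:
    """Published cardiac fold regulation and p-values (13 significant miRNAs)."""
    return _load_validation("cardiac_qpcr_validation.tsv")
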