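"""Loaders for the small reference panels shipped with the package.

``load_qpcr_panel`` returns the published RT-qPCR ΔΔCP summary panel
(mean ± sample SD over 4 biological replicates, with the published
significance flag) for 35 *A. nidulans* genes in the control and ΔatfA
strains under MSB, tBOOH and diamide stress.  ``load_enzyme_panel`` returns
specific enzyme activities and sterol contents (mean ± SD, n = 3) with the
published stressed-vs-untreated significance flags.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml


def _data_path(name: str):
    return resources.files("stressregulon") / "data" / name


def load_qpcr_panel() -> pd.DataFrame:
    """Published qPCR ΔΔCP panel: one row per gene x strain x stress."""
    with resources.as_file(_data_path("qpcr_panel.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    df["significant"] = df["significant"].astype(bool)
    return df


def load_enzyme_panel() -> pd.DataFrame:
    """Published enzyme-activity / sterol panel: one row per culture x assay."""
    with resources.as_file(_data_path("enzyme_panel.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    df["significant"] = df["significant"].astype(bool)
    return df


def load_curated_groups() -> dict[str, dict]:
    """Curated gene groups of the validation panel, ``{id: {label, genes}}``."""
    with resources.as_file(_data_path("curated_groups.yaml")) as path:
        with open(path) as fh:
            return yaml.safe_load(fh)
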