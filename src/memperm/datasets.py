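"""Loaders for the small packaged reference tables.

These ship the published blood-brain-barrier model inputs used by the reporting
stage: the model-membrane lipid composition, the per-molecule permeability and
literature-comparison table, the fitted barrier metrics, and the default
head/tail partition of lipid atoms for contact aggregation.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml


def _path(name: str):
    return resources.files("memperm.data").joinpath(name)


def load_lipid_composition() -> pd.DataFrame:
    """Lipid species, full names, and mole percentages of the BBB model membrane."""
    with resources.as_file(_path("lipid_composition.csv")) as p:
        return pd.read_csv(p)


def load_permeability_table() -> pd.DataFrame:
    """Per-molecule permeabilities (cm/s): simulated at 440 K (mean +- SD),
    effective 310 K extrapolations, and literature candidates where available."""
    with resources.as_file(_path("permeability_table.csv")) as p:
        return pd.read_csv(p)


def load_barrier_table() -> pd.DataFrame:
    """Per-molecule free-energy barrier heights (kcal/mol) and Gaussian widths."""
    with resources.as_file(_path("barrier_table.csv")) as p:
        return pd.read_csv(p)


def load_head_tail_scheme() -> dict:
    """Default per-species head/tail atom-name partition (editable YAML)."""
    with resources.as_file(_path("head_tail_scheme.yaml")) as p:
        with open(p) as fh:
            raw = yaml.safe_load(fh)
    return {
        species: {"head": set(v["head"]), "tail": set(v["tail"])}
        for species, v in raw.items()
    }
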