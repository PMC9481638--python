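"""Bundled fixture data (all synthetic; no licensed vocabularies)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .prioritize import SignalAnnotation, load_annotations
from .vocab import DrugMap, PhecodeMap, load_drug_map, load_phecode_map


def _path(name: str) -> Path:
    return Path(resources.files("medwas").joinpath("data", name))


def toy_signals() -> pd.DataFrame:
    """Six hand-built scan signals used as the triage worked example."""
    df = pd.read_csv(_path("toy_signals.tsv"), sep="\t")
    df["bonferroni_significant"] = df["bonferroni_significant"].astype(bool)
    return df


def toy_annotations() -> dict[str, SignalAnnotation]:
    """Annotations for :func:`toy_signals`."""
    return load_annotations(_path("toy_annotations.tsv"))


def fixture_phecode_map() -> PhecodeMap:
    """12-row synthetic phecode map (synthetic codes, not the real table)."""
    return load_phecode_map(_path("synthetic_phecode_map.csv"))


def fixture_phecode_map_path() -> Path:
    return _path("synthetic_phecode_map.csv")


def fixture_drug_map() -> DrugMap:
    """Small synthetic drug→ATC-4 map."""
    return load_drug_map(_path("synthetic_drug_map.tsv"))


def fixture_gestation_dictionary_path() -> Path:
    return _path("gestation_dictionary.tsv")
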