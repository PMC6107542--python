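"""Packaged study fixtures: the compared treatments and the outcomes of interest."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_treatments", "load_outcomes"]


def _load(name: str) -> pd.DataFrame:
    source = resources.files("evigrid.data") / name
    with resources.as_file(source) as p:
        return pd.read_csv(p)


def load_treatments() -> pd.DataFrame:
    """The 17 depression treatments (concept_id, name)."""
    return _load("treatments.csv")


def load_outcomes() -> pd.DataFrame:
    """The 22 outcomes of clinical interest (concept_id, name)."""
    return _load("outcomes.csv")
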