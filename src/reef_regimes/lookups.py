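"""Packaged lookup tables.

Small curated tables shipped with the package: a species list with
length-weight coefficients, functional-group membership and survey-exclusion
flags; a benthic category -> cover-group map; and a coral life-history trait
classification (competitive / stress-tolerant / generalist / weedy).

The species and benthic tables are synthetic stand-ins: taxa and coefficients
are plausible for Hawaiian forereefs but were assembled for testing, not
measured.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("reef_regimes.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def species_lookup() -> pd.DataFrame:
    """Species table: group, family, trophic level, length-weight a/b,
    typical total length, schooling and exclusion flags."""
    df = _read("species_lookup_synthetic.csv")
    df["schooling"] = df["schooling"].astype(bool)
    df["excluded"] = df["excluded"].astype(bool)
    return df


@lru_cache(maxsize=None)
def benthic_lookup() -> pd.DataFrame:
    """Benthic survey category -> one of the 5 cover groups."""
    return _read("benthic_lookup_synthetic.csv")


@lru_cache(maxsize=None)
def coral_traits() -> pd.DataFrame:
    """Coral species -> life-history trait class."""
    return _read("coral_traits.csv")


def length_weight_params() -> pd.DataFrame:
    """Length-weight coefficients (a, b) per species."""
    return species_lookup()[["species", "a", "b"]].copy()


def exclusion_list() -> pd.DataFrame:
    """Species excluded from biomass calculations (cryptic, nocturnal,
    pelagic-schooling taxa and manta rays), with the reason."""
    sp = species_lookup()
    return sp.loc[sp["excluded"], ["species", "exclusion_reason"]].reset_index(drop=True)
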