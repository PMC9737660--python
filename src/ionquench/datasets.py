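"""Packaged fixture tables.

Transcriptions of the scored per-species fluence/LET tables, the entrance
relative-efficiency table, and the published Birks parameter tables, for
regression-style comparisons.  These are fixtures, not computed outputs.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("ionquench.data").joinpath(name)


def load_fluence_let_tables() -> pd.DataFrame:
    """Scored per-species fluence (%) and LET_f (keV/um) rows per beam.

    Columns: beam, row_kind (entrance|plateau|peak|falloff), depth_mm,
    species, fluence_pct, let_kev_um.
    """
    with _data_path("tables_3_4_5.csv").open() as fh:
        return pd.read_csv(fh)


def load_entrance_efficiency() -> pd.DataFrame:
    """Relative luminescence efficiency at entrance per probe and beam."""
    with _data_path("table_2.csv").open() as fh:
        return pd.read_csv(fh)


def load_birks_tables() -> dict:
    """Published per-species Birks parameters keyed by species then probe."""
    with _data_path("tables_6_7_8.json").open() as fh:
        return json.load(fh)


def published_birks_params(probe: str):
    """Published (kB, RL0) fixture values as a params mapping for ``probe``.

    Returns ``{species: BirksParams}`` for H-1, He-4 and C-12.
    """
    from .quenching import BirksParams

    raw = load_birks_tables()
    out = {}
    for species, entry in raw.items():
        p = entry["probes"][probe]
        out[species] = BirksParams(
            species=species,
            kb_ug_per_mev_cm2=p["kb_ug_per_mev_cm2"],
            rl0=p["rl0"],
            let_range_mev_cm=tuple(entry["let_range_mev_cm"]),
            kb_stderr=p["kb_stderr"],
        )
    return out
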