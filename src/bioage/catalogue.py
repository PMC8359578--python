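"""Catalogue of automated 12-lead ECG measurements.

The GE MUSE system reports 639 automatically measured parameters per ECG.
Of these, 438 are retained for biological-age modelling (6 not lead-specific
plus 36 lead-specific measurements in each of the 12 leads); the remaining
201 are coordinate points or redundant recalculations and are excluded.
Lead-specific columns follow the ``<Parameter>__<Lead>`` naming convention
with leads I, II, III, aVR, aVL, aVF, V1-V6.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

LEADS = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass(frozen=True)
class Catalogue:
    """The full parameter catalogue with used/excluded status per column."""

    table: pd.DataFrame  # columns: parameter, lead, column, status

    @property
    def used_columns(self) -> list[str]:
        return self.table.loc[self.table["status"] == "used", "column"].tolist()

    @property
    def excluded_columns(self) -> list[str]:
        return self.table.loc[self.table["status"] == "excluded", "column"].tolist()

    @property
    def n_used(self) -> int:
        return int((self.table["status"] == "used").sum())

    @property
    def n_excluded(self) -> int:
        return int((self.table["status"] == "excluded").sum())

    def family(self, column: str) -> str:
        """Base parameter name (lead stripped) for a catalogue column."""
        row = self.table.loc[self.table["column"] == column]
        if row.empty:
            raise KeyError(f"column {column!r} not in catalogue")
        return str(row["parameter"].iloc[0])


def load_catalogue() -> Catalogue:
    """Load the packaged ECG parameter catalogue."""
    ref = resources.files("bioage").joinpath("data/parameter_catalogue.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", keep_default_na=False)
    return Catalogue(table=table)
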