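"""Repeated-record phenotype table.

One row per litter record: individual id, parity number, contemporary group
(farm-year-month analogue), period (integer time block used by the
whole/partial validation split), and the trait value.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

REQUIRED_COLUMNS = ("individual_id", "parity", "group", "period", "y")


@dataclass
class PhenotypeRecords:
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if self.df["y"].isna().any():
            raise ValueError("phenotype table contains missing trait values")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def individuals(self) -> pd.Index:
        return pd.Index(self.df["individual_id"].unique())

    def subset(self, mask) -> "PhenotypeRecords":
        return PhenotypeRecords(self.df.loc[mask].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeRecords":
        return cls(pd.read_csv(path, sep="\t"))
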