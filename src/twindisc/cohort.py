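"""Twin cohort bookkeeping: the sample <-> (pair, sibling) mapping."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from twindisc.errors import PairingError


@dataclass
class TwinCohort:
    """Maps each sample to its twin pair and sibling slot.

    ``pairs`` has columns ``sample_id``, ``pair_id``, ``sibling`` (1 or 2);
    every pair has exactly two samples, one per sibling slot.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.pairs
        required = {"sample_id", "pair_id", "sibling"}
        missing = required - set(df.columns)
        if missing:
            raise PairingError(f"pairing table missing columns {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            raise PairingError("duplicate sample_id in pairing table")
        if not df["sibling"].isin([1, 2]).all():
            raise PairingError("sibling must be 1 or 2")
        for pair_id, grp in df.groupby("pair_id"):
            if len(grp) != 2 or set(grp["sibling"]) != {1, 2}:
                raise PairingError(
                    f"pair {pair_id!r} must have exactly one sibling 1 and one sibling 2"
                )
        self.pairs = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.pairs["sample_id"])

    @property
    def pair_ids(self) -> list:
        return list(dict.fromkeys(self.pairs["pair_id"]))

    @property
    def n_pairs(self) -> int:
        return self.pairs["pair_id"].nunique()

    def pair_table(self) -> pd.DataFrame:
        """One row per pair: pair_id, sample1, sample2."""
        wide = self.pairs.pivot(index="pair_id", columns="sibling", values="sample_id")
        out = wide.rename(columns={1: "sample1", 2: "sample2"}).reset_index()
        # preserve first-appearance order of pairs
        order = {p: i for i, p in enumerate(self.pair_ids)}
        return out.sort_values("pair_id", key=lambda s: s.map(order)).reset_index(drop=True)

    def sibling_of(self, sample_id: str) -> str:
        """The co-twin of a sample."""
        row = self.pairs[self.pairs["sample_id"] == sample_id]
        if row.empty:
            raise PairingError(f"unknown sample {sample_id!r}")
        pair = self.pairs[self.pairs["pair_id"] == row["pair_id"].iloc[0]]
        other = pair[pair["sample_id"] != sample_id]
        return other["sample_id"].iloc[0]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TwinCohort":
        df = pd.read_csv(path, sep="\t")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)
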