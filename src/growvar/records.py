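"""Containers and text I/O for longitudinal weight records and SNP dosages.

The canonical on-disk layout for weight records is a long-format CSV with one
row per (fish, measurement age):

    fish_id,pond,hapa,sex,start_weight,age,weight

``pond`` takes the values ``aerated`` / ``non_aerated``, ``hapa`` is the
nursery net-cage (1-4), ``sex`` is ``male`` / ``female`` / ``unknown``.
Weights are grams, ages are days since stocking (stocking = day 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PONDS = ("aerated", "non_aerated")
SEXES = ("male", "female", "unknown")

RECORD_COLUMNS = ["fish_id", "pond", "hapa", "sex", "start_weight", "age", "weight"]


@dataclass
class WeightRecordSet:
    """Longitudinal weights plus covariates, one row per fish per age.

    Wraps a long-format :class:`pandas.DataFrame`.  Construction validates
    positivity of weights and strictly increasing ages within fish.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"weight records missing columns: {missing}")
        df = df[RECORD_COLUMNS].copy()
        if (df["weight"] <= 0).any():
            bad = df.loc[df["weight"] <= 0, "fish_id"].unique()[:5]
            raise ValueError(f"non-positive weights for fish {list(bad)}")
        if (df["age"] <= 0).any():
            raise ValueError("ages must be positive (stocking = day 1)")
        # ages strictly increasing within fish
        df = df.sort_values(["fish_id", "age"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(["fish_id", "age"])
        if dup.any():
            bad = df.loc[dup, "fish_id"].unique()[:5]
            raise ValueError(f"duplicate (fish, age) rows for fish {list(bad)}")
        self.data = df

    # -- basic accessors -------------------------------------------------
    @property
    def fish_ids(self) -> np.ndarray:
        return self.data["fish_id"].unique()

    @property
    def n_fish(self) -> int:
        return self.data["fish_id"].nunique()

    @property
    def ages(self) -> np.ndarray:
        return np.sort(self.data["age"].unique())

    def per_fish(self) -> pd.DataFrame:
        """One row per fish with the constant covariates."""
        cols = ["fish_id", "pond", "hapa", "sex", "start_weight"]
        return self.data[cols].drop_duplicates("fish_id").set_index("fish_id")

    def subset(self, fish_ids) -> "WeightRecordSet":
        keep = self.data["fish_id"].isin(np.asarray(fish_ids))
        return WeightRecordSet(self.data.loc[keep].reset_index(drop=True))

    def complete_cases(self, min_obs: int = 3) -> "WeightRecordSet":
        """Drop fish with fewer than ``min_obs`` retained records (logged)."""
        counts = self.data.groupby("fish_id").size()
        bad = counts.index[counts < min_obs]
        if len(bad):
            log.warning("excluding %d fish with < %d records", len(bad), min_obs)
        keep = self.data["fish_id"].isin(counts.index[counts >= min_obs])
        return WeightRecordSet(self.data.loc[keep].reset_index(drop=True))

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeightRecordSet":
        df = pd.read_csv(path)
        df["fish_id"] = df["fish_id"].astype(str)
        return cls(df)


def write_dosages(path, ids, dosages: np.ndarray) -> None:
    """Write a fish x SNP dosage matrix as TSV with an id header column."""
    dosages = np.asarray(dosages)
    with open(path, "w") as fh:
        fh.write("fish_id\t" + "\t".join(f"snp{j}" for j in range(dosages.shape[1])) + "\n")
        for i, fid in enumerate(ids):
            fh.write(str(fid) + "\t" + "\t".join(str(int(x)) if x == x else "NA" for x in dosages[i]) + "\n")


def read_dosages(path) -> tuple[list, np.ndarray]:
    """Read an ``id <tab> 0/1/2...`` dosage matrix; 'NA' becomes NaN."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    ids = df.iloc[:, 0].astype(str).tolist()
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    return ids, X
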