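"""Named genomic intervals (bins, genes, target regions).

A thin, validated wrapper around a pandas DataFrame with BED semantics:
0-based, half-open, columns (chrom, start, end, name).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd


@dataclass
class IntervalSet:
    df: pd.DataFrame  # columns: chrom, start, end, name

    def __post_init__(self) -> None:
        req = ["chrom", "start", "end"]
        missing = [c for c in req if c not in self.df.columns]
        if missing:
            raise ValueError(f"interval table missing columns {missing}")
        df = self.df.copy()
        if "name" not in df.columns:
            df["name"] = [f"iv{i}" for i in range(len(df))]
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']} (start >= end)"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], names: bool = True
    ) -> "IntervalSet":
        rows = list(records)
        if rows and len(rows[0]) >= 4:
            df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        else:
            df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(df)

    @classmethod
    def from_bed(cls, path: str) -> "IntervalSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "name"],
            dtype={0: str},
        )
        return cls(df)

    def to_bed(self, path: str) -> None:
        self.df[["chrom", "start", "end", "name"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def shifted(
        self, shift: int, chrom_lengths: Mapping[str, int] | None = None
    ) -> "IntervalSet":
        """Expand every interval by *shift* bp on both sides, clamping at 0
        and (when lengths are known) at the chromosome end."""
        df = self.df.copy()
        df["start"] = (df["start"] - shift).clip(lower=0)
        if chrom_lengths is not None:
            ends = df["chrom"].map(chrom_lengths)
            if ends.isna().any():
                unknown = df.loc[ends.isna(), "chrom"].iloc[0]
                raise KeyError(f"interval on unknown chromosome {unknown!r}")
            df["end"] = pd.concat([df["end"] + shift, ends], axis=1).min(axis=1).astype(int)
        else:
            df["end"] = df["end"] + shift
        return IntervalSet(df)
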