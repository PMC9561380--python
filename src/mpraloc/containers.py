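"""Shared in-memory containers for UMI-resolved MPRA counts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: recognised sample conditions
CONDITIONS = ("neurite", "soma", "t0", "t4", "t24")


@dataclass
class UmiCountMatrix:
    """Deduplicated UMI counts, variants x samples, plus a sample sheet.

    ``counts`` is indexed by variant_id with one column per sample_id;
    ``samples`` has columns sample_id, condition, replicate and one row per
    counts column.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.samples = self.samples.reset_index(drop=True)
        if list(self.counts.columns) != list(self.samples.sample_id):
            raise ValueError("counts columns must match sample sheet order")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate variant ids")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        bad = set(self.samples.condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {bad}")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_conditions(self, conditions) -> "UmiCountMatrix":
        keep = self.samples[self.samples.condition.isin(conditions)]
        return UmiCountMatrix(self.counts[list(keep.sample_id)].copy(), keep.copy())

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.rename_axis("variant_id").to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "UmiCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="variant_id")
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(counts[list(samples.sample_id)].astype(np.int64), samples)
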