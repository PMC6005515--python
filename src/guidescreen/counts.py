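"""Guide x sample count matrix with sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Non-negative integer guide counts plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of shape (guides, samples); index = guide ids,
        columns = sample names, values non-negative integers.
    samples
        DataFrame indexed by sample name with columns ``replicate``
        (str), ``arm`` (str) and ``day`` (int). Every count column must
        appear here.
    """

    counts: pd.DataFrame = field(repr=False)
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for c in ("replicate", "arm", "day"):
            if c not in self.samples.columns:
                raise ValueError(f"sample sheet missing column '{c}'")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples in counts absent from sample sheet: {missing}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("count matrix contains non-numeric values")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                "negative count at guide "
                f"'{self.counts.index[r]}', sample '{self.counts.columns[c]}'"
            )
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "guide_id"
        self.counts.columns.name = None
        self.samples = self.samples.loc[self.counts.columns].copy()
        self.samples["day"] = self.samples["day"].astype(int)

    @property
    def guide_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_guides(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def select_samples(self, *, arm: str | None = None, day: int | None = None,
                       replicate: str | None = None) -> list[str]:
        """Sample names matching the given metadata filters."""
        mask = pd.Series(True, index=self.samples.index)
        if arm is not None:
            mask &= self.samples["arm"] == arm
        if day is not None:
            mask &= self.samples["day"] == int(day)
        if replicate is not None:
            mask &= self.samples["replicate"] == replicate
        return list(self.samples.index[mask])

    def subset_guides(self, guide_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[guide_ids].copy(), self.samples.copy())

    def subset_samples(self, sample_names) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_names)].copy(),
            self.samples.loc[list(sample_names)].copy(),
        )

    # -- IO -------------------------------------------------------------

    def write(self, counts_path: str | Path, samplesheet_path: str | Path) -> None:
        """Write counts as TSV (first column guide id) and sample sheet as CSV."""
        self.counts.to_csv(counts_path, sep="\t", index_label="guide_id")
        self.samples.to_csv(samplesheet_path, index_label="sample")
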