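"""The guide library: the guide -> gene map with non-targeting-control flags."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Pseudo-gene label grouping all non-targeting control guides.
NTC_GENE = "NTC"

_COLUMNS = ["gene", "sequence", "is_ntc"]


@dataclass
class GuideLibrary:
    """Annotation of every guide in a pooled library.

    Parameters
    ----------
    table
        DataFrame indexed by unique ``guide_id`` with columns ``gene``
        (the target gene symbol, or ``"NTC"`` for non-targeting
        controls), ``sequence`` (spacer DNA, optional — may be empty
        strings), and ``is_ntc`` (bool).

    The library is the universe over which gene-level aggregation
    happens; guides absent from it are rejected by the IO layer.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"library table missing columns: {missing}")
        if not t.index.is_unique:
            dups = t.index[t.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate guide ids in library: {dups}")
        t["is_ntc"] = t["is_ntc"].astype(bool)
        # is_ntc must agree with the NTC pseudo-gene label
        mismatch = t["is_ntc"] != (t["gene"] == NTC_GENE)
        if mismatch.any():
            bad = t.index[mismatch].tolist()[:5]
            raise ValueError(
                f"is_ntc flag inconsistent with gene=='{NTC_GENE}' for: {bad}"
            )

    @property
    def guide_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_guides(self) -> int:
        return len(self.table)

    @property
    def n_ntc(self) -> int:
        return int(self.table["is_ntc"].sum())

    @property
    def genes(self) -> list[str]:
        """Targeted genes (excludes the NTC pseudo-gene), in first-seen order."""
        g = self.table.loc[~self.table["is_ntc"], "gene"]
        return list(dict.fromkeys(g))

    def guides_for(self, gene: str) -> pd.Index:
        return self.table.index[self.table["gene"] == gene]

    def gene_of(self) -> pd.Series:
        """guide_id -> gene mapping as a Series."""
        return self.table["gene"]

    # -- IO -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GuideLibrary":
        t = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "gene": str})
        if "guide_id" not in t.columns:
            raise ValueError(f"{path}: expected a 'guide_id' column")
        t = t.set_index("guide_id")
        if "sequence" not in t.columns:
            t["sequence"] = ""
        t["sequence"] = t["sequence"].fillna("").astype(str)
        if "is_ntc" not in t.columns:
            t["is_ntc"] = t["gene"] == NTC_GENE
        return cls(t[_COLUMNS].copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["is_ntc"] = out["is_ntc"].map({True: "true", False: "false"})
        out.to_csv(path, sep="\t", index_label="guide_id")
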