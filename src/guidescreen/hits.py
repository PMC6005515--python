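"""Gene-level aggregation, hit calling, cross-arm overlap, concordance."""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .library import NTC_GENE, GuideLibrary

log = logging.getLogger(__name__)


def gene_median_lfc(
    guide_stats: pd.DataFrame, library: GuideLibrary
) -> pd.DataFrame:
    """Median guide log2 fold-change per gene.

    ``guide_stats`` is indexed by guide id and must carry an ``lfc``
    column (as produced by the contrast fit); guides filtered out
    upstream are simply absent and do not contribute. Medians of an
    even number of guides use the midpoint of the two central values.
    Non-targeting controls are aggregated under the ``NTC`` pseudo-gene
    (reported for QC, excluded from hit sets downstream). Library genes
    with no surviving guides are omitted with a warning.

    Returns a DataFrame indexed by gene with ``n_guides`` and
    ``median_lfc``.
    """
    genes = library.gene_of().reindex(guide_stats.index)
    unknown = guide_stats.index[genes.isna()]
    if len(unknown):
        raise ValueError(f"guides absent from library: {list(unknown[:5])}")

    grouped = guide_stats["lfc"].groupby(genes)
    out = pd.DataFrame(
        {"n_guides": grouped.size(), "median_lfc": grouped.median()}
    )
    out.index.name = "gene"

    all_genes = set(library.genes) | ({NTC_GENE} if library.n_ntc else set())
    lost = all_genes - set(out.index)
    if lost:
        log.warning(
            "%d gene(s) have no surviving guides and are omitted (e.g. %s)",
            len(lost),
            sorted(lost)[:3],
        )
    return out


def call_hits(
    results: pd.DataFrame, cutoff: float = 1.0
) -> tuple[set[str], set[str]]:
    """Enriched / depleted gene sets at an absolute median-LFC cutoff.

    Strict inequalities: a gene at exactly the cutoff is not a hit
    (a ">2-fold" criterion maps to |median LFC| > 1). The NTC
    pseudo-gene is never a hit.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    med = results["median_lfc"].drop(index=NTC_GENE, errors="ignore")
    enriched = set(med.index[med > cutoff])
    depleted = set(med.index[med < -cutoff])
    return enriched, depleted


def arm_overlap(
    hits_by_arm: Mapping[str, tuple[set[str], set[str]]]
) -> pd.DataFrame:
    """Venn partition of hit genes across arms, per direction.

    For each direction (enriched / depleted) and each gene hit in at
    least one arm, reports which arms called it and whether it is
    shared by all arms or exclusive to one. Returns a tidy DataFrame
    with columns ``direction``, ``gene``, ``arms`` (comma-joined sorted
    arm labels) and ``category`` (``shared`` if hit in every arm,
    ``<arm>-exclusive`` if hit in exactly one, else ``partial``).
    """
    if len(hits_by_arm) < 2:
        raise ValueError("overlap needs at least two arms")
    arms = list(hits_by_arm)
    rows = []
    for direction, idx in (("enriched", 0), ("depleted", 1)):
        sets = {a: hits_by_arm[a][idx] for a in arms}
        for gene in sorted(set().union(*sets.values())):
            members = sorted(a for a in arms if gene in sets[a])
            if len(members) == len(arms):
                cat = "shared"
            elif len(members) == 1:
                cat = f"{members[0]}-exclusive"
            else:
                cat = "partial"
            rows.append((direction, gene, ",".join(members), cat))
    return pd.DataFrame(rows, columns=["direction", "gene", "arms", "category"])


def overlap_counts(partition: pd.DataFrame) -> pd.DataFrame:
    """Counts of genes per (direction, category) from :func:`arm_overlap`."""
    return (
        partition.groupby(["direction", "category"])
        .size()
        .rename("n_genes")
        .reset_index()
    )


def concordance_r2(lfc_a: pd.Series, lfc_b: pd.Series) -> float:
    """Squared Pearson correlation of two LFC profiles over shared guides.

    The screen-to-screen concordance statistic: invariant to affine
    rescaling of either profile (and to sign flips, as R-squared is).
    Requires at least 3 shared guides with finite values.
    """
    shared = lfc_a.index.intersection(lfc_b.index)
    a = lfc_a.loc[shared].to_numpy(dtype=float)
    b = lfc_b.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared guides with finite LFCs")
    r = np.corrcoef(a[ok], b[ok])[0, 1]
    return float(r**2)
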