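"""Reading, writing, FASTQ guide counting and the low-count guide filter."""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from Bio import SeqIO

from .counts import CountMatrix
from .library import GuideLibrary

log = logging.getLogger(__name__)


def read_counts(
    count_path: str | Path,
    samplesheet_path: str | Path,
    library_path: str | Path | GuideLibrary,
) -> CountMatrix:
    """Load and validate a count table against its sample sheet and library.

    Guides present in the count table but absent from the library are
    dropped with a warning; a count sample missing from the sample sheet
    or a malformed/negative cell is a hard error naming the offender.
    """
    library = (
        library_path
        if isinstance(library_path, GuideLibrary)
        else GuideLibrary.from_tsv(library_path)
    )
    raw = pd.read_csv(count_path, sep="\t", index_col=0)
    for col in raw.columns:
        bad = pd.to_numeric(raw[col], errors="coerce").isna()
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{count_path}: non-numeric count at guide '{row}', sample '{col}'"
            )
    samples = pd.read_csv(samplesheet_path, index_col=0)

    unknown = raw.index.difference(library.guide_ids)
    if len(unknown):
        log.warning(
            "%d guide(s) in counts absent from library; dropped (e.g. %s)",
            len(unknown),
            list(unknown[:3]),
        )
        raw = raw.drop(index=unknown)
    return CountMatrix(raw, samples)


def write_counts(matrix: CountMatrix, count_path: str | Path,
                 samplesheet_path: str | Path) -> None:
    matrix.write(count_path, samplesheet_path)


class FastqCounts(NamedTuple):
    """Per-guide counts from one FASTQ plus read-fate tallies."""

    counts: pd.Series
    n_reads: int
    n_ambiguous: int
    n_unmapped: int


def count_guides_from_fastq(
    fastq_path: str | Path,
    library: GuideLibrary,
    spacer_window: tuple[int, int] | None = None,
) -> FastqCounts:
    """Count reads per guide by exact spacer match (forward strand).

    Each read is scanned for an exact substring match of a guide's
    spacer; ``spacer_window`` restricts the allowed match start offsets
    to ``[start, stop)``. Reads matching two or more distinct guides are
    discarded as ambiguous; reads matching none are tallied unmapped.
    Amplicon reads have fixed structure, so no mismatches are tolerated.
    """
    seqs = library.table["sequence"]
    if (seqs == "").any():
        raise ValueError("library has guides without sequences")
    lengths = seqs.str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"guide sequences must have equal length, got {sorted(lengths)}")
    k = int(lengths[0])
    if seqs.duplicated().any():
        dup = seqs[seqs.duplicated()].iloc[0]
        raise ValueError(f"duplicate guide sequence in library: {dup}")
    lookup = {s: g for g, s in seqs.items()}

    counts = pd.Series(0, index=library.guide_ids, dtype=int)
    n_reads = n_amb = n_unmapped = 0
    path = Path(fastq_path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            n_reads += 1
            read = str(rec.seq).upper()
            lo, hi = (0, len(read)) if spacer_window is None else spacer_window
            hi = min(hi, len(read) - k + 1)
            hits = {
                lookup[read[i:i + k]]
                for i in range(max(lo, 0), hi)
                if read[i:i + k] in lookup
            }
            if len(hits) == 1:
                counts[hits.pop()] += 1
            elif len(hits) > 1:
                n_amb += 1
            else:
                n_unmapped += 1
    return FastqCounts(counts, n_reads, n_amb, n_unmapped)


def filter_low_count_guides(
    counts: CountMatrix, min_total: int = 10
) -> tuple[CountMatrix, list[str]]:
    """Discard guides with fewer than ``min_total`` reads summed over all samples.

    The threshold is strict: a guide totalling exactly ``min_total`` is
    retained. Returns the filtered matrix and the removed guide ids.
    """
    totals = counts.counts.sum(axis=1)
    keep = totals >= min_total
    removed = list(counts.counts.index[~keep])
    kept = CountMatrix(counts.counts.loc[keep].copy(), counts.samples.copy())
    if removed:
        log.info("filtered %d guide(s) with total < %d reads", len(removed), min_total)
    return kept, removed
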