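"""End-to-end screen pipeline: filter -> normalize/test -> aggregate -> overlap."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from ._version import __version__
from .config import RunConfig
from .counts import CountMatrix
from .diffexp import differential_abundance
from .hits import arm_overlap, call_hits, gene_median_lfc, overlap_counts
from .io import filter_low_count_guides, read_counts
from .library import GuideLibrary

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _config_hash(config: RunConfig) -> str:
    # analysis parameters only: where files live must not change the hash
    d = asdict(config)
    for key in ("library_path", "counts_path", "samplesheet_path", "output_dir"):
        d.pop(key, None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_screen_pipeline(
    config: RunConfig,
    library: GuideLibrary | None = None,
    counts: CountMatrix | None = None,
) -> dict:
    """Run the full analysis and write its artifacts to ``output_dir``.

    Stages: load inputs, drop low-total guides, per-guide differential
    abundance for every drug arm vs the control arm at the analysis
    day, gene-level median-LFC aggregation, hit calling at each
    configured cutoff, and (with >= 2 drug arms) the cross-arm overlap
    partition. Writes ``guide_stats_<arm>.tsv``, ``gene_results.tsv``,
    ``hits_<cutoff>.tsv``, ``overlap.tsv`` and a ``manifest.json``
    recording config hash, seed, version and guide counts per stage.
    Identical config + inputs produce byte-identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if library is None:
            library = GuideLibrary.from_tsv(config.library_path)
        if counts is None:
            counts = read_counts(
                config.counts_path, config.samplesheet_path, library
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    n_in = counts.n_guides
    try:
        counts, removed = filter_low_count_guides(counts, config.min_total)
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter", exc) from exc
    assert n_in == counts.n_guides + len(removed), "stage guide counts not conserved"

    arms = [a for a in counts.samples["arm"].unique() if a != config.control_arm]
    if not arms:
        raise StageError("test", ValueError("no drug arm in sample sheet"))
    if config.analysis_day not in set(counts.samples["day"]):
        raise StageError(
            "test", ValueError(f"analysis day {config.analysis_day} not in sample sheet")
        )

    guide_stats: dict[str, pd.DataFrame] = {}
    gene_results: dict[str, pd.DataFrame] = {}
    hits: dict[str, dict[float, tuple[set, set]]] = {}
    for arm in arms:
        try:
            gs = differential_abundance(
                counts,
                library,
                treat_arm=arm,
                control_arm=config.control_arm,
                day=config.analysis_day,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"test[{arm}]", exc) from exc
        guide_stats[arm] = gs
        gr = gene_median_lfc(gs, library)
        gene_results[arm] = gr
        hits[arm] = {c: call_hits(gr, c) for c in config.hit_cutoffs}

        cols = ["gene", "lfc", "t_mod", "p", "fdr", "mean_log_cpm"]
        gs[cols].to_csv(out / f"guide_stats_{arm}.tsv", sep="\t", index_label="guide_id")

    gene_table = pd.concat(
        {a: r["median_lfc"] for a, r in gene_results.items()}, axis=1
    )
    gene_table.columns = [f"median_lfc_{a}" for a in gene_results]
    gene_table.insert(0, "n_guides", next(iter(gene_results.values()))["n_guides"])
    for c in config.hit_cutoffs:
        for a in arms:
            enr, dep = hits[a][c]
            gene_table[f"hit_{a}_at_{c:g}"] = [
                "enriched" if g in enr else "depleted" if g in dep else "none"
                for g in gene_table.index
            ]
    gene_table.sort_index().to_csv(out / "gene_results.tsv", sep="\t", index_label="gene")

    if len(arms) >= 2:
        for c in config.hit_cutoffs:
            part = arm_overlap({a: hits[a][c] for a in arms})
            part.to_csv(out / f"overlap_at_{c:g}.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "control_arm": config.control_arm,
        "analysis_day": config.analysis_day,
        "arms": list(arms),
        "n_guides_in": int(n_in),
        "n_guides_filtered": int(len(removed)),
        "n_guides_tested": int(counts.n_guides),
        "hit_counts": {
            a: {
                f"{c:g}": {"enriched": len(hits[a][c][0]), "depleted": len(hits[a][c][1])}
                for c in config.hit_cutoffs
            }
            for a in arms
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "guide_stats": guide_stats,
        "gene_results": gene_results,
        "hits": hits,
        "manifest": manifest,
    }
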