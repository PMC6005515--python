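"""Bliss-style drug x gene combination scoring.

The interaction statistic works on fraction inhibition
``f = control / treatment`` (>1 means the treatment suppressed growth).
Under Bliss independence the combined effect of a gene knockout and a
drug is multiplicative, ``f_combo_predicted = f_guide * f_drug``; the
combination score is the gap ``delta = f_combo_observed -
f_combo_predicted``. Positive delta means the knockout and the drug
kill more than multiplicatively (a sensitizer), negative delta a rescue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .library import NTC_GENE, GuideLibrary

log = logging.getLogger(__name__)


def fraction_inhibition(
    control_value: float, treatment_value: float, floor: float | None = None
) -> float:
    """Fraction inhibition ``f = control / treatment``.

    f = 1 means no effect, f > 1 inhibition. A non-positive treatment
    value is an error unless ``floor`` is given, in which case the value
    is clamped to the floor (callers flag such scores as censored).
    """
    if control_value <= 0:
        raise ValueError("control value must be positive")
    if treatment_value <= 0:
        if floor is None:
            raise ValueError(
                f"non-positive treatment value {treatment_value} (no floor configured)"
            )
        treatment_value = floor
    return control_value / treatment_value


@dataclass
class CombinationScore:
    """Observed-vs-predicted fraction-inhibition gap for one unit.

    ``f_combo_predicted`` is exactly ``f_guide * f_drug`` and ``delta``
    exactly ``f_combo_observed - f_combo_predicted``. ``censored`` marks
    scores where a non-positive well value was clamped to the floor.
    """

    unit_id: str
    f_guide: float
    f_drug: float
    f_combo_observed: float
    passage: int | None = None
    censored: bool = False
    f_combo_predicted: float = field(init=False)
    delta: float = field(init=False)

    def __post_init__(self) -> None:
        self.f_combo_predicted = self.f_guide * self.f_drug
        self.delta = self.f_combo_observed - self.f_combo_predicted


def combo_score(
    ntc_vehicle: float,
    guide_vehicle: float,
    ntc_drug: float,
    guide_drug: float,
    unit_id: str = "",
    passage: int | None = None,
    floor: float | None = None,
) -> CombinationScore:
    """Score one guide from its four condition values (replicate-averaged).

    f_guide = ntc_vehicle / guide_vehicle (knockout effect alone),
    f_drug = ntc_vehicle / ntc_drug (drug effect alone),
    f_combo_observed = ntc_vehicle / guide_drug.
    """
    censored = any(
        v <= 0 for v in (guide_vehicle, ntc_drug, guide_drug)
    )
    if censored and floor is None:
        raise ValueError(
            f"non-positive condition value for '{unit_id}' (no floor configured)"
        )
    return CombinationScore(
        unit_id=unit_id,
        passage=passage,
        f_guide=fraction_inhibition(ntc_vehicle, guide_vehicle, floor),
        f_drug=fraction_inhibition(ntc_vehicle, ntc_drug, floor),
        f_combo_observed=fraction_inhibition(ntc_vehicle, guide_drug, floor),
        censored=censored,
    )


@dataclass
class ArrayedPlate:
    """Arrayed viability wells: one guide (or NTC) per well x condition x passage.

    ``wells`` columns: ``well``, ``guide_id``, ``condition`` (``vehicle``
    or ``drug``), ``passage`` (int), ``value`` (luminescence / count
    scale). NTC wells carry ``ntc_id`` as their guide id.
    """

    wells: pd.DataFrame = field(repr=False)
    ntc_id: str = "NTC"

    def __post_init__(self) -> None:
        required = {"guide_id", "condition", "passage", "value"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        bad = set(self.wells["condition"]) - {"vehicle", "drug"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        self.wells = self.wells.copy()
        self.wells["passage"] = self.wells["passage"].astype(int)
        self.wells["value"] = self.wells["value"].astype(float)

    @property
    def passages(self) -> list[int]:
        return sorted(self.wells["passage"].unique())

    def cell_means(self) -> pd.DataFrame:
        """Replicate wells averaged per (guide, condition, passage)."""
        return (
            self.wells.groupby(["guide_id", "condition", "passage"])["value"]
            .mean()
            .rename("value")
            .reset_index()
        )

    @classmethod
    def from_csv(cls, path: str | Path, ntc_id: str = "NTC") -> "ArrayedPlate":
        return cls(pd.read_csv(path), ntc_id=ntc_id)

    def to_csv(self, path: str | Path) -> None:
        self.wells.to_csv(path, index=False)


def score_arrayed_assay(
    plate: ArrayedPlate,
    gene_map: Mapping[str, str] | GuideLibrary,
    floor: float | None = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combination scores per guide per passage, plus per-gene means.

    Replicate wells are averaged per (guide, condition, passage) before
    any ratio is taken. A passage missing either NTC cell is skipped
    with a warning. The per-gene value at each passage is the
    arithmetic mean of its guides' deltas; returns
    ``(per_guide, gene_by_passage)`` where the latter is a
    heat-map-ready gene x passage table of mean deltas.

    ``floor="auto"`` censors non-positive cell means at half the
    smallest positive well value on the plate; ``floor=None`` makes
    them an error.
    """
    if isinstance(gene_map, GuideLibrary):
        gene_map = gene_map.gene_of().to_dict()
    if floor == "auto":
        pos = plate.wells.loc[plate.wells["value"] > 0, "value"]
        floor = float(pos.min()) / 2.0 if len(pos) else None

    cells = plate.cell_means().set_index(["guide_id", "condition", "passage"])[
        "value"
    ]
    guides = sorted(set(plate.wells["guide_id"]) - {plate.ntc_id})

    rows = []
    for passage in plate.passages:
        try:
            ntc_veh = cells[(plate.ntc_id, "vehicle", passage)]
            ntc_drug = cells[(plate.ntc_id, "drug", passage)]
        except KeyError:
            log.warning("passage %d lacks an NTC cell; skipped", passage)
            continue
        for g in guides:
            try:
                gv = cells[(g, "vehicle", passage)]
                gd = cells[(g, "drug", passage)]
            except KeyError:
                continue
            sc = combo_score(
                ntc_veh, gv, ntc_drug, gd, unit_id=g, passage=passage, floor=floor
            )
            rows.append(
                (
                    g,
                    gene_map.get(g, g),
                    passage,
                    sc.f_guide,
                    sc.f_drug,
                    sc.f_combo_observed,
                    sc.f_combo_predicted,
                    sc.delta,
                    sc.censored,
                )
            )
    per_guide = pd.DataFrame(
        rows,
        columns=[
            "guide_id",
            "gene",
            "passage",
            "f_guide",
            "f_drug",
            "f_combo_observed",
            "f_combo_predicted",
            "delta",
            "censored",
        ],
    )
    gene_by_passage = per_guide.pivot_table(
        index="gene", columns="passage", values="delta", aggfunc="mean"
    )
    return per_guide, gene_by_passage


def pooled_combo_score(
    counts: CountMatrix,
    library: GuideLibrary,
    guide: str,
    arm: str,
    day: int = 21,
    control_arm: str = "vehicle",
    floor: float | None = "auto",
) -> CombinationScore:
    """Combination score for one guide from pooled screen counts.

    Counts are converted to CPM and averaged across replicates. Because
    pooled abundances are compositional, each trajectory is expressed
    as growth relative to the shared day-0 reference: the "well value"
    of a guide in an arm is ``cpm(arm, day) / cpm(day 0)``, and the
    no-guide reference is the aggregate CPM of all non-targeting
    controls treated the same way. The four values then feed the same
    formulas as the arrayed assay. For the NTC pseudo-guide the score
    is identically zero by construction.
    """
    cpm = counts.counts / counts.counts.sum(axis=0) * 1e6

    def cell(guide_id: str, a: str, d: int) -> float:
        samps = counts.select_samples(arm=a, day=d) if d != 0 else counts.select_samples(day=0)
        if not samps:
            raise ValueError(f"no samples for arm '{a}' day {d}")
        if guide_id == NTC_GENE:
            ntc = library.table.index[library.table["is_ntc"]]
            return float(cpm.loc[ntc, samps].sum(axis=0).mean())
        if guide_id not in cpm.index:
            raise KeyError(f"guide '{guide_id}' absent from counts")
        return float(cpm.loc[guide_id, samps].mean())

    if floor == "auto":
        pos = cpm.to_numpy()
        pos = pos[pos > 0]
        floor = float(pos.min()) / 2.0 if pos.size else None

    ntc_ref0 = cell(NTC_GENE, control_arm, 0)
    g0 = cell(guide, control_arm, 0)
    ntc_vehicle = cell(NTC_GENE, control_arm, day) / ntc_ref0
    ntc_drug = cell(NTC_GENE, arm, day) / ntc_ref0
    if g0 <= 0:
        if floor is None:
            raise ValueError(f"guide '{guide}' absent at day 0")
        g0 = floor
    guide_vehicle = cell(guide, control_arm, day) / g0
    guide_drug = cell(guide, arm, day) / g0
    return combo_score(
        ntc_vehicle,
        guide_vehicle,
        ntc_drug,
        guide_drug,
        unit_id=guide,
        floor=floor,
    )
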