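"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the simulated pooled screen.

    Defaults mirror a druggable-genome knockout screen: 2194 genes with
    8 guides each plus 40 non-targeting controls, three independent
    replicate infections maintained at 1000x coverage, sampled at days
    0, 4, 7, 14 and 21 under a vehicle arm and two drug arms.

    Attributes
    ----------
    coverage
        Expected reads per guide per sample (sequencing depth is
        ``coverage * n_guides``).
    dispersion
        Negative-binomial dispersion of sequencing counts;
        variance = mu + dispersion * mu**2. 0 gives Poisson counts.
    bottleneck_cells_per_guide
        Expected cells per guide at infection; the day-0 guide
        distribution is multinomially sampled from this many cells.
        ``inf`` disables the bottleneck (exactly uniform start).
    """

    n_genes: int = 2194
    guides_per_gene: int = 8
    n_ntc: int = 40
    n_replicates: int = 3
    arms: tuple[str, ...] = ("vehicle", "MEKi", "ERKi")
    days: tuple[int, ...] = (0, 4, 7, 14, 21)
    coverage: float = 1000.0
    dispersion: float = 0.05
    bottleneck_cells_per_guide: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1:
            raise ValueError("n_genes and guides_per_gene must be positive")
        if self.n_ntc < 0:
            raise ValueError("n_ntc must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if len(self.arms) < 1:
            raise ValueError("at least one arm (the control) is required")
        days = tuple(int(d) for d in self.days)
        if days[0] != 0:
            raise ValueError("first day must be 0 (the reference sample)")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        self.days = days
        self.arms = tuple(self.arms)
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.bottleneck_cells_per_guide <= 0:
            raise ValueError("bottleneck_cells_per_guide must be > 0")

    @property
    def control_arm(self) -> str:
        return self.arms[0]

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.guides_per_gene + self.n_ntc

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["arms"] = list(d["arms"])
        d["days"] = list(d["days"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class EffectTable:
    """Planted per-gene growth effects, in log2 doublings per day.

    ``phi[gene]`` is a base fitness offset applied in every arm (a gene
    whose knockout slows growth regardless of drug). ``delta[(gene, arm)]``
    is the drug x gene interaction: an extra growth offset applied only
    in that drug arm (negative = sensitizer, guides deplete under drug).
    ``gamma[arm]`` is a whole-population growth penalty of the drug
    itself. Genes absent from ``phi``/``delta`` default to zero; NTC
    guides always have zero effect.
    """

    phi: dict[str, float] = field(default_factory=dict)
    delta: dict[tuple[str, str], float] = field(default_factory=dict)
    gamma: dict[str, float] = field(default_factory=dict)

    def rate(self, gene: str, arm: str, is_ntc: bool, control_arm: str) -> float:
        """Total log2 growth-rate offset per day for a guide's cells."""
        if is_ntc:
            return float(self.gamma.get(arm, 0.0))
        d = 0.0 if arm == control_arm else self.delta.get((gene, arm), 0.0)
        return float(self.phi.get(gene, 0.0) + d + self.gamma.get(arm, 0.0))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``analysis_day`` is the harvest timepoint for the treatment-vs-
    control contrast (day 21 by default). ``hit_cutoffs`` are the
    absolute median-LFC thresholds at which gene hit sets are reported.
    """

    library_path: str = "library.tsv"
    counts_path: str = "counts.tsv"
    samplesheet_path: str = "samples.csv"
    output_dir: str = "results"
    analysis_day: int = 21
    control_arm: str = "vehicle"
    hit_cutoffs: tuple[float, ...] = (1.0, 0.5)
    min_total: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.hit_cutoffs = tuple(float(c) for c in self.hit_cutoffs)
        if any(c <= 0 for c in self.hit_cutoffs):
            raise ValueError("hit cutoffs must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["hit_cutoffs"] = list(d["hit_cutoffs"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
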