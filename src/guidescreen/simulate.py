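"""Synthetic pooled-screen and arrayed-plate generators with known truth.

The pooled generator plants per-gene growth effects (log2 doublings per
day) into an exponential-growth model, passes the library through a
multinomial infection bottleneck, and draws sequencing counts from a
negative-binomial with a single global dispersion. The arrayed generator
produces viability plates whose true Bliss-style combination score is an
input, so recovery can be checked exactly.
"""

from __future__ import annotations

import hashlib
from typing import Mapping

import numpy as np
import pandas as pd

from .combo import ArrayedPlate
from .config import EffectTable, SimulationConfig
from .counts import CountMatrix
from .library import NTC_GENE, GuideLibrary

_BASES = np.array(list("ACGT"))


def _stream(seed: int, *names) -> np.random.Generator:
    """Named RNG stream: independent of the order other streams are drawn.

    Each stream is keyed by the global seed plus a hash of its name
    parts, so adding arms/replicates/days never shifts the draws of
    existing streams.
    """
    digest = hashlib.sha256(("/".join(map(str, names))).encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def simulate_library(config: SimulationConfig) -> GuideLibrary:
    """Build a synthetic guide library per the configured geometry.

    Returns ``n_genes * guides_per_gene`` targeting guides (genes named
    ``GENE0001`` ...) plus ``n_ntc`` non-targeting controls, each with a
    unique random 20-nt spacer.
    """
    rng = _stream(config.seed, "library")
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    ids, gene_col, ntc_col = [], [], []
    for g in genes:
        for j in range(config.guides_per_gene):
            ids.append(f"{g}_g{j + 1}")
            gene_col.append(g)
            ntc_col.append(False)
    for j in range(config.n_ntc):
        ids.append(f"NTC_g{j + 1}")
        gene_col.append(NTC_GENE)
        ntc_col.append(True)

    n = len(ids)
    seqs: set[str] = set()
    seq_col = []
    while len(seq_col) < n:
        s = "".join(rng.choice(_BASES, size=20))
        if s not in seqs:
            seqs.add(s)
            seq_col.append(s)
    table = pd.DataFrame(
        {"gene": gene_col, "sequence": seq_col, "is_ntc": ntc_col},
        index=pd.Index(ids, name="guide_id"),
    )
    return GuideLibrary(table)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with variance mu + dispersion * mu**2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0.0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.shape) * mu / shape, 0.0)
    return rng.poisson(lam)


def simulate_screen(
    library: GuideLibrary,
    effects: EffectTable,
    config: SimulationConfig,
) -> CountMatrix:
    """Simulate guide counts across replicates, arms and days.

    For replicate ``r`` the starting guide fractions ``p(0)`` are drawn
    once from a multinomial bottleneck of
    ``bottleneck_cells_per_guide * n_guides`` cells (infinite bottleneck
    gives a uniform start) and shared by every arm — the day-0 sample of
    a replicate is sequenced once and serves all arms as the reference.
    At day ``t`` the expected relative abundance of guide ``g`` in arm
    ``a`` is proportional to ``p_g(0) * 2**(rate_g_a * t)`` where the
    rate is the sum of the gene's base fitness, its drug interaction in
    that arm, and the arm's drug growth penalty. Counts are
    negative-binomial with mean ``coverage * n_guides * p_g(t)``.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    if config.dispersion < 0:
        raise ValueError("dispersion must be >= 0")

    tab = library.table
    n = len(tab)
    depth = config.coverage * n
    control = config.control_arm

    # per-guide growth rate for each arm (log2 / day)
    rates = {
        arm: np.array(
            [
                effects.rate(g, arm, ntc, control)
                for g, ntc in zip(tab["gene"], tab["is_ntc"])
            ]
        )
        for arm in config.arms
    }

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for r in range(1, config.n_replicates + 1):
        rep = f"rep{r}"
        if np.isinf(config.bottleneck_cells_per_guide):
            p0 = np.full(n, 1.0 / n)
        else:
            cells = _stream(config.seed, "bottleneck", rep).multinomial(
                int(round(config.bottleneck_cells_per_guide * n)),
                np.full(n, 1.0 / n),
            )
            p0 = cells / cells.sum()

        name0 = f"{rep}_{control}_d0"
        cols[name0] = _nb_counts(
            _stream(config.seed, "counts", rep, "d0"), depth * p0, config.dispersion
        )
        meta_rows.append((name0, rep, control, 0))

        for arm in config.arms:
            for day in config.days[1:]:
                w = p0 * np.exp2(rates[arm] * day)
                p = w / w.sum()
                name = f"{rep}_{arm}_d{day}"
                cols[name] = _nb_counts(
                    _stream(config.seed, "counts", rep, arm, day),
                    depth * p,
                    config.dispersion,
                )
                meta_rows.append((name, rep, arm, day))

    counts = pd.DataFrame(cols, index=tab.index)
    samples = pd.DataFrame(
        meta_rows, columns=["sample", "replicate", "arm", "day"]
    ).set_index("sample")
    return CountMatrix(counts, samples)


def simulate_plate(
    f_guide_true: Mapping[str, float],
    f_drug_true: float,
    bliss_gap: Mapping[str, float] | float,
    noise_cv: float,
    seed: int = 0,
    *,
    passages: tuple[int, ...] = (1, 2, 3, 4),
    n_wells: int = 3,
    ntc_id: str = "NTC",
) -> ArrayedPlate:
    """Simulate an arrayed viability plate with a planted combination score.

    Well means are set so that, noise-free, downstream scoring recovers
    exactly ``f_guide_true``, ``f_drug_true`` and a combination score
    (observed minus Bliss-predicted fraction inhibition) equal to
    ``bliss_gap`` for every guide at every passage: NTC/vehicle wells
    have mean 1, guide/vehicle ``1/f_guide``, NTC/drug ``1/f_drug`` and
    guide/drug ``1/(f_guide*f_drug + gap)``. Multiplicative lognormal
    noise with coefficient of variation ``noise_cv`` is applied per well.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if f_drug_true <= 0:
        raise ValueError("f_drug_true must be > 0")
    gaps = (
        dict(bliss_gap)
        if isinstance(bliss_gap, Mapping)
        else {g: float(bliss_gap) for g in f_guide_true}
    )
    means: dict[tuple[str, str], float] = {(ntc_id, "vehicle"): 1.0,
                                           (ntc_id, "drug"): 1.0 / f_drug_true}
    for g, fg in f_guide_true.items():
        if fg <= 0:
            raise ValueError(f"f_guide_true for {g} must be > 0")
        combo = fg * f_drug_true + gaps.get(g, 0.0)
        if combo <= 0:
            raise ValueError(
                f"bliss_gap for {g} implies non-positive combined inhibition"
            )
        means[(g, "vehicle")] = 1.0 / fg
        means[(g, "drug")] = 1.0 / combo

    rng = _stream(seed, "plate")
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for passage in passages:
        for (guide, cond), mu in means.items():
            for w in range(n_wells):
                noise = (
                    1.0
                    if noise_cv == 0
                    else np.exp(rng.normal(-sigma**2 / 2, sigma))
                )
                rows.append((f"{guide}_{cond}_p{passage}_w{w + 1}",
                             guide, cond, passage, mu * noise))
    wells = pd.DataFrame(
        rows, columns=["well", "guide_id", "condition", "passage", "value"]
    )
    return ArrayedPlate(wells, ntc_id=ntc_id)
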