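"""Stochastic early-S origin-firing simulator under hydroxyurea arrest.

The model embodies the limiting-initiator picture of budding-yeast origin
control: cells license many origins, but a small pool of the rate-limiting
activator DDK allows only ``pool_size`` of them to fire at the start of
S phase. Two recruitment pathways bias which origins win the competition:

* Fkh1/2 bind directly at Fkh-activated origins and multiply their firing
  weight by ``fkh_boost``;
* the Ctf19 kinetochore pathway recruits DDK to centromeres, boosting
  nearby origins with a factor that decays linearly from ``cen_boost`` at
  the centromere to 1 at ``cen_range`` (~25 kb).

Dbf4 alleles modulate the pathways: the Zn-finger point mutant (``Zn*``)
abolishes the CEN pathway while leaving Fkh targeting intact (plus a mild
global efficiency cost); the C-terminal truncation (``dC``) is a strong
hypomorph that loses the CEN pathway and retains only part of the Fkh boost.

Fired origins replicate bidirectionally at HU-slowed fork speed ``v`` for
``T`` minutes, additionally limited by a shared per-cell synthesis budget
(HU depletes dNTPs, so the more forks a cell runs the shorter each travels):
per-side extent = min(v*T, budget / (2 * fired)). BrdU incorporation (QBU)
is read out as the per-bin replicated-cell fraction with Poisson sampling
noise; Dbf4 ChIP tracks are background plus Gaussian enrichment at CENs and,
weaker, at CEN-proximal origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import BinnedTrack, GenomeBuild, GenomicInterval
from .origins import Centromere, Origin, OriginSet, distance_to_nearest_cen
from .preprocess import ReplicateSet

__all__ = [
    "Genotype",
    "GENOTYPES",
    "SimConfig",
    "CellOutcome",
    "SimFixture",
    "build_sim_fixture",
    "assign_firing_weights",
    "simulate_cells",
    "brdu_track",
    "dbf4_chip_track",
    "simulate_experiment",
]


@dataclass(frozen=True)
class Genotype:
    """Pathway on/off switches plus the Dbf4 allele.

    ``dbf4_allele``: "WT", "Zn*" (Zn-finger point mutant) or "dC"
    (C-terminal truncation). Both mutant alleles force the CEN-recruitment
    pathway off regardless of ``ctf19``; ``dC`` additionally attenuates the
    Fkh boost (a partial loss, see ``SimConfig.dc_fkh_retention``) and both
    apply a global efficiency multiplier.
    """

    fkh1: bool = True
    fkh2: bool = True
    ctf19: bool = True
    dbf4_allele: str = "WT"

    def __post_init__(self) -> None:
        if self.dbf4_allele not in ("WT", "Zn*", "dC"):
            raise ValueError(f"unknown dbf4 allele {self.dbf4_allele!r}")

    @property
    def cen_pathway_active(self) -> bool:
        return self.ctf19 and self.dbf4_allele == "WT"


#: The strain panel studied in the experiments this simulator emulates.
GENOTYPES: dict[str, Genotype] = {
    "WT": Genotype(),
    "ctf19∆": Genotype(ctf19=False),
    "dbf4-Zn*": Genotype(dbf4_allele="Zn*"),
    "fkh1∆": Genotype(fkh1=False),
    "fkh1∆ fkh2-dsm": Genotype(fkh1=False, fkh2=False),
    "dbf4∆C": Genotype(dbf4_allele="dC"),
}


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters; defaults define the study conditions.

    The toy genome (16 x 300 kb, origins every 30 kb, one mid-chromosome
    centromere each) keeps runs at seconds scale while preserving the
    yeast-like layout the classifiers expect.
    """

    # genome / annotation layout
    chrom_count: int = 16
    chrom_length: int = 300_000
    bin_width: int = 50
    origin_spacing: int = 30_000
    cen_offset: int = 150_000
    base_eff_range: tuple[float, float] = (0.1, 0.4)
    fkh_positions: tuple[int, ...] = (1, 3, 7)   # per-chromosome origin indices
    fkh1_sensitive_positions: tuple[int, ...] = (3,)
    # pathway effect sizes
    fkh_boost: float = 3.0
    cen_boost: float = 4.0
    cen_range: float = 25_000.0
    dc_fkh_retention: float = 0.3
    global_multiplier: dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "Zn*": 0.8, "dC": 0.4}
    )
    # firing and fork dynamics
    pool_size: int = 10
    fork_speed: float = 100.0          # bp/min under HU
    duration_min: float = 60.0
    duration_dc_min: float = 90.0      # dC strains are held in HU longer
    synthesis_budget_bp: float = 120_000.0  # per-cell dNTP budget
    exponential_firing_times: bool = False
    # readout
    cells: int = 2000
    read_depth: float = 100.0
    overdispersion: float = 0.0        # gamma-Poisson mixing (0 = pure Poisson)
    # Dbf4 ChIP model
    chip_background: float = 1.0
    chip_cen_amp: float = 4.0
    chip_prox_amp: float = 1.0
    chip_sigma_bp: float = 400.0
    chip_zn_factor: float = 0.3
    chip_depth: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 0 or self.fork_speed < 0 or self.duration_min <= 0:
            raise ValueError("pool_size, fork_speed must be >= 0 and duration > 0")
        lo, hi = self.base_eff_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("base efficiencies must lie in (0, 1]")

    def duration_for(self, genotype: Genotype) -> float:
        return self.duration_dc_min if genotype.dbf4_allele == "dC" else self.duration_min


@dataclass(frozen=True)
class CellOutcome:
    """Firing outcome of one cell: fired origins and replicated intervals."""

    fired: tuple[int, ...]                      # origin indices
    firing_times: tuple[float, ...]
    intervals: tuple[tuple[str, int, int], ...]  # merged, per chromosome

    @property
    def replicated_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


@dataclass
class SimFixture:
    """Genome + annotations + per-origin base efficiencies for one config."""

    genome: GenomeBuild
    origin_set: OriginSet
    centromeres: list[Centromere]
    base_efficiency: np.ndarray  # aligned with origin_set.origins


def build_sim_fixture(config: SimConfig, rng: np.random.Generator | None = None) -> SimFixture:
    """Lay out the toy genome, origins, centromeres and base efficiencies.

    Base efficiencies are drawn once from U(base_eff_range) using the
    config seed (or a supplied generator), so a config fully determines its
    fixture.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = tuple(f"chr{i + 1:02d}" for i in range(config.chrom_count))
    genome = GenomeBuild(names, (config.chrom_length,) * config.chrom_count)
    origins: list[Origin] = []
    cens: list[Centromere] = []
    per_chrom = config.chrom_length // config.origin_spacing
    for ci, chrom in enumerate(names):
        cens.append(Centromere(chrom, config.cen_offset, f"CEN{ci + 1}"))
        for oi in range(per_chrom):
            mid = config.origin_spacing // 2 + oi * config.origin_spacing
            iv = GenomicInterval(chrom, mid - 100, mid + 100,
                                 name=f"ARS{ci + 1:02d}{oi:02d}")
            origins.append(
                Origin(
                    interval=iv,
                    name=iv.name,
                    confirmed=True,
                    fkh_activated=oi in config.fkh_positions,
                    fkh1_sensitive=oi in config.fkh1_sensitive_positions,
                )
            )
    base = rng.uniform(*config.base_eff_range, size=len(origins))
    return SimFixture(genome, OriginSet(origins), cens, base)


def _fkh_boost_factor(origin: Origin, genotype: Genotype, config: SimConfig) -> float:
    """Fkh-pathway multiplier for one origin.

    Fkh1-sensitive origins need Fkh1 specifically; the remaining
    Fkh-activated origins are stimulated by either Fkh1 or Fkh2. The dC
    allele retains only ``dc_fkh_retention`` of the boost above baseline.
    """
    if not origin.fkh_activated:
        return 1.0
    if origin.fkh1_sensitive:
        pathway_on = genotype.fkh1
    else:
        pathway_on = genotype.fkh1 or genotype.fkh2
    if not pathway_on:
        return 1.0
    boost = config.fkh_boost
    if genotype.dbf4_allele == "dC":
        boost = 1.0 + (boost - 1.0) * config.dc_fkh_retention
    return boost


def _cen_boost_factor(dist: float, genotype: Genotype, config: SimConfig) -> float:
    if not genotype.cen_pathway_active or dist > config.cen_range:
        return 1.0
    return 1.0 + (config.cen_boost - 1.0) * (1.0 - dist / config.cen_range)


def assign_firing_weights(
    origin_set: OriginSet,
    cens: list[Centromere],
    genotype: Genotype,
    config: SimConfig,
    base_efficiency: np.ndarray | Sequence[float],
) -> np.ndarray:
    """Per-origin firing weight: base x Fkh boost x CEN boost x allele factor."""
    base = np.asarray(base_efficiency, dtype=float)
    if base.shape != (len(origin_set),):
        raise ValueError("base_efficiency length does not match origin set")
    g = config.global_multiplier[genotype.dbf4_allele]
    weights = np.empty_like(base)
    for i, o in enumerate(origin_set.origins):
        dist = distance_to_nearest_cen(o, cens)
        weights[i] = (
            base[i]
            * _fkh_boost_factor(o, genotype, config)
            * _cen_boost_factor(dist, genotype, config)
            * g
        )
    return weights


def sample_fired(
    weights: np.ndarray, k: int, rng: np.random.Generator, n_cells: int = 1
) -> np.ndarray:
    """Weighted sampling without replacement for each of ``n_cells`` cells.

    Uses exponential race keys (key = Exp(1)/weight, take the k smallest),
    which is distributionally identical to successive draws proportional to
    weight; validated against exhaustive enumeration in the test suite.
    Returns an (n_cells, k) index array.
    """
    n = len(weights)
    k = min(k, n)
    if k == 0:
        return np.empty((n_cells, 0), dtype=int)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    keys = rng.exponential(size=(n_cells, n)) / weights
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def simulate_cells(
    weights: np.ndarray,
    fixture: SimFixture,
    genotype: Genotype,
    config: SimConfig,
    rng: np.random.Generator,
    n_cells: int | None = None,
) -> list[CellOutcome]:
    """Simulate firing and fork progression for a population of cells."""
    n_cells = config.cells if n_cells is None else n_cells
    fired_idx = sample_fired(weights, config.pool_size, rng, n_cells)
    duration = config.duration_for(genotype)
    origins = fixture.origin_set.origins
    mids = np.array([o.midpoint for o in origins])
    chroms = [o.chrom for o in origins]
    lengths = fixture.genome.lengths
    outcomes: list[CellOutcome] = []
    for c in range(n_cells):
        fired = np.sort(fired_idx[c])
        n_fired = len(fired)
        if n_fired == 0:
            outcomes.append(CellOutcome((), (), ()))
            continue
        if config.exponential_firing_times:
            times = tuple(rng.exponential(scale=1.0 / weights[fired]))
        else:
            times = (0.0,) * n_fired
        extent = config.fork_speed * duration
        if n_fired > 0:
            extent = min(extent, config.synthesis_budget_bp / (2.0 * n_fired))
        raw: list[tuple[str, int, int]] = []
        for i, t in zip(fired, times):
            reach = max(0.0, extent - config.fork_speed * t)
            if reach <= 0:
                continue
            chrom = chroms[i]
            s = max(0, int(round(mids[i] - reach)))
            e = min(lengths[chrom], int(round(mids[i] + reach)))
            if e > s:
                raw.append((chrom, s, e))
        outcomes.append(
            CellOutcome(tuple(int(i) for i in fired), times, _merge(raw))
        )
    return outcomes


def _merge(intervals: list[tuple[str, int, int]]) -> tuple[tuple[str, int, int], ...]:
    """Union of half-open intervals, grouped by chromosome."""
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _, _ in intervals}):
        chunk = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = chunk[0]
        for s, e in chunk[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return tuple(merged)


def _coverage_fraction(
    outcomes: Sequence[CellOutcome], genome: GenomeBuild, bin_width: int
) -> BinnedTrack:
    """Per-bin fraction of cells in which the bin is replicated
    (bp-weighted for partially covered bins)."""
    cover = BinnedTrack.zeros(genome, bin_width)
    w = bin_width
    for cell in outcomes:
        for chrom, s, e in cell.intervals:
            acc = cover.values[chrom]
            i0, i1 = s // w, (e - 1) // w
            if i0 == i1:
                acc[i0] += (e - s) / w
            else:
                acc[i0] += ((i0 + 1) * w - s) / w
                acc[i1] += (e - i1 * w) / w
                if i1 > i0 + 1:
                    acc[i0 + 1 : i1] += 1.0
    n = max(len(outcomes), 1)
    for chrom in cover.values:
        # last bin may be narrower than w; renormalize its bp fraction
        widths = genome.bin_widths(chrom, w)
        cover.values[chrom] = cover.values[chrom] * (w / widths) / n
        np.clip(cover.values[chrom], 0.0, 1.0, out=cover.values[chrom])
    return cover


def _poissonish(
    mean: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counts, optionally gamma-mixed for overdispersion."""
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        mean = np.where(
            mean > 0, rng.gamma(shape, scale=np.maximum(mean, 1e-300) / shape), 0.0
        )
    return rng.poisson(mean).astype(float)


def brdu_track(
    outcomes: Sequence[CellOutcome],
    fixture: SimFixture,
    config: SimConfig,
    rng: np.random.Generator,
) -> BinnedTrack:
    """QBU-like coverage: Poisson(read_depth x replicated-cell fraction)."""
    if not outcomes:
        raise ValueError("need at least one cell outcome")
    frac = _coverage_fraction(outcomes, fixture.genome, config.bin_width)
    out = frac.copy()
    for chrom in out.values:
        out.values[chrom] = _poissonish(
            config.read_depth * frac.values[chrom], config, rng
        )
    return out


def dbf4_chip_track(
    fixture: SimFixture,
    genotype: Genotype,
    config: SimConfig,
    rng: np.random.Generator,
    cen_proximal_names: frozenset[str] | None = None,
) -> BinnedTrack:
    """Dbf4 occupancy track: background + Gaussian CEN/CEN-proximal peaks.

    The Zn* allele suppresses kinetochore-mediated recruitment, scaling both
    CEN and CEN-proximal amplitudes by ``chip_zn_factor``; origins outside
    the CEN neighbourhood carry no strain-dependent enrichment.
    """
    from .origins import classify_cen_proximal

    if cen_proximal_names is None:
        cen_proximal_names = classify_cen_proximal(
            fixture.origin_set, fixture.centromeres
        ).cen_proximal
    z = config.chip_zn_factor if genotype.dbf4_allele == "Zn*" else 1.0
    intensity = BinnedTrack.zeros(fixture.genome, config.bin_width)
    for chrom in intensity.values:
        intensity.values[chrom][:] = config.chip_background
    peaks: list[tuple[str, int, float]] = [
        (c.chrom, c.position, config.chip_cen_amp * z) for c in fixture.centromeres
    ]
    peaks += [
        (o.chrom, o.midpoint, config.chip_prox_amp * z)
        for o in fixture.origin_set.origins
        if o.name in cen_proximal_names
    ]
    w = config.bin_width
    sig = config.chip_sigma_bp
    half_span = int(4 * sig)
    for chrom, pos, amp in peaks:
        if amp <= 0:
            continue
        v = intensity.values[chrom]
        i0 = max(0, (pos - half_span) // w)
        i1 = min(len(v), (pos + half_span) // w + 1)
        centers = (np.arange(i0, i1) + 0.5) * w
        v[i0:i1] += amp * np.exp(-0.5 * ((centers - pos) / sig) ** 2)
    out = intensity.copy()
    for chrom in out.values:
        out.values[chrom] = _poissonish(
            config.chip_depth * intensity.values[chrom], config, rng
        )
    return out


def simulate_experiment(
    config: SimConfig,
    genotypes: dict[str, Genotype] | None = None,
    replicates: int = 2,
    seed: int | None = None,
) -> tuple[dict[str, ReplicateSet], pd.DataFrame, SimFixture]:
    """End-to-end QBU experiment: replicate BrdU tracks per genotype + truth.

    Each replicate uses an independent cell population and independent read
    noise. The truth table reports each origin's empirical firing frequency
    per genotype (pooled over replicates). Fixed seed => identical outputs.
    """
    if genotypes is None:
        genotypes = dict(GENOTYPES)
    if seed is None:
        seed = config.seed
    master = np.random.default_rng(seed)
    fixture = build_sim_fixture(config, rng=np.random.default_rng(seed))
    repsets: dict[str, ReplicateSet] = {}
    truth_rows = []
    names = [o.name for o in fixture.origin_set.origins]
    for label, genotype in genotypes.items():
        weights = assign_firing_weights(
            fixture.origin_set, fixture.centromeres, genotype, config,
            fixture.base_efficiency,
        )
        tracks = []
        fired_counts = np.zeros(len(names))
        total_cells = 0
        for _ in range(replicates):
            rng = master.spawn(1)[0]
            outcomes = simulate_cells(weights, fixture, genotype, config, rng)
            for cell in outcomes:
                fired_counts[list(cell.fired)] += 1
            total_cells += len(outcomes)
            tracks.append(brdu_track(outcomes, fixture, config, rng))
        repsets[label] = ReplicateSet(label, tracks)
        freq = fired_counts / max(total_cells, 1)
        for name, w, f in zip(names, weights, freq):
            truth_rows.append(
                {"origin": name, "genotype": label, "weight": w,
                 "firing_frequency": f}
            )
    truth = pd.DataFrame(truth_rows)
    return repsets, truth, fixture
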