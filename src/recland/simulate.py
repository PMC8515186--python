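"""Synthetic F2 populations with known crossover truth.

The generator emulates a biparental F2 mapping experiment genotyped on a
dense SNP array: each individual is the fusion of two independently
simulated gametes, each gamete the mosaic of the two parental haplotypes
produced by crossovers placed along the chromosome.  Crossovers are placed
on the *genetic* scale by a stationary gamma renewal process (shape
``nu``; ``nu = 1`` is the no-interference Poisson case) and mapped to
physical coordinates through the inverse CDF of a piecewise-constant
recombination landscape, so distally concentrated recombination — the
hallmark of large cereal genomes such as barley — is the default.

Genotyping noise is applied after the truth is recorded: each call is
replaced by one of the other two codes with probability
``allele_error_rate`` and set to missing with probability ``missing_rate``.

Defaults mirror the study design this package targets: two populations of
90 F2 individuals, 7 chromosomes of MorexV2-like physical size, ~2.6
markers/Mbp (~11,000 markers genome-wide), and a U-shaped landscape whose
genetic mass per zone follows the published control-population zone totals
(distal zone 1 ~50.7%, interstitial zone 2 ~49.2%, proximal zone 3 ~0.1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import HET, MISSING, GenotypeMatrix, MarkerMap

# relative zone boundaries (fraction of chromosome length):
# Z1 [0, .04], Z2 (.04, .38], Z3 (.38, .62], Z2 (.62, .96], Z1 (.96, 1]
DEFAULT_ZONE_BOUNDS = (0.04, 0.38, 0.62, 0.96)
# genetic mass per segment, same order (two Z1 arms, two Z2 arms, central Z3)
DEFAULT_ZONE_MASS = (0.2535, 0.246, 0.001, 0.246, 0.2535)


@dataclass(frozen=True)
class Landscape:
    """Piecewise-constant recombination intensity on relative position [0, 1].

    ``breaks`` are segment edges (increasing, first 0, last 1); ``mass`` is
    the un-normalised genetic mass of each segment.  The landscape fixes the
    *shape* only; a chromosome's total genetic length scales it.
    """

    breaks: tuple
    mass: tuple

    def __post_init__(self):
        b = np.asarray(self.breaks, dtype=float)
        m = np.asarray(self.mass, dtype=float)
        if b[0] != 0.0 or b[-1] != 1.0 or np.any(np.diff(b) <= 0):
            raise ValueError("breaks must increase from 0 to 1")
        if len(m) != len(b) - 1 or np.any(m < 0) or m.sum() <= 0:
            raise ValueError("one non-negative mass per segment, total > 0")

    def _cum(self) -> tuple[np.ndarray, np.ndarray]:
        b = np.asarray(self.breaks, dtype=float)
        m = np.asarray(self.mass, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(m)]) / m.sum()
        return b, cum

    def quantile(self, u: np.ndarray) -> np.ndarray:
        """Relative physical position holding genetic fraction ``u`` in [0, 1]."""
        b, cum = self._cum()
        u = np.asarray(u, dtype=float)
        seg = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(b) - 2)
        width = cum[seg + 1] - cum[seg]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(width > 0, (u - cum[seg]) / width, 0.0)
        return b[seg] + frac * (b[seg + 1] - b[seg])

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """Genetic fraction accumulated left of relative physical position ``x``."""
        b, cum = self._cum()
        x = np.asarray(x, dtype=float)
        seg = np.clip(np.searchsorted(b, x, side="right") - 1, 0, len(b) - 2)
        frac = (x - b[seg]) / (b[seg + 1] - b[seg])
        return cum[seg] + frac * (cum[seg + 1] - cum[seg])


def uniform_landscape() -> Landscape:
    return Landscape(breaks=(0.0, 1.0), mass=(1.0,))


def default_landscape() -> Landscape:
    """U-shaped, distally enriched landscape (see module docstring)."""
    return Landscape(breaks=(0.0,) + DEFAULT_ZONE_BOUNDS + (1.0,), mass=DEFAULT_ZONE_MASS)


def apply_distal_shift(
    landscape: Landscape,
    moved_fraction: float = 0.10,
    interstitial_spans=((0.04, 0.38), (0.62, 0.96)),
    terminal: float = 0.02,
) -> Landscape:
    """Move ``moved_fraction`` of the interstitial genetic mass to the
    terminal ``terminal`` fraction of each arm, keeping total mass unchanged.

    This is the generator's knockdown-like alternative: recombination is
    redistributed from interstitial regions to the extreme chromosome ends
    without changing overall map length.
    """
    if not 0 <= moved_fraction <= 1:
        raise ValueError("moved_fraction must be in [0, 1]")
    edges = set(landscape.breaks) | {terminal, 1.0 - terminal}
    for a, b in interstitial_spans:
        edges |= {a, b}
    breaks = np.array(sorted(edges))
    # per refined segment mass, pro-rata from the original landscape
    cdf = landscape.cdf(breaks) * np.sum(landscape.mass)
    mass = np.diff(cdf)
    mids = (breaks[:-1] + breaks[1:]) / 2
    inter = np.zeros(len(mass), dtype=bool)
    for a, b in interstitial_spans:
        inter |= (mids > a) & (mids < b)
    moved = moved_fraction * mass[inter].sum()
    mass[inter] *= 1.0 - moved_fraction
    term = (mids < terminal) | (mids > 1.0 - terminal)
    seg_len = np.diff(breaks)
    mass[term] += moved * seg_len[term] / seg_len[term].sum()
    return Landscape(breaks=tuple(breaks), mass=tuple(mass))


@dataclass(frozen=True)
class ChromosomeSpec:
    """One simulated chromosome: physical length, per-gamete genetic length,
    and the landscape mapping genetic to physical position."""

    name: str
    length_bp: int
    genetic_length_cm: float
    landscape: Landscape = field(default_factory=default_landscape)

    def __post_init__(self):
        if self.length_bp < 0:
            raise ValueError("length_bp must be >= 0")
        if self.genetic_length_cm < 0:
            raise ValueError("genetic length must be >= 0 cM")


def barley_like_chromosomes(
    genetic_length_cm: float = 74.0, landscape: Landscape | None = None
) -> list[ChromosomeSpec]:
    """Seven chromosomes with MorexV2-like physical sizes (Mbp-scale)."""
    lengths = {
        "1H": 522_000_000,
        "2H": 665_000_000,
        "3H": 622_000_000,
        "4H": 610_000_000,
        "5H": 588_000_000,
        "6H": 583_000_000,
        "7H": 657_000_000,
    }
    ls = landscape if landscape is not None else default_landscape()
    return [
        ChromosomeSpec(name, bp, genetic_length_cm, ls) for name, bp in lengths.items()
    ]


@dataclass(frozen=True)
class TruthRecord:
    """True crossover positions of one gamete on one chromosome."""

    individual: str
    gamete: int  # 1 or 2
    chrom: str
    positions: np.ndarray  # strictly increasing bp in (0, length)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("truth positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 90
    chromosomes: tuple = tuple(barley_like_chromosomes())
    interference_shape: float = 1.0  # gamma renewal shape nu; 1 = no interference
    marker_density: float = 2.6  # markers per Mbp (ignored if markers given)
    markers: MarkerMap | None = None
    allele_error_rate: float = 0.002
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.allele_error_rate <= 1:
            raise ValueError("allele_error_rate must be in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.interference_shape <= 0:
            raise ValueError("interference_shape must be > 0")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


def sample_gamete_crossovers(
    spec: ChromosomeSpec, interference_shape: float, rng: np.random.Generator
) -> np.ndarray:
    """CO physical positions (bp, float) of one gamete on one chromosome.

    Events form a stationary gamma renewal process on the genetic scale with
    mean inter-event distance 100 cM (one CO per Morgan); ``nu = 1`` reduces
    to a homogeneous Poisson process.  Genetic positions are mapped to
    physical bp by the landscape's inverse CDF.
    """
    nu = float(interference_shape)
    if nu <= 0:
        raise ValueError("interference_shape must be > 0")
    L = spec.genetic_length_cm
    if L <= 0 or spec.length_bp <= 0:
        return np.empty(0)
    if nu == 1.0:
        n = rng.poisson(L / 100.0)
        g = np.sort(rng.random(n)) * L
    else:
        # stationary start: forward recurrence time as U x length-biased draw
        arrivals = []
        t = rng.random() * rng.gamma(nu + 1.0, 100.0 / nu)
        while t < L:
            arrivals.append(t)
            t += rng.gamma(nu, 100.0 / nu)
        g = np.asarray(arrivals)
    if g.size == 0:
        return np.empty(0)
    pos = spec.landscape.quantile(g / L) * spec.length_bp
    pos = pos[(pos > 0) & (pos < spec.length_bp)]
    return np.unique(pos)  # ties have probability zero; guard anyway


def _default_marker_map(config: SimConfig) -> MarkerMap:
    import pandas as pd

    rows = []
    for spec in config.chromosomes:
        n = max(2, int(round(config.marker_density * spec.length_bp / 1e6)))
        pos = np.floor((np.arange(n) + 0.5) * spec.length_bp / n).astype(np.int64) + 1
        pos = np.minimum(pos, spec.length_bp)
        for i, p in enumerate(pos):
            rows.append((f"{spec.name}_m{i + 1:05d}", spec.name, int(p)))
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos"]))


def simulate_f2(config: SimConfig) -> tuple[GenotypeMatrix, MarkerMap, list[TruthRecord]]:
    """Simulate an F2 population; returns genotypes, marker map and truth.

    Each individual combines two independent gametes; a gamete alternates
    parental haplotype at its CO positions, with the starting haplotype
    drawn uniformly (the F1 phase is arbitrary).  Error and missingness are
    applied after truth is recorded; truth records are returned unperturbed.
    """
    rng = np.random.default_rng(config.seed)
    mm = config.markers if config.markers is not None else _default_marker_map(config)
    chrom_specs = {c.name: c for c in config.chromosomes}
    if set(mm.chroms) - set(chrom_specs):
        raise ValueError(f"markers on unknown chromosomes: {set(mm.chroms) - set(chrom_specs)}")
    for chrom in mm.chroms:
        pos = mm.positions(chrom)
        if pos.size and (pos.min() < 1 or pos.max() > chrom_specs[chrom].length_bp):
            raise ValueError(f"marker positions outside chromosome {chrom} bounds")

    individuals = [f"ind{i + 1:04d}" for i in range(config.n_individuals)]
    n = config.n_individuals
    calls = np.empty((mm.n_markers, n), dtype=np.int8)
    truths: list[TruthRecord] = []

    for chrom in mm.chroms:
        spec = chrom_specs[chrom]
        p = mm.positions(chrom).astype(float)
        rows = mm.chrom_indices(chrom)
        m = len(rows)
        n_gam = 2 * n  # gametes 2i, 2i+1 belong to individual i
        if config.interference_shape == 1.0 and spec.genetic_length_cm > 0 and spec.length_bp > 0:
            # Poisson fast path, vectorised across all gametes
            counts = rng.poisson(spec.genetic_length_cm / 100.0, n_gam)
            u = rng.random(int(counts.sum()))
            bp = spec.landscape.quantile(u) * spec.length_bp
            gid = np.repeat(np.arange(n_gam), counts)
            order = np.lexsort((bp, gid))
            bp, gid = bp[order], gid[order]
            keep = (bp > 0) & (bp < spec.length_bp)
            bp, gid = bp[keep], gid[keep]
            co_lists = np.split(bp, np.searchsorted(gid, np.arange(1, n_gam)))
        else:
            co_lists = [
                sample_gamete_crossovers(spec, config.interference_shape, rng)
                for _ in range(n_gam)
            ]
            bp = np.concatenate(co_lists) if co_lists else np.empty(0)
            gid = np.repeat(np.arange(n_gam), [len(c) for c in co_lists])
        starts = rng.integers(0, 2, size=n_gam)
        # haplotype at marker j flips once per crossover left of it
        flips = np.zeros((m + 1, n_gam), dtype=np.int16)
        if bp.size:
            np.add.at(flips, (np.searchsorted(p, bp), gid), 1)
        cum = np.cumsum(flips[:m], axis=0)
        hap = (starts[None, :] + cum) % 2
        calls[rows] = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)  # 0=AA,1=HET,2=BB
        for g in range(n_gam):
            truths.append(
                TruthRecord(
                    individual=individuals[g // 2],
                    gamete=g % 2 + 1,
                    chrom=chrom,
                    positions=np.asarray(co_lists[g], dtype=float),
                )
            )

    if config.allele_error_rate > 0:
        err = rng.random(calls.shape) < config.allele_error_rate
        # replace by one of the other two codes, uniformly
        shift = rng.integers(1, 3, size=calls.shape, dtype=np.int8)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls = np.where(miss, np.int8(MISSING), calls)

    gm = GenotypeMatrix(calls, list(mm.marker_ids), individuals)
    return gm, mm, truths


def with_shifted_landscape(config: SimConfig, moved_fraction: float = 0.10) -> SimConfig:
    """Copy of ``config`` whose chromosomes carry the distally shifted landscape."""
    chroms = tuple(
        replace(spec, landscape=apply_distal_shift(spec.landscape, moved_fraction))
        for spec in config.chromosomes
    )
    return replace(config, chromosomes=chroms)


def total_true_crossovers(truths) -> int:
    return int(sum(len(t.positions) for t in truths))
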