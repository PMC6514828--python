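"""Forward-in-time Wright–Fisher simulation of a standing biallelic variant
under a founding bottleneck followed by instantaneous expansion, with
time-limited codominant selection, plus the fixation-proportion parameter
grid and an exact small-population Markov-chain oracle.

Model
-----
Generation 0 holds the initial frequency ``p0``.  Each of the
``total_generations`` subsequent generations applies, in order:

1. deterministic viability selection (while the generation index is within
   the selection ``duration``), with genotype fitnesses ``1+s``, ``1+h*s``,
   ``1`` for the focal homozygote, heterozygote and other homozygote:
   ``p' = p * (p*(1+s) + q*(1+h*s)) / w_bar``;
2. binomial resampling of ``2N`` alleles, where ``N`` is the bottleneck
   size for the first ``bottleneck_duration`` generations and the expanded
   size thereafter.

States 0 and 1 are absorbing.  Fixation is assessed at the final
generation, which (absorption) equals "ever fixed".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Demography",
    "SelectionRegime",
    "TrajectoryResult",
    "FixationGrid",
    "NEUTRAL",
    "simulate_trajectory",
    "fixation_proportion",
    "run_grid",
    "exact_fixation_probability",
    "PAPER_GRID_AXES",
]


@dataclass(frozen=True)
class Demography:
    """Bottleneck-then-expansion history in diploid effective sizes."""

    bottleneck_size: int
    expanded_size: int
    total_generations: int = 534
    bottleneck_duration: int = 10

    def __post_init__(self) -> None:
        if self.bottleneck_duration > self.total_generations:
            raise ValueError("bottleneck_duration must be <= total_generations")
        if min(self.bottleneck_size, self.expanded_size) < 1:
            raise ValueError("population sizes must be >= 1")

    def size_at(self, generation: int) -> int:
        """Diploid size of the population sampled at 1-based ``generation``."""
        return self.bottleneck_size if generation <= self.bottleneck_duration else self.expanded_size

    @property
    def max_size(self) -> int:
        return max(self.bottleneck_size, self.expanded_size)


@dataclass(frozen=True)
class SelectionRegime:
    """Codominant selection on the focal allele for the first ``duration``
    generations of the simulation (counted from its start, so selection can
    span the bottleneck).  ``after_bottleneck_only=True`` instead restricts
    selection to post-bottleneck generations within that window."""

    s: float
    duration: int
    h: float = 0.5
    after_bottleneck_only: bool = False

    def __post_init__(self) -> None:
        if self.s <= -1:
            raise ValueError("selection coefficient must be > -1 (non-negative fitness)")
        if not 0 <= self.h <= 1:
            raise ValueError("codominance coefficient h must be in [0, 1]")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    def active(self, generation: int, demography: Demography) -> bool:
        if generation > self.duration:
            return False
        if self.after_bottleneck_only and generation <= demography.bottleneck_duration:
            return False
        return True


NEUTRAL = SelectionRegime(s=0.0, duration=0)


@dataclass
class TrajectoryResult:
    frequencies: np.ndarray  # length total_generations + 1, includes p0
    fixed: bool
    lost: bool


def _select(p: np.ndarray | float, s: float, h: float):
    """One generation of deterministic codominant viability selection."""
    q = 1.0 - p
    w_bar = p * p * (1.0 + s) + 2.0 * p * q * (1.0 + h * s) + q * q
    return p * (p * (1.0 + s) + q * (1.0 + h * s)) / w_bar


def _simulate_batch(
    p0: float,
    demography: Demography,
    selection: SelectionRegime,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Final allele frequencies of ``n_replicates`` independent trajectories."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    gens = demography.total_generations
    two_n_sched = np.array([2 * demography.size_at(g) for g in range(1, gens + 1)])
    sel_sched = np.array(
        [selection.active(g, demography) and selection.s != 0.0 for g in range(1, gens + 1)]
    )
    s, h = selection.s, selection.h
    binomial = rng.binomial
    p = np.full(n_replicates, float(p0))
    for g in range(gens):
        if sel_sched[g]:
            p = _select(p, s, h)
        two_n = two_n_sched[g]
        p = binomial(two_n, p) / two_n
        if g % 64 == 63 and not np.any((p > 0.0) & (p < 1.0)):
            break  # all replicates absorbed
    return p


def simulate_trajectory(
    p0: float,
    demography: Demography,
    selection: SelectionRegime = NEUTRAL,
    seed: int | np.random.Generator = 0,
) -> TrajectoryResult:
    """Single full trajectory, recording the frequency at every generation."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.empty(demography.total_generations + 1)
    freqs[0] = p = float(p0)
    for g in range(1, demography.total_generations + 1):
        if p in (0.0, 1.0):
            freqs[g:] = p
            break
        if selection.active(g, demography) and selection.s != 0.0:
            p = _select(p, selection.s, selection.h)
        two_n = 2 * demography.size_at(g)
        p = rng.binomial(two_n, p) / two_n
        freqs[g] = p
    return TrajectoryResult(freqs, fixed=freqs[-1] == 1.0, lost=freqs[-1] == 0.0)


def fixation_proportion(
    p0: float,
    demography: Demography,
    selection: SelectionRegime = NEUTRAL,
    replicates: int = 100,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> float:
    """Fraction of seeded replicate trajectories fixed (frequency 1) at the
    final generation."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    final = _simulate_batch(p0, demography, selection, replicates, rng)
    return float(np.mean(final == 1.0))


# the parameter grid of the selection study
PAPER_GRID_AXES = {
    "bottleneck_sizes": (100, 200, 300, 400, 500),
    "expanded_sizes": (2_000, 4_000, 6_000, 8_000, 10_000),
    "durations": (67, 133, 200, 267, 333, 400, 467, 534),
    "coefficients": (0.0, 0.1, 0.01, 0.001),
    "p0_values": tuple(np.round(np.arange(0.30, 0.951, 0.05), 2)),
}


@dataclass
class FixationGrid:
    """Fixation proportions over the Cartesian parameter grid."""

    table: pd.DataFrame  # bottleneck_size, expanded_size, duration, s, p0, prop_fixed, replicates
    replicates: int

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _simulate_cell_block(
    demography: Demography,
    durations: np.ndarray,
    s_values: np.ndarray,
    p0_values: np.ndarray,
    h: float,
    replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fixation proportions for many (duration, s, p0) cells sharing one
    demography, simulated as a single flat replicate vector."""
    n_cells = len(durations)
    dur = np.repeat(durations, replicates).astype(float)
    s = np.repeat(s_values, replicates)
    p = np.repeat(p0_values, replicates).astype(float)
    gens = demography.total_generations
    for g in range(1, gens + 1):
        active = (g <= dur) & (s != 0.0)
        if active.any():
            p = np.where(active, _select(p, s, h), p)
        two_n = 2 * demography.size_at(g)
        p = rng.binomial(two_n, p) / two_n
    return (p.reshape(n_cells, replicates) == 1.0).mean(axis=1)


def run_grid(
    bottleneck_sizes=PAPER_GRID_AXES["bottleneck_sizes"],
    expanded_sizes=PAPER_GRID_AXES["expanded_sizes"],
    durations=PAPER_GRID_AXES["durations"],
    coefficients=PAPER_GRID_AXES["coefficients"],
    p0_values=PAPER_GRID_AXES["p0_values"],
    replicates: int = 100,
    seed: int = 0,
    h: float = 0.5,
    total_generations: int = 534,
    bottleneck_duration: int = 10,
) -> FixationGrid:
    """Fixation proportions over the full Cartesian product of the axes.

    Cells sharing one demography (bottleneck size, expanded size) are
    simulated together as a flat vector of independent replicates, with one
    counter-based child seed per demography block spawned from the master
    seed — so grids are bit-reproducible for a given seed and axes, and
    replicates are mutually independent within and across cells.
    """
    axes = [bottleneck_sizes, expanded_sizes, durations, coefficients, p0_values]
    if any(len(ax) == 0 for ax in axes):
        raise ValueError("all grid axes must be non-empty")
    demog_blocks = list(itertools.product(bottleneck_sizes, expanded_sizes))
    cell_axes = list(itertools.product(durations, coefficients, p0_values))
    child_seeds = np.random.SeedSequence(seed).spawn(len(demog_blocks))

    # validate every cell up front, naming the offender
    for nb, ne in demog_blocks:
        for dur, s, p0 in cell_axes:
            try:
                Demography(
                    bottleneck_size=nb,
                    expanded_size=ne,
                    total_generations=total_generations,
                    bottleneck_duration=bottleneck_duration,
                )
                SelectionRegime(s=s, duration=dur, h=h)
                if dur > total_generations:
                    raise ValueError("selection duration exceeds total_generations")
                if not 0.0 <= p0 <= 1.0:
                    raise ValueError("p0 must be in [0, 1]")
            except ValueError as exc:
                raise ValueError(
                    f"invalid grid cell (bottleneck={nb}, expanded={ne}, "
                    f"duration={dur}, s={s}, p0={p0}): {exc}"
                ) from exc

    dur_v = np.array([c[0] for c in cell_axes])
    s_v = np.array([c[1] for c in cell_axes])
    p0_v = np.array([c[2] for c in cell_axes])
    rows = []
    for (nb, ne), child in zip(demog_blocks, child_seeds):
        demog = Demography(
            bottleneck_size=nb,
            expanded_size=ne,
            total_generations=total_generations,
            bottleneck_duration=bottleneck_duration,
        )
        props = _simulate_cell_block(
            demog, dur_v, s_v, p0_v, h, replicates, np.random.default_rng(child)
        )
        for (dur, s, p0), prop in zip(cell_axes, props):
            rows.append((nb, ne, dur, s, p0, prop, replicates))
    table = pd.DataFrame(
        rows,
        columns=["bottleneck_size", "expanded_size", "duration", "s", "p0", "prop_fixed", "replicates"],
    )
    return FixationGrid(table=table, replicates=replicates)


def exact_fixation_probability(
    p0: float,
    demography: Demography,
    selection: SelectionRegime = NEUTRAL,
    max_alleles: int = 200,
) -> float:
    """Exact probability of absorption at frequency 1 by the final generation,
    by propagating the allele-count distribution through per-generation
    binomial transition matrices (selection applied to the expected frequency
    first).  Tractable only for small populations: refuses when
    ``2 * max(N) > max_alleles``.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if 2 * demography.max_size > max_alleles:
        raise ValueError(
            f"2*max(N) = {2 * demography.max_size} exceeds the tractability "
            f"bound {max_alleles}; use the stochastic simulator instead"
        )
    # distribution over allele counts of the current generation's population
    dist = np.array([1.0])
    freqs = np.array([float(p0)])  # frequencies corresponding to dist states
    for g in range(1, demography.total_generations + 1):
        p = freqs
        if selection.active(g, demography) and selection.s != 0.0:
            p = _select(p, selection.s, selection.h)
        two_n = 2 * demography.size_at(g)
        counts = np.arange(two_n + 1)
        # transition[i, j] = P(j successes | 2N trials, prob p_i)
        trans = stats.binom.pmf(counts[None, :], two_n, p[:, None])
        dist = dist @ trans
        freqs = counts / two_n
    return float(dist[-1])
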