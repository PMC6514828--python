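"""Synthetic inputs for every pipeline stage.

Three generators, each seeded and bit-reproducible:

* :func:`simulate_haplogroup_alignment` — a two-cluster haplotype alignment
  (ancestral vs derived haplogroup) with intermediate archaic lineages and a
  reconstructed ancestor sequence, built under the infinite-sites model so
  the divergence-based TMRCA estimator has a well-defined truth.
* :func:`simulate_frequency_panel` — a three-population allele-count panel
  under the Balding–Nichols model, optionally with one sweep-like site of
  elevated differentiation in the focal population.
* :func:`simulate_cline_table` — per-population haplogroup proportions with
  a linear latitude effect and an admixture covariate.

The haplogroup generator's clusters are stars by default: every haplotype
hangs off its cluster founder by an independent branch, so per-lineage
mutation counts are independent Poisson draws with mean
``tmrca * a_hc / (2 * t_hc) * length_high_quality``.  Cluster-defining
shared mutations (the tag SNP and the derived-cluster stem) are placed at
sites excluded from the high-quality ancestor mask, which keeps the
divergence clock at high-quality sites driven purely by post-MRCA private
mutations; a ``stem_in_high_quality`` switch exists to demonstrate the
upward bias shared stem mutations would otherwise induce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import BASES, HaplotypeAlignment

__all__ = [
    "HaplogroupSimConfig",
    "PanelSimConfig",
    "ClineSimConfig",
    "simulate_haplogroup_alignment",
    "simulate_frequency_panel",
    "simulate_cline_table",
    "tag_site_position",
]

# Defaults mirroring the study region (hg19 chr11 FADS LD block).
REGION_CHROM = "chr11"
REGION_START = 61_543_499
TAG_POS = 61_552_680
DEFAULT_A_HC = 0.00829
DEFAULT_T_HC = 6_500_000.0


@dataclass(frozen=True)
class HaplogroupSimConfig:
    """Parameters of the two-cluster haplogroup alignment generator.

    Times are years before present; ``a_hc`` is the per-site human–chimp
    divergence fraction and ``t_hc`` the human–chimp split time, so the
    per-lineage substitution rate is ``a_hc / (2 * t_hc)`` per site per year.
    """

    n_derived: int = 50
    n_ancestral: int = 50
    n_archaic_near_derived: int = 2
    n_archaic_near_ancestral: int = 2
    length_total: int = 48_408
    length_high_quality: int = 47_820
    tmrca_derived: float = 688_474.0
    tmrca_all: float = 1_300_000.0
    archaic_branch_time: float = 650_000.0
    a_hc: float = DEFAULT_A_HC
    t_hc: float = DEFAULT_T_HC
    genealogy: str = "star"  # "star" | "coalescent"
    stem_in_high_quality: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_high_quality > self.length_total:
            raise ValueError("length_high_quality must be <= length_total")
        if not (0 <= self.tmrca_derived < self.tmrca_all):
            raise ValueError("require 0 <= tmrca_derived < tmrca_all")
        if min(
            self.n_derived,
            self.n_ancestral,
            self.n_archaic_near_derived,
            self.n_archaic_near_ancestral,
        ) < 0:
            raise ValueError("haplotype counts must be >= 0")
        if not 0 < self.a_hc < 1:
            raise ValueError("a_hc must be in (0, 1)")
        if self.genealogy not in ("star", "coalescent"):
            raise ValueError("genealogy must be 'star' or 'coalescent'")

    @property
    def rate_per_site_year(self) -> float:
        return self.a_hc / (2.0 * self.t_hc)


def tag_site_position(config: HaplogroupSimConfig) -> int:
    """1-based position of the tag SNP in a generated alignment (falls back
    to the region midpoint when the alignment is shorter than the real
    region, mirroring the generator)."""
    tag_idx = TAG_POS - REGION_START
    if tag_idx >= config.length_total:
        tag_idx = config.length_total // 2
    return REGION_START + tag_idx


def _mutate(hap: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> None:
    """Substitute each listed site with a random base differing from current."""
    for j in sites:
        current = hap[j]
        choices = [b for b in BASES if b != current]
        hap[j] = choices[rng.integers(len(choices))]


def _star_branch_lengths(n: int, depth: float) -> np.ndarray:
    return np.full(n, depth)


def _coalescent_branch_depths(n: int, depth: float, rng: np.random.Generator) -> list[tuple[np.ndarray, float]]:
    """Kingman genealogy rescaled so the root sits exactly at ``depth``.

    Returns a list of (tip membership mask, branch length in years): one
    entry per branch of the tree, where a tip below the branch inherits all
    mutations placed on it.
    """
    if n == 1:
        return [(np.array([True]), depth)]
    # coalescent waiting times in coalescent units, rescaled to total depth
    k = np.arange(n, 1, -1)
    waits = rng.exponential(scale=2.0 / (k * (k - 1)))
    times = np.concatenate([[0.0], np.cumsum(waits)])  # node heights, tips at 0
    times = times / times[-1] * depth
    # sequential random coalescence recording branches
    lineages: list[tuple[np.ndarray, float]] = [
        (np.eye(n, dtype=bool)[i], 0.0) for i in range(n)
    ]
    branches: list[tuple[np.ndarray, float]] = []
    for step in range(n - 1):
        t_new = times[step + 1]
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (mask_i, born_i) = lineages[i]
        (mask_j, born_j) = lineages[j]
        branches.append((mask_i, t_new - born_i))
        branches.append((mask_j, t_new - born_j))
        merged = (mask_i | mask_j, t_new)
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return branches


class MutationBudgetError(RuntimeError):
    """Raised when the infinite-sites site budget is exhausted."""


class _SitePool:
    """Draws globally distinct site indices (infinite-sites bookkeeping)."""

    def __init__(self, indices: np.ndarray, rng: np.random.Generator):
        self._free = rng.permutation(indices).tolist()

    def draw(self, k: int) -> np.ndarray:
        if k > len(self._free):
            raise MutationBudgetError(
                f"mutation budget exceeded: requested {k} sites, "
                f"{len(self._free)} available (infinite-sites violation)"
            )
        out = [self._free.pop() for _ in range(k)]
        return np.array(out, dtype=np.int64)


def simulate_haplogroup_alignment(config: HaplogroupSimConfig) -> HaplotypeAlignment:
    """Generate the two-cluster haplogroup alignment described in the module
    docstring.

    The ancestral cluster founder equals the ancestor sequence (the
    ancestral haplogroup matches nonhuman primates); the derived cluster
    founder carries the derived tag allele plus Poisson-distributed stem
    mutations accrued between ``tmrca_all`` and ``tmrca_derived``.  Archaic
    lineages branch from the respective founder ``archaic_branch_time``
    years ago.  All mutations obey the infinite-sites model.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length_total
    positions = np.arange(REGION_START, REGION_START + L, dtype=np.int64)

    ancestor = BASES[rng.integers(4, size=L)]
    tag_idx = int(TAG_POS - REGION_START)
    if tag_idx >= L:
        tag_idx = L // 2  # tiny test alignments: keep the tag inside the region
    ancestor[tag_idx] = "T"

    # high-quality mask: all sites minus a random low-quality subset that
    # always contains the tag site (cluster-defining differences live there)
    n_low = L - cfg.length_high_quality
    if n_low < 1:
        raise ValueError("need at least one low-quality site to host the tag SNP")
    low_candidates = np.delete(np.arange(L), tag_idx)
    low_idx = np.concatenate(
        [[tag_idx], rng.choice(low_candidates, size=n_low - 1, replace=False)]
    )
    high_quality = np.ones(L, dtype=bool)
    high_quality[low_idx] = False

    hq_sites = np.flatnonzero(high_quality)
    lq_sites = np.setdiff1d(np.flatnonzero(~high_quality), [tag_idx])
    hq_pool = _SitePool(hq_sites, rng)
    lq_pool = _SitePool(lq_sites, rng)

    rate = cfg.rate_per_site_year
    lam_private = rate * cfg.length_high_quality  # expected mutations / year / lineage

    # derived founder: ancestor + tag allele + stem mutations accrued between
    # tmrca_all and tmrca_derived over the whole region length
    derived_founder = ancestor.copy()
    derived_founder[tag_idx] = "G"
    stem_years = cfg.tmrca_all - cfg.tmrca_derived
    n_stem = int(rng.poisson(stem_years * rate * cfg.length_total))
    stem_pool = hq_pool if cfg.stem_in_high_quality else lq_pool
    _mutate(derived_founder, stem_pool.draw(n_stem), rng)

    haplotypes: list[np.ndarray] = []
    ids: list[str] = []
    clusters: list[str] = []

    def add_cluster(founder: np.ndarray, n: int, depth: float, prefix: str, cluster: str) -> None:
        if n == 0:
            return
        tips = [founder.copy() for _ in range(n)]
        if cfg.genealogy == "star" or n == 1:
            branches = [(np.eye(n, dtype=bool)[i], depth) for i in range(n)]
        else:
            branches = _coalescent_branch_depths(n, depth, rng)
        for mask, years in branches:
            sites = hq_pool.draw(int(rng.poisson(years * lam_private)))
            carriers = np.flatnonzero(mask)
            for j in sites:
                new_base = BASES[rng.choice(np.flatnonzero(BASES != founder[j]))]
                for t in carriers:
                    tips[t][j] = new_base
        for i, hap in enumerate(tips):
            haplotypes.append(hap)
            ids.append(f"{prefix}{i + 1:03d}")
            clusters.append(cluster)

    add_cluster(derived_founder, cfg.n_derived, cfg.tmrca_derived, "DER", "derived")
    add_cluster(ancestor, cfg.n_ancestral, cfg.tmrca_all, "ANC", "ancestral")
    add_cluster(
        derived_founder, cfg.n_archaic_near_derived, cfg.archaic_branch_time, "NEA", "archaic_near_derived"
    )
    add_cluster(
        ancestor, cfg.n_archaic_near_ancestral, cfg.archaic_branch_time, "DEN", "archaic_near_ancestral"
    )

    matrix = np.stack(haplotypes) if haplotypes else np.empty((0, L), dtype="<U1")
    meta = pd.DataFrame(
        {
            "haplotype_id": ids,
            "sample": [f"IND{i // 2:04d}" for i in range(len(ids))],
            "hap_index": [i % 2 for i in range(len(ids))],
            "population": "SIM",
            "ancestry": [c if c.startswith("archaic") else "modern" for c in clusters],
            "cluster": clusters,
        }
    )
    return HaplotypeAlignment(matrix, positions, REGION_CHROM, ancestor, high_quality, meta)


# ---------------------------------------------------------------------------
# three-population allele-count panels (Balding–Nichols)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelSimConfig:
    """Balding–Nichols null (or single-sweep alternative) panel generator.

    ``drift_f`` holds one differentiation parameter per population; the
    shared ancestral allele frequency of each site is uniform on
    ``ancestral_freq_range``.  ``selected_site`` is an optional
    ``(site_index, frequency_shift)`` pair applied to population A (the
    focal population) before binomial sampling.
    """

    n_sites: int = 10_000
    sample_sizes: tuple[int, int, int] = (100, 100, 100)  # diploids per population
    drift_f: tuple[float, float, float] = (0.01, 0.01, 0.01)
    selected_site: tuple[int, float] | None = None
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    chrom: str = REGION_CHROM
    start_pos: int = 12_000_000
    pos_step: int = 10_000  # genome-scale spacing: most sites sit outside any focal window
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < f < 1 for f in self.drift_f):
            raise ValueError("drift_f entries must be strictly inside (0, 1)")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample_sizes must be >= 1")
        if self.selected_site is not None and not 0 <= self.selected_site[0] < self.n_sites:
            raise ValueError("selected_site index out of range")


def simulate_frequency_panel(config: PanelSimConfig) -> pd.DataFrame:
    """Allele-count panel: one row per site with per-population ref/alt counts.

    Per site, an ancestral frequency ``p`` is drawn, then each population's
    frequency from ``Beta(p (1-F)/F, (1-p)(1-F)/F)``, then allele counts as
    ``Binomial(2 * diploids, freq)``.  Columns follow the scan interface:
    ``CHROM, POS, A_REF, A_ALT, B_REF, B_ALT, C_REF, C_ALT``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_sites)

    out = {"CHROM": np.full(cfg.n_sites, cfg.chrom), "POS": cfg.start_pos + cfg.pos_step * np.arange(cfg.n_sites)}
    for pop, (n_dip, F) in zip("ABC", zip(cfg.sample_sizes, cfg.drift_f)):
        shape = (1.0 - F) / F
        freq = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        if pop == "A" and cfg.selected_site is not None:
            idx, shift = cfg.selected_site
            freq[idx] = np.clip(freq[idx] + shift, 0.0, 1.0)
        alt = rng.binomial(2 * n_dip, freq)
        out[f"{pop}_REF"] = 2 * n_dip - alt
        out[f"{pop}_ALT"] = alt
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# latitude-cline tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClineSimConfig:
    """Generator for per-population haplogroup-proportion cline tables."""

    n_populations: int = 40
    latitude_range: tuple[float, float] = (10.0, 70.0)
    beta_latitude: float = 0.01
    beta_admixture: float = -0.2
    intercept: float = 0.1
    admixture_range: tuple[float, float] = (0.0, 0.5)
    noise_sd: float = 0.02
    haplotypes_per_population: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 3:
            raise ValueError("need at least 3 populations")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_cline_table(config: ClineSimConfig) -> pd.DataFrame:
    """One row per population: latitude, admixture, haplogroup proportion.

    ``proportion = intercept + beta_latitude * latitude
    + beta_admixture * admixture + N(0, noise_sd)``, clipped to [0, 1].
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lat = rng.uniform(*cfg.latitude_range, size=cfg.n_populations)
    adm = rng.uniform(*cfg.admixture_range, size=cfg.n_populations)
    prop = (
        cfg.intercept
        + cfg.beta_latitude * lat
        + cfg.beta_admixture * adm
        + (rng.normal(0.0, cfg.noise_sd, size=cfg.n_populations) if cfg.noise_sd > 0 else 0.0)
    )
    return pd.DataFrame(
        {
            "population": [f"POP{i + 1:02d}" for i in range(cfg.n_populations)],
            "proportion": np.clip(prop, 0.0, 1.0),
            "admixture": adm,
            "latitude": lat,
            "n_haplotypes": cfg.haplotypes_per_population,
        }
    )
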