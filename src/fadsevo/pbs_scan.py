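"""Three-population selection scan: per-site F_ST, the population branch
statistic (PBS), and genome-background Z-scores with Bonferroni correction
for a focal window.

For populations A (focal), B and C, per-site pairwise F_ST values are
transformed to branch lengths ``T = -ln(1 - F_ST)`` and combined as

    PBS_A = (T_AB + T_AC - T_BC) / 2,

the length of the focal population's branch since its divergence from B and
C.  Each PBS in a window around the focal region is compared with the
genome-wide PBS mean and SD via a Z-score, converted to an upper-tail
normal p-value and Bonferroni-corrected by the number of focal-window sites
tested.

The default F_ST estimator is the Weir–Cockerham (1984) moment estimator
evaluated from allele counts (haploid ANOVA form); Hudson's estimator is
available for sensitivity.  Negative estimates are retained (they yield
negative branch lengths); estimates at the upper boundary are clamped just
below 1 before the log transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .util import PBS_SCAN_REGION, Region

__all__ = [
    "fst_weir_cockerham",
    "fst_hudson",
    "pbs_from_fst",
    "pbs_all_branches",
    "pbs_scan",
]

logger = logging.getLogger(__name__)

_CLAMP = 1.0 - 1e-12


def fst_weir_cockerham(ref1, alt1, ref2, alt2):
    """Two-population single-site Weir–Cockerham F_ST from allele counts.

    Moment (ANOVA) estimator for samples of alleles: with sample sizes
    ``n_i`` (allele counts) and alt frequencies ``p_i``,

        MSP   = sum n_i (p_i - p_bar)^2
        MSG   = sum n_i p_i (1 - p_i) / sum (n_i - 1)
        n_c   = sum n_i - sum n_i^2 / sum n_i
        theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

    Negative estimates are retained.  Monomorphic-overall sites are
    undefined and returned as NaN.  Accepts scalars or equal-length arrays.
    """
    ref1, alt1, ref2, alt2 = (np.asarray(x, dtype=float) for x in (ref1, alt1, ref2, alt2))
    n1, n2 = ref1 + alt1, ref2 + alt2
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("each population needs >= 2 allele observations")
    p1, p2 = alt1 / n1, alt2 / n2
    n_tot = n1 + n2
    p_bar = (alt1 + alt2) / n_tot
    msp = n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2
    msg = (n1 * p1 * (1.0 - p1) + n2 * p2 * (1.0 - p2)) / (n_tot - 2.0)
    n_c = n_tot - (n1**2 + n2**2) / n_tot
    denom = msp + (n_c - 1.0) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, (msp - msg) / np.where(denom > 0, denom, 1.0), np.nan)
    monomorphic = (p_bar == 0.0) | (p_bar == 1.0)
    theta = np.where(monomorphic, np.nan, theta)
    return float(theta) if theta.ndim == 0 else theta


def fst_hudson(ref1, alt1, ref2, alt2):
    """Hudson's F_ST estimator from allele counts (sensitivity alternative)."""
    ref1, alt1, ref2, alt2 = (np.asarray(x, dtype=float) for x in (ref1, alt1, ref2, alt2))
    n1, n2 = ref1 + alt1, ref2 + alt2
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("each population needs >= 2 allele observations")
    p1, p2 = alt1 / n1, alt2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(fst) if fst.ndim == 0 else fst


_ESTIMATORS = {"wc": fst_weir_cockerham, "hudson": fst_hudson}


def pbs_from_fst(fst_ab, fst_ac, fst_bc):
    """PBS of the focal branch from the three pairwise F_ST values.

    All inputs must be < 1 (callers clamp boundary estimates first).
    """
    arrs = [np.asarray(f, dtype=float) for f in (fst_ab, fst_ac, fst_bc)]
    for a in arrs:
        if np.any(a[~np.isnan(a)] >= 1.0):
            raise ValueError("F_ST >= 1 has an infinite branch length; clamp below 1 first")
    t_ab, t_ac, t_bc = (-np.log1p(-a) for a in arrs)
    pbs = (t_ab + t_ac - t_bc) / 2.0
    return float(pbs) if pbs.ndim == 0 else pbs


def pbs_all_branches(fst_ab, fst_ac, fst_bc):
    """PBS of all three branches (A, B, C); their sum is
    ``(T_AB + T_AC + T_BC) / 2``."""
    return (
        pbs_from_fst(fst_ab, fst_ac, fst_bc),
        pbs_from_fst(fst_ab, fst_bc, fst_ac),
        pbs_from_fst(fst_ac, fst_bc, fst_ab),
    )


def pbs_scan(
    panel: pd.DataFrame,
    focal_region: Region | str = PBS_SCAN_REGION,
    window: int = 500_000,
    estimator: str = "wc",
    two_sided: bool = False,
    bonferroni: str = "window",
) -> pd.DataFrame:
    """Genome-wide PBS with focal-window Z-scores and Bonferroni p-values.

    Parameters
    ----------
    panel : table with columns ``CHROM, POS, A_REF, A_ALT, B_REF, B_ALT,
        C_REF, C_ALT`` (population A is the focal branch).
    focal_region : the gene region; sites within ``window`` bases of it get
        Z-scores against the genome-wide PBS background (which includes the
        window itself).
    bonferroni : "window" multiplies p by the number of focal-window sites
        with defined PBS; "genome" uses all defined-PBS sites.

    Returns the per-site table with columns ``CHROM, POS, FST_AB, FST_AC,
    FST_BC, PBS, Z, P_BONF`` (Z and P_BONF are NaN outside the window).
    Sites with any undefined pairwise F_ST are dropped and counted in a log
    message.  A zero background SD is an error.
    """
    if isinstance(focal_region, str):
        focal_region = Region.parse(focal_region)
    est = _ESTIMATORS[estimator]

    fst_ab = est(panel["A_REF"], panel["A_ALT"], panel["B_REF"], panel["B_ALT"])
    fst_ac = est(panel["A_REF"], panel["A_ALT"], panel["C_REF"], panel["C_ALT"])
    fst_bc = est(panel["B_REF"], panel["B_ALT"], panel["C_REF"], panel["C_ALT"])

    defined = ~(np.isnan(fst_ab) | np.isnan(fst_ac) | np.isnan(fst_bc))
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("dropping %d sites with undefined pairwise F_ST", n_dropped)

    out = panel.loc[defined, ["CHROM", "POS"]].copy()
    fab, fac, fbc = (np.minimum(f[defined], _CLAMP) for f in (fst_ab, fst_ac, fst_bc))
    out["FST_AB"], out["FST_AC"], out["FST_BC"] = fab, fac, fbc
    out["PBS"] = pbs_from_fst(fab, fac, fbc)

    bg_mean = out["PBS"].mean()
    bg_sd = out["PBS"].std(ddof=1)
    if not np.isfinite(bg_sd) or bg_sd <= 1e-12 * max(1.0, abs(bg_mean)):
        raise ValueError("genome-background PBS SD is zero; Z-scores undefined")

    in_window = (
        (out["CHROM"] == focal_region.chrom)
        & (out["POS"] >= focal_region.start - window)
        & (out["POS"] <= focal_region.end + window)
    ).to_numpy()
    if not in_window.any():
        raise ValueError(f"no defined-PBS sites within +/-{window} bp of {focal_region}")

    z = np.full(len(out), np.nan)
    z[in_window] = (out["PBS"].to_numpy()[in_window] - bg_mean) / bg_sd
    out["Z"] = z

    n_tests = int(in_window.sum()) if bonferroni == "window" else len(out)
    p = stats.norm.sf(np.abs(z)) * 2.0 if two_sided else stats.norm.sf(z)
    out["P_BONF"] = np.minimum(p * n_tests, 1.0)
    return out.reset_index(drop=True)
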