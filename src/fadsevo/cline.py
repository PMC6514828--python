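"""Latitude cline of the ancestral-haplogroup proportion, with an
admixture covariate, and the genome-wide empirical outlier test.

The model is the ordinary least-squares regression

    proportion ~ European_admixture + latitude

fitted per population table; inference concerns the latitude coefficient
(two-sided t test).  Proportions are regressed untransformed by default
(a logit option exists).  The empirical outlier p-value of a focal site is
the fraction of genome-wide per-site regression p-values strictly smaller
than the focal one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ClineFit", "fit_cline", "empirical_outlier_p", "genome_wide_latitude_pvalues"]


@dataclass
class ClineFit:
    beta_latitude: float
    beta_admixture: float
    intercept: float
    r_squared: float
    p_latitude: float
    n: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _logit(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    p = np.clip(p, eps, 1 - eps)
    return np.log(p / (1 - p))


def fit_cline(table: pd.DataFrame, logit: bool = False) -> ClineFit:
    """OLS fit of ``proportion ~ admixture + latitude`` with intercept.

    Requires >= 4 rows and non-constant latitude; near-collinear covariates
    (|corr| > 0.999) are an error.  A constant admixture column is dropped
    (its coefficient reported as 0) so exactly-linear latitude examples
    remain full rank.
    """
    required = {"proportion", "admixture", "latitude"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cline table missing columns: {sorted(missing)}")
    if len(table) < 4:
        raise ValueError("need >= 4 populations to fit the cline")
    lat = table["latitude"].to_numpy(dtype=float)
    adm = table["admixture"].to_numpy(dtype=float)
    y = table["proportion"].to_numpy(dtype=float)
    if logit:
        y = _logit(y)
    if np.ptp(lat) == 0:
        raise ValueError("latitude is constant; cline undefined")
    if np.ptp(y) == 0:
        # flat response: no cline, trivially zero fit
        return ClineFit(0.0, 0.0, float(y[0]), 0.0, 1.0, len(table))
    use_adm = np.ptp(adm) > 0
    if use_adm and abs(np.corrcoef(adm, lat)[0, 1]) > 0.999:
        raise ValueError("admixture and latitude are collinear (|corr| > 0.999)")

    cols = {"admixture": adm, "latitude": lat} if use_adm else {"latitude": lat}
    X = sm.add_constant(pd.DataFrame(cols))
    res = sm.OLS(y, X).fit()
    return ClineFit(
        beta_latitude=float(res.params["latitude"]),
        beta_admixture=float(res.params.get("admixture", 0.0)),
        intercept=float(res.params["const"]),
        r_squared=float(res.rsquared),
        p_latitude=float(res.pvalues["latitude"]),
        n=len(table),
    )


def empirical_outlier_p(focal_p: float, background_p) -> float:
    """Fraction of background p-values strictly smaller than the focal one.

    The denominator is the full background set (which may include the focal
    site itself); ties count as not smaller.
    """
    bg = np.asarray(background_p, dtype=float)
    if bg.size == 0:
        raise ValueError("empty background p-value set")
    return float((bg < focal_p).sum() / bg.size)


def genome_wide_latitude_pvalues(
    site_proportions: np.ndarray | pd.DataFrame,
    admixture: np.ndarray,
    latitude: np.ndarray,
) -> np.ndarray:
    """Per-site latitude p-values for the empirical null: fits the same
    proportion ~ admixture + latitude model at every site (rows = sites,
    columns = populations)."""
    mat = np.asarray(site_proportions, dtype=float)
    out = np.empty(mat.shape[0])
    base = pd.DataFrame({"admixture": np.asarray(admixture, float), "latitude": np.asarray(latitude, float)})
    for i in range(mat.shape[0]):
        table = base.copy()
        table["proportion"] = mat[i]
        out[i] = fit_cline(table).p_latitude
    return out
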