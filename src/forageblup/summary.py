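"""Genetic-parameter and selection summaries from REML/BLUP fits.

Narrow-sense heritability h2n = s2A / s2P (s2P the sum of the fitted
variance components), breeding-value tables with rankings, genetic
correlations from bivariate G matrices, and the selection-response
arithmetic: direct response R = i h2 sigmaP, correlated response
CR = i rg hx hy sigmaP(y), and relative selection efficiency
RSE = CR / R (equivalently rg hx / hy).

``as_reported`` mode rounds intermediate h2 and rg to two decimals
before the response formulas, matching how printed summary tables are
customarily derived from rounded heritabilities; full precision is the
default for new analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import OrderedPedigree
from .reml import REMLResult
from .studydesign import family_of

DEFAULT_INTENSITY = 1.75  # 10% selected


class UndefinedQuantityError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2n: float
    se: float | None
    trait: str | None = None
    scope: str | None = None


@dataclass(frozen=True)
class SelectionSummary:
    i: float
    rg: float
    h_x: float
    h_y: float
    sigmaP_y: float
    R_y: float
    CR_y: float
    RSE: float


def heritability_from_components(
    sigma2_A: float, sigma2_P: float, trait=None, scope=None
) -> HeritabilityEstimate:
    """h2n from already-summed components (worked-example path)."""
    if sigma2_P == 0:
        raise UndefinedQuantityError("phenotypic variance is zero")
    return HeritabilityEstimate(h2n=sigma2_A / sigma2_P, se=None, trait=trait, scope=scope)


def heritability(result: REMLResult, trait=None, scope=None) -> HeritabilityEstimate:
    """h2n = s2A / s2P with a delta-method SE from the inverse AI matrix.

    s2P sums all fitted components; cut-specific residual variances
    enter through their mean.
    """
    vc = result.vc
    if vc.sigma2_A is None:
        raise ValueError("fit has no additive variance component")
    s2P = vc.sigma2_P
    if not s2P:
        raise UndefinedQuantityError("phenotypic variance is zero")
    h2 = vc.sigma2_A / s2P

    # gradient of a/P wrt each packed parameter
    names = result.param_names
    grad = np.zeros(len(names))
    e_names = [n for n in names if n.startswith("sigma2_e")]
    for i, n in enumerate(names):
        if n == "sigma2_A":
            grad[i] = (s2P - vc.sigma2_A) / s2P**2
        elif n == "sigma2_pe":
            grad[i] = -vc.sigma2_A / s2P**2
        elif n.startswith("sigma2_e"):
            grad[i] = -vc.sigma2_A / (len(e_names) * s2P**2)
    try:
        var = float(grad @ result.theta_cov() @ grad)
        se = float(np.sqrt(max(var, 0.0)))
    except np.linalg.LinAlgError:
        se = None
    return HeritabilityEstimate(
        h2n=h2, se=se, trait=trait or result.meta.get("trait"), scope=scope
    )


def genetic_correlation(result: REMLResult) -> tuple[float, float | None]:
    """rg = G_xy / sqrt(G_xx G_yy) from a bivariate fit, with
    delta-method SE on the inverse AI matrix."""
    G = result.vc.G_mat
    if G is None or G.shape != (2, 2):
        raise ValueError("genetic correlation needs a bivariate fit")
    gxx, gxy, gyy = G[0, 0], G[0, 1], G[1, 1]
    if gxx <= 0 or gyy <= 0:
        raise UndefinedQuantityError("zero genetic variance in one trait")
    rg = gxy / np.sqrt(gxx * gyy)
    names = result.param_names
    grad = np.zeros(len(names))
    mapping = {"G[0,0]": -rg / (2 * gxx), "G[0,1]": 1.0 / np.sqrt(gxx * gyy), "G[1,1]": -rg / (2 * gyy)}
    for i, n in enumerate(names):
        if n in mapping:
            grad[i] = mapping[n]
    try:
        var = float(grad @ result.theta_cov() @ grad)
        se = float(np.sqrt(max(var, 0.0)))
    except np.linalg.LinAlgError:
        se = None
    return float(rg), se


def selection_response(
    h2n: float, sigmaP: float, i: float = DEFAULT_INTENSITY, as_reported: bool = False
) -> float:
    """Direct response to selection R = i h2 sigmaP."""
    if as_reported:
        h2n = round(h2n, 2)
    return i * h2n * sigmaP


def correlated_response(
    rg: float,
    h_x: float,
    h_y: float,
    sigmaP_y: float,
    i: float = DEFAULT_INTENSITY,
) -> float:
    """Correlated response CR_y = i rg h_x h_y sigmaP(y)."""
    if abs(rg) > 1 + 1e-12:
        raise ValueError("|rg| must be <= 1")
    return i * rg * h_x * h_y * sigmaP_y


def correlated_response_from_h2(
    rg: float,
    h2_x: float,
    h2_y: float,
    sigmaP_y: float,
    i: float = DEFAULT_INTENSITY,
    as_reported: bool = False,
) -> float:
    if as_reported:
        rg, h2_x, h2_y = round(rg, 2), round(h2_x, 2), round(h2_y, 2)
    return correlated_response(rg, np.sqrt(h2_x), np.sqrt(h2_y), sigmaP_y, i=i)


def rse(CR_y: float, R_y: float) -> float:
    """Relative selection efficiency CR_y / R_y (= rg h_x / h_y)."""
    if R_y == 0:
        raise UndefinedQuantityError("direct response is zero")
    return CR_y / R_y


def indirect_selection_summary(
    rg_value: float,
    h2_x: float,
    h2_y: float,
    sigma2P_y: float,
    i: float = DEFAULT_INTENSITY,
    as_reported: bool = False,
) -> SelectionSummary:
    """Full R / CR / RSE chain for selecting on trait x to improve y."""
    if as_reported:
        rg_value, h2_x, h2_y = round(rg_value, 2), round(h2_x, 2), round(h2_y, 2)
    sP = float(np.sqrt(sigma2P_y))
    R = i * h2_y * sP
    CR = correlated_response(rg_value, np.sqrt(h2_x), np.sqrt(h2_y), sP, i=i)
    return SelectionSummary(
        i=i, rg=rg_value, h_x=float(np.sqrt(h2_x)), h_y=float(np.sqrt(h2_y)),
        sigmaP_y=sP, R_y=R, CR_y=CR,
        RSE=rse(CR, R) if R > 0 else float("nan"),
    )


def breeding_value_table(
    results: dict[str, REMLResult], ped: OrderedPedigree
) -> pd.DataFrame:
    """Genetic BLUPs for every pedigree member, with per-trait ranks.

    ``results`` maps trait name to a univariate (single- or multi-cut
    repeatability) fit; ranks are descending (1 = highest breeding
    value).  A trait whose additive variance collapsed to the boundary
    yields all-zero BVs and a degenerate ranking, flagged in the
    ``degenerate`` attribute set.
    """
    rows = {"id": list(ped.ids)}
    rows["role"] = ["parent" if ped.sire[i] < 0 and ped.dam[i] < 0 else "progeny" for i in range(ped.n)]
    rows["family"] = [family_of(x) or "" for x in ped.ids]
    df = pd.DataFrame(rows)
    degenerate = []
    for trait, res in results.items():
        u = np.asarray(res.u_genetic)
        if len(u) != ped.n:
            raise ValueError(f"fit for {trait!r} does not cover the pedigree")
        df[f"BV_{trait}"] = u
        if res.boundary or np.allclose(u, 0.0):
            degenerate.append(trait)
        df[f"rank_{trait}"] = (
            pd.Series(u).rank(ascending=False, method="min").astype(int)
        )
    df.attrs["degenerate_traits"] = degenerate
    return df
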