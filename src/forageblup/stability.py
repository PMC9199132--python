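"""Yield stability and multivariate genotype screening.

Eberhart-Russell stability: for each entry, the ordinary least-squares
regression of its yearly mean yield on the environmental index (the
grand mean of all entries in that year).  b = 1 indicates average
stability; the slope is tested against 1 with a two-sided t-test on
n_years - 2 degrees of freedom.  The deviation-from-regression variance
S2d is reported alongside as the second Eberhart-Russell parameter.

Genotype screening uses correlation-matrix PCA of entity x trait means
with biplot output; entity sets (parents, families, progenies) are
analyzed separately, each with its own environmental index / scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PCAResult:
    scores: pd.DataFrame  # entity x component
    loadings: pd.DataFrame  # trait x component
    var_explained: np.ndarray  # percent per component, sums to 100
    standardized: pd.DataFrame


def eberhart_russell(yearly_means: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Stability slopes for an entity x year matrix of yields.

    The environmental index is the per-year mean over all entities
    (computed from complete data).  Entities missing a year are fitted
    on their available years and flagged; entities with fewer than 3
    usable years are omitted with a warning.

    Returns a DataFrame indexed by entity with columns
    ``b, se_b, t_vs_1, p_vs_1, significant_vs_1, S2d, n_years, complete``.
    """
    ym = yearly_means.astype(float)
    if ym.shape[1] < 3:
        raise ValueError("stability regression needs at least 3 years")
    env = ym.mean(axis=0)  # environmental index per year

    rows = {}
    for entity, vals in ym.iterrows():
        ok = vals.notna()
        n = int(ok.sum())
        if n < 3:
            warnings.warn(
                f"entity {entity!r} has fewer than 3 usable years; omitted", UserWarning
            )
            continue
        x = env[ok].to_numpy()
        y = vals[ok].to_numpy()
        xc = x - x.mean()
        sxx = float(xc @ xc)
        b = float(xc @ (y - y.mean()) / sxx)
        resid = y - (y.mean() + b * xc)
        df_res = n - 2
        s2d = float(resid @ resid / df_res)  # deviation-from-regression variance
        se_b = float(np.sqrt(s2d / sxx))
        if se_b > 0:
            tstat = (b - 1.0) / se_b
        else:  # perfect fit: significant iff the slope itself differs from 1
            tstat = 0.0 if np.isclose(b, 1.0) else np.inf
        pval = 2.0 * stats.t.sf(abs(tstat), df_res)
        rows[entity] = {
            "b": b,
            "se_b": se_b,
            "t_vs_1": tstat,
            "p_vs_1": pval,
            "significant_vs_1": bool(pval < alpha),
            "S2d": s2d,
            "n_years": n,
            "complete": bool(ok.all()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def pca_biplot(trait_means: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of an entity x trait table.

    Traits are standardized (mean 0, unit sample variance); constant
    traits are dropped with a warning.  Component signs are fixed by
    making the largest-magnitude loading of each component positive, so
    output is invariant to entity order.
    """
    tm = trait_means.astype(float)
    if tm.shape[0] < 2 or tm.shape[1] < 2:
        raise ValueError("PCA needs at least 2 entities and 2 traits")
    sd = tm.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant traits dropped from PCA: {constant}", UserWarning)
        tm = tm.drop(columns=constant)
        sd = sd.drop(index=constant)
    Zs = (tm - tm.mean(axis=0)) / sd

    U, svals, Vt = np.linalg.svd(Zs.to_numpy(), full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for k in range(len(svals)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    eig = svals**2
    var_explained = 100.0 * eig / eig.sum() if eig.sum() > 0 else eig
    comp = [f"PC{k + 1}" for k in range(len(svals))]
    scores = pd.DataFrame(U * svals, index=tm.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=tm.columns, columns=comp)
    return PCAResult(
        scores=scores, loadings=loadings, var_explained=var_explained, standardized=Zs
    )


def plot_biplot(pca: PCAResult, path, title: str = "") -> None:
    """Render a PC1/PC2 biplot (scores + trait loading arrows) to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    sc = pca.scores
    ax.scatter(sc.iloc[:, 0], sc.iloc[:, 1], s=14, color="tab:blue")
    for name, row in sc.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1]), fontsize=6, alpha=0.7)
    scale = 0.9 * np.abs(sc.iloc[:, :2].to_numpy()).max() if len(sc) else 1.0
    for trait, row in pca.loadings.iterrows():
        ax.arrow(0, 0, row.iloc[0] * scale, row.iloc[1] * scale,
                 color="tab:red", head_width=0.02 * scale, length_includes_head=True)
        ax.annotate(trait, (row.iloc[0] * scale * 1.06, row.iloc[1] * scale * 1.06),
                    color="tab:red", fontsize=8)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(f"PC1 ({pca.var_explained[0]:.1f}%)")
    if len(pca.var_explained) > 1:
        ax.set_ylabel(f"PC2 ({pca.var_explained[1]:.1f}%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
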