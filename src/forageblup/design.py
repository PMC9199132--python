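"""Phenotype table handling and incidence-matrix construction.

Phenotypes live in a long-format :class:`pandas.DataFrame` with one row
per (genotype, replicate, year, harvest) plot record and one column per
trait.  Fixed factors are expanded to reference-level (drop-first)
dummies so that X is full rank; the genetic incidence Z always carries a
column for every pedigree member (individuals without records still
receive breeding values through A), and the permanent-environment
incidence W indexes the physical plant, i.e. the genotype x replicate
clone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import OrderedPedigree

KEY_COLUMNS = ("genotype", "replicate", "year", "harvest")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a univariate animal model.

    ``fixed`` lists categorical columns modelled as fixed factors (an
    intercept is always included); the genetic term uses the pedigree
    relationship matrix, and ``permanent_env`` adds a plant-level
    random effect with identity covariance.
    """

    response: str
    fixed: tuple[str, ...] = ("year",)
    permanent_env: bool = False


@dataclass
class DesignMatrices:
    X: np.ndarray
    Z: sp.csr_matrix
    W: sp.csr_matrix | None
    y: np.ndarray
    fixed_names: list[str]
    plant_labels: list[tuple] = field(default_factory=list)
    rows: pd.DataFrame | None = None


def validate_phenotypes(pheno: pd.DataFrame, ped: OrderedPedigree, traits=None) -> None:
    """Check key uniqueness and pedigree coverage; raise on violation."""
    missing_cols = [c for c in KEY_COLUMNS if c not in pheno.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks key columns {missing_cols}")
    dup = pheno.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicated (genotype, replicate, year, harvest) records"
        )
    unknown = set(pheno["genotype"].astype(str)) - set(ped.ids)
    if unknown:
        raise KeyError(f"genotypes absent from pedigree: {sorted(unknown)[:5]} ...")
    if traits:
        lacking = [t for t in traits if t not in pheno.columns]
        if lacking:
            raise ValueError(f"trait columns missing from table: {lacking}")


def dummy_code(values: pd.Series, factor: str) -> tuple[np.ndarray, list[str]]:
    """Drop-first dummy coding with sorted levels; degenerate factors
    (a single observed level) are dropped with a warning."""
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        warnings.warn(
            f"fixed factor {factor!r} has a single level and was dropped",
            UserWarning,
            stacklevel=3,
        )
        return np.empty((len(values), 0)), []
    cols = []
    names = []
    for lev in levels[1:]:
        cols.append((values == lev).to_numpy(dtype=float))
        names.append(f"{factor}[{lev}]")
    return np.column_stack(cols), names


def build_design_matrices(
    pheno: pd.DataFrame, spec: ModelSpec, ped: OrderedPedigree
) -> DesignMatrices:
    """Build (X, Z, W) and the response vector for ``spec``.

    Rows with a missing response are dropped.  X gets an intercept plus
    drop-first dummies per fixed factor; Z has one column per pedigree
    member; W (when requested) one column per observed plant.
    """
    df = pheno.loc[pheno[spec.response].notna()].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"no non-missing records for trait {spec.response!r}")
    n = len(df)

    blocks = [np.ones((n, 1))]
    names = ["(intercept)"]
    for fac in spec.fixed:
        mat, nm = dummy_code(df[fac], fac)
        if mat.shape[1]:
            blocks.append(mat)
            names.extend(nm)
    X = np.column_stack(blocks)

    gidx = df["genotype"].astype(str).map(ped.index_of)
    if gidx.isna().any():
        bad = df.loc[gidx.isna(), "genotype"].unique()
        raise KeyError(f"genotypes absent from pedigree: {list(bad)[:5]}")
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), gidx.to_numpy(dtype=int))),
        shape=(n, ped.n),
    )

    W = None
    plant_labels: list[tuple] = []
    if spec.permanent_env:
        plants = list(zip(df["genotype"].astype(str), df["replicate"]))
        plant_labels = sorted(set(plants))
        pmap = {p: j for j, p in enumerate(plant_labels)}
        pidx = np.array([pmap[p] for p in plants])
        W = sp.csr_matrix(
            (np.ones(n), (np.arange(n), pidx)), shape=(n, len(plant_labels))
        )

    y = df[spec.response].to_numpy(dtype=float)
    return DesignMatrices(
        X=X, Z=Z, W=W, y=y, fixed_names=names, plant_labels=plant_labels, rows=df
    )
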