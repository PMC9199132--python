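"""Synthetic trial generator with the exact structure the models assume.

Generates pedigrees (the real 21-parent / 42-family / 120-progeny trial
design, or randomized variants), multi-trait breeding values by the
mendelian-sampling recursion (so that Cov(a) = SigmaG (x) A by
construction), and long-format plot records

    y = mean + year + harvest + breeding value + permanent environment + residual,

where clones of a genotype share its breeding value, the permanent
environment is drawn once per physical plant (genotype x replicate) and
shared across its repeated measures, and residuals are independent
across records with cut-specific variances and an optional cross-trait
correlation within a record.

Default variance components, seasonal means and genetic correlations
are set to the scale the trial reported (forage yield in g/plant with
sigma2_A near 4.4e3 and phenotypic variance near 1.9e4, etc.), so
synthetic output is directly comparable with the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import studydesign as sd
from .pedigree import OrderedPedigree, PedigreeRecord, validate_and_order

DEFAULT_SEED = 20170101


@dataclass(frozen=True)
class TraitTruth:
    """True components for one trait (trait units squared)."""

    sigma2_A: float
    sigma2_pe: float
    sigma2_e: dict[str, float]  # per harvest
    grand_mean: float
    year_effects: dict[int, float]
    harvest_effects: dict[str, float]
    spring_only: bool = False


def _default_traits() -> dict[str, TraitTruth]:
    return {
        "DFY": TraitTruth(
            sigma2_A=4350.66, sigma2_pe=3000.0,
            sigma2_e={"spring": 14000.0, "summer": 10000.0, "autumn": 11250.0},
            grand_mean=150.0,
            year_effects={2017: -80.0, 2018: 60.0, 2019: 110.0, 2020: -30.0},
            harvest_effects={"spring": 80.0, "summer": -60.0, "autumn": -20.0},
        ),
        "H": TraitTruth(
            sigma2_A=75.60, sigma2_pe=40.0,
            sigma2_e={"spring": 120.0, "summer": 95.0, "autumn": 110.0},
            grand_mean=55.0,
            year_effects={2017: -15.0, 2018: 5.0, 2019: 25.0, 2020: -5.0},
            harvest_effects={"spring": 15.0, "summer": -15.0, "autumn": 0.0},
        ),
        "CD": TraitTruth(
            sigma2_A=12.61, sigma2_pe=5.0,
            sigma2_e={"spring": 13.6, "summer": 11.6, "autumn": 12.6},
            grand_mean=18.0,
            year_effects={2017: -5.0, 2018: 0.0, 2019: 8.0, 2020: -3.0},
            harvest_effects={"spring": 4.0, "summer": -5.0, "autumn": 1.0},
        ),
        "NS": TraitTruth(
            sigma2_A=71.22, sigma2_pe=40.0,
            sigma2_e={"spring": 78.3},
            grand_mean=45.0,
            year_effects={2017: -10.0, 2018: 0.0, 2019: 15.0, 2020: -5.0},
            harvest_effects={"spring": 0.0},
            spring_only=True,
        ),
        "FL": TraitTruth(
            sigma2_A=9.50, sigma2_pe=6.0,
            sigma2_e={"spring": 15.7},
            grand_mean=160.0,
            year_effects={2017: -3.0, 2018: 2.0, 2019: 4.0, 2020: -3.0},
            harvest_effects={"spring": 0.0},
            spring_only=True,
        ),
    }


def _default_genetic_corr(traits: tuple[str, ...]) -> pd.DataFrame:
    full = pd.DataFrame(np.eye(5), index=sd.TRAITS, columns=sd.TRAITS)
    pub = {
        ("DFY", "H"): 0.86, ("DFY", "CD"): 0.85, ("DFY", "NS"): 0.83,
        ("DFY", "FL"): 0.50, ("H", "CD"): 0.65, ("H", "NS"): 0.69,
        ("H", "FL"): 0.38, ("CD", "NS"): 0.59, ("CD", "FL"): 0.44,
        ("NS", "FL"): 0.36,
    }
    for (a, b), r in pub.items():
        full.loc[a, b] = full.loc[b, a] = r
    return full.loc[list(traits), list(traits)]


@dataclass
class SimulationTruth:
    """Full specification of one synthetic trial."""

    traits: tuple[str, ...] = sd.TRAITS
    trait_truth: dict[str, TraitTruth] = field(default_factory=_default_traits)
    genetic_corr: pd.DataFrame | None = None
    resid_corr: float = 0.2  # cross-trait residual correlation within a record
    n_reps: int = sd.N_REPS
    years: tuple[int, ...] = sd.YEARS
    harvests: tuple[str, ...] = sd.HARVESTS
    pedigree_mode: str = "study"  # or "random"
    n_parents: int = sd.N_PARENTS
    n_families: int = sd.N_FAMILIES
    mean_family_size: float = sd.N_PROGENY / sd.N_FAMILIES
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.genetic_corr is None:
            self.genetic_corr = _default_genetic_corr(self.traits)
        C = self.genetic_corr.loc[list(self.traits), list(self.traits)].to_numpy()
        if np.linalg.eigvalsh(C)[0] <= 0:
            raise ValueError("genetic correlation matrix is not positive definite")
        for t in self.traits:
            if t not in self.trait_truth:
                raise ValueError(f"no truth configured for trait {t!r}")
            for v in (self.trait_truth[t].sigma2_A, self.trait_truth[t].sigma2_pe):
                if v < 0:
                    raise ValueError("variance components must be >= 0")

    def genetic_cov(self) -> np.ndarray:
        """SigmaG: trait genetic covariance matrix."""
        s = np.sqrt([self.trait_truth[t].sigma2_A for t in self.traits])
        C = self.genetic_corr.loc[list(self.traits), list(self.traits)].to_numpy()
        return C * np.outer(s, s)


@dataclass
class SimulatedDataset:
    pedigree: OrderedPedigree
    phenotypes: pd.DataFrame
    true_bv: pd.DataFrame  # individual x trait
    truth: SimulationTruth


def reduced_truth(truth: SimulationTruth, n_families: int, seed=None, **kw) -> SimulationTruth:
    """A smaller randomized design with the same variance structure."""
    return replace(
        truth,
        pedigree_mode="random",
        n_families=n_families,
        seed=truth.seed if seed is None else seed,
        **kw,
    )


def simulate_pedigree(truth: SimulationTruth, rng: np.random.Generator) -> OrderedPedigree:
    """Trial pedigree: exact study design, or a randomized analogue.

    Random mode samples ``n_families`` distinct parent pairs from
    ``n_parents`` founders and Poisson family sizes (mean
    ``mean_family_size``, at least 1).
    """
    if truth.pedigree_mode == "study":
        return sd.study_pedigree()
    parents = [f"P{i + 1}" for i in range(truth.n_parents)]
    recs = [PedigreeRecord(p) for p in parents]
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < truth.n_families:
        i, j = rng.choice(truth.n_parents, size=2, replace=False)
        pairs.add((int(i), int(j)))
    for code, (i, j) in enumerate(sorted(pairs), start=1):
        n_prog = max(1, int(rng.poisson(truth.mean_family_size)))
        for k in range(1, n_prog + 1):
            recs.append(
                PedigreeRecord(sd.progeny_id(code, k), sire_id=parents[j], dam_id=parents[i])
            )
    return validate_and_order(recs)


def simulate_breeding_values(
    ped: OrderedPedigree, truth: SimulationTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Multi-trait breeding values via the mendelian-sampling recursion.

    Founders are drawn from N(0, SigmaG); a descendant receives the
    parental average plus a mendelian deviation with covariance
    (1 - 0.25(1+F_s) - 0.25(1+F_d)) SigmaG, terms dropped for unknown
    parents.  Cov(vec a) = SigmaG (x) A exactly.
    """
    SigmaG = truth.genetic_cov()
    t = len(truth.traits)
    L = np.linalg.cholesky(SigmaG) if np.any(np.diag(SigmaG) > 0) else np.zeros((t, t))
    F = ped.inbreeding()
    bv = np.zeros((ped.n, t))
    for i in range(ped.n):
        d_i = 1.0
        mean = np.zeros(t)
        for par in (ped.sire[i], ped.dam[i]):
            if par >= 0:
                d_i -= 0.25 * (1.0 + F[par])
                mean += 0.5 * bv[par]
        bv[i] = mean + np.sqrt(d_i) * (L @ rng.standard_normal(t))
    return pd.DataFrame(bv, index=ped.ids, columns=list(truth.traits))


def simulate_phenotypes(
    ped: OrderedPedigree,
    true_bv: pd.DataFrame,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Plot records for every (genotype, replicate, year, harvest).

    Spring-only traits are missing outside the spring cut.  Residuals
    within a record share correlation ``resid_corr`` across traits.
    """
    traits = list(truth.traits)
    t = len(traits)
    Ce = np.full((t, t), truth.resid_corr) + (1 - truth.resid_corr) * np.eye(t)
    Le = np.linalg.cholesky(Ce)

    rows = []
    bv = true_bv.loc[ped.ids].to_numpy()
    for gi, geno in enumerate(ped.ids):
        for rep in range(1, truth.n_reps + 1):
            pe = np.array(
                [np.sqrt(truth.trait_truth[tr].sigma2_pe) for tr in traits]
            ) * rng.standard_normal(t)
            for year in truth.years:
                for harv in truth.harvests:
                    z = Le @ rng.standard_normal(t)
                    rec = {"genotype": geno, "replicate": rep, "year": year, "harvest": harv}
                    for k, tr in enumerate(traits):
                        tt = truth.trait_truth[tr]
                        if tt.spring_only and harv != "spring":
                            rec[tr] = np.nan
                            continue
                        sde = np.sqrt(tt.sigma2_e[harv])
                        rec[tr] = (
                            tt.grand_mean
                            + tt.year_effects[year]
                            + tt.harvest_effects[harv]
                            + bv[gi, k]
                            + pe[k]
                            + sde * z[k]
                        )
                    rows.append(rec)
    return pd.DataFrame(rows)


def simulate_dataset(truth: SimulationTruth, seed: int | None = None) -> SimulatedDataset:
    """Pedigree + breeding values + phenotypes for one replicate trial."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ped = simulate_pedigree(truth, rng)
    bv = simulate_breeding_values(ped, truth, rng)
    pheno = simulate_phenotypes(ped, bv, truth, rng)
    return SimulatedDataset(pedigree=ped, phenotypes=pheno, true_bv=bv, truth=truth)
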