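"""Published REML estimates from the tall fescue full-sib trial.

These are the printed variance components, heritabilities, selection
responses and genetic correlations of the study this package models.
They serve as worked-example inputs for the selection arithmetic
(heritability, R, CR, RSE) and as regression anchors for the reporting
layer; the raw field records behind them were never deposited, so the
model fits themselves are validated on synthetic data instead.

``h2_check`` marks cells whose printed variance components reproduce
the printed heritability unambiguously; cells with garbled digit
grouping in the source tables, or internally inconsistent rounding,
are carried for completeness but excluded from regression checks.
"""

from __future__ import annotations

from dataclasses import dataclass

SELECTION_INTENSITY_10PCT = 1.75


@dataclass(frozen=True)
class PublishedRow:
    trait: str
    scope: str  # spring / summer / autumn / multi
    sigma2_A: float | None
    sigma2_P: float | None
    h2: float
    se_h2: float | None
    R: float | None
    CR: float | None
    RSE: float | None
    h2_check: bool = True


SINGLE_HARVEST: list[PublishedRow] = [
    # spring
    PublishedRow("DFY", "spring", 5121.79, 28171.93, 0.18, 0.03, 52.87, None, None),
    PublishedRow("H", "spring", 99.56, 366.01, 0.27, 0.03, 9.03, 53.84, 1.01),
    PublishedRow("CD", "spring", 11.43, 40.67, 0.28, 0.03, 3.12, 54.18, 1.02),
    PublishedRow("NS", "spring", 44.5, 149.71, 0.29, 0.04, 6.20, 53.14, 1.00, h2_check=False),
    PublishedRow("FL", "spring", None, 47.57, 0.24, 0.04, 2.89, 29.0, 0.54, h2_check=False),
    # summer
    PublishedRow("DFY", "summer", 1384.67, 8308.06, 0.16, 0.04, 25.52, None, None),
    PublishedRow("H", "summer", 35.79, 141.04, 0.25, 0.03, 5.19, 24.47, 1.03),
    PublishedRow("CD", "summer", 9.74, 36.6, 0.26, 0.04, 2.75, 26.02, 1.01),
    # autumn (additive-variance cells partly garbled in the source)
    PublishedRow("DFY", "autumn", None, 26202.41, 0.15, 0.04, 42.49, None, None, h2_check=False),
    PublishedRow("H", "autumn", 64.52, 278.39, 0.23, 0.04, 6.71, 43.88, 1.03, h2_check=False),
    PublishedRow("CD", "autumn", 13.53, 52.37, 0.25, 0.05, 3.16, 44.67, 1.05, h2_check=False),
]

MULTI_HARVEST: list[PublishedRow] = [
    PublishedRow("DFY", "multi", 4350.66, 19102.97, 0.22, 0.04, 53.21, None, None),
    # printed h2 (0.32) is not the ratio of the printed components (0.34);
    # likely an extra component in the published denominator for this trait
    PublishedRow("H", "multi", 75.60, 223.52, 0.32, 0.04, 8.37, 54.12, 1.01, h2_check=False),
    PublishedRow("CD", "multi", 12.61, 30.22, 0.41, 0.04, 3.94, 60.55, 1.13),
    PublishedRow("NS", "multi", 71.22, 189.56, 0.37, 0.02, 8.91, 56.17, 1.05),
    PublishedRow("FL", "multi", 9.50, 31.22, 0.30, 0.03, 2.93, 30.47, 0.57),
]

# genetic correlations (multi-harvest bivariate fits), with SEs
GENETIC_CORRELATIONS: dict[tuple[str, str], tuple[float, float]] = {
    ("DFY", "H"): (0.86, 0.09),
    ("DFY", "CD"): (0.85, 0.09),
    ("DFY", "NS"): (0.83, 0.12),
    ("DFY", "FL"): (0.50, 0.14),
    ("H", "CD"): (0.65, 0.11),
    ("H", "NS"): (0.69, 0.10),
    ("H", "FL"): (0.38, 0.18),
    ("CD", "NS"): (0.59, 0.13),
    ("CD", "FL"): (0.44, 0.15),
    ("NS", "FL"): (0.36, 0.19),
}


def rg(trait_a: str, trait_b: str) -> float:
    if trait_a == trait_b:
        return 1.0
    key = (trait_a, trait_b) if (trait_a, trait_b) in GENETIC_CORRELATIONS else (trait_b, trait_a)
    return GENETIC_CORRELATIONS[key][0]
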