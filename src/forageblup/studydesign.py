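"""Design of the tall fescue full-sib breeding trial this package models.

Twenty-one field-collected parental genotypes were intercrossed (polycross,
with paternity later resolved by EST-SSR markers), yielding 42 full-sib
families comprising 120 progeny genotypes.  Parents and progenies were
clonally replicated (2 replicates) in a randomized complete block design
and measured over 4 years (2017-2020) at three seasonal harvests
(spring, summer, autumn).

``CROSSES`` lists (family_code, dam, sire, n_progeny).  Reciprocal
crosses (e.g. families 15 and 25) are genetically full sibs.
"""

from __future__ import annotations

from .pedigree import OrderedPedigree, PedigreeRecord, validate_and_order

PARENTS: list[str] = [
    "1E", "2E", "3E", "4E", "10E", "14E", "16E",
    "1M", "3M", "11M", "17M", "21M", "22M", "23M",
    "2L", "3L", "6L", "12L", "15L", "20L", "25L",
]

# (family code, dam, sire, number of progeny genotypes)
CROSSES: list[tuple[int, str, str, int]] = [
    (1, "1E", "2E", 2),
    (2, "1E", "4E", 1),
    (3, "1E", "1M", 6),
    (4, "3E", "10E", 2),
    (5, "3E", "14E", 2),
    (6, "3E", "1M", 1),
    (7, "3E", "11M", 3),
    (8, "4E", "11M", 2),
    (9, "4E", "17M", 3),
    (10, "10E", "1M", 5),
    (11, "14E", "1E", 1),
    (12, "14E", "2E", 11),
    (13, "14E", "25L", 2),
    (14, "14E", "11M", 6),
    (15, "1M", "21M", 3),
    (16, "3M", "2E", 3),
    (17, "3M", "1M", 4),
    (18, "3M", "6L", 1),
    (19, "11M", "2E", 9),
    (20, "11M", "16E", 1),
    (21, "11M", "1M", 1),
    (22, "17M", "1M", 7),
    (23, "17M", "2L", 1),
    (24, "21M", "14E", 2),
    (25, "21M", "1M", 3),
    (26, "21M", "11M", 2),
    (27, "21M", "6L", 1),
    (28, "22M", "4E", 2),
    (29, "22M", "10E", 1),
    (30, "22M", "1M", 2),
    (31, "22M", "21M", 1),
    (32, "23M", "14E", 2),
    (33, "23M", "17M", 2),
    (34, "23M", "3L", 2),
    (35, "23M", "15L", 1),
    (36, "6L", "1E", 2),
    (37, "6L", "1M", 1),
    (38, "12L", "1E", 6),
    (39, "12L", "1M", 4),
    (40, "12L", "2L", 3),
    (41, "20L", "4E", 4),
    (42, "20L", "14E", 2),
]

N_PARENTS = len(PARENTS)
N_FAMILIES = len(CROSSES)
N_PROGENY = sum(n for _, _, _, n in CROSSES)

YEARS = (2017, 2018, 2019, 2020)
HARVESTS = ("spring", "summer", "autumn")
N_REPS = 2

TRAITS = ("DFY", "H", "CD", "NS", "FL")
# NS and FL are scored once per year, at the spring harvest
SPRING_ONLY_TRAITS = ("NS", "FL")


def progeny_id(family_code: int, k: int) -> str:
    """Stable label for the k-th progeny (1-based) of a family."""
    return f"F{family_code:02d}-{k}"


def family_of(individual_id: str) -> str | None:
    """Family cross label for a progeny id, None for parents."""
    if individual_id.startswith("F") and "-" in individual_id:
        return individual_id.split("-")[0]
    return None


def cross_label(family_code: int) -> str:
    for code, dam, sire, _ in CROSSES:
        if code == family_code:
            return f"{dam} x {sire}"
    raise KeyError(family_code)


def study_pedigree_records() -> list[PedigreeRecord]:
    """The full trial pedigree: 21 founder parents + 120 progenies."""
    recs = [PedigreeRecord(p) for p in PARENTS]
    for code, dam, sire, n in CROSSES:
        for k in range(1, n + 1):
            recs.append(PedigreeRecord(progeny_id(code, k), sire_id=sire, dam_id=dam))
    return recs


def study_pedigree() -> OrderedPedigree:
    return validate_and_order(study_pedigree_records())
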