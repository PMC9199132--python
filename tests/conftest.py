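import numpy as np
import pytest

from forageblup import pedigree as pg
from forageblup import studydesign as sd


def random_pedigree(n: int, n_founders: int, rng: np.random.Generator) -> pg.OrderedPedigree:
    """Random valid pedigree: founders first, later individuals draw
    parents among earlier ones (possibly unknown)."""
    recs = [pg.PedigreeRecord(f"I{i}") for i in range(n_founders)]
    for i in range(n_founders, n):
        pick = rng.random()
        if pick < 0.1:
            recs.append(pg.PedigreeRecord(f"I{i}", f"I{rng.integers(i)}", pg.UNKNOWN))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            recs.append(pg.PedigreeRecord(f"I{i}", f"I{s}", f"I{d}"))
    return pg.validate_and_order(recs)


@pytest.fixture(scope="session")
def study_ped() -> pg.OrderedPedigree:
    return sd.study_pedigree()


@pytest.fixture(scope="session")
def study_A(study_ped) -> np.ndarray:
    return pg.numerator_relationship_matrix(study_ped)
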