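import numpy as np
import pytest

from sisterres.phantom_sim import PhantomSpec, generate_population
from sisterres.separation_score import SliceMaskParams, cell_score

# mask parameters scaled to the 72x72-pixel phantom fields used in tests
PHANTOM_MASK = SliceMaskParams(min_object_size=64)

#: phantom population size per condition used throughout the suite
N_CELLS = 8

SEPARATIONS_NM = (0.0, 200.0, 400.0, 600.0, 800.0)


@pytest.fixture(scope="session")
def mask_params():
    return PHANTOM_MASK


def _population_sccs(label_mode: str, separation_d: float, seed: int,
                     n_cells: int = N_CELLS):
    spec = PhantomSpec(label_mode=label_mode, separation_d=separation_d,
                       seed=seed)
    cells = []
    for i, (stack, _) in enumerate(generate_population(spec, n_cells)):
        c = cell_score(stack, PHANTOM_MASK,
                       cell_id=f"{label_mode}_d{separation_d:.0f}_{i}")
        assert c is not None
        cells.append(c)
    return cells


@pytest.fixture(scope="session")
def two_sister_reference_cells():
    """Two-sister-labelled phantoms (separation 0): the score-0 anchor."""
    return _population_sccs("two_sister", 0.0, seed=101)


@pytest.fixture(scope="session")
def one_sister_reference_cells():
    """One-sister-labelled separated phantoms: the score-1 anchor."""
    return _population_sccs("one_sister", 600.0, seed=102)


@pytest.fixture(scope="session")
def one_sister_separation_scan():
    """Per-separation one-sister populations over the tested range."""
    return {d: _population_sccs("one_sister", d, seed=200 + int(d))
            for d in SEPARATIONS_NM}


def brute_force_spearman(a, b):
    """Independent oracle: average-rank assignment + Pearson on the ranks."""
    def ranks(v):
        v = np.asarray(v, dtype=np.float64)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(v.size, dtype=np.float64)
        i = 0
        while i < v.size:
            j = i
            while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r
    ra, rb = ranks(a), ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))
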