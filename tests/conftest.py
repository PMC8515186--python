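import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from recland.core import GenotypeMatrix, MarkerMap, TOKEN_TO_CODE

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=200)
settings.load_profile("ci")


def codes(tokens: str | list) -> np.ndarray:
    """'A A H NA B' -> int8 call codes."""
    if isinstance(tokens, str):
        tokens = tokens.split()
    return np.array([TOKEN_TO_CODE[t] for t in tokens], dtype=np.int8)


def matrix_from_rows(rows: dict[str, str], chrom: str = "c1", spacing: int = 100):
    """Build an aligned (GenotypeMatrix, MarkerMap) from per-marker token rows.

    ``rows`` maps marker id -> whitespace-separated tokens (one per
    individual); markers are placed ``spacing`` bp apart in dict order.
    """
    marker_ids = list(rows)
    calls = np.stack([codes(rows[m]) for m in marker_ids])
    n_ind = calls.shape[1]
    mm = MarkerMap(
        pd.DataFrame(
            {
                "marker": marker_ids,
                "chrom": chrom,
                "pos": spacing * (np.arange(len(marker_ids)) + 1),
            }
        )
    )
    gm = GenotypeMatrix(calls, marker_ids, [f"i{j+1}" for j in range(n_ind)])
    return gm, mm


@pytest.fixture
def small_sim_config():
    """Two short, dense chromosomes; error-free unless overridden."""
    from recland.simulate import ChromosomeSpec, SimConfig, uniform_landscape

    chroms = (
        ChromosomeSpec("c1", 10_000_000, 50.0, uniform_landscape()),
        ChromosomeSpec("c2", 8_000_000, 40.0, uniform_landscape()),
    )
    return SimConfig(
        n_individuals=30,
        chromosomes=chroms,
        marker_density=20.0,
        allele_error_rate=0.0,
        missing_rate=0.0,
        seed=11,
    )
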