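import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

from nutrifa.datasets import load_pasture_mowing
from nutrifa.synthetic import default_templates


@pytest.fixture(scope="session")
def pasture():
    return load_pasture_mowing()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


def cld_oracle_maximal_cliques(sig: np.ndarray) -> list[set[int]]:
    """Independent letter-display oracle: letters = maximal cliques of the
    non-significance graph (each clique is one shared letter).

    Brute force over all vertex subsets; usable up to ~10 groups.
    """
    k = sig.shape[0]
    comp = ~sig & ~np.eye(k, dtype=bool)
    cliques = []
    for mask in range(1, 1 << k):
        members = [i for i in range(k) if mask >> i & 1]
        if all(comp[a, b] for a, b in itertools.combinations(members, 2)):
            cliques.append(set(members))
    return [c for c in cliques if not any(c < o for o in cliques)]


def sharing_matrix_from_letters(letters: dict[str, str], labels: tuple[str, ...]) -> np.ndarray:
    """share[i, j] = the two groups' letter strings intersect."""
    k = len(labels)
    share = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        share[i, j] = share[j, i] = bool(set(letters[labels[i]]) & set(letters[labels[j]]))
    return share
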