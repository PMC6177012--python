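import itertools

import numpy as np
import pytest

from midflux.correction import load_isotope_table


@pytest.fixture(scope="session")
def isotopes():
    """The packaged natural-abundance table (IUPAC values)."""
    return load_isotope_table()


@pytest.fixture(scope="session")
def pure_isotopes():
    """A fictitious table with no heavy isotopes (abundance 1 at shift 0)."""
    return {el: [(0, 1.0)] for el in ("C", "H", "O", "N")}


def brute_force_matrix(counts, tracer_element, n_label, isotopes, max_shift):
    """Independent correction-matrix oracle: enumerate every per-atom
    isotope assignment of the unlabeled atoms and accumulate the joint
    probability by total mass shift. Tracer purity 1 (labeled positions
    contribute a fixed shift of +1 each)."""
    A = np.zeros((max_shift + 1, n_label + 1))
    for j in range(n_label + 1):
        n_unlabeled_tracer = counts[tracer_element] - j
        atoms_j = []
        for element, n in counts.items():
            n_free = n_unlabeled_tracer if element == tracer_element else n
            atoms_j.extend([isotopes[element]] * n_free)
        for assignment in itertools.product(*atoms_j) if atoms_j else [()]:
            shift = j + sum(s for s, _ in assignment)
            prob = np.prod([a for _, a in assignment]) if assignment else 1.0
            if shift <= max_shift:
                A[shift, j] += prob
    return A
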