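from __future__ import annotations

import numpy as np
import pytest

from delkit import (
    DesignFailure,
    DesignParams,
    SyntheticSpec,
    design_primer_set,
    generate_genome,
    generate_marker_and_vector,
)


@pytest.fixture(scope="session")
def params():
    return DesignParams()


@pytest.fixture(scope="session")
def small_bundle():
    """A 20-gene synthetic genome with marker/vector, for unit tests."""
    spec = SyntheticSpec(seed=11, n_genes=20, n_contigs=4)
    contigs, genes, truth = generate_genome(spec)
    marker, vector = generate_marker_and_vector(spec)
    return spec, contigs, genes, truth, marker, vector


@pytest.fixture(scope="session")
def full_bundle():
    """The 200-gene seed-1 genome used by the acceptance criteria."""
    spec = SyntheticSpec(seed=1)
    contigs, genes, truth = generate_genome(spec)
    marker, vector = generate_marker_and_vector(spec)
    return spec, contigs, genes, truth, marker, vector


@pytest.fixture(scope="session")
def full_designs(full_bundle, params):
    """Primer sets (or failures) for every gene of the 200-gene genome."""
    _, contigs, genes, _, _, _ = full_bundle
    return {g.gene_id: design_primer_set(g, contigs, params) for g in genes}


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
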