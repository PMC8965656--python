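"""Shared fixtures: toy tables and synthetic benchmark instances.

Everything is generated programmatically — there are no stored data
files.  The "database-scale" edge list mimics the size and duplication
pattern of the curated human microbe-disease association download (39
diseases, 292 microbes, 483 raw / 450 unique pairs) so the parser and
bookkeeping can be exercised at realistic scale; it is synthetic, not
the real database.
"""

from __future__ import annotations

import numpy as np
import pytest

from mdalink import Hyperparams, SyntheticConfig, generate
from mdalink.synthetic import write_database_scale_edgelist


@pytest.fixture(scope="session")
def toy_edge_lines() -> list[tuple[str, str]]:
    """Six unique (disease, microbe) pairs over 3 diseases x 4 microbes."""
    return [
        ("colitis", "Bacteroides"),
        ("colitis", "Prevotella"),
        ("asthma", "Bacteroides"),
        ("asthma", "Lactobacillus"),
        ("obesity", "Firmicutes"),
        ("obesity", "Prevotella"),
    ]


@pytest.fixture()
def toy_edgelist_path(tmp_path, toy_edge_lines):
    path = tmp_path / "toy.tsv"
    path.write_text("".join(f"{d}\t{m}\n" for d, m in toy_edge_lines))
    return path


def make_database_scale_edgelist(path, **kwargs):
    """Synthetic edge list with the curated-database pair counts."""
    return write_database_scale_edgelist(path, **kwargs)


@pytest.fixture(scope="session")
def database_scale_edgelist(tmp_path_factory):
    path = tmp_path_factory.mktemp("db") / "synthetic_database_scale.tsv"
    return make_database_scale_edgelist(path)


@pytest.fixture(scope="session")
def planted_default():
    """Default planted-community benchmark (seed 0): 30 x 120, 3 blocks."""
    return generate(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def planted_small():
    """Scaled-down benchmark for the heavier cross-validation tests."""
    return generate(SyntheticConfig(nd=20, nm=60, seed=0))


@pytest.fixture(scope="session")
def planted_tiny():
    """Very small benchmark for smoke/bookkeeping tests."""
    return generate(SyntheticConfig(nd=10, nm=24, n_blocks=2, seed=0))


@pytest.fixture()
def default_params() -> Hyperparams:
    """Model defaults with the latent dimension sized for the 30-disease fixture."""
    return Hyperparams(k=20)


@pytest.fixture()
def small_params() -> Hyperparams:
    return Hyperparams(k=15)


@pytest.fixture()
def tiny_params() -> Hyperparams:
    return Hyperparams(k=6, iterations=150)


def random_similarity(rng, n, unit_diag=True):
    """Random symmetric similarity matrix with entries in [0, 1]."""
    S = rng.random((n, n))
    S = 0.5 * (S + S.T)
    if unit_diag:
        np.fill_diagonal(S, 1.0)
    return S
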