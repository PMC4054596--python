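"""Shared fixtures: small synthetic genomes and event tables.

Everything is generated programmatically; nothing is read from disk except
files the tests themselves write into tmp directories.
"""
from __future__ import annotations

import numpy as np
import pytest

from rnamotifs.genome_io import load_exon_events, load_genome
from rnamotifs.synthetic_fixtures import FixtureConfig, generate_dataset


@pytest.fixture(scope="session")
def small_planted(tmp_path_factory):
    """A small planted-YCAY dataset (20/20/200 events) with its genome."""
    cfg = FixtureConfig(n_enhanced=20, n_silenced=20, n_control=200, seed=7)
    outdir = tmp_path_factory.mktemp("small_planted")
    fasta, table = generate_dataset(cfg, outdir)
    return cfg, load_genome(fasta), load_exon_events(table), fasta, table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
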