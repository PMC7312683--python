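"""Shared fixtures: synthetic duplexes and probed complexes."""

from __future__ import annotations

import numpy as np
import pytest

from minorgroove import synthetic_data as synth
from minorgroove.helix_model import build_duplexes, detect_base_pairs


@pytest.fixture(scope="session")
def b_duplex():
    """14-bp ideal B-form duplex with its ledger."""
    return synth.generate_fiber_duplex(synth.FiberModelSpec("B", "ATGCATGCATGCAT"))


@pytest.fixture(scope="session")
def a_duplex():
    """12-bp ideal A-form duplex with its ledger."""
    return synth.generate_fiber_duplex(synth.FiberModelSpec("A", "GCGCGCGCGCGC"))


@pytest.fixture(scope="session")
def probed_complex():
    """B-form duplex with probes straddling the contact cutoff and groove rule."""
    model, ledger = synth.generate_fiber_duplex(
        synth.FiberModelSpec("B", "ATGCATGCATGCAT"), structure_id="PROBED"
    )
    plans = [
        synth.ProbeSpec("PHE", "A", "7", "minor", 5.0),
        synth.ProbeSpec("LYS", "A", "8", "minor", 6.5),
        synth.ProbeSpec("ASN", "B", "7", "major", 4.0),
        synth.ProbeSpec("SER", "B", "6", "minor", 5.9),
        synth.ProbeSpec("GLY", "A", "5", "minor", 6.1),
    ]
    return synth.plant_probe_residues(model, plans, ledger, seed=11)


def duplex_of(model):
    """The single duplex of a generated model."""
    dna = [c for c in model.chains if c.kind == "dna"]
    duplexes = build_duplexes(detect_base_pairs(dna), model.chains)
    assert len(duplexes) == 1
    return duplexes[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
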