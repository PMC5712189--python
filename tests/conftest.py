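"""Shared fixtures: the default simulated study dataset, built once per session."""

from types import SimpleNamespace

import numpy as np
import pytest

import phagevo as pv
from phagevo.simulate import CoverageSpec, simulate_coverage

# input order for alignment: outgroup last
GENOME_ORDER = ["D29", "StarStuff", "Pomar16", "Kerberos", "Serenity"]


@pytest.fixture(scope="session")
def sim():
    """Default simulator output under a fixed seed: the study conditions."""
    layout, leaves, log, tree = pv.simulate_clade(seed=1)
    return SimpleNamespace(layout=layout, leaves=leaves, log=log, tree=tree)


@pytest.fixture(scope="session")
def sim_aln(sim):
    return pv.build_alignment([sim.leaves[g] for g in GENOME_ORDER])


@pytest.fixture(scope="session")
def sim_rooted_tree(sim_aln):
    jc, _ = pv.jc_distance_matrix(sim_aln)
    return pv.root_by_outgroup(pv.neighbor_joining(jc), "Serenity")


@pytest.fixture(scope="session")
def sim_coverage(sim):
    cspec = CoverageSpec.default_for(sim.layout)
    tracks = simulate_coverage(sim.layout.genome, cspec,
                               np.random.default_rng(7))
    return SimpleNamespace(spec=cspec, tracks=tracks)
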