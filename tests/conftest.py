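"""Shared fixtures: small designs, synthetic spectra, toy networks."""

import numpy as np
import pytest

import fingernet as fn
from fingernet.design import StudyDesign


@pytest.fixture(scope="session")
def bpa_design():
    """1 control (N=17) + 3 dose groups (N=12) for one compound."""
    return fn.default_design(("BPA",))


@pytest.fixture(scope="session")
def two_group_design():
    return StudyDesign.from_group_sizes(
        {"DMSO": 18, "BPA_high": 18}, "DMSO", {"DMSO": "DMSO", "BPA_high": "BPA"}
    )


@pytest.fixture(scope="session")
def strong_spectra(bpa_design):
    """Mixed-profile signal at 3x noise SD on 10 bins, plus a confounder."""
    sigs = fn.demo_signatures(bpa_design, n_signal_bins=10, effect=3.0, seed=11)
    m = fn.simulate_spectra(bpa_design, sigs, n_bins=200, noise_sd=1.0,
                            confounder_sd=2.0, seed=11)
    return fn.scale(fn.normalize_total_area(m), "center_pareto")


@pytest.fixture(scope="session")
def noise_spectra(bpa_design):
    """Pure noise under the same design."""
    m = fn.simulate_spectra(bpa_design, [], n_bins=200, noise_sd=1.0,
                            confounder_sd=0.0, seed=12)
    return fn.scale(fn.normalize_total_area(m), "center_pareto")


@pytest.fixture(scope="session")
def hub_graph():
    """Chain A-r1-B-r2-C plus a detour A-r3-H-r4-C through a degree-8 hub."""
    mets = ["A", "B", "C", "H"] + [f"X{i}" for i in range(6)]
    rxns = [
        fn.network.Reaction("r1", "r1", (("A", 1.0),), (("B", 1.0),)),
        fn.network.Reaction("r2", "r2", (("B", 1.0),), (("C", 1.0),)),
        fn.network.Reaction("r3", "r3", (("A", 1.0),), (("H", 1.0),)),
        fn.network.Reaction("r4", "r4", (("H", 1.0),), (("C", 1.0),)),
    ] + [
        fn.network.Reaction(f"rx{i}", f"rx{i}", ((f"X{i}", 1.0),), (("H", 1.0),))
        for i in range(6)
    ]
    net = fn.MetabolicNetwork(
        [fn.network.Metabolite(m, m, "c") for m in mets], rxns, name="hub"
    )
    return fn.build_compound_graph(net, weight_scheme="degree_squared")


def random_toy_graph(rng, max_nodes=12, weight_scheme="degree_squared"):
    """Small random connected compound graph for oracle comparisons."""
    n_met = int(rng.integers(3, max_nodes // 2 + 1))
    n_rxn = int(rng.integers(n_met - 1, n_met + 3))
    net = fn.generate_toy_network(
        n_met, n_rxn, n_compartments=1, seed=int(rng.integers(2**31))
    )
    return fn.build_compound_graph(net, weight_scheme=weight_scheme)
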