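"""Shared fixtures: small synthetic training sets, a trained model pair,
and the planted-truth genome. Session-scoped because training the SVM and
laying out the genome dominate the suite's runtime."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plantlnc import classifiers as clf
from plantlnc.simulate import (
    SimulationConfig,
    simulate_genome,
    simulate_lncrna,
    simulate_mrna,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=length)])


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_mrna=300, n_lnc=300)


@pytest.fixture(scope="session")
def mrna_seqs(sim_config):
    seqs, _ = simulate_mrna(sim_config)
    return seqs


@pytest.fixture(scope="session")
def lnc_seqs(sim_config):
    seqs, _ = simulate_lncrna(sim_config)
    return seqs


@pytest.fixture(scope="session")
def cpat_model(lnc_seqs, mrna_seqs):
    spec = clf.ModelSpec("logistic", "cpat")
    return clf.train_from_sequences(lnc_seqs, mrna_seqs, spec, seed=1)


@pytest.fixture(scope="session")
def lncfinder_model(lnc_seqs, mrna_seqs):
    spec = clf.ModelSpec("svm_rbf", "lncfinder-lite")
    return clf.train_from_sequences(lnc_seqs, mrna_seqs, spec, seed=1)


@pytest.fixture(scope="session")
def genome_sim():
    return simulate_genome(SimulationConfig(seed=11, n_mrna=0, n_lnc=0))


@pytest.fixture(scope="session")
def trained_model_paths(tmp_path_factory, cpat_model, lncfinder_model):
    d = tmp_path_factory.mktemp("models")
    clf.save_model(cpat_model, d / "cpat.json")
    clf.save_model(lncfinder_model, d / "lncfinder.json")
    return d / "cpat.json", d / "lncfinder.json"
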