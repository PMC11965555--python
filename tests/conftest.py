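"""Shared fixtures: a moderate-scale simulated discovery run reused across
test modules, plus helpers to run the discovery pipeline from a config."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import funclock as fl


def run_discovery(config: fl.SimulationConfig, dcfg: fl.DiscoveryConfig | None = None) -> dict:
    """Simulate every discovery input from one config and run the full
    discovery stage; returns all intermediates keyed by name."""
    dcfg = dcfg or fl.DiscoveryConfig()
    universe = fl.build_probe_universe(config)
    betas, sheet, truth = fl.simulate_cohort(config, universe)
    annot = fl.simulate_probe_annotation(config, universe)
    ref, fetal = fl.simulate_reference_profiles(config, universe)

    sen_b, sen_s, sen_t = fl.simulate_condition_experiment(config, "senescence", universe)
    sen_assoc = fl.fit_condition_models(sen_b, sen_s, "treated", ["cell_type", "dataset"])
    sen = fl.select_condition_cpgs(sen_assoc, annot, dcfg)

    pro_b, pro_s, pro_t = fl.simulate_condition_experiment(
        config, "proliferation_inhibition", universe)
    pro_assoc = fl.fit_condition_models(pro_b, pro_s, "treated", ["cell_type", "dataset"])
    # treatment reduces proliferation; express directions w.r.t. increased proliferation
    pro = -fl.select_condition_cpgs(pro_assoc, annot, dcfg)

    ac = fl.age_correlation(betas, sheet, dcfg)
    pcgt = fl.select_pcgt_cpgs(fl.pcgt_gene_list(config), annot, fetal, dcfg)
    signatures = fl.build_signatures(ac, sen, pro, pcgt, dcfg)
    return {
        "config": config, "discovery_config": dcfg, "universe": universe,
        "betas": betas, "sheet": sheet, "truth": truth, "annot": annot,
        "reference": ref, "fetal": fetal,
        "sen_assoc": sen_assoc, "sen": sen, "sen_truth": sen_t,
        "pro_assoc": pro_assoc, "pro": pro, "pro_truth": pro_t,
        "age": ac, "pcgt": pcgt, "signatures": signatures,
    }


@pytest.fixture(scope="session")
def small_config() -> fl.SimulationConfig:
    return fl.SimulationConfig(
        n_probes=800, n_samples=200,
        n_age_gen=60, n_age_epi=40, n_age_imm=40,
        n_sen=80, n_pro=80, n_pcgt_genes=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def bundle(small_config) -> dict:
    """Full discovery run on the small standard simulation."""
    return run_discovery(small_config)


@pytest.fixture(scope="session")
def signatures(bundle) -> fl.SignatureSet:
    return bundle["signatures"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_beta_matrix(values, probe_ids=None, sample_ids=None) -> fl.BetaMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:07d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(values.shape[1])]
    return fl.BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))
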