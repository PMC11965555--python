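"""Discovery-stage tests: condition models against a brute-force oracle,
age-correlation classification rules, PCGT promoter selection, signature
assembly, and the mouse ortholog transfer."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import funclock as fl
from funclock.signature_discovery import SIGNATURE_NAMES

from conftest import make_beta_matrix


def _age_table(rows: dict) -> pd.DataFrame:
    """Build an AgeCorrelation-style table from {probe: (rho_epi, q_epi, rho_imm, q_imm)}."""
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["rho_epi", "q_epi", "rho_imm", "q_imm"])
    df["p_epi"] = df["q_epi"]
    df["p_imm"] = df["q_imm"]
    df["class"] = fl.classify_age_cpgs(df)
    return df


class TestFitConditionModels:
    def test_matches_per_probe_statsmodels_ols(self, rng):
        """Vectorized fit agrees with explicit per-probe OLS to 6 sig figs."""
        n_probes, n = 200, 40
        sheet = pd.DataFrame({
            "treated": rng.integers(0, 2, n),
            "cell_type": rng.choice(["a", "b"], n),
            "dataset": rng.choice(["d1", "d2", "d3"], n),
        }, index=[f"S{i:03d}" for i in range(n)])
        betas = make_beta_matrix(rng.uniform(0.1, 0.9, (n_probes, n)))
        got = fl.fit_condition_models(betas, sheet, "treated", ["cell_type", "dataset"])
        X = pd.get_dummies(sheet[["cell_type", "dataset"]], drop_first=True, dtype=float)
        X.insert(0, "treated", sheet["treated"].astype(float))
        X = sm.add_constant(X)
        for p in betas.probe_ids[::23]:
            fit = sm.OLS(betas.values.loc[p].to_numpy(), X.to_numpy()).fit()
            assert got.at[p, "effect"] == pytest.approx(fit.params[1], rel=1e-6)
            assert got.at[p, "p"] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_recovers_planted_condition_probes(self):
        cfg = fl.SimulationConfig(n_probes=600, n_samples=40, n_age_gen=0, n_age_epi=0,
                                  n_age_imm=0, n_sen=60, n_pro=0, n_pcgt_genes=0,
                                  condition_delta=0.2, noise_sd=0.05, seed=21)
        betas, sheet, truth = fl.simulate_condition_experiment(cfg, "senescence")
        assoc = fl.fit_condition_models(betas, sheet, "treated", ["cell_type", "dataset"])
        up = truth.probes_with_role("sen_up")
        hits = (assoc.loc[up, "q"] < 0.05) & (assoc.loc[up, "direction"] == 1)
        assert hits.mean() >= 0.9

    def test_constant_probe_never_significant(self):
        sheet = pd.DataFrame({"treated": [0, 0, 1, 1]}, index=list("abcd"))
        betas = make_beta_matrix(np.full((3, 4), 0.5), sample_ids=list("abcd"))
        assoc = fl.fit_condition_models(betas, sheet, "treated")
        assert (assoc["p"] == 1.0).all()
        assert (assoc["direction"] == 0).all()

    def test_constant_condition_rejected(self):
        sheet = pd.DataFrame({"treated": [1, 1, 1, 1]}, index=list("abcd"))
        betas = make_beta_matrix(np.full((2, 4), 0.5), sample_ids=list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            fl.fit_condition_models(betas, sheet, "treated")

    def test_collinear_covariate_named_in_error(self):
        sheet = pd.DataFrame({
            "treated": [0, 0, 1, 1, 0, 1],
            "batch": ["x", "x", "y", "y", "x", "y"],  # perfectly aligned with arm
        }, index=list("abcdef"))
        betas = make_beta_matrix(np.random.default_rng(0).uniform(0.2, 0.8, (2, 6)),
                                 sample_ids=list("abcdef"))
        with pytest.raises(ValueError, match="batch"):
            fl.fit_condition_models(betas, sheet, "treated", ["batch"])


class TestSelectConditionCpgs:
    @pytest.fixture()
    def annot(self):
        return pd.DataFrame({
            "chrom": ["chr1", "chrX", "chr2", "chr3"],
            "autosomal": [True, False, True, True],
        }, index=["p1", "p2", "p3", "p4"])

    def test_threshold_and_autosomal_rules(self, annot):
        assoc = pd.DataFrame({
            "effect": [0.1, 0.1, -0.2, 0.1],
            "direction": [1, 1, -1, 1],
            "p": [0.001, 0.001, 0.001, 0.04],
            "q": [0.01, 0.01, 0.049, 0.06],
        }, index=["p1", "p2", "p3", "p4"])
        sel = fl.select_condition_cpgs(assoc, annot)
        # p2 dropped (chrX), p4 dropped (q ≥ 0.05); q=0.049 retained
        assert dict(sel) == {"p1": 1, "p3": -1}

    def test_q_exactly_at_threshold_excluded(self, annot):
        assoc = pd.DataFrame({"effect": [0.1], "direction": [1],
                              "p": [0.04], "q": [0.05]}, index=["p1"])
        assert len(fl.select_condition_cpgs(assoc, annot)) == 0


class TestAgeCorrelation:
    def test_planted_gen_probe_significant_in_both_compartments(self, bundle):
        ac, truth = bundle["age"], bundle["truth"]
        gen = truth.probes_with_role("age_gen")
        sub = ac.loc[gen]
        frac = ((sub["q_epi"] < 0.05) & (sub["q_imm"] < 0.05)
                & (sub["rho_epi"].abs() > 0.2) & (sub["rho_imm"].abs() > 0.2)).mean()
        assert frac >= 0.9

    def test_sign_symmetry_of_planted_slopes(self, bundle):
        ac, truth = bundle["age"], bundle["truth"]
        gen = truth.probes_with_role("age_gen")
        signs = truth.realized_parameters.loc[gen, "age_sign"]
        assert (np.sign(ac.loc[gen, "rho_imm"]) == signs).mean() >= 0.95

    def test_constant_probe_flagged_unclassified(self):
        rng = np.random.default_rng(1)
        n = 40
        vals = rng.uniform(0.2, 0.8, (3, n))
        vals[0] = 0.5  # constant probe
        betas = make_beta_matrix(vals)
        sheet = pd.DataFrame({
            "age": rng.uniform(20, 80, n),
            "compartment": ["epithelial"] * (n // 2) + ["immune"] * (n // 2),
        }, index=betas.sample_ids)
        ac = fl.age_correlation(betas, sheet)
        assert np.isnan(ac.iloc[0]["rho_epi"])
        assert ac.iloc[0]["class"] == "unclassified"

    def test_small_compartment_errors_with_name(self):
        betas = make_beta_matrix(np.full((2, 6), 0.4))
        sheet = pd.DataFrame({
            "age": [30, 40, 50, 60, 70, 80],
            "compartment": ["epithelial"] * 5 + ["immune"],
        }, index=betas.sample_ids)
        with pytest.raises(ValueError, match="immune"):
            fl.age_correlation(betas, sheet)


class TestClassifyAgeCpgs:
    @pytest.mark.parametrize("rho_epi,q_epi,rho_imm,q_imm,expected", [
        (0.5, 0.001, 0.3, 0.01, "gen"),
        (0.5, 0.001, 0.01, 0.9, "epi"),
        (0.01, 0.9, -0.5, 0.001, "imm"),
        (0.25, 0.01, 0.1, 0.5, "unclassified"),  # fails gen (|ρ_imm| ≤ .2) and epi (≥ .02)
        (0.1, 0.5, 0.1, 0.5, "nonage"),
        (0.21, 0.01, 0.019, 0.6, "epi"),      # other-compartment ρ just inside
        (0.21, 0.01, 0.021, 0.6, "unclassified"),  # just outside
        (0.19, 0.01, 0.01, 0.6, "nonage"),    # main ρ below 0.2 with small q
        (0.5, 0.001, 0.21, 0.04, "gen"),      # both just above 0.2
        (0.5, 0.001, 0.2, 0.04, "unclassified"),  # ρ_imm exactly 0.2 fails gen
        (-0.4, 0.001, -0.4, 0.001, "gen"),    # negative correlations allowed
    ])
    def test_rule_application(self, rho_epi, q_epi, rho_imm, q_imm, expected):
        tab = _age_table({"p": (rho_epi, q_epi, rho_imm, q_imm)})
        assert tab.at["p", "class"] == expected

    def test_every_probe_gets_exactly_one_class(self, bundle):
        assert bundle["age"]["class"].isin(
            ["gen", "epi", "imm", "nonage", "unclassified"]).all()


class TestSelectPcgtCpgs:
    @pytest.fixture()
    def inputs(self):
        annot = pd.DataFrame({
            "gene": ["G1", "G1", "G2", "OTHER", "G1"],
            "tss_distance": [150, 300, 200, 100, 201],
            "chrom": "chr1", "pos": 1, "autosomal": True,
        }, index=[f"p{i}" for i in range(5)])
        fetal = make_beta_matrix(
            np.array([[0.1, 0.1], [0.1, 0.1], [0.19, 0.19], [0.1, 0.1], [0.1, 0.1]]),
            probe_ids=list(annot.index), sample_ids=["f1", "f2"])
        return ["G1", "G2"], annot, fetal

    def test_window_gene_and_fetal_rules(self, inputs):
        genes, annot, fetal = inputs
        got = set(fl.select_pcgt_cpgs(genes, annot, fetal))
        # p0: in gene+window+unmethylated; p1: tss 300 out; p2: tss exactly 200
        # in, fetal 0.19 < 0.2 in; p3: gene not listed; p4: tss 201 out
        assert got == {"p0", "p2"}

    def test_fetal_mean_at_threshold_excluded(self, inputs):
        genes, annot, fetal = inputs
        fetal.values.loc["p0"] = 0.2
        assert "p0" not in set(fl.select_pcgt_cpgs(genes, annot, fetal))

    def test_fetal_mean_above_threshold_excluded(self, inputs):
        genes, annot, fetal = inputs
        fetal.values.loc["p0"] = 0.3
        assert "p0" not in set(fl.select_pcgt_cpgs(genes, annot, fetal))

    def test_probe_missing_from_fetal_excluded_with_warning(self, inputs, caplog):
        genes, annot, fetal = inputs
        fetal2 = fl.BetaMatrix(fetal.values.drop(index="p0"))
        with caplog.at_level("WARNING"):
            got = set(fl.select_pcgt_cpgs(genes, annot, fetal2))
        assert got == {"p2"}
        assert any("absent from fetal" in r.message for r in caplog.records)


class TestBuildSignatures:
    def test_enumeration_is_exactly_22(self, signatures):
        assert len(signatures) == 22
        assert signatures.names == list(SIGNATURE_NAMES)

    def test_sen_membership_is_exact_intersection(self, bundle):
        sigs, ac, sen = bundle["signatures"], bundle["age"], bundle["sen"]
        gen_probes = set(ac.index[ac["class"] == "gen"])
        sen_gen = set(sigs["SENgen"].probes)
        assert sen_gen <= gen_probes & set(sen.index)
        # every dropped gen∩sen probe is direction-discordant
        for p in (gen_probes & set(sen.index)) - sen_gen:
            assert np.sign(ac.at[p, "rho_epi"]) != sen.at[p] or \
                np.sign(ac.at[p, "rho_epi"]) != np.sign(ac.at[p, "rho_imm"])

    def test_sign_coherence_sen_and_pro(self, bundle):
        sigs, ac, sen, pro = (bundle["signatures"], bundle["age"],
                              bundle["sen"], bundle["pro"])
        for p, w in zip(sigs["SENgen"].probes, sigs["SENgen"].weights):
            assert w == sen.at[p] == np.sign(ac.at[p, "rho_epi"])
        for p, w in zip(sigs["PROgen-"].probes, sigs["PROgen-"].weights):
            assert w == np.sign(ac.at[p, "rho_epi"])
            assert np.sign(ac.at[p, "rho_epi"]) != pro.at[p]

    def test_age_signatures_exclude_functional_probes(self, bundle):
        sigs = bundle["signatures"]
        functional = (set(bundle["sen"].index) | set(bundle["pro"].index)
                      | set(bundle["pcgt"]))
        for name in ("AGE", "AGEepi", "AGEimm"):
            assert not set(sigs[name].probes) & functional

    def test_pcgt_signatures_only_positive_age_correlation(self, bundle):
        sigs, ac = bundle["signatures"], bundle["age"]
        for name in ("PCGTgen", "PCGTpure"):
            assert all(ac.at[p, "rho_epi"] > 0 for p in sigs[name].probes)
            assert all(w == 1 for w in sigs[name].weights)

    def test_pure_signatures_exclusive_to_one_functional_set(self, bundle):
        sigs = bundle["signatures"]
        sen_set, pro_set = set(bundle["sen"].index), set(bundle["pro"].index)
        pcgt_set = set(bundle["pcgt"])
        assert not set(sigs["SENpure"].probes) & (pro_set | pcgt_set)
        assert not set(sigs["PCGTpure"].probes) & (sen_set | pro_set)
        assert not set(sigs["PROpure+"].probes) & (sen_set | pcgt_set)

    def test_concordance_rules_on_constructed_probes(self):
        # probe a: gen ρ>0, senescence +1 → SENgen (w=+1), SENpure, not AGE
        # probe b: gen ρ>0, proliferation −1 → PROgen− (w=+1), not PROgen+
        # probe c: nonage, senescence −1 → SENnonage (w=−1)
        age = _age_table({
            "a": (0.5, 0.001, 0.4, 0.001),
            "b": (0.5, 0.001, 0.4, 0.001),
            "c": (0.05, 0.9, 0.05, 0.9),
        })
        sigs = fl.build_signatures(age, sen={"a": 1, "c": -1}, pro={"b": -1}, pcgt=[])
        assert sigs["SENgen"].probes == ("a",) and sigs["SENgen"].weights == (1,)
        assert sigs["SENpure"].probes == ("a",)
        assert "a" not in sigs["AGE"].probes
        assert sigs["PROgen-"].probes == ("b",) and sigs["PROgen-"].weights == (1,)
        assert sigs["PROgen+"].probes == ()
        assert sigs["SENnonage"].probes == ("c",) and sigs["SENnonage"].weights == (-1,)

    def test_discordant_gen_probe_dropped_with_warning(self, caplog):
        age = _age_table({"a": (0.5, 0.001, -0.4, 0.001)})  # signs disagree
        with caplog.at_level("WARNING"):
            sigs = fl.build_signatures(age, sen={"a": 1}, pro={}, pcgt=[])
        assert sigs["SENgen"].probes == ()
        assert any("discordant" in r.message for r in caplog.records)

    def test_probe_outside_universe_rejected(self):
        age = _age_table({"a": (0.5, 0.001, 0.4, 0.001)})
        with pytest.raises(ValueError, match="outside"):
            fl.build_signatures(age, sen={"zz": 1}, pro={}, pcgt=[])

    def test_empty_signatures_flagged_unusable(self, signatures):
        empties = [s for s in signatures if not s.usable]
        assert all(len(s) == 0 for s in empties)


def _values_with_spearman(rng, age, lo, hi, max_tries=50):
    """Deterministically construct a vector whose Spearman ρ with age lies
    in (lo, hi) — used to place probes on either side of the mouse rules.
    Bisects the amplitude of an additive noise vector (ρ falls from 1
    towards 0 as the amplitude grows)."""
    n = len(age)
    scale = np.std(age)
    for _ in range(max_tries):
        noise = rng.normal(0, 1, n)
        c_lo, c_hi = 0.0, 1e3
        for _ in range(80):
            c = 0.5 * (c_lo + c_hi)
            y = age + c * scale * noise
            rho = stats.spearmanr(y, age)[0]
            if rho > hi:
                c_lo = c
            elif rho < lo:
                c_hi = c
            else:
                ranks = stats.rankdata(y)
                return 0.05 + 0.03 * ranks / n, rho
    raise AssertionError("no vector found in window")


class TestTransferOrthologs:
    def test_recovers_planted_mouse_age_structure(self, small_config):
        inputs = fl.simulate_mouse_transfer_inputs(small_config)
        m_gen, m_non = fl.transfer_signature_orthologs(
            fl.pcgt_gene_list(small_config), inputs["ortholog_map"],
            inputs["annotation"], inputs["fetal"], inputs["betas"], inputs["sheet"])
        truth = inputs["truth_age_correlated"]
        gen_true = set(truth.index[truth])
        assert len(m_gen.probes) > 0
        assert set(m_gen.probes) <= gen_true
        assert len(set(m_gen.probes)) / len(gen_true) >= 0.8
        assert not set(m_non.probes) & gen_true
        assert all(w == 1 for w in m_gen.weights + m_non.weights)

    def test_correlation_and_significance_boundaries(self):
        """cor > 0.2 with q < 0.05 → mPCGTgen; |cor| < 0.2 → mPCGTnonage;
        cor > 0.2 without significance → neither."""
        rng = np.random.default_rng(77)
        n = 30
        age = np.arange(n, dtype=float)
        v_gen, _ = _values_with_spearman(rng, age, 0.68, 0.75)   # q < 0.05
        v_non, _ = _values_with_spearman(rng, age, 0.00, 0.10)   # |cor| < 0.2
        v_mid, _ = _values_with_spearman(rng, age, 0.23, 0.28)   # >0.2 but p ≈ 0.2
        v_low, _ = _values_with_spearman(rng, age, 0.15, 0.198)  # just below 0.2
        vals = np.vstack([v_gen, v_non, v_mid, v_low])
        probes = ["m_gen", "m_non", "m_mid", "m_low"]
        betas = make_beta_matrix(vals, probe_ids=probes,
                                 sample_ids=[f"M{i}" for i in range(n)])
        sheet = pd.DataFrame({"age": age, "tissue": "breast"}, index=betas.sample_ids)
        annot = pd.DataFrame({"gene": "Pcgt0", "tss_distance": 100,
                              "chrom": "chr1", "autosomal": True}, index=probes)
        fetal = make_beta_matrix(np.full((4, 3), 0.05), probe_ids=probes,
                                 sample_ids=["f1", "f2", "f3"])
        ortho = pd.DataFrame({"human_symbol": ["PCGT0"], "mouse_symbol": ["Pcgt0"]})
        m_gen, m_non = fl.transfer_signature_orthologs(
            ["PCGT0"], ortho, annot, fetal, betas, sheet)
        assert set(m_gen.probes) == {"m_gen"}
        assert set(m_non.probes) == {"m_non", "m_low"}
        assert "m_mid" not in set(m_gen.probes) | set(m_non.probes)

    def test_sex_chromosome_and_window_filters(self, small_config):
        inputs = fl.simulate_mouse_transfer_inputs(small_config)
        annot = inputs["annotation"].copy()
        first = annot.index[0]
        annot.loc[first, "chrom"] = "chrX"
        annot.loc[first, "autosomal"] = False
        m_gen, m_non = fl.transfer_signature_orthologs(
            fl.pcgt_gene_list(small_config), inputs["ortholog_map"], annot,
            inputs["fetal"], inputs["betas"], inputs["sheet"])
        assert first not in set(m_gen.probes) | set(m_non.probes)

    def test_empty_candidate_set_rejected(self, small_config):
        inputs = fl.simulate_mouse_transfer_inputs(small_config)
        with pytest.raises(ValueError, match="empty"):
            fl.transfer_signature_orthologs(
                ["NOSUCHGENE"], inputs["ortholog_map"], inputs["annotation"],
                inputs["fetal"], inputs["betas"], inputs["sheet"])
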