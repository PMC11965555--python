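"""Synthetic methylation cohorts with planted, recoverable structure.

The generator emulates the statistical shape of the discovery and evaluation
inputs: age-correlated CpGs shared between or specific to the epithelial and
immune compartments, senescence- and proliferation-responsive CpGs measured
in batch-confounded condition experiments, polycomb-target (PCGT) promoter
CpGs unmethylated in a fetal reference, mixed-cell samples that are convex
combinations of compartment profiles, and case/control cohorts shifted along
signature weight vectors.

Betas are generated on a latent Gaussian (logit-like) scale and mapped
through the logistic function, so every emitted value lies strictly in
(0, 1) and monotone age relationships survive the transform — Spearman-based
discovery is invariant to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .types import BetaMatrix, ReferenceProfiles, Signature, SignatureSet

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "ProbeUniverse",
    "simulate_cohort",
    "simulate_condition_experiment",
    "simulate_case_control",
    "simulate_reference_profiles",
    "simulate_probe_annotation",
    "pcgt_gene_list",
    "simulate_mouse_transfer_inputs",
]

# Fixed child-seed rule: rng(stage) = default_rng(SeedSequence(seed, spawn_key=(key,))).
# Stages are therefore independently reproducible from the single config seed.
_STAGE_KEYS = {
    "cohort": 0,
    "condition_senescence": 1,
    "condition_proliferation_inhibition": 2,
    "case_control": 3,
    "reference": 4,
    "annotation": 5,
    "mouse": 6,
}

PROBE_ROLES = (
    "age_gen", "age_epi", "age_imm",
    "sen_up", "sen_down", "pro_up", "pro_down",
    "pcgt", "null",
)


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure simulation.

    Defaults correspond to the standard discovery-scale scenario used by the
    test and acceptance suites: 5 000 probes, 200 samples aged 20–80,
    age-CpG Spearman magnitude 0.5, condition effect 0.2 on the beta scale,
    latent noise SD 0.05.
    """

    n_probes: int = 5000
    n_samples: int = 200
    age_range: tuple[float, float] = (20.0, 80.0)
    # tissue label -> (sampling weight, compartment, immune-proportion range)
    compartment_mix: dict = field(default_factory=lambda: {
        "blood": {"weight": 0.4, "immune_range": (1.0, 1.0)},
        "buccal": {"weight": 0.3, "immune_range": (0.0, 0.15)},
        "cervical": {"weight": 0.3, "immune_range": (0.0, 0.35)},
    })
    n_age_gen: int = 100
    n_age_epi: int = 100
    n_age_imm: int = 100
    target_rho: float = 0.5
    rho_other: float = 0.005  # near-zero cross-compartment leak for specific probes
    n_sen: int = 200
    n_pro: int = 200
    condition_delta: float = 0.2
    n_pcgt_genes: int = 50
    probes_per_pcgt_gene: int = 2
    fetal_baseline: float = 0.1
    case_effect: float = 0.05
    noise_sd: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_age_gen, self.n_age_epi, self.n_age_imm,
                  self.n_sen, self.n_pro,
                  self.n_pcgt_genes * self.probes_per_pcgt_gene)
        if any(c < 0 for c in counts) or self.n_probes < 0 or self.n_samples < 0:
            raise ValueError("all counts must be non-negative")
        if sum(counts) > self.n_probes:
            raise ValueError(
                f"planted probe counts ({sum(counts)}) exceed n_probes ({self.n_probes})"
            )
        if not 0 < self.target_rho < 1:
            raise ValueError("target_rho must lie in (0, 1)")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise ValueError("age_range must be an increasing pair of positive ages")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for tissue, spec in self.compartment_mix.items():
            lo, hi = spec["immune_range"]
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"immune range for {tissue!r} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGE_KEYS[stage],))
        )


@dataclass
class SimulationTruth:
    """Planted ground truth: per-probe roles, realized effect parameters,
    and per-signature case directions (filled by :func:`simulate_case_control`)."""

    probe_role: pd.Series  # probe_id -> role
    realized_parameters: pd.DataFrame  # per-probe slopes / deltas / directions
    planted_case_direction: dict[str, str] = field(default_factory=dict)

    def probes_with_role(self, role: str) -> pd.Index:
        return self.probe_role.index[self.probe_role == role]

    def to_json(self) -> str:
        return json.dumps({
            "probe_role": self.probe_role.to_dict(),
            "planted_case_direction": self.planted_case_direction,
            "realized_parameters": self.realized_parameters.to_dict(orient="index"),
        }, sort_keys=True)


@dataclass
class ProbeUniverse:
    """Deterministic layout of probe roles, genes and chromosomes.

    The same universe underlies every stage generated from one config, so
    condition experiments and cohorts share probe identities.
    """

    probe_ids: pd.Index
    roles: pd.Series
    gene: pd.Series
    tss_distance: pd.Series
    chrom: pd.Series
    age_sign: pd.Series      # planted sign of age slope (0 = none)
    age_scope: pd.Series     # both / epi / imm / none
    condition_dir: pd.Series  # sen/pro probes: sign of beta change w.r.t. the process

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


# fraction of trailing null probes assigned to sex/mito chromosomes, and to
# decoy PCGT-gene annotations that must be rejected by the TSS / fetal filters
_N_SEX = 40
_N_DECOY_TSS = 20
_N_DECOY_FETAL = 20


def build_probe_universe(config: SimulationConfig) -> ProbeUniverse:
    config.validate()
    rng = config.rng("annotation")
    n = config.n_probes
    probe_ids = pd.Index([f"cg{i:07d}" for i in range(n)], name="probe_id")

    roles = np.full(n, "null", dtype=object)
    age_sign = np.zeros(n, dtype=int)
    age_scope = np.full(n, "none", dtype=object)
    cond_dir = np.zeros(n, dtype=int)
    gene = np.full(n, "", dtype=object)
    tss = np.full(n, -1, dtype=int)

    i = 0

    def take(k):
        nonlocal i
        sl = slice(i, i + k)
        i += k
        return sl

    sl = take(config.n_age_gen)
    roles[sl] = "age_gen"
    age_sign[sl] = rng.choice([-1, 1], size=config.n_age_gen)
    age_scope[sl] = "both"

    sl = take(config.n_age_epi)
    roles[sl] = "age_epi"
    age_sign[sl] = rng.choice([-1, 1], size=config.n_age_epi)
    age_scope[sl] = "epi"

    sl = take(config.n_age_imm)
    roles[sl] = "age_imm"
    age_sign[sl] = rng.choice([-1, 1], size=config.n_age_imm)
    age_scope[sl] = "imm"

    # Senescence probes: hyper- (sen_up) or hypomethylated (sen_down) in
    # senescent cells; their planted age slope is concordant in both
    # compartments so they feed the SEN×age overlaps downstream.
    n_up = config.n_sen // 2
    sl = take(n_up)
    roles[sl] = "sen_up"
    cond_dir[sl] = 1
    age_sign[sl] = 1
    age_scope[sl] = "both"
    sl = take(config.n_sen - n_up)
    roles[sl] = "sen_down"
    cond_dir[sl] = -1
    age_sign[sl] = -1
    age_scope[sl] = "both"

    # Proliferation probes: direction is w.r.t. INCREASED proliferation.
    # pro_up gains methylation with both age and proliferation (PRO+);
    # pro_down gains with age but loses with proliferation (PRO−).
    n_up = config.n_pro // 2
    sl = take(n_up)
    roles[sl] = "pro_up"
    cond_dir[sl] = 1
    age_sign[sl] = 1
    age_scope[sl] = "both"
    sl = take(config.n_pro - n_up)
    roles[sl] = "pro_down"
    cond_dir[sl] = -1
    age_sign[sl] = 1
    age_scope[sl] = "both"

    # PCGT promoter probes: unmethylated in fetal tissue; half gain
    # methylation with age in both compartments (→ PCGTgen), half stay flat
    # (→ PCGTnonage).
    n_pcgt = config.n_pcgt_genes * config.probes_per_pcgt_gene
    sl = take(n_pcgt)
    roles[sl] = "pcgt"
    idx = np.arange(sl.start, sl.stop)
    for k, j in enumerate(idx):
        g = k // config.probes_per_pcgt_gene
        gene[j] = f"PCGT{g}"
        tss[j] = int(rng.integers(0, 201))
        if k % 2 == 0:
            age_sign[j] = 1
            age_scope[j] = "both"

    chrom = rng.choice([f"chr{c}" for c in range(1, 23)], size=n).astype(object)

    # Null-region decoys exercising the rejection filters end to end.
    null_idx = np.flatnonzero(roles == "null")
    if len(null_idx) >= _N_SEX + _N_DECOY_TSS + _N_DECOY_FETAL:
        sex = null_idx[:_N_SEX]
        chrom[sex] = rng.choice(["chrX", "chrY", "chrMT"], size=_N_SEX)
        d1 = null_idx[_N_SEX:_N_SEX + _N_DECOY_TSS]
        gene[d1] = [f"PCGT{k % max(config.n_pcgt_genes, 1)}" for k in range(len(d1))]
        tss[d1] = rng.integers(300, 1500, size=len(d1))  # outside the TSS window
        d2 = null_idx[_N_SEX + _N_DECOY_TSS:_N_SEX + _N_DECOY_TSS + _N_DECOY_FETAL]
        gene[d2] = [f"PCGT{k % max(config.n_pcgt_genes, 1)}" for k in range(len(d2))]
        tss[d2] = rng.integers(0, 201, size=len(d2))  # in-window but fetal-methylated

    return ProbeUniverse(
        probe_ids=probe_ids,
        roles=pd.Series(roles, index=probe_ids, name="role"),
        gene=pd.Series(gene, index=probe_ids, name="gene"),
        tss_distance=pd.Series(tss, index=probe_ids, name="tss_distance"),
        chrom=pd.Series(chrom, index=probe_ids, name="chrom"),
        age_sign=pd.Series(age_sign, index=probe_ids, name="age_sign"),
        age_scope=pd.Series(age_scope, index=probe_ids, name="age_scope"),
        condition_dir=pd.Series(cond_dir, index=probe_ids, name="condition_dir"),
    )


def _age_slope(config: SimulationConfig, magnitude: float) -> float:
    """Latent slope per unit standardized age achieving a target Spearman ρ.

    For a bivariate-normal latent pair, Spearman ρ_s relates to Pearson ρ_p
    by ρ_s = (6/π)·asin(ρ_p/2); inverting gives the Pearson target, and the
    slope follows from ρ_p = s/√(s²+σ²).  With noise_sd = 0 any positive
    slope yields a strictly monotone latent, hence |ρ_s| = 1.
    """
    if magnitude <= 0:
        return 0.0
    if config.noise_sd == 0:
        return 1.0
    rho_p = 2.0 * np.sin(np.pi * magnitude / 6.0)
    rho_p = min(rho_p, 0.999)
    return config.noise_sd * rho_p / np.sqrt(1.0 - rho_p**2)


def _apply_missing(values: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        mask = rng.random(values.shape) < rate
        values = values.copy()
        values[mask] = np.nan
    return values


def simulate_cohort(
    config: SimulationConfig,
    universe: ProbeUniverse | None = None,
) -> tuple[BetaMatrix, pd.DataFrame, SimulationTruth]:
    """Generate an age-structured cohort with mixed-cell samples.

    Each sample carries an immune proportion p; its beta profile is the
    convex combination (1−p)·epithelial + p·immune of two compartment
    profiles sharing the per-probe baseline but with compartment-specific
    age slopes.  Samples with p = 1 are labelled immune, p = 0 epithelial,
    anything in between mixed.
    """
    config.validate()
    if universe is None:
        universe = build_probe_universe(config)
    rng = config.rng("cohort")
    n_p, n_s = universe.n_probes, config.n_samples

    ages = rng.uniform(*config.age_range, size=n_s)
    tissues = list(config.compartment_mix)
    weights = np.array([config.compartment_mix[t]["weight"] for t in tissues], dtype=float)
    weights /= weights.sum()
    tissue = rng.choice(tissues, size=n_s, p=weights)
    immune_prop = np.empty(n_s)
    for t in tissues:
        lo, hi = config.compartment_mix[t]["immune_range"]
        sel = tissue == t
        immune_prop[sel] = rng.uniform(lo, hi, size=sel.sum())
    compartment = np.where(
        immune_prop >= 1.0, "immune", np.where(immune_prop <= 0.0, "epithelial", "mixed")
    )

    z = (ages - ages.mean()) / ages.std()
    baseline = logit(rng.uniform(0.1, 0.9, size=n_p))

    s_main = _age_slope(config, config.target_rho)
    s_leak = _age_slope(config, config.rho_other)
    sign = universe.age_sign.to_numpy()
    scope = universe.age_scope.to_numpy()
    slope_epi = np.where(scope == "both", s_main,
                         np.where(scope == "epi", s_main, np.where(scope == "imm", s_leak, 0.0)))
    slope_imm = np.where(scope == "both", s_main,
                         np.where(scope == "imm", s_main, np.where(scope == "epi", s_leak, 0.0)))
    slope_epi = slope_epi * sign
    slope_imm = slope_imm * sign

    noise_epi = rng.normal(0.0, config.noise_sd, size=(n_p, n_s))
    noise_imm = rng.normal(0.0, config.noise_sd, size=(n_p, n_s))
    lat_epi = baseline[:, None] + slope_epi[:, None] * z[None, :] + noise_epi
    lat_imm = baseline[:, None] + slope_imm[:, None] * z[None, :] + noise_imm
    betas = (1.0 - immune_prop)[None, :] * expit(lat_epi) + immune_prop[None, :] * expit(lat_imm)
    betas = _apply_missing(betas, config.missing_rate, rng)

    sample_ids = [f"S{i:04d}" for i in range(n_s)]
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "age": ages,
        "sex": rng.choice(["F", "M"], size=n_s),
        "tissue": tissue,
        "compartment": compartment,
        "dataset": "sim_cohort",
        "group": "control",
        "immune_proportion": immune_prop,
    }).set_index("sample_id")

    truth = SimulationTruth(
        probe_role=universe.roles.copy(),
        realized_parameters=pd.DataFrame({
            "slope_epi": slope_epi,
            "slope_imm": slope_imm,
            "age_sign": sign,
            "condition_dir": universe.condition_dir.to_numpy(),
        }, index=universe.probe_ids),
    )
    bm = BetaMatrix(pd.DataFrame(betas, index=universe.probe_ids, columns=sample_ids))
    return bm, sheet, truth


_CONDITION_ROLES = {
    "senescence": ("sen_up", "sen_down"),
    "proliferation_inhibition": ("pro_up", "pro_down"),
}


def simulate_condition_experiment(
    config: SimulationConfig,
    condition: str,
    universe: ProbeUniverse | None = None,
) -> tuple[BetaMatrix, pd.DataFrame, SimulationTruth]:
    """Two-arm in-vitro experiment with batch and cell-type confounding.

    Treated samples shift planted probes by ±condition_delta on the beta
    scale.  Per-dataset and per-cell-type offsets are added on the latent
    scale, and arm assignment is deliberately unbalanced across datasets so
    a model ignoring the covariates is confounded.

    For ``proliferation_inhibition`` the treatment REDUCES proliferation, so
    the fitted treatment effect has the opposite sign to the probe's
    association with increased proliferation recorded in the truth table.
    """
    config.validate()
    if condition not in _CONDITION_ROLES:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(_CONDITION_ROLES)}"
        )
    if universe is None:
        universe = build_probe_universe(config)
    rng = config.rng(f"condition_{condition}")
    n_p = universe.n_probes
    n_s = config.n_samples
    n_treat = n_s // 2

    datasets = np.array(["d1", "d2", "d3"])
    cell_types = np.array(["fibroblast", "endothelial"])
    # Unbalanced arm-by-dataset assignment (the confound): treated samples
    # come preferentially from d1, controls from d3.
    treated = np.zeros(n_s, dtype=bool)
    treated[:n_treat] = True
    p_ds_treated = np.array([0.6, 0.3, 0.1])
    p_ds_control = np.array([0.1, 0.3, 0.6])
    dataset = np.where(
        treated,
        rng.choice(datasets, size=n_s, p=p_ds_treated),
        rng.choice(datasets, size=n_s, p=p_ds_control),
    )
    cell_type = rng.choice(cell_types, size=n_s)

    baseline = logit(rng.uniform(0.2, 0.6, size=n_p))
    ds_offset = {d: rng.normal(0.0, 0.2) for d in datasets}
    ct_offset = {c: rng.normal(0.0, 0.2) for c in cell_types}
    offsets = np.array([ds_offset[d] + ct_offset[c] for d, c in zip(dataset, cell_type)])

    noise = rng.normal(0.0, config.noise_sd, size=(n_p, n_s))
    betas = expit(baseline[:, None] + offsets[None, :] + noise)

    up_role, down_role = _CONDITION_ROLES[condition]
    dirs = universe.condition_dir.to_numpy().astype(float)
    planted = universe.roles.isin([up_role, down_role]).to_numpy()
    effect_dir = np.where(planted, dirs, 0.0)
    if condition == "proliferation_inhibition":
        effect_dir = -effect_dir  # treatment reduces proliferation
    betas = betas + config.condition_delta * effect_dir[:, None] * treated[None, :]
    betas = np.clip(betas, 1e-6, 1 - 1e-6)
    betas = _apply_missing(betas, config.missing_rate, rng)

    sample_ids = [f"C{i:04d}" for i in range(n_s)]
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "age": np.full(n_s, 40.0),
        "sex": "F",
        "tissue": "cell_line",
        "compartment": "epithelial",
        "dataset": dataset,
        "cell_type": cell_type,
        "group": np.where(treated, condition, "control"),
        "treated": treated.astype(int),
    }).set_index("sample_id")

    truth = SimulationTruth(
        probe_role=universe.roles.copy(),
        realized_parameters=pd.DataFrame({
            "condition_dir": universe.condition_dir.to_numpy(),
            "planted_delta": config.condition_delta * effect_dir,
        }, index=universe.probe_ids),
    )
    bm = BetaMatrix(pd.DataFrame(betas, index=universe.probe_ids, columns=sample_ids))
    return bm, sheet, truth


def simulate_case_control(
    config: SimulationConfig,
    signatures: SignatureSet,
    directions: Mapping[str, str] | None = None,
    universe: ProbeUniverse | None = None,
) -> tuple[BetaMatrix, pd.DataFrame, SimulationTruth]:
    """Case/control cohort with per-signature planted clock shifts.

    ``directions`` maps signature names to 'accelerated', 'decelerated' or
    'null' (unlisted signatures are null).  An accelerated signature shifts
    case samples by +case_effect along its weight vector (weight −1 probes
    move down); decelerated is the mirror image.  A probe belonging to
    several planted signatures takes its shift from the first one in
    signature order.  Age and immune-proportion draws are identical
    multisets in the two arms, so planted effects are not confounded.
    """
    config.validate()
    if universe is None:
        universe = build_probe_universe(config)
    directions = dict(directions or {})
    for name, d in directions.items():
        if name not in signatures.signatures:
            raise ValueError(f"unknown signature {name!r} in directions")
        if d not in ("accelerated", "decelerated", "null"):
            raise ValueError(f"invalid direction {d!r} for signature {name!r}")
    probe_pos = pd.Index(universe.probe_ids)
    for sig in signatures:
        missing = set(sig.probes) - set(probe_pos)
        if missing:
            raise ValueError(
                f"signature {sig.name!r} references probes absent from the "
                f"matrix: {sorted(missing)[:5]}"
            )

    rng = config.rng("case_control")
    n_s = config.n_samples
    n_case = n_s // 2
    n_ctrl = n_s - n_case
    n_p = universe.n_probes

    # matched covariate distributions: same drawn values in both arms
    base_ages = rng.uniform(*config.age_range, size=n_ctrl)
    base_imm = rng.uniform(0.0, 0.3, size=n_ctrl)
    ages = np.concatenate([base_ages, rng.permutation(base_ages)[:n_case]])
    immune_prop = np.concatenate([base_imm, rng.permutation(base_imm)[:n_case]])
    is_case = np.zeros(n_s, dtype=bool)
    is_case[n_ctrl:] = True

    baseline = logit(rng.uniform(0.2, 0.7, size=n_p))
    noise = rng.normal(0.0, config.noise_sd, size=(n_p, n_s))
    betas = expit(baseline[:, None] + noise)

    shift = np.zeros(n_p)
    assigned = np.zeros(n_p, dtype=bool)
    sign_of = {"accelerated": 1.0, "decelerated": -1.0, "null": 0.0}
    planted = {}
    for sig in signatures:
        d = directions.get(sig.name, "null")
        planted[sig.name] = d
        if d == "null" or not sig.usable:
            continue
        locs = probe_pos.get_indexer(list(sig.probes))
        w = np.asarray(sig.weights, dtype=float)
        fresh = ~assigned[locs]
        shift[locs[fresh]] = sign_of[d] * config.case_effect * w[fresh]
        assigned[locs[fresh]] = True

    betas = betas + shift[:, None] * is_case[None, :]
    betas = np.clip(betas, 1e-6, 1 - 1e-6)
    betas = _apply_missing(betas, config.missing_rate, rng)

    sample_ids = [f"P{i:04d}" for i in range(n_s)]
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "age": ages,
        "sex": "F",
        "tissue": "cervical",
        "compartment": "mixed",
        "dataset": "sim_case_control",
        "group": np.where(is_case, "case", "control"),
        "immune_proportion": immune_prop,
    }).set_index("sample_id")

    truth = SimulationTruth(
        probe_role=universe.roles.copy(),
        realized_parameters=pd.DataFrame({"case_shift": shift}, index=universe.probe_ids),
        planted_case_direction=planted,
    )
    bm = BetaMatrix(pd.DataFrame(betas, index=universe.probe_ids, columns=sample_ids))
    return bm, sheet, truth


def simulate_reference_profiles(
    config: SimulationConfig,
    universe: ProbeUniverse | None = None,
    n_markers_per_component: int = 50,
    marker_separation: float = 0.6,
    components: tuple[str, ...] = ("epithelial", "immune"),
    n_fetal_samples: int = 8,
) -> tuple[ReferenceProfiles, BetaMatrix]:
    """Deconvolution reference profiles plus a fetal reference matrix.

    Markers are drawn from the null-probe block: for each component a block
    of probes is high (separated by ``marker_separation``) in that component
    and low in the others.  The fetal matrix covers the whole probe
    universe; planted PCGT-promoter probes have mean beta below the
    configured fetal baseline, everything else is methylated.
    """
    config.validate()
    if universe is None:
        universe = build_probe_universe(config)
    rng = config.rng("reference")

    null_probes = universe.roles.index[universe.roles == "null"]
    # skip decoy/sex blocks at the head of the null region
    start = _N_SEX + _N_DECOY_TSS + _N_DECOY_FETAL
    need = n_markers_per_component * len(components)
    if len(null_probes) < start + need:
        raise ValueError("not enough null probes to carve marker blocks from")
    marker_ids = null_probes[start:start + need]

    low = max(0.05, 0.5 - marker_separation / 2)
    high = min(0.95, 0.5 + marker_separation / 2)
    prof = np.full((need, len(components)), low)
    for k in range(len(components)):
        sl = slice(k * n_markers_per_component, (k + 1) * n_markers_per_component)
        prof[sl, k] = high
    if len(components) == 1:
        prof[:] = high
    profiles = ReferenceProfiles(pd.DataFrame(prof, index=marker_ids, columns=list(components)))

    # fetal reference: PCGT promoters hypomethylated, rest methylated
    n_p = universe.n_probes
    is_pcgt = (universe.roles == "pcgt").to_numpy()
    fetal_mean = rng.uniform(0.3, 0.9, size=n_p)
    fetal_mean[is_pcgt] = rng.uniform(0.01, 0.9 * config.fetal_baseline, size=is_pcgt.sum())
    # fetal-methylated decoys stay methylated: decoy block carries PCGT gene
    # annotations but fetal means drawn from the methylated range above
    noise = rng.normal(0.0, 0.01, size=(n_p, n_fetal_samples))
    fetal = np.clip(fetal_mean[:, None] + noise, 1e-6, 1 - 1e-6)
    fetal_ids = [f"F{i:03d}" for i in range(n_fetal_samples)]
    fetal_bm = BetaMatrix(pd.DataFrame(fetal, index=universe.probe_ids, columns=fetal_ids))
    return profiles, fetal_bm


def simulate_probe_annotation(
    config: SimulationConfig,
    universe: ProbeUniverse | None = None,
) -> pd.DataFrame:
    """Probe annotation table: chromosome, position, gene, TSS distance."""
    config.validate()
    if universe is None:
        universe = build_probe_universe(config)
    rng = config.rng("annotation")
    n = universe.n_probes
    chrom = universe.chrom
    annot = pd.DataFrame({
        "probe_id": universe.probe_ids,
        "chrom": chrom.to_numpy(),
        "pos": rng.integers(1, 2_000_000, size=n),
        "gene": universe.gene.to_numpy(),
        "tss_distance": universe.tss_distance.to_numpy(),
    })
    annot["autosomal"] = ~annot["chrom"].isin(["chrX", "chrY", "chrMT"])
    return annot.set_index("probe_id")


def pcgt_gene_list(config: SimulationConfig) -> list[str]:
    """The planted polycomb-target gene symbols."""
    return [f"PCGT{g}" for g in range(config.n_pcgt_genes)]


def simulate_mouse_transfer_inputs(
    config: SimulationConfig,
    n_tissues: int = 4,
    n_mouse_samples: int = 88,
    frac_age_correlated: float = 0.5,
) -> dict:
    """Inputs for the human→mouse ortholog signature transfer.

    Emits an ortholog map (PCGTn → Pcgtn), a mouse probe annotation whose
    PCGT-ortholog promoters sit within the TSS window, a fetal mouse
    reference unmethylated at those promoters, and a multi-tissue aging
    beta matrix in which half the candidate probes are age-correlated after
    tissue adjustment and half are flat.
    """
    config.validate()
    rng = config.rng("mouse")
    genes_h = pcgt_gene_list(config)
    ortho = pd.DataFrame({
        "human_symbol": genes_h,
        "mouse_symbol": [g.capitalize() for g in genes_h],
    })

    n_cand = len(genes_h)
    probe_ids = pd.Index([f"mmu{i:06d}" for i in range(n_cand + 50)], name="probe_id")
    gene = np.full(len(probe_ids), "", dtype=object)
    tss = np.full(len(probe_ids), 1000, dtype=int)
    gene[:n_cand] = [g.capitalize() for g in genes_h]
    tss[:n_cand] = rng.integers(0, 201, size=n_cand)
    chrom = rng.choice([f"chr{c}" for c in range(1, 20)], size=len(probe_ids)).astype(object)
    annot = pd.DataFrame({
        "chrom": chrom, "pos": rng.integers(1, 2_000_000, size=len(probe_ids)),
        "gene": gene, "tss_distance": tss,
    }, index=probe_ids)
    annot["autosomal"] = ~annot["chrom"].isin(["chrX", "chrY", "chrMT"])

    fetal_mean = np.full(len(probe_ids), 0.6)
    fetal_mean[:n_cand] = rng.uniform(0.01, 0.15, size=n_cand)
    fetal = np.clip(fetal_mean[:, None] + rng.normal(0, 0.01, size=(len(probe_ids), 6)),
                    1e-6, 1 - 1e-6)
    fetal_bm = BetaMatrix(pd.DataFrame(
        fetal, index=probe_ids, columns=[f"MF{i}" for i in range(6)]))

    ages = rng.uniform(80, 340, size=n_mouse_samples)  # days
    tissue = rng.choice([f"tissue{t}" for t in range(n_tissues)], size=n_mouse_samples)
    tissue_offsets = {t: rng.normal(0, 0.3) for t in np.unique(tissue)}
    offs = np.array([tissue_offsets[t] for t in tissue])
    z = (ages - ages.mean()) / ages.std()
    n_age = int(round(frac_age_correlated * n_cand))
    slope = np.zeros(len(probe_ids))
    slope[:n_age] = _age_slope(config, config.target_rho)
    baseline = logit(rng.uniform(0.1, 0.4, size=len(probe_ids)))
    noise = rng.normal(0, config.noise_sd, size=(len(probe_ids), n_mouse_samples))
    lat = baseline[:, None] + slope[:, None] * z[None, :] + offs[None, :] + noise
    betas = BetaMatrix(pd.DataFrame(
        expit(lat), index=probe_ids, columns=[f"M{i:03d}" for i in range(n_mouse_samples)]))
    sheet = pd.DataFrame({
        "sample_id": betas.sample_ids,
        "age": ages,
        "tissue": tissue,
        "group": "aging",
    }).set_index("sample_id")
    truth_age = pd.Series(slope > 0, index=probe_ids, name="age_correlated")
    return {
        "ortholog_map": ortho,
        "annotation": annot,
        "fetal": fetal_bm,
        "betas": betas,
        "sheet": sheet,
        "truth_age_correlated": truth_age,
    }
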