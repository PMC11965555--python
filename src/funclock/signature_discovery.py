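"""Discovery of condition-, age- and polycomb-target-associated CpGs, and
assembly of the 22 functionally enriched signatures.

The discovery criteria are:

* condition CpGs — per-probe ordinary least squares of beta on a binary
  condition indicator plus nuisance covariates (cell type, dataset);
  autosomal probes significant after Benjamini–Hochberg correction
  (q < 0.05) are kept with the sign of the condition coefficient; no
  delta-beta filter is applied.
* age CpGs — per-compartment Spearman correlation with chronological age,
  classified as gen (significant and |ρ| > 0.2 in both compartments),
  epi/imm (|ρ| > 0.2 and significant in one, |ρ| < 0.02 in the other),
  nonage (|ρ| < 0.2 in both) or unclassified.
* PCGT CpGs — promoter probes (TSS distance ≤ 200 bp) of polycomb-target
  genes that are unmethylated (mean beta < 0.2) in a fetal reference.

Signatures are overlaps of the age classes with the functional sets under
direction-concordance rules, with ±1 weights given by the sign of the age
correlation (or of the functional effect, for nonage signatures).
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import BetaMatrix, DiscoveryConfig, Signature, SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "fit_condition_models",
    "select_condition_cpgs",
    "age_correlation",
    "classify_age_cpgs",
    "select_pcgt_cpgs",
    "build_signatures",
    "transfer_signature_orthologs",
    "SIGNATURE_NAMES",
]


def _design_matrix(sheet: pd.DataFrame, condition: str, covariates: Sequence[str]) -> pd.DataFrame:
    cond = sheet[condition]
    if cond.nunique() < 2:
        raise ValueError(f"condition column {condition!r} is constant")
    if cond.nunique() > 2:
        raise ValueError(f"condition column {condition!r} is not binary")
    levels = sorted(cond.unique())
    x_cond = (cond == levels[1]).astype(float)
    X = pd.DataFrame({"intercept": 1.0, "condition": x_cond}, index=sheet.index)
    for cov in covariates:
        dummies = pd.get_dummies(sheet[cov], prefix=cov, drop_first=True, dtype=float)
        # collinearity check: can the condition be predicted from this covariate?
        if sheet.groupby(cov, observed=True)[condition].nunique().max() == 1 and sheet[cov].nunique() > 1:
            raise ValueError(
                f"covariate {cov!r} is collinear with the condition "
                f"(condition constant within every {cov!r} level)"
            )
        X = pd.concat([X, dummies], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    return X


def fit_condition_models(
    betas: BetaMatrix,
    sheet: pd.DataFrame,
    condition: str,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-probe OLS of beta on a binary condition plus covariate dummies.

    Returns one row per probe with columns ``effect`` (condition
    coefficient on the beta scale), ``direction`` (its sign), ``p``
    (two-sided) and ``q`` (Benjamini–Hochberg across all tested probes).
    Probes with zero residual variance get p = 1 and direction 0.
    """
    sheet = sheet.loc[betas.sample_ids]
    counts = sheet[condition].value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 samples per condition level")
    X = _design_matrix(sheet, condition, covariates).to_numpy(dtype=float)
    Y = betas.values.to_numpy(dtype=float).T  # samples × probes
    if np.isnan(Y).any():
        # mean-impute per probe: OLS needs complete rows; rare under MAR defaults
        col_mean = np.nanmean(Y, axis=0)
        Y = np.where(np.isnan(Y), col_mean[None, :], Y)

    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    coef = H @ Y  # k × probes
    resid = Y - X @ coef
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    j = 1  # condition column
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[j, j], 0.0))
    effect = coef[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, effect / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(se > 0, p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "effect": effect,
        "direction": np.sign(effect).astype(int),
        "p": p,
        "q": q,
    }, index=betas.probe_ids)
    out.loc[se <= 0, "direction"] = 0
    return out


def select_condition_cpgs(
    assoc: pd.DataFrame,
    annot: pd.DataFrame,
    cfg: DiscoveryConfig | None = None,
) -> pd.Series:
    """Significant autosomal condition CpGs, as a probe → direction Series.

    Selection is q < q_max on autosomes only; no effect-size (delta-beta)
    filter is applied.
    """
    cfg = cfg or DiscoveryConfig()
    missing = assoc.index.difference(annot.index)
    if len(missing) > 0:
        raise ValueError(f"annotation missing for probes: {list(missing[:5])}")
    autosomal = annot.loc[assoc.index, "autosomal"].astype(bool)
    keep = (assoc["q"] < cfg.q_max) & autosomal & (assoc["direction"] != 0)
    return assoc.loc[keep, "direction"].astype(int)


def _spearman_vs_age(values: np.ndarray, age: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman ρ of a probes × samples block against age, with
    p-values from the large-sample t approximation.  Constant rows → NaN."""
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1, nan_policy="omit")
    age_rank = stats.rankdata(age)
    rx = ranks - np.nanmean(ranks, axis=1, keepdims=True)
    ry = age_rank - age_rank.mean()
    # handle missing entries pairwise by zeroing their contribution
    nan_mask = np.isnan(rx)
    if nan_mask.any():
        rho = np.empty(values.shape[0])
        p = np.empty(values.shape[0])
        for i in range(values.shape[0]):
            ok = ~np.isnan(values[i])
            if ok.sum() < 3 or np.nanstd(values[i]) == 0:
                rho[i], p[i] = np.nan, np.nan
            else:
                rho[i], p[i] = stats.spearmanr(values[i, ok], age[ok])
        return rho, p
    num = (rx * ry[None, :]).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(den > 0, num / den, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.isnan(rho), np.nan, p)
    return rho, p


def _bh_with_nan(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.sum() > 0:
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def age_correlation(
    betas: BetaMatrix,
    sheet: pd.DataFrame,
    cfg: DiscoveryConfig | None = None,
) -> pd.DataFrame:
    """Per-probe Spearman correlation with age in each compartment.

    The epithelial subset comprises samples labelled epithelial or whose
    inferred immune proportion is below the immune filter; the immune
    subset comprises samples labelled immune.  BH correction is applied
    within each compartment separately.
    """
    cfg = cfg or DiscoveryConfig()
    sheet = sheet.loc[betas.sample_ids]
    imm_prop = sheet.get("immune_proportion", pd.Series(np.nan, index=sheet.index))
    epi_mask = (sheet["compartment"] == "epithelial") | (imm_prop < cfg.immune_filter)
    imm_mask = sheet["compartment"] == "immune"
    for name, mask in (("epithelial", epi_mask), ("immune", imm_mask)):
        if mask.sum() < 5:
            raise ValueError(f"compartment {name!r} has fewer than 5 samples ({int(mask.sum())})")

    out = pd.DataFrame(index=betas.probe_ids)
    vals = betas.values.to_numpy(dtype=float)
    age = sheet["age"].to_numpy(dtype=float)
    for tag, mask in (("epi", epi_mask.to_numpy()), ("imm", imm_mask.to_numpy())):
        rho, p = _spearman_vs_age(vals[:, mask], age[mask])
        out[f"rho_{tag}"] = rho
        out[f"p_{tag}"] = p
        out[f"q_{tag}"] = _bh_with_nan(p)
    out["class"] = classify_age_cpgs(out, cfg)
    return out


def classify_age_cpgs(ac: pd.DataFrame, cfg: DiscoveryConfig | None = None) -> pd.Series:
    """Assign each probe to gen / epi / imm / nonage / unclassified.

    gen: significant with |ρ| > rho_min in both compartments.
    epi (imm): significant with |ρ| > rho_min in that compartment and
    |ρ| < rho_other_max in the other.  nonage: |ρ| < nonage_rho_max in
    both.  Probes with undefined ρ in either compartment are unclassified.
    """
    cfg = cfg or DiscoveryConfig()
    re_, ri = ac["rho_epi"].to_numpy(), ac["rho_imm"].to_numpy()
    qe, qi = ac["q_epi"].to_numpy(), ac["q_imm"].to_numpy()
    defined = ~(np.isnan(re_) | np.isnan(ri))
    gen = defined & (qe < cfg.q_max) & (qi < cfg.q_max) \
        & (np.abs(re_) > cfg.rho_min) & (np.abs(ri) > cfg.rho_min)
    epi = defined & (qe < cfg.q_max) & (np.abs(re_) > cfg.rho_min) \
        & (np.abs(ri) < cfg.rho_other_max)
    imm = defined & (qi < cfg.q_max) & (np.abs(ri) > cfg.rho_min) \
        & (np.abs(re_) < cfg.rho_other_max)
    nonage = defined & (np.abs(re_) < cfg.nonage_rho_max) & (np.abs(ri) < cfg.nonage_rho_max)
    cls = np.full(len(ac), "unclassified", dtype=object)
    cls[nonage] = "nonage"
    cls[imm] = "imm"
    cls[epi] = "epi"
    cls[gen] = "gen"
    return pd.Series(cls, index=ac.index, name="class")


def select_pcgt_cpgs(
    pcgt_genes: Iterable[str],
    annot: pd.DataFrame,
    fetal: BetaMatrix,
    cfg: DiscoveryConfig | None = None,
) -> pd.Index:
    """Polycomb-target promoter probes unmethylated in the fetal reference.

    A probe qualifies if its annotated gene is in the PCGT list, it lies
    within the TSS window, and its mean fetal beta is below the ceiling.
    Probes absent from the fetal matrix are excluded with a warning
    (conservative: absence of evidence of fetal hypomethylation).
    """
    cfg = cfg or DiscoveryConfig()
    genes = set(pcgt_genes)
    in_gene = annot["gene"].isin(genes)
    in_window = annot["tss_distance"].between(0, cfg.tss_window)
    candidates = annot.index[in_gene & in_window]
    missing = candidates.difference(fetal.probe_ids)
    if len(missing) > 0:
        logger.warning(
            "select_pcgt_cpgs: %d candidate probes absent from fetal reference; excluded",
            len(missing),
        )
    candidates = candidates.intersection(fetal.probe_ids)
    fetal_mean = fetal.values.loc[candidates].mean(axis=1)
    return candidates[fetal_mean < cfg.fetal_beta_max]


# Full family enumeration: AGE×3 + SEN×5 + PCGT×5 + PRO×9 = 22 signatures.
SIGNATURE_NAMES = (
    "AGE", "AGEepi", "AGEimm",
    "SENgen", "SENepi", "SENimm", "SENpure", "SENnonage",
    "PCGTgen", "PCGTepi", "PCGTimm", "PCGTpure", "PCGTnonage",
    "PROgen+", "PROgen-", "PROepi+", "PROepi-", "PROimm+", "PROimm-",
    "PROpure+", "PROpure-", "PROnonage",
)


def _age_sign(ac: pd.DataFrame, probe: str, cls: str) -> int | None:
    """Sign of the age correlation in the class-defining compartment.

    For gen the two compartment signs must agree; discordant probes return
    None and are dropped by the caller with a warning.
    """
    re_, ri = ac.at[probe, "rho_epi"], ac.at[probe, "rho_imm"]
    if cls == "epi":
        return int(np.sign(re_))
    if cls == "imm":
        return int(np.sign(ri))
    se, si = int(np.sign(re_)), int(np.sign(ri))
    if se != si:
        return None
    return se


def build_signatures(
    age: pd.DataFrame,
    sen: Mapping[str, int] | pd.Series,
    pro: Mapping[str, int] | pd.Series,
    pcgt: Iterable[str],
    cfg: DiscoveryConfig | None = None,
    provenance: dict | None = None,
) -> SignatureSet:
    """Overlap the age classes with the functional sets into 22 signatures.

    ``sen`` and ``pro`` map probes to ±1 directions; ``pro`` directions are
    with respect to INCREASED proliferation (flip the sign of a
    reduced-proliferation treatment coefficient before calling).  ``pcgt``
    is the set of qualifying polycomb-target promoter probes.

    Concordance: SEN overlaps require the age-correlation sign to equal the
    senescence direction; PCGT overlaps admit only positively
    age-correlated probes; PRO+ requires age and proliferation signs to
    agree, PRO− to disagree.  Weights are the age-correlation sign for
    age-containing signatures and the functional direction for nonage
    signatures (PCGTnonage: +1).  Empty overlaps are emitted flagged
    unusable so the enumeration is always complete.
    """
    cfg = cfg or DiscoveryConfig()
    sen = pd.Series(sen, dtype=int) if not isinstance(sen, pd.Series) else sen.astype(int)
    pro = pd.Series(pro, dtype=int) if not isinstance(pro, pd.Series) else pro.astype(int)
    pcgt = pd.Index(pcgt)
    for name, idx in (("sen", sen.index), ("pro", pro.index), ("pcgt", pcgt)):
        stray = idx.difference(age.index)
        if len(stray) > 0:
            raise ValueError(
                f"{name} probes outside the age-correlation universe: {list(stray[:5])}"
            )

    cls = age["class"]
    age_classes = {c: set(cls.index[cls == c]) for c in ("gen", "epi", "imm", "nonage")}
    age_union = age_classes["gen"] | age_classes["epi"] | age_classes["imm"]
    sen_set, pro_set, pcgt_set = set(sen.index), set(pro.index), set(pcgt)
    functional = sen_set | pro_set | pcgt_set
    only = {
        "SEN": sen_set - pro_set - pcgt_set,
        "PRO": pro_set - sen_set - pcgt_set,
        "PCGT": pcgt_set - sen_set - pro_set,
    }

    n_discordant = 0

    def signed_members(probes: set, compartment_cls: str) -> dict[str, int]:
        nonlocal n_discordant
        out = {}
        for p in sorted(probes):
            s = _age_sign(age, p, compartment_cls)
            if s is None or s == 0:
                n_discordant += 1
                continue
            out[p] = s
        return out

    def probe_cls(p: str) -> str:
        return cls.at[p]

    sigs: dict[str, Signature] = {}

    def emit(name, function, specificity, members: dict[str, int], pro_sign="n/a"):
        probes = tuple(sorted(members))
        weights = tuple(int(members[p]) for p in probes)
        sig = Signature(name=name, function=function, specificity=specificity,
                        probes=probes, weights=weights, pro_sign=pro_sign)
        if not sig.usable:
            logger.warning("signature %s is empty; flagged unusable", name)
        sigs[name] = sig

    # AGE: aging alone — class members not in any functional set
    for cname, sname in (("gen", "AGE"), ("epi", "AGEepi"), ("imm", "AGEimm")):
        members = signed_members(age_classes[cname] - functional, cname)
        emit(sname, "AGE", cname if cname != "gen" else "gen", members)

    # SEN family: concordance sign(age ρ) == senescence direction
    def sen_concordant(probes: set, cname_of) -> dict[str, int]:
        nonlocal n_discordant
        out = {}
        for p in sorted(probes):
            s = _age_sign(age, p, cname_of(p))
            if s is None or s == 0:
                n_discordant += 1
                continue
            if s == int(sen.at[p]):
                out[p] = s
        return out

    for cname in ("gen", "epi", "imm"):
        members = sen_concordant(age_classes[cname] & sen_set, lambda p, c=cname: c)
        emit(f"SEN{cname}", "SEN", cname, members)
    members = sen_concordant(age_union & only["SEN"], probe_cls)
    emit("SENpure", "SEN", "pure", members)
    members = {p: int(sen.at[p]) for p in sorted(age_classes["nonage"] & sen_set)}
    emit("SENnonage", "SEN", "nonage", members)

    # PCGT family: positively age-correlated sites only; weights +1
    def pcgt_members(probes: set, cname_of) -> dict[str, int]:
        out = {}
        nonlocal n_discordant
        for p in sorted(probes):
            s = _age_sign(age, p, cname_of(p))
            if s is None:
                n_discordant += 1
                continue
            if s > 0:
                out[p] = 1
        return out

    for cname in ("gen", "epi", "imm"):
        members = pcgt_members(age_classes[cname] & pcgt_set, lambda p, c=cname: c)
        emit(f"PCGT{cname}", "PCGT", cname, members)
    members = pcgt_members(age_union & only["PCGT"], probe_cls)
    emit("PCGTpure", "PCGT", "pure", members)
    members = {p: 1 for p in sorted(age_classes["nonage"] & pcgt_set)}
    emit("PCGTnonage", "PCGT", "nonage", members)

    # PRO family: + requires concordant signs, − opposing signs
    def pro_members(probes: set, cname_of, want_concordant: bool) -> dict[str, int]:
        out = {}
        nonlocal n_discordant
        for p in sorted(probes):
            s = _age_sign(age, p, cname_of(p))
            if s is None or s == 0:
                n_discordant += 1
                continue
            concordant = s == int(pro.at[p])
            if concordant == want_concordant:
                out[p] = s
        return out

    for cname in ("gen", "epi", "imm"):
        pool = age_classes[cname] & pro_set
        emit(f"PRO{cname}+", "PRO", cname,
             pro_members(pool, lambda p, c=cname: c, True), pro_sign="+")
        emit(f"PRO{cname}-", "PRO", cname,
             pro_members(pool, lambda p, c=cname: c, False), pro_sign="-")
    pool = age_union & only["PRO"]
    emit("PROpure+", "PRO", "pure", pro_members(pool, probe_cls, True), pro_sign="+")
    emit("PROpure-", "PRO", "pure", pro_members(pool, probe_cls, False), pro_sign="-")
    members = {p: int(pro.at[p]) for p in sorted(age_classes["nonage"] & pro_set)}
    emit("PROnonage", "PRO", "nonage", members)

    if n_discordant > 0:
        logger.warning("build_signatures: dropped %d probes with discordant or zero "
                       "compartment correlation signs", n_discordant)

    prov = dict(provenance or {})
    prov["discovery_config"] = asdict(cfg)
    out = SignatureSet({n: sigs[n] for n in SIGNATURE_NAMES}, provenance=prov)
    return out


def transfer_signature_orthologs(
    pcgt_genes_human: Iterable[str],
    ortholog_map: pd.DataFrame,
    mouse_annot: pd.DataFrame,
    mouse_fetal: BetaMatrix,
    mouse_age_betas: BetaMatrix,
    mouse_sheet: pd.DataFrame,
    cfg: DiscoveryConfig | None = None,
) -> tuple[Signature, Signature]:
    """Transfer the PCGT signature to mouse via gene orthologs.

    Candidate probes are mouse-array probes whose gene is a murine ortholog
    of a human PCGT gene, within the TSS window, autosomal, and
    unmethylated in fetal mouse tissue.  Age correlation is computed on
    tissue-adjusted residuals (beta regressed on tissue indicators, then
    Spearman against age).  mPCGTgen collects candidates with ρ > rho_min
    and q < q_max; mPCGTnonage those with |ρ| < nonage_rho_max.  All
    weights are +1.
    """
    cfg = cfg or DiscoveryConfig()
    human = set(pcgt_genes_human)
    mouse_genes = set(
        ortholog_map.loc[ortholog_map["human_symbol"].isin(human), "mouse_symbol"]
    )
    cand = mouse_annot.index[
        mouse_annot["gene"].isin(mouse_genes)
        & mouse_annot["tss_distance"].between(0, cfg.tss_window)
        & mouse_annot["autosomal"].astype(bool)
    ]
    cand = cand.intersection(mouse_fetal.probe_ids)
    fetal_mean = mouse_fetal.values.loc[cand].mean(axis=1)
    cand = cand[fetal_mean < cfg.fetal_beta_max]
    cand = cand.intersection(mouse_age_betas.probe_ids)
    if len(cand) == 0:
        raise ValueError("empty ortholog candidate set after filtering")

    sheet = mouse_sheet.loc[mouse_age_betas.sample_ids]
    tissues = pd.get_dummies(sheet["tissue"], dtype=float)
    X = np.column_stack([np.ones(len(sheet)), tissues.to_numpy()[:, 1:]])
    Y = mouse_age_betas.values.loc[cand].to_numpy(dtype=float).T
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ coef).T  # probes × samples
    rho, p = _spearman_vs_age(resid, sheet["age"].to_numpy(dtype=float))
    q = _bh_with_nan(p)

    gen_mask = (rho > cfg.rho_min) & (q < cfg.q_max)
    nonage_mask = np.abs(rho) < cfg.nonage_rho_max
    gen_probes = tuple(sorted(cand[np.nan_to_num(gen_mask)]))
    nonage_probes = tuple(sorted(cand[np.nan_to_num(nonage_mask)]))
    m_gen = Signature("mPCGTgen", "PCGT", "gen", gen_probes, (1,) * len(gen_probes))
    m_non = Signature("mPCGTnonage", "PCGT", "nonage", nonage_probes,
                      (1,) * len(nonage_probes))
    return m_gen, m_non
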