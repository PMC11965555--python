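"""Contrast evaluation: covariate residualization, fixed-direction AUC,
rank tests with FDR, and expression validation.

Clock scores are first adjusted for nuisance covariates (chronological age
and inferred immune proportion, unless a contrast opts out) by ordinary
least squares over the pooled reference + comparison samples, and the
residuals are compared.  The AUC is the probability that a comparison
sample scores above a reference sample (ties count half); the direction is
never flipped, so AUC > 0.5 always reads as "epigenetically older than the
reference".  Significance requires both the Benjamini–Hochberg-adjusted
two-sided rank-test q below 0.05 and a confidence interval excluding 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ComparisonSpec

__all__ = [
    "residualize",
    "compute_auc",
    "AucResult",
    "evaluate_contrast",
    "test_and_adjust",
    "correlate_with_expression",
    "build_result_table",
]


def residualize(
    scores: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates: list[str] | tuple[str, ...],
) -> pd.DataFrame:
    """OLS residuals of each score column on the covariates.

    Fitted over all rows of ``scores`` (the pooled contrast samples).  An
    empty covariate list returns mean-centred scores, which leaves every
    rank-based downstream statistic unchanged.
    """
    sub = sheet.loc[scores.index]
    if not covariates:
        return scores - scores.mean(axis=0)
    cols = []
    for cov in covariates:
        if cov not in sub.columns:
            raise ValueError(f"covariate {cov!r} not in sample sheet")
        v = sub[cov].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            raise ValueError(f"covariate {cov!r} is constant across contrast samples")
        cols.append(v)
    X = np.column_stack([np.ones(len(sub))] + cols)
    Y = scores.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return pd.DataFrame(resid, index=scores.index, columns=scores.columns)


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    n_ref: int
    n_cmp: int


def _placements(cmp_vals: np.ndarray, ref_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # V10_i: fraction of reference values below comparison value i (ties half)
    diff = cmp_vals[:, None] - ref_vals[None, :]
    gt = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return gt.mean(axis=1), gt.mean(axis=0)


def compute_auc(
    scores: pd.Series,
    ref_ids,
    cmp_ids,
    ci_level: float = 0.95,
    small_n: int = 10,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> AucResult:
    """Fixed-direction AUC of comparison vs reference scores with CI.

    AUC = P(score_cmp > score_ref) + ½·P(tie) over all cross-group pairs,
    identical to U/(n_ref·n_cmp).  The CI uses the asymptotic variance of
    the placement values (DeLong); when either arm has fewer than
    ``small_n`` samples a percentile bootstrap over both arms is used
    instead.  The AUC is never reflected around 0.5.
    """
    ref_vals = scores.loc[ref_ids].to_numpy(dtype=float)
    cmp_vals = scores.loc[cmp_ids].to_numpy(dtype=float)
    n_ref, n_cmp = len(ref_vals), len(cmp_vals)
    if n_ref == 0 or n_cmp == 0:
        raise ValueError("both reference and comparison groups must be non-empty")
    v10, v01 = _placements(cmp_vals, ref_vals)
    auc = float(v10.mean())

    zq = stats.norm.ppf(0.5 + ci_level / 2)
    if min(n_ref, n_cmp) >= small_n:
        var = 0.0
        if n_cmp > 1:
            var += np.var(v10, ddof=1) / n_cmp
        if n_ref > 1:
            var += np.var(v01, ddof=1) / n_ref
        half = zq * np.sqrt(var)
        lo, hi = auc - half, auc + half
    else:
        rng = rng or np.random.default_rng(0)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            rv = ref_vals[rng.integers(0, n_ref, n_ref)]
            cv = cmp_vals[rng.integers(0, n_cmp, n_cmp)]
            boots[b] = _placements(cv, rv)[0].mean()
        alpha = 1 - ci_level
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return AucResult(auc=auc, ci_low=float(max(lo, 0.0)), ci_high=float(min(hi, 1.0)),
                     n_ref=n_ref, n_cmp=n_cmp)


def _rank_p(scores: pd.Series, ref_ids, cmp_ids, spec: ComparisonSpec,
            sheet: pd.DataFrame | None) -> float:
    cmp_vals = scores.loc[cmp_ids].to_numpy(dtype=float)
    ref_vals = scores.loc[ref_ids].to_numpy(dtype=float)
    if spec.paired:
        if sheet is None or spec.pair_column not in sheet.columns:
            raise ValueError(
                f"paired contrast {spec.contrast_id!r} needs pair column "
                f"{spec.pair_column!r} in the sample sheet"
            )
        ref_by = pd.Series(ref_vals, index=sheet.loc[ref_ids, spec.pair_column])
        cmp_by = pd.Series(cmp_vals, index=sheet.loc[cmp_ids, spec.pair_column])
        common = ref_by.index.intersection(cmp_by.index)
        if len(common) < 2:
            raise ValueError(f"paired contrast {spec.contrast_id!r}: fewer than 2 pairs")
        d = cmp_by.loc[common].to_numpy() - ref_by.loc[common].to_numpy()
        if np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
    if np.all(cmp_vals[:, None] == ref_vals[None, :]):
        return 1.0
    return float(stats.mannwhitneyu(cmp_vals, ref_vals, alternative="two-sided").pvalue)


def evaluate_contrast(
    scores: pd.DataFrame,
    sheet: pd.DataFrame,
    spec: ComparisonSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Residualize, compute AUC + CI + rank-test p per signature, then FDR.

    Covariate adjustment follows the contrast spec; the BH family is all
    signatures within this one contrast.  ``significant`` requires q < 0.05
    and a CI excluding 0.5.
    """
    ref_ids, cmp_ids = spec.select(sheet.loc[scores.index.intersection(sheet.index)])
    ref_ids = ref_ids.intersection(scores.index)
    cmp_ids = cmp_ids.intersection(scores.index)
    pooled = ref_ids.append(cmp_ids)
    adjusted = residualize(scores.loc[pooled], sheet, list(spec.covariates))

    rows = []
    for name in scores.columns:
        s = adjusted[name]
        res = compute_auc(s, ref_ids, cmp_ids, rng=rng)
        p = _rank_p(s, ref_ids, cmp_ids, spec, sheet)
        rows.append({
            "contrast": spec.contrast_id, "signature": name,
            "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p": p, "n_ref": res.n_ref, "n_cmp": res.n_cmp,
        })
    out = pd.DataFrame(rows)
    return test_and_adjust(out)


def test_and_adjust(results: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """BH-adjust rank-test p-values within each contrast and flag significance.

    significant ⇔ q < q_max and the AUC confidence interval excludes 0.5.
    """
    out = results.copy()
    out["q"] = np.nan
    for _, idx in out.groupby("contrast").groups.items():
        out.loc[idx, "q"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    excludes_half = (out["ci_low"] > 0.5) | (out["ci_high"] < 0.5)
    out["significant"] = (out["q"] < q_max) & excludes_half
    return out


def correlate_with_expression(
    scores: pd.DataFrame,
    expression: pd.Series,
    signature: str,
) -> tuple[float, float]:
    """Spearman correlation of one signature's scores with gene expression.

    Returns (ρ, p); constant expression yields (nan, nan) — flagged
    undefined rather than erroring, since TCGA-style expression panels can
    contain non-expressed genes.
    """
    common = scores.index.intersection(expression.index)
    if len(common) < 5:
        raise ValueError("need at least 5 paired samples")
    x = scores.loc[common, signature].to_numpy(dtype=float)
    y = expression.loc[common].to_numpy(dtype=float)
    if np.std(y) == 0 or np.std(x) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def build_result_table(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format result table plus a contrasts × signatures AUC matrix.

    The matrix export marks significant cells with an asterisk in a parallel
    string table (heatmap-ready).
    """
    cols = ["contrast", "signature", "auc", "ci_low", "ci_high", "p", "q",
            "n_ref", "n_cmp", "significant"]
    if len(results) == 0:
        return pd.DataFrame(columns=cols), pd.DataFrame()
    long = results.loc[:, [c for c in cols if c in results.columns]].copy()
    matrix = long.pivot(index="contrast", columns="signature", values="auc")
    return long, matrix
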