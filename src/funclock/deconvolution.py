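"""Reference-based cell-composition estimation and composition filters.

Proportions are obtained by non-negative least squares of each sample's
marker betas on the reference profiles, renormalised to sum to one — a
simplified constrained-regression stand-in for reference-based
deconvolution of immune/epithelial/tumor fractions, sufficient to drive
the <20 % immune filter and the 0 %-tumor exclusion downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .types import BetaMatrix, DiscoveryConfig, ReferenceProfiles

__all__ = ["estimate_proportions", "filter_samples", "TUMOR_EPS"]

# "0 % inferred tumor" tolerance: estimated fractions below this are zero
TUMOR_EPS = 1e-6


def estimate_proportions(
    betas: BetaMatrix,
    ref: ReferenceProfiles,
    min_marker_overlap: float = 0.8,
) -> pd.DataFrame:
    """Per-sample component fractions by NNLS on the reference markers.

    Returns a samples × components DataFrame of fractions (non-negative,
    summing to one) plus a ``residual`` column with the per-sample residual
    norm of the constrained fit.
    """
    markers = ref.markers.intersection(betas.probe_ids)
    if len(ref.markers) == 0 or len(markers) / len(ref.markers) < min_marker_overlap:
        raise ValueError(
            f"only {len(markers)}/{len(ref.markers)} reference markers present "
            f"in the matrix (need ≥ {min_marker_overlap:.0%})"
        )
    A = ref.profiles.loc[markers].to_numpy(dtype=float)
    if len(markers) < A.shape[1]:
        raise ValueError("fewer overlapping markers than components")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("reference profiles are rank deficient over shared markers")
    B = betas.values.loc[markers].to_numpy(dtype=float)

    n_samples = B.shape[1]
    fractions = np.zeros((n_samples, A.shape[1]))
    residuals = np.zeros(n_samples)
    for j in range(n_samples):
        b = B[:, j]
        ok = ~np.isnan(b)
        coef, rnorm = nnls(A[ok], b[ok])
        total = coef.sum()
        fractions[j] = coef / total if total > 0 else 1.0 / A.shape[1]
        residuals[j] = rnorm
    out = pd.DataFrame(fractions, index=betas.sample_ids, columns=ref.components)
    out["residual"] = residuals
    return out


def filter_samples(
    sheet: pd.DataFrame,
    rule: str,
    cfg: DiscoveryConfig | None = None,
) -> pd.Index:
    """Retain samples passing a composition rule.

    ``epithelial`` keeps samples with immune_proportion strictly below the
    immune filter (< 20 % by default); ``tumor_free`` keeps samples whose
    estimated tumor fraction is zero (below a small numerical tolerance).
    """
    cfg = cfg or DiscoveryConfig()
    if rule == "epithelial":
        col = "immune_proportion"
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
        keep = sheet[col] < cfg.immune_filter
    elif rule == "tumor_free":
        col = "tumor_fraction"
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
        keep = sheet[col] <= TUMOR_EPS
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    return sheet.index[keep.fillna(False)]
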