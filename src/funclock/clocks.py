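"""Clock scoring: the ±1 weighted-mean statistic and generic linear clocks.

The signature clock for a sample is

    clock = Σ_i (w_i · β_i) / n

where w_i ∈ {+1, −1} are the directionality weights, β_i the methylation
betas of the signature's CpGs and n the number of CpGs.  No training is
involved: the score is a direct weighted mean, deliberately not optimised
to predict chronological age.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import BetaMatrix, LinearClockSpec, Signature, SignatureSet

__all__ = ["compute_clock", "compute_clock_set", "compute_linear_clock"]


def compute_clock(
    betas: BetaMatrix,
    sig: Signature,
    missing_policy: str = "available",
) -> pd.DataFrame:
    """Per-sample weighted-mean score for one signature.

    ``missing_policy='available'`` (default) divides by the number of
    signature probes actually present and non-missing per sample, so the
    score stays comparable across array generations with different probe
    sets; ``'strict'`` always divides by the full signature size.

    Returns a DataFrame indexed by sample with columns ``score`` and
    ``n_used``.
    """
    if missing_policy not in ("available", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    present = [p for p in sig.probes if p in betas.probe_ids]
    if len(present) == 0:
        raise ValueError(f"no probes of signature {sig.name!r} present in the matrix")
    w = sig.weight_series().loc[present].to_numpy()
    vals = betas.values.loc[present].to_numpy(dtype=float)  # probes × samples
    contrib = w[:, None] * vals
    observed = ~np.isnan(vals)
    n_used = observed.sum(axis=0)
    total = np.nansum(np.where(observed, contrib, 0.0), axis=0)
    denom = float(len(sig.probes)) if missing_policy == "strict" else n_used.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(n_used > 0, total / denom, np.nan)
    return pd.DataFrame({"score": score, "n_used": n_used}, index=betas.sample_ids)


def compute_clock_set(
    betas: BetaMatrix,
    signatures: SignatureSet,
    missing_policy: str = "available",
    skip_unusable: bool = True,
) -> pd.DataFrame:
    """Score every signature of a set; samples × signatures score table."""
    cols = {}
    for sig in signatures:
        if skip_unusable and not sig.usable:
            continue
        cols[sig.name] = compute_clock(betas, sig, missing_policy)["score"]
    return pd.DataFrame(cols, index=betas.sample_ids)


_TRANSFORMS = {
    None: lambda x: x,
    "identity": lambda x: x,
    "log": np.log,
    "exp": np.exp,
}


def compute_linear_clock(
    betas: BetaMatrix,
    spec: LinearClockSpec,
    max_missing_fraction: float = 0.2,
) -> pd.Series:
    """Apply a user-supplied linear clock: intercept + Σ coef·β.

    Probes listed in the spec but absent from the matrix are dropped; if
    more than ``max_missing_fraction`` of them are missing the clock is
    refused, since the published coefficient sets are not designed to be
    renormalised.
    """
    spec_probes = spec.coefficients.index
    present = spec_probes.intersection(betas.probe_ids)
    missing_frac = 1.0 - len(present) / max(len(spec_probes), 1)
    if missing_frac > max_missing_fraction:
        raise ValueError(
            f"clock {spec.name!r}: {missing_frac:.0%} of coefficient probes "
            f"missing from the matrix (limit {max_missing_fraction:.0%})"
        )
    coef = spec.coefficients.loc[present].to_numpy(dtype=float)
    vals = betas.values.loc[present].to_numpy(dtype=float)
    value = spec.intercept + coef @ np.nan_to_num(vals)
    out = pd.Series(_TRANSFORMS[spec.transform](value), index=betas.sample_ids,
                    name=spec.name)
    return out
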