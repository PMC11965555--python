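"""Core containers shared across the pipeline.

All tabular data travel as pandas objects; the thin dataclasses here only
add validation and naming that a bare DataFrame cannot express (probe/sample
orientation, ±1 signature weights, planted simulation truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "Signature",
    "SignatureSet",
    "ReferenceProfiles",
    "LinearClockSpec",
    "DiscoveryConfig",
    "ComparisonSpec",
    "validate_sample_sheet",
]

SIGNATURE_FUNCTIONS = ("AGE", "SEN", "PCGT", "PRO")
SPECIFICITIES = ("gen", "epi", "imm", "pure", "nonage")
AGE_CLASSES = ("gen", "epi", "imm", "nonage", "unclassified")


@dataclass
class BetaMatrix:
    """Methylation beta values, probes as rows and samples as columns.

    Values are methylation fractions in [0, 1]; NaN marks missing entries.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("BetaMatrix.values must be a pandas DataFrame")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate probe ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            pi, si = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"beta value out of [0, 1] at probe {v.index[pi]!r}, "
                f"sample {v.columns[si]!r}: {arr[pi, si]}"
            )
        self.values = v.rename_axis(index="probe_id")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probes)])

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(samples)])


@dataclass
class Signature:
    """A named CpG group with ±1 directionality weights.

    ``function`` is the functional family (AGE/SEN/PCGT/PRO), ``specificity``
    the age-correlation class (gen/epi/imm/pure/nonage) and ``pro_sign``
    distinguishes PRO+ from PRO− (n/a otherwise).  A signature that came out
    empty from an overlap is kept (``usable=False``) so the enumeration of
    families is stable.
    """

    name: str
    function: str
    specificity: str
    probes: tuple[str, ...]
    weights: tuple[int, ...]
    pro_sign: str = "n/a"
    usable: bool = True

    def __post_init__(self) -> None:
        if self.function not in SIGNATURE_FUNCTIONS:
            raise ValueError(f"unknown signature function {self.function!r}")
        if len(self.probes) != len(self.weights):
            raise ValueError("probes and weights length mismatch")
        if len(set(self.probes)) != len(self.probes):
            raise ValueError(f"duplicate probes in signature {self.name!r}")
        if any(w not in (-1, 1) for w in self.weights):
            raise ValueError(f"weights must be ±1 in signature {self.name!r}")
        if len(self.probes) == 0:
            self.usable = False

    def __len__(self) -> int:
        return len(self.probes)

    def weight_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.probes), dtype=float)


@dataclass
class SignatureSet:
    """An ordered, name-keyed collection of signatures with provenance."""

    signatures: dict[str, Signature]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sig in self.signatures.items():
            if name != sig.name:
                raise ValueError(f"key {name!r} does not match signature name {sig.name!r}")

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures.values())

    def __getitem__(self, name: str) -> Signature:
        return self.signatures[name]

    @property
    def names(self) -> list[str]:
        return list(self.signatures)

    def usable(self) -> "SignatureSet":
        return SignatureSet(
            {n: s for n, s in self.signatures.items() if s.usable},
            provenance=dict(self.provenance),
        )


@dataclass
class ReferenceProfiles:
    """Mean beta per marker probe × cell component, for deconvolution."""

    profiles: pd.DataFrame  # markers × components

    def __post_init__(self) -> None:
        arr = self.profiles.to_numpy(dtype=float)
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("reference profile betas must lie in [0, 1]")
        if self.profiles.index.has_duplicates:
            raise ValueError("duplicate marker probe ids in reference profiles")

    @property
    def markers(self) -> pd.Index:
        return self.profiles.index

    @property
    def components(self) -> pd.Index:
        return self.profiles.columns


@dataclass
class LinearClockSpec:
    """User-supplied linear clock: value = intercept + Σ coef·β (+ transform)."""

    name: str
    intercept: float
    coefficients: pd.Series  # index: probe_id
    transform: str | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coefficients.to_numpy(dtype=float))):
            raise ValueError(f"non-finite coefficient in clock {self.name!r}")
        if self.transform not in (None, "identity", "log", "exp"):
            raise ValueError(f"unknown transform tag {self.transform!r}")


@dataclass
class DiscoveryConfig:
    """Thresholds of the signature-discovery stage.

    Defaults follow the published criteria: FDR q < 0.05, compartment
    |Spearman ρ| > 0.2, cross-compartment |ρ| < 0.02 for specific classes,
    fetal mean beta < 0.2 for polycomb-target promoters, TSS window 200 bp,
    epithelial samples restricted to < 20 % inferred immune proportion.
    """

    q_max: float = 0.05
    rho_min: float = 0.2
    rho_other_max: float = 0.02
    fetal_beta_max: float = 0.2
    tss_window: int = 200
    immune_filter: float = 0.20
    nonage_rho_max: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must lie in (0, 1)")
        if not 0 < self.rho_other_max < self.rho_min < 1:
            raise ValueError("need 0 < rho_other_max < rho_min < 1")
        for name in ("fetal_beta_max", "immune_filter", "nonage_rho_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tss_window <= 0:
            raise ValueError("tss_window must be positive")


@dataclass
class ComparisonSpec:
    """One reference-vs-comparison contrast over a sample sheet.

    Selectors are pandas ``query`` expressions; the comparison group is the
    fixed positive class, so AUC > 0.5 always reads as "comparison scores
    higher than reference".
    """

    contrast_id: str
    reference_query: str
    comparison_query: str
    covariates: tuple[str, ...] = ()
    paired: bool = False
    pair_column: str = "individual"
    dataset_id: str | None = None

    def select(self, sheet: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
        ref = sheet.query(self.reference_query).index
        cmp_ = sheet.query(self.comparison_query).index
        overlap = ref.intersection(cmp_)
        if len(overlap) > 0:
            raise ValueError(
                f"contrast {self.contrast_id!r}: selectors overlap on "
                f"{list(overlap[:5])}"
            )
        return ref, cmp_


REQUIRED_SHEET_COLUMNS = ("sample_id", "age", "group")


def validate_sample_sheet(sheet: pd.DataFrame, betas: BetaMatrix | None = None) -> pd.DataFrame:
    """Validate a sample sheet, returning it indexed by sample_id."""
    sheet = sheet.copy()
    if "sample_id" in sheet.columns:
        sheet = sheet.set_index("sample_id")
    if sheet.index.has_duplicates:
        raise ValueError("duplicate sample_id in sample sheet")
    if "age" in sheet.columns:
        ages = sheet["age"].dropna()
        if (ages <= 0).any():
            raise ValueError("ages must be positive")
    for col in ("immune_proportion", "tumor_fraction"):
        if col in sheet.columns:
            vals = sheet[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
    if betas is not None:
        missing = sheet.index.difference(betas.sample_ids)
        if len(missing) > 0:
            raise ValueError(f"sheet samples absent from beta matrix: {list(missing[:5])}")
    return sheet
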