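"""Readers/writers for the pipeline's text formats, plus array-level QC.

Dialects are fixed: UTF-8 throughout, '.' decimal separator, beta matrices
as tab-separated text with probes as rows and a leading ``probe_id``
column, sample sheets and annotation as comma-separated with a header row,
signatures as a three-column TSV (signature, probe_id, weight).  Probe and
sample order is preserved on round trips.  CRLF and LF inputs parse
identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import BetaMatrix, ComparisonSpec, ReferenceProfiles, Signature, SignatureSet

__all__ = [
    "read_beta_tsv", "write_beta_tsv",
    "read_sample_sheet", "write_sample_sheet",
    "read_annotation", "write_annotation",
    "read_signatures", "write_signatures",
    "read_gene_list", "read_ortholog_map",
    "read_reference_profiles", "write_reference_profiles",
    "read_contrasts", "write_results",
    "write_provenance", "file_digest",
    "QCReport", "qc_filter",
]


def read_beta_tsv(path: str | Path) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    arr = df.apply(pd.to_numeric, errors="coerce")
    non_numeric = arr.isna() & df.notna() & (df.astype(str) != "")
    if non_numeric.to_numpy().any():
        pi, si = np.argwhere(non_numeric.to_numpy())[0]
        raise ValueError(
            f"non-numeric beta at probe {df.index[pi]!r}, sample {df.columns[si]!r}: "
            f"{df.iat[pi, si]!r}"
        )
    return BetaMatrix(arr.astype(float))


def write_beta_tsv(betas: BetaMatrix, path: str | Path) -> None:
    betas.values.rename_axis("probe_id").to_csv(path, sep="\t", lineterminator="\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    if "sample_id" not in sheet.columns:
        raise ValueError("sample sheet must have a sample_id column")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in sample sheet")
    return sheet.set_index("sample_id")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.rename_axis("sample_id").to_csv(path, lineterminator="\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Probe annotation CSV: probe_id, chrom, pos, gene, tss_distance.

    Positions are 1-based inclusive (array-manifest convention).  An
    ``autosomal`` column is derived from the chromosome label when absent.
    """
    annot = pd.read_csv(path)
    required = {"probe_id", "chrom", "pos", "gene", "tss_distance"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    annot = annot.set_index("probe_id")
    if annot.index.has_duplicates:
        raise ValueError("duplicate probe_id in annotation")
    if "autosomal" not in annot.columns:
        label = annot["chrom"].astype(str).str.replace("chr", "", regex=False).str.upper()
        annot["autosomal"] = ~label.isin(["X", "Y", "MT", "M"])
    return annot


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.rename_axis("probe_id").to_csv(path, lineterminator="\n")


def read_signatures(path: str | Path) -> SignatureSet:
    df = pd.read_csv(path, sep="\t")
    sigs: dict[str, Signature] = {}
    meta_cols = {"function", "specificity", "pro_sign"}
    for name, grp in df.groupby("signature", sort=False):
        fn = grp["function"].iloc[0] if "function" in df.columns else "AGE"
        spec = grp["specificity"].iloc[0] if "specificity" in df.columns else "gen"
        pro_sign = grp["pro_sign"].iloc[0] if "pro_sign" in df.columns else "n/a"
        grp = grp.dropna(subset=["probe_id"])
        sigs[name] = Signature(
            name=name, function=fn, specificity=spec, pro_sign=pro_sign,
            probes=tuple(grp["probe_id"]),
            weights=tuple(int(w) for w in grp["weight"]),
        )
    return SignatureSet(sigs)


def write_signatures(signatures: SignatureSet, path: str | Path,
                     provenance_path: str | Path | None = None) -> None:
    rows = []
    for sig in signatures:
        for p, w in zip(sig.probes, sig.weights):
            rows.append({"signature": sig.name, "probe_id": p, "weight": w,
                         "function": sig.function, "specificity": sig.specificity,
                         "pro_sign": sig.pro_sign})
        if len(sig.probes) == 0:
            rows.append({"signature": sig.name, "probe_id": np.nan, "weight": 0,
                         "function": sig.function, "specificity": sig.specificity,
                         "pro_sign": sig.pro_sign})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
    if provenance_path is not None:
        Path(provenance_path).write_text(
            json.dumps(signatures.provenance, indent=2, sort_keys=True, default=str))


def read_gene_list(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"human_symbol", "mouse_symbol"} - set(df.columns)
    if missing:
        raise ValueError(f"ortholog map missing columns: {sorted(missing)}")
    return df


def read_reference_profiles(path: str | Path) -> ReferenceProfiles:
    df = pd.read_csv(path).set_index("probe_id")
    return ReferenceProfiles(df)


def write_reference_profiles(ref: ReferenceProfiles, path: str | Path) -> None:
    ref.profiles.rename_axis("probe_id").to_csv(path, lineterminator="\n")


def read_contrasts(path: str | Path) -> list[ComparisonSpec]:
    """Contrast definitions from YAML: a list of mappings with keys
    contrast_id, reference, comparison (pandas query strings), covariates,
    paired, pair_column, dataset."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("contrast YAML must be a list of contrast mappings")
    specs = []
    for item in raw:
        specs.append(ComparisonSpec(
            contrast_id=str(item["contrast_id"]),
            reference_query=item["reference"],
            comparison_query=item["comparison"],
            covariates=tuple(item.get("covariates", []) or []),
            paired=bool(item.get("paired", False)),
            pair_column=item.get("pair_column", "individual"),
            dataset_id=item.get("dataset"),
        ))
    return specs


def write_results(results: pd.DataFrame, tsv_path: str | Path,
                  json_path: str | Path | None = None) -> None:
    results.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    if json_path is not None:
        Path(json_path).write_text(results.to_json(orient="records", indent=2))


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(path: str | Path, *, command: str, inputs: dict[str, str],
                     config: dict, seed: int | None = None) -> None:
    """Record what produced an output directory: command, config, seed and
    sha256 digests of every input file."""
    from . import __version__
    payload = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_digests": {k: file_digest(v) for k, v in inputs.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# array-level QC


@dataclass
class QCReport:
    """Removals produced by :func:`qc_filter`, with machine-readable reasons."""

    removed_samples: dict[str, str] = field(default_factory=dict)
    removed_probes: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    n_failed_entries: int = 0

    @property
    def clean(self) -> bool:
        return not self.removed_samples and not self.removed_probes


def qc_filter(
    detection_p: pd.DataFrame,
    intensity_summary: pd.DataFrame,
    detection_p_max: float = 0.01,
    sample_fail_max: float = 0.10,
    probe_fail_max: float = 0.10,
    min_median_intensity: float = 9.5,
) -> tuple[QCReport, pd.DataFrame]:
    """Array QC: drop low-intensity / high-failure samples, then failed probes.

    A probe×sample entry fails when its detection p-value exceeds
    ``detection_p_max``.  Samples are removed first — if either median
    (log2) methylated or unmethylated intensity is below
    ``min_median_intensity``, or if more than ``sample_fail_max`` of their
    probes failed (fractions computed before any probe removal).  Probes
    failing in more than ``probe_fail_max`` of the retained samples are
    then removed.  Returns the report and a boolean retained-mask aligned
    to the input (True = keep).
    """
    required = {"median_methylated", "median_unmethylated"}
    missing = required - set(intensity_summary.columns)
    if missing:
        raise ValueError(f"intensity summary missing columns: {sorted(missing)}")
    if not detection_p.columns.equals(intensity_summary.index):
        if set(detection_p.columns) != set(intensity_summary.index):
            raise ValueError("detection-p samples and intensity summary misaligned")
        intensity_summary = intensity_summary.loc[detection_p.columns]

    failed = detection_p > detection_p_max
    report = QCReport(thresholds={
        "detection_p_max": detection_p_max,
        "sample_fail_max": sample_fail_max,
        "probe_fail_max": probe_fail_max,
        "min_median_intensity": min_median_intensity,
    }, n_failed_entries=int(failed.to_numpy().sum()))

    low_intensity = (
        (intensity_summary["median_methylated"] < min_median_intensity)
        | (intensity_summary["median_unmethylated"] < min_median_intensity)
    )
    sample_fail_frac = failed.mean(axis=0)
    for s in detection_p.columns:
        if low_intensity.loc[s]:
            report.removed_samples[s] = "median_intensity_below_threshold"
        elif sample_fail_frac.loc[s] > sample_fail_max:
            report.removed_samples[s] = "failed_probe_fraction_above_threshold"

    kept_samples = [s for s in detection_p.columns if s not in report.removed_samples]
    if kept_samples:
        probe_fail_frac = failed[kept_samples].mean(axis=1)
        report.removed_probes = list(detection_p.index[probe_fail_frac > probe_fail_max])
    else:
        report.removed_probes = []

    mask = pd.DataFrame(True, index=detection_p.index, columns=detection_p.columns)
    mask.loc[:, list(report.removed_samples)] = False
    mask.loc[report.removed_probes, :] = False
    return report, mask
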