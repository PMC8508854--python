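"""Readers and writers for the package's plain-text interchange formats.

Matrices (beta, detection p, M) travel as TSV with a leading ``probe_id``
column and one column per sample; the manifest as TSV with columns
probe_id, chrom, pos, gene, design_type, snp_flag; the sample sheet as
CSV with booleans serialized as true/false.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix", "write_matrix",
    "read_manifest", "write_manifest",
    "read_sample_sheet", "write_sample_sheet",
    "write_json", "read_json",
]


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id",
                     dtype={"chrom": str, "gene": str, "design_type": str})
    df["gene"] = df["gene"].fillna("")
    df["snp_flag"] = df["snp_flag"].astype(bool)
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    out = manifest.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    if "on_treatment" in df.columns and df["on_treatment"].dtype == object:
        df["on_treatment"] = df["on_treatment"].map(
            {"true": True, "false": False, True: True, False: False})
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    out = sheet.copy()
    out.index.name = "sample_id"
    if "on_treatment" in out.columns:
        out["on_treatment"] = out["on_treatment"].map(
            {True: "true", False: "false"})
    out.to_csv(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
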