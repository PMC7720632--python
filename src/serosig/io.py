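"""Readers, writers, validation and the run manifest.

All artifacts are plain text: TSV for the spot table and expression
matrices, CSV for clinical data and reports, JSON for panels, weights,
statistics and the manifest. Tabular outputs carry a single comment
header line with the package version, a hash of the configuration and
the seed; readers skip comment lines.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .preprocess import SPOT_COLUMNS, ExpressionMatrix

TP53_VOCABULARY = {"wild-type", "deleted", "mutated", "missing"}

CLINICAL_REQUIRED = ["patient_id", "os_months", "os_event", "pfs_months", "pfs_event"]


class SchemaError(ValueError):
    """Input table violates the documented schema."""


def _version() -> str:
    from . import __version__

    return __version__


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_comment(cfg: Optional[dict] = None, seed: Optional[int] = None) -> str:
    parts = [f"serosig v{_version()}"]
    if cfg is not None:
        parts.append(f"config={config_hash(cfg)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts)


def _write_table(df: pd.DataFrame, path, sep: str, comment: Optional[str],
                 index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(comment.rstrip("\n") + "\n")
        df.to_csv(fh, sep=sep, index=index, lineterminator="\n")


def write_spot_table(spots: pd.DataFrame, path, comment: Optional[str] = None) -> None:
    _write_table(spots[SPOT_COLUMNS], path, "\t", comment)


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spot table missing column(s): {missing}")
    bad_rep = ~df["replicate"].isin([1, 2, 3])
    if bad_rep.any():
        row = int(np.where(bad_rep)[0][0])
        raise SchemaError(
            f"replicate index {df['replicate'].iloc[row]} at row {row} "
            "(analytes are printed in three replicates; expected 1-3)"
        )
    for col in ("fg", "bg"):
        v = pd.to_numeric(df[col], errors="coerce")
        if v.isna().any() or (v < 0).any():
            raise SchemaError(f"column {col!r} must be non-negative numeric")
    dup = df.duplicated(["sample_id", "analyte_id", "replicate"])
    if dup.any():
        first = df.loc[dup, ["sample_id", "analyte_id", "replicate"]].iloc[0]
        raise SchemaError(
            f"duplicate spot key (sample={first['sample_id']}, "
            f"analyte={first['analyte_id']}, replicate={first['replicate']})"
        )
    return df


def write_clinical(clinical: pd.DataFrame, path, comment: Optional[str] = None) -> None:
    _write_table(clinical, path, ",", comment)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing column(s): {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise SchemaError(f"duplicate patient_id {dup!r}")
    for col in ("os_event", "pfs_event"):
        if not df[col].isin([0, 1]).all():
            raise SchemaError(f"column {col!r} must be binary 0/1")
    if (df["pfs_months"] > df["os_months"] + 1e-9).any():
        pid = df.loc[df["pfs_months"] > df["os_months"] + 1e-9, "patient_id"].iloc[0]
        raise SchemaError(f"pfs_months exceeds os_months for patient {pid!r}")
    if "tp53_status" in df.columns:
        vals = set(df["tp53_status"].dropna().unique())
        bad = vals - TP53_VOCABULARY
        if bad:
            raise SchemaError(
                f"tp53_status value(s) {sorted(bad)} outside the vocabulary "
                f"{sorted(TP53_VOCABULARY)}"
            )
    return df


def write_annotation(annotation: pd.DataFrame, path, comment: Optional[str] = None) -> None:
    _write_table(annotation, path, ",", comment)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("analyte_id", "clone_id", "protein_id"):
        if col not in df.columns:
            raise SchemaError(f"annotation missing column {col!r}")
    if df["analyte_id"].duplicated().any():
        raise SchemaError("duplicate analyte_id in annotation")
    return df


def write_expression(matrix: ExpressionMatrix, values_path, samples_path=None,
                     comment: Optional[str] = None) -> None:
    _write_table(matrix.values, values_path, "\t", comment, index=True)
    if samples_path is not None:
        _write_table(matrix.obs.reset_index(names="sample_id"), samples_path,
                     "\t", comment)


def read_expression(values_path, samples_path, annotation: pd.DataFrame) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", comment="#", index_col=0)
    obs = pd.read_csv(samples_path, sep="\t", comment="#").set_index("sample_id")
    obs = obs.loc[values.index]
    var = annotation.set_index("analyte_id").loc[values.columns]
    return ExpressionMatrix(values=values, obs=obs, var=var)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (frozenset, set)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    config_snapshot: dict,
    seed: int,
    inputs: Dict[str, str],
    outputs: Dict[str, str],
) -> dict:
    """Deterministic run manifest: config snapshot, version, seed and
    per-artifact checksums. Wall-clock timestamps are deliberately kept
    out (they go to the run log) so identical runs produce byte-identical
    manifests."""
    return {
        "version": _version(),
        "seed": int(seed),
        "config": config_snapshot,
        "config_hash": config_hash(config_snapshot),
        "inputs": {k: sha256_file(v) for k, v in sorted(inputs.items())},
        "outputs": {k: sha256_file(v) for k, v in sorted(outputs.items())},
    }
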