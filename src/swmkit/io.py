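"""TSV interchange with schema validation.

Every stage reads and writes tab-separated tables with a one-line header so
intermediate results stay diff-able and language-neutral.  Readers validate
the expected columns and report the offending column and file on mismatch.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

__all__ = ["SchemaError", "SCHEMAS", "read_table", "write_table", "file_sha256"]


class SchemaError(ValueError):
    """An input table does not match its expected schema."""


SCHEMAS: dict[str, list[str]] = {
    "trials": [
        "study_id", "participant_id", "trial",
        "target_angle_deg", "target_amp_dva",
        "response_angle_deg", "response_amp_dva",
    ],
    "truth": ["study_id", "participant_id", "sigma", "w", "amp_bias"],
    "activity": ["participant_id", "study_id", "network", "phase", "activity"],
    "summaries": [
        "study_id", "participant_id", "pure_angular_error",
        "angular_bias_rmsd", "amplitude_bias", "excluded",
        "z_pure_angular_error", "z_angular_bias",
    ],
    "timeseries": ["participant_id", "network", "frame", "value"],
    "events": [
        "trial", "encoding_onset", "encoding_duration",
        "delay_onset", "delay_duration",
        "response_onset", "response_duration", "outlier",
    ],
}


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if schema is not None:
        for col in SCHEMAS[schema]:
            if col not in df.columns:
                raise SchemaError(
                    f"missing column '{col}' in {schema} table ({path})"
                )
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                columns: list[str] | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df[columns] if columns is not None else df
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
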