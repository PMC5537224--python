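"""Reading, writing and validating the pipeline's delimited-text tables.

CSV dialect: comma-separated, UTF-8, header row required, '.' decimal,
missing values as empty fields.

Survival table columns: animal_id, diet, time_days, event, cause,
tumor_count (event: 1 = death, 0 = censored; cause/tumor_count empty for
censored records). Phenotype table columns: animal_id, trait_id, age,
diet, cage, value. Longitudinal table columns: diet, cage, mouse_id,
week, weight_g.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_survival_csv",
    "read_phenotype_csv",
    "read_longitudinal_csv",
    "validate_inputs",
]

SURVIVAL_COLUMNS = ["animal_id", "diet", "time_days", "event"]
PHENOTYPE_COLUMNS = ["animal_id", "trait_id", "age", "diet", "value"]
LONGITUDINAL_COLUMNS = ["diet", "cage", "week", "weight_g"]

DIET_LEVELS = {"AL", "EOD"}
AGE_LEVELS = {"young", "old"}


def read_survival_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "cause" not in df.columns:
        df["cause"] = None
    if "tumor_count" not in df.columns:
        df["tumor_count"] = None
    return df


def read_phenotype_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_longitudinal_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LONGITUDINAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _check_levels(df, column, allowed, path, issues):
    bad = set(df[column].dropna().astype(str)) - allowed
    for level in sorted(bad):
        rows = df.index[df[column].astype(str) == level].tolist()
        issues.append(
            {
                "file": str(path),
                "row": int(rows[0]) + 2,  # 1-based, after the header
                "issue": f"unknown factor level {level!r} in column {column!r}",
            }
        )


def validate_inputs(
    survival: str | Path | None = None,
    phenotypes: str | Path | None = None,
    longitudinal: str | Path | None = None,
) -> list[dict]:
    """Check input tables; returns a machine-readable list of issues.

    Each issue is ``{"file", "row", "issue"}`` (row 0 for file-level
    problems). An empty list means the inputs are well formed.
    """
    issues: list[dict] = []

    def file_issue(path, msg):
        issues.append({"file": str(path), "row": 0, "issue": msg})

    if survival is not None:
        try:
            df = read_survival_csv(survival)
        except Exception as exc:  # noqa: BLE001
            file_issue(survival, str(exc))
        else:
            _check_levels(df, "diet", DIET_LEVELS, survival, issues)
            for idx in df.index[pd.to_numeric(df["time_days"], errors="coerce") <= 0]:
                issues.append(
                    {
                        "file": str(survival),
                        "row": int(idx) + 2,
                        "issue": "nonpositive time",
                    }
                )
            bad_event = ~df["event"].isin([0, 1])
            for idx in df.index[bad_event]:
                issues.append(
                    {
                        "file": str(survival),
                        "row": int(idx) + 2,
                        "issue": f"event flag must be 0 or 1, got {df.loc[idx, 'event']!r}",
                    }
                )
    if phenotypes is not None:
        try:
            df = read_phenotype_csv(phenotypes)
        except Exception as exc:  # noqa: BLE001
            file_issue(phenotypes, str(exc))
        else:
            _check_levels(df, "diet", DIET_LEVELS, phenotypes, issues)
            _check_levels(df, "age", AGE_LEVELS, phenotypes, issues)
    if longitudinal is not None:
        try:
            df = read_longitudinal_csv(longitudinal)
        except Exception as exc:  # noqa: BLE001
            file_issue(longitudinal, str(exc))
        else:
            _check_levels(df, "diet", DIET_LEVELS, longitudinal, issues)
    return issues
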