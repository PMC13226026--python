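"""Schema-validated CSV round-tripping for every pipeline table.

All tables are plain tidy CSVs written with pandas; reading validates the
header against the declared schema and parses numerics with C-locale semantics
(including exponent notation), so files round-trip byte-identically for a
fixed seed and are portable across locales.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

COHORT_SCHEMA = ["dam_id", "group", "gd", "marker", "kind", "value"]
ENDPOINT_SCHEMA = ["dam_id", "group", "rescue_z", "fetal_weight", "placental_weight",
                   "hif1a", "cd31"]
METRICS_SCHEMA = ["dam_id", "group", "marker", "beta_raw", "beta_adjusted",
                  "n_points", "rss", "fri_percent"]
STATS_SCHEMA = ["marker", "effect", "statistic", "df", "p", "adjustment"]
SUMMARY_SCHEMA = ["marker", "slope_disease", "slope_disease_sem", "slope_treated",
                  "slope_treated_sem", "slope_p", "fri_mean", "fri_sem", "response_pattern"]

_NUMERIC = {
    tuple(COHORT_SCHEMA): ["gd", "value"],
    tuple(ENDPOINT_SCHEMA): ["rescue_z", "fetal_weight", "placental_weight", "hif1a", "cd31"],
    tuple(METRICS_SCHEMA): ["beta_raw", "beta_adjusted", "n_points", "rss", "fri_percent"],
    tuple(STATS_SCHEMA): ["statistic", "p"],
    tuple(SUMMARY_SCHEMA): ["slope_disease", "slope_disease_sem", "slope_treated",
                            "slope_treated_sem", "slope_p", "fri_mean", "fri_sem"],
}


def write_table(df: pd.DataFrame, path, schema: list[str]) -> None:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {path}: missing columns {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[schema].to_csv(path, index=False, lineterminator="\n")


def read_table(path, schema: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != schema:
        raise SchemaError(
            f"{path}: header {list(df.columns)} does not match schema {schema}"
        )
    for col in _NUMERIC.get(tuple(schema), []):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().sum() > df[col].isna().sum():
            raise SchemaError(f"{path}: non-numeric entries in column {col!r}")
        df[col] = parsed
    return df


def write_cohort(truths: pd.DataFrame, path, measured: pd.DataFrame | None = None) -> None:
    """Tidy long cohort table; ground truths and measured values share one file,
    distinguished by the ``kind`` column."""
    frames = [truths.assign(kind="truth")]
    if measured is not None:
        frames.append(measured.assign(kind="measured"))
    combined = pd.concat(frames, ignore_index=True)
    write_table(combined, path, COHORT_SCHEMA)


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    df = read_table(path, COHORT_SCHEMA)
    truths = df[df["kind"] == "truth"].drop(columns="kind").reset_index(drop=True)
    measured = df[df["kind"] == "measured"].drop(columns="kind").reset_index(drop=True)
    return truths, (measured if len(measured) else None)
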