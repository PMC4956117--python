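"""Survey ingestion: read child records, validate, and recode covariates.

The canonical interchange is a plain CSV with one row per child (column
dictionary in the README).  SPSS SAV files — the format DHS child recode
files ship in — are supported through an optional ``pyreadstat`` dependency
and an editable column-map profile, because DHS variable codes vary by
release.

Validation flags structurally invalid rows (bad illness flags, bad region,
age out of range) with per-row reasons; complete-case filtering for *model*
covariates happens downstream, at design-build time, never silently here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .outcomes import encode_outcomes

__all__ = [
    "CANONICAL_COLUMNS",
    "RecodeOptions",
    "ValidationReport",
    "read_survey",
    "recode_covariates",
    "default_edhs_column_map",
]

#: Canonical column dictionary of the CSV interchange format.
CANONICAL_COLUMNS = [
    "child_id",
    "diarrhoea",
    "fever",
    "cough",
    "child_age_months",
    "sex",
    "maternal_age_first_birth_years",
    "bmi",
    "residence",
    "household_size",
    "antenatal_visits",
    "place_of_delivery",
    "working_status",
    "wealth_quintile",
    "mother_education",
    "region_id",
]

_MANDATORY = ["diarrhoea", "fever", "cough", "region_id"]


@dataclass
class ValidationReport:
    """Outcome of structural validation during ingestion."""

    rows_read: int = 0
    rows_flagged: int = 0
    exclusions: list[dict] = field(default_factory=list)

    @property
    def rows_valid(self) -> int:
        return self.rows_read - self.rows_flagged

    def flag(self, row_id, reason: str) -> None:
        self.rows_flagged += 1
        self.exclusions.append({"row_id": row_id, "reason": reason})

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rows_read": self.rows_read,
                    "rows_flagged": self.rows_flagged,
                    "rows_valid": self.rows_valid,
                    "exclusions": self.exclusions,
                },
                indent=2,
            )
        )


def default_edhs_column_map() -> dict:
    """The bundled EDHS-2008 column-map profile (editable YAML)."""
    text = resources.files("morbmap.data").joinpath("edhs_column_map.yaml").read_text()
    return yaml.safe_load(text)


def _read_sav(path, column_map: dict) -> pd.DataFrame:
    try:
        import pyreadstat
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading SPSS .sav files requires the optional 'pyreadstat' "
            "dependency (pip install morbmap[sav]); convert to CSV otherwise"
        ) from err
    df, _ = pyreadstat.read_sav(str(path))
    divide_bmi = float(column_map.pop("divide_bmi_by", 1) or 1)
    rename = {src: dst for dst, src in column_map.items() if src in df.columns}
    missing = [dst for dst, src in column_map.items() if src not in df.columns]
    if any(column_map.get(m) for m in missing if m in _MANDATORY):
        raise ValueError(f"unmapped mandatory column(s): {missing}")
    out = df.rename(columns=rename)[list(rename.values())].copy()

    # DHS code conventions -> canonical values (documented best effort;
    # verify against the release's recode manual before trusting).
    def yesno(col):
        return col.map(lambda v: 1 if v in (1, 2) else (0 if v == 0 else np.nan))

    for c in ("diarrhoea", "fever", "cough"):
        if c in out:
            out[c] = yesno(out[c])
    if "sex" in out:
        out["sex"] = out["sex"].map({1: "male", 2: "female"})
    if "residence" in out:
        out["residence"] = out["residence"].map({1: "urban", 2: "rural"})
    if "antenatal_visits" in out:
        out["antenatal_visits"] = out["antenatal_visits"].map(
            lambda v: np.nan if v in (98, 99) or pd.isna(v) else ("none" if v == 0 else "some")
        )
    if "place_of_delivery" in out:
        out["place_of_delivery"] = out["place_of_delivery"].map(
            lambda v: np.nan
            if pd.isna(v) or v >= 90
            else ("home_or_other" if v < 20 else "public_or_private_hospital")
        )
    if "working_status" in out:
        out["working_status"] = out["working_status"].map({0: "not_working", 1: "working"})
    if "wealth_quintile" in out:
        out["wealth_quintile"] = out["wealth_quintile"].map(
            {1: "poorest", 2: "poorer", 3: "middle", 4: "richer", 5: "richest"}
        )
    if "mother_education" in out:
        out["mother_education"] = out["mother_education"].map(
            lambda v: np.nan
            if pd.isna(v)
            else ("none_or_primary" if v <= 1 else "secondary_or_higher")
        )
    if "bmi" in out and divide_bmi != 1:
        out["bmi"] = pd.to_numeric(out["bmi"], errors="coerce") / divide_bmi
    return out


def read_survey(
    path,
    dialect: str = "csv",
    column_map: dict | None = None,
    graph=None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and structurally validate a child-level survey file.

    Returns the valid records (flagged rows removed) and a
    :class:`ValidationReport` listing every exclusion with its reason.
    ``graph``, when given, checks ``region_id`` membership.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        if path.stat().st_size == 0:
            raise ValueError(f"empty survey file: {path}")
        df = pd.read_csv(path)
        if column_map:
            df = df.rename(columns={src: dst for dst, src in column_map.items()})
    elif dialect == "sav":
        df = _read_sav(path, dict(column_map or default_edhs_column_map()))
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'csv' or 'sav')")
    if df.empty:
        raise ValueError(f"no records in survey file: {path}")

    missing_cols = [c for c in _MANDATORY if c not in df.columns]
    if missing_cols:
        raise ValueError(f"unmapped mandatory column(s): {missing_cols}")
    if "child_id" not in df.columns:
        df.insert(0, "child_id", [f"row{i}" for i in range(len(df))])

    report = ValidationReport(rows_read=len(df))
    bad = pd.Series(False, index=df.index)
    for c in ("diarrhoea", "fever", "cough"):
        invalid = ~df[c].isin([0, 1]) | df[c].isna()
        for idx in df.index[invalid & ~bad]:
            report.flag(df.at[idx, "child_id"], f"missing or non-binary illness flag '{c}'")
        bad |= invalid
    if "child_age_months" in df.columns:
        age = pd.to_numeric(df["child_age_months"], errors="coerce")
        invalid = age.notna() & ~age.between(0, 60)
        for idx in df.index[invalid & ~bad]:
            report.flag(df.at[idx, "child_id"], "child_age_months outside [0, 60]")
        bad |= invalid
    if graph is not None:
        invalid = ~df["region_id"].isin(graph.region_ids)
        for idx in df.index[invalid & ~bad]:
            report.flag(df.at[idx, "child_id"], f"region_id {df.at[idx, 'region_id']} not in graph")
        bad |= invalid

    valid = df.loc[~bad].reset_index(drop=True)
    if not valid.empty:
        valid = valid.copy()
        for c in ("diarrhoea", "fever", "cough"):
            valid[c] = valid[c].astype(int)
        valid["category"] = encode_outcomes(valid["diarrhoea"], valid["fever"], valid["cough"])
    return valid, report


@dataclass(frozen=True)
class RecodeOptions:
    """Binning choices for the analysis view; all recorded in the manifest.

    ``bmi_threshold`` defaults to the WHO underweight cut-point 18.5; 18.0
    is the documented alternative reading of the source's "BMI over 18".
    """

    child_age_bins: tuple[float, float] = (20.0, 40.0)
    maternal_age_threshold: float = 20.0
    bmi_threshold: float = 18.5
    collapse_wealth: bool = False

    def manifest(self) -> dict:
        return {
            "child_age_bins": "[0,20) / [20,40) / [40,60]",
            "maternal_age_threshold": f"<= {self.maternal_age_threshold} vs > (closed left)",
            "bmi_threshold": self.bmi_threshold,
            "collapse_wealth": self.collapse_wealth,
        }


def recode_covariates(
    records: pd.DataFrame, options: RecodeOptions = RecodeOptions()
) -> pd.DataFrame:
    """Recode metrical covariates into the categorical analysis view.

    Child age is binned into <20 / 20–40 / >40 months with half-open,
    left-closed intervals; maternal age at first birth splits at 20 years
    (<=20 closed on the left); BMI splits at ``options.bmi_threshold``.
    Idempotent: re-applying to an already-coded table recomputes the same
    values.  Out-of-domain values raise with the offending row ids.
    """
    out = records.copy()
    lo, hi = options.child_age_bins
    if "child_age_months" in out.columns:
        age = pd.to_numeric(out["child_age_months"], errors="coerce")
        bad = age.notna() & ~age.between(0, 60)
        if bad.any():
            raise ValueError(
                f"child_age_months outside [0,60] for rows {list(out.index[bad])}"
            )
        out["child_age_group"] = pd.cut(
            age,
            bins=[0, lo, hi, 60],
            right=False,
            include_lowest=True,
            labels=[f"<{lo:g}", f"{lo:g}-{hi:g}", f">{hi:g}"],
        )
        # pd.cut(right=False) puts 60 out of the last bin; fold it back in.
        out.loc[age == 60, "child_age_group"] = f">{hi:g}"
        out["child_age_group"] = out["child_age_group"].astype(
            pd.CategoricalDtype([f"<{lo:g}", f"{lo:g}-{hi:g}", f">{hi:g}"])
        )
    if "maternal_age_first_birth_years" in out.columns:
        t = options.maternal_age_threshold
        mage = pd.to_numeric(out["maternal_age_first_birth_years"], errors="coerce")
        out["maternal_age_group"] = pd.Categorical(
            np.where(mage.isna(), None, np.where(mage <= t, f"<={t:g}", f">{t:g}")),
            categories=[f"<={t:g}", f">{t:g}"],
        )
    if "bmi" in out.columns:
        t = options.bmi_threshold
        bmi = pd.to_numeric(out["bmi"], errors="coerce")
        if (bmi <= 0).any():
            raise ValueError(f"non-positive BMI for rows {list(out.index[bmi <= 0])}")
        out["bmi_group"] = pd.Categorical(
            np.where(bmi.isna(), None, np.where(bmi > t, f">{t:g}", f"<={t:g}")),
            categories=[f"<={t:g}", f">{t:g}"],
        )
    if options.collapse_wealth and "wealth_quintile" in out.columns:
        out["wealth_group"] = out["wealth_quintile"].map(
            {
                "poorest": "poorest/poorer",
                "poorer": "poorest/poorer",
                "middle": "middle",
                "richer": "richer/richest",
                "richest": "richer/richest",
            }
        )
    return out
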