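"""Descriptive layer: cross-tabulations, chi-squared screens, outcome distribution.

Mirrors the usual first pass over a DHS-style morbidity table: each
socio-demographic factor is cross-tabulated against each binary illness and
screened with a Pearson chi-squared test at the 0.05 level, and the 8-level
comorbidity outcome is tabulated as counts and percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .outcomes import CATEGORY_LABELS

__all__ = [
    "CrossTab",
    "chi_squared_test",
    "cross_tabulate",
    "category_distribution",
    "write_descriptive_tables",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CrossTab:
    factor: str
    row_labels: list[str]
    col_labels: list[str]
    observed: np.ndarray
    chi2: float
    df: int
    p_value: float

    @property
    def row_margins(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def significant(self) -> bool:
        """Association flag at the conventional P < 0.05 screen."""
        return self.p_value < ALPHA

    def to_frame(self, percent_within: str = "row") -> pd.DataFrame:
        """Counts with percentages; orientation ('row'/'col') is explicit
        because conditioning on the factor vs on the illness read differently."""
        obs = pd.DataFrame(self.observed, index=self.row_labels, columns=self.col_labels)
        if percent_within == "row":
            pct = obs.div(obs.sum(axis=1), axis=0) * 100
        elif percent_within == "col":
            pct = obs.div(obs.sum(axis=0), axis=1) * 100
        else:
            raise ValueError("percent_within must be 'row' or 'col'")
        out = obs.astype(int).astype(str) + " (" + pct.round(1).astype(str) + "%)"
        out.index.name = self.factor
        return out


def chi_squared_test(counts) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a contingency table.

    No continuity correction is applied (``correction`` flag on
    :func:`cross_tabulate` switches it on).  Degenerate tables — fewer than
    two rows/columns, or an all-zero margin — raise with the offending
    margin named.  Expected cell counts below 5 trigger a warning, not an
    automatic exact test.
    """
    return _chi_squared(counts, correction=False)


def _chi_squared(counts, correction: bool) -> tuple[float, int, float]:
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(f"contingency table must be at least 2x2, got shape {obs.shape}")
    if (obs < 0).any() or not np.isfinite(obs).all():
        raise ValueError("contingency table must contain non-negative finite counts")
    zero_rows = np.flatnonzero(obs.sum(axis=1) == 0)
    zero_cols = np.flatnonzero(obs.sum(axis=0) == 0)
    if zero_rows.size or zero_cols.size:
        raise ValueError(
            f"degenerate table: zero margin in rows {zero_rows.tolist()} "
            f"and columns {zero_cols.tolist()}"
        )
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=correction)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} cell(s) have expected count < 5; "
            "the chi-squared approximation may be poor",
            stacklevel=3,
        )
    return float(chi2), int(df), float(p)


def cross_tabulate(
    records: pd.DataFrame,
    factor: str,
    illness: str,
    correction: bool = False,
) -> CrossTab:
    """Cross-tabulate one categorical factor against one binary illness."""
    if factor not in records.columns or illness not in records.columns:
        raise ValueError(f"missing column '{factor}' or '{illness}'")
    sub = records[[factor, illness]].dropna()
    table = pd.crosstab(sub[factor], sub[illness])
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    chi2, df, p = _chi_squared(table.to_numpy(), correction=correction)
    return CrossTab(
        factor=factor,
        row_labels=[str(x) for x in table.index],
        col_labels=[str(x) for x in table.columns],
        observed=table.to_numpy(),
        chi2=chi2,
        df=df,
        p_value=p,
    )


def category_distribution(categories) -> pd.DataFrame:
    """Count and percentage per comorbidity category (0..7).

    Percentages sum to 100 exactly up to float rounding; the ``percent``
    column is full precision, ``percent_2dp`` is the formatted view.
    """
    ks = np.asarray(categories)
    if ks.size == 0:
        raise ValueError("empty outcome list")
    if not np.isin(ks, list(CATEGORY_LABELS)).all():
        raise ValueError("categories must lie in 0..7")
    counts = np.bincount(ks, minlength=8)
    pct = counts / counts.sum() * 100
    return pd.DataFrame(
        {
            "category": list(CATEGORY_LABELS),
            "label": [CATEGORY_LABELS[k] for k in CATEGORY_LABELS],
            "count": counts,
            "percent": pct,
            "percent_2dp": np.round(pct, 2),
        }
    )


def write_descriptive_tables(
    records: pd.DataFrame,
    factors: list[str],
    out_dir,
    illnesses: tuple[str, ...] = ("diarrhoea", "fever", "cough"),
    percent_within: str = "row",
) -> dict[str, Path]:
    """Emit the descriptive CSVs: factor x illness screen + outcome distribution."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for factor in factors:
        for illness in illnesses:
            ct = cross_tabulate(records, factor, illness)
            for i, lev in enumerate(ct.row_labels):
                rows.append(
                    {
                        "factor": factor,
                        "level": lev,
                        "illness": illness,
                        "n_ill": int(ct.observed[i, ct.col_labels.index("1")])
                        if "1" in ct.col_labels
                        else 0,
                        "n_total": int(ct.row_margins[i]),
                        "chi2": ct.chi2,
                        "df": ct.df,
                        "p_value": ct.p_value,
                        "significant_p_lt_0.05": ct.significant,
                        "percent_within": percent_within,
                    }
                )
    screen_path = out_dir / "factor_illness_screen.csv"
    pd.DataFrame(rows).to_csv(screen_path, index=False)
    dist_path = out_dir / "category_distribution.csv"
    category_distribution(records["category"].to_numpy()).to_csv(dist_path, index=False)
    return {"screen": screen_path, "distribution": dist_path}
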