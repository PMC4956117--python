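"""Posterior result surfaces: odds-ratio tables and region-effect tables.

The "posterior OR" convention here is exp(posterior mean of the
coefficient), with the 95% interval as exp of the 2.5%/97.5% empirical
coefficient quantiles (equal-tailed, linear-interpolation quantiles) —
i.e. summarise on the log-odds scale, then transform.  Summarising the
exp-transformed draws instead is available behind ``transform_draws=True``
and is recorded whenever used.  "Significant" means the OR interval
excludes 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples
from .outcomes import CATEGORY_LABELS

__all__ = ["ORSummary", "summarize_or", "or_table", "spatial_effect_table", "write_results"]


@dataclass(frozen=True)
class ORSummary:
    """Posterior odds ratio for one covariate contrast in one category."""

    category: int
    contrast: str
    posterior_mean_coef: float
    or_: float
    ci_low: float
    ci_high: float
    significant: bool
    transform_draws: bool = False


def summarize_or(
    chain,
    contrast: str = "",
    category: int = 1,
    level: float = 0.95,
    transform_draws: bool = False,
) -> ORSummary:
    """Summarise one coefficient chain into a posterior odds ratio.

    Chains shorter than 100 draws are summarised anyway but trigger a
    warning — interval endpoints are then dominated by Monte-Carlo noise.
    """
    x = np.asarray(chain, dtype=float)
    if x.size == 0:
        raise ValueError("empty chain")
    if x.size < 100:
        warnings.warn(f"chain for '{contrast}' has only {x.size} draws", stacklevel=2)
    alpha = (1.0 - level) / 2.0
    if transform_draws:
        draws = np.exp(x)
        or_ = float(draws.mean())
        lo, hi = (float(q) for q in np.quantile(draws, [alpha, 1 - alpha]))
    else:
        or_ = float(np.exp(x.mean()))
        qlo, qhi = np.quantile(x, [alpha, 1 - alpha])
        lo, hi = float(np.exp(qlo)), float(np.exp(qhi))
    return ORSummary(
        category=category,
        contrast=contrast,
        posterior_mean_coef=float(x.mean()),
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        significant=not (lo <= 1.0 <= hi),
        transform_draws=transform_draws,
    )


def or_table(
    samples: PosteriorSamples,
    category: int,
    include_intercept: bool = False,
    transform_draws: bool = False,
) -> pd.DataFrame:
    """Posterior OR table for one comorbidity category (vs no illness)."""
    if category not in samples.categories:
        raise KeyError(f"unknown category {category}")
    beta = samples.categories[category]["beta"]
    rows = []
    for j, name in enumerate(samples.columns):
        if name == "intercept" and not include_intercept:
            continue
        s = summarize_or(beta[:, j], contrast=name, category=category,
                         transform_draws=transform_draws)
        rows.append(
            {
                "category": category,
                "label": CATEGORY_LABELS[category],
                "contrast": name,
                "posterior_mean_coef": s.posterior_mean_coef,
                "or": s.or_,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "significant": s.significant,
            }
        )
    return pd.DataFrame(rows)


def spatial_effect_table(
    samples: PosteriorSamples,
    category: int,
    name_lookup: pd.DataFrame | None = None,
    component: str = "theta",
) -> pd.DataFrame:
    """Per-region posterior summary of the spatial effect for one category.

    Summarises the structured effect theta by default (``component="total"``
    adds the unstructured phi).  Rows are sorted by region id; the
    ``rank_risk`` column identifies the highest-risk region (rank 1).
    """
    if category not in samples.categories:
        raise KeyError(f"unknown category {category}")
    blocks = samples.categories[category]
    if component == "theta":
        chain = blocks["theta"]
    elif component == "total":
        chain = blocks["theta"] + blocks["phi"]
    else:
        raise ValueError("component must be 'theta' or 'total'")
    mean = chain.mean(axis=0)
    med = np.quantile(chain, 0.5, axis=0)
    lo = np.quantile(chain, 0.025, axis=0)
    hi = np.quantile(chain, 0.975, axis=0)
    df = pd.DataFrame(
        {
            "region_id": list(samples.region_ids),
            "category": category,
            "label": CATEGORY_LABELS[category],
            "posterior_mean": mean,
            "posterior_median": med,
            "or_scale": np.exp(mean),
            "ci_low": lo,
            "ci_high": hi,
            "significant": (lo > 0) | (hi < 0),
        }
    ).sort_values("region_id", ignore_index=True)
    df["rank_risk"] = df["posterior_mean"].rank(ascending=False).astype(int)
    if name_lookup is not None:
        df = df.merge(name_lookup, on="region_id", how="left", validate="1:1")
    return df


def write_results(
    samples: PosteriorSamples,
    out_dir,
    name_lookup: pd.DataFrame | None = None,
    transform_draws: bool = False,
) -> dict:
    """Write one OR CSV and one spatial CSV per category plus a JSON bundle.

    The JSON bundle round-trips to the same summaries (it is their exact
    serialisation) and records which OR convention was used.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {"or": {}, "spatial": {}}
    bundle = {
        "or_convention": "exp of summarised draws" if transform_draws else "summaries of draws, then exp",
        "categories": {},
    }
    for k in sorted(samples.categories):
        ors = or_table(samples, k, transform_draws=transform_draws)
        spat = spatial_effect_table(samples, k, name_lookup=name_lookup)
        p_or = out_dir / f"or_category{k}.csv"
        p_sp = out_dir / f"spatial_category{k}.csv"
        ors.to_csv(p_or, index=False)
        spat.to_csv(p_sp, index=False)
        paths["or"][k] = p_or
        paths["spatial"][k] = p_sp
        bundle["categories"][str(k)] = {
            "label": CATEGORY_LABELS[k],
            "odds_ratios": ors.to_dict(orient="records"),
            "spatial": spat.drop(columns=[c for c in ("macro_region",) if c in spat]).to_dict(
                orient="records"
            ),
        }
    p_json = out_dir / "results.json"
    p_json.write_text(json.dumps(bundle, indent=2, default=float))
    paths["json"] = p_json
    return paths
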