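"""Synthetic DHS-like child morbidity surveys with known ground truth.

The generator is the exact generative mirror of the model fitted downstream:
for child *i* in region *s* the linear predictor of comorbidity category
``k`` (k = 1..7, reference 0) is

    eta_ik = z_i' beta_k + theta_{s,k} + phi_{s,k}

with ``theta`` an intrinsic-CAR (graph Laplacian) draw on the region graph,
``phi`` exchangeable Gaussian heterogeneity, and the category sampled from
the multinomial-logit probabilities.  The three binary illness flags are
then back-filled deterministically from the sampled category, so encoding
round-trips exactly.

Covariates are drawn independently from stated marginals (no covariate
dependence is part of the stated world; a user-supplied joint sampler hook
overrides this).  Identical seeds give byte-identical surveys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignBundle, build_design
from .graphs import AdjacencyGraph, build_icar_precision, egypt_governorates
from .outcomes import decode_outcome

__all__ = [
    "CategoricalCovariate",
    "MetricalCovariate",
    "TruthConfig",
    "SyntheticSurvey",
    "sample_icar",
    "generate_survey",
    "write_survey",
    "two_binary_truth",
    "edhs_like_truth",
]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class CategoricalCovariate:
    """Categorical covariate: levels with marginal probabilities (sum to 1)."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs) or len(self.levels) < 2:
            raise ValueError(f"covariate '{self.name}': levels/probs mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError(
                f"covariate '{self.name}': marginal probabilities sum to "
                f"{sum(self.probs)!r}, not 1"
            )
        if any(p < 0 for p in self.probs):
            raise ValueError(f"covariate '{self.name}': negative probability")


@dataclass(frozen=True)
class MetricalCovariate:
    """Metrical covariate drawn uniformly over ``[low, high]`` by default."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"covariate '{self.name}': need low < high")


@dataclass
class TruthConfig:
    """Ground-truth parameters of a synthetic survey.

    ``betas`` maps each non-reference category (1..7) to its coefficient
    vector in design order: intercept first, then L-1 dummies per
    categorical covariate (reference = first level), then one slope per
    metrical covariate.
    """

    n_children: int
    betas: dict[int, np.ndarray]
    covariates: list
    spatial_var: float = 0.3
    unstructured_var: float = 0.1
    graph: AdjacencyGraph = None
    seed: int = 0
    region_weights: np.ndarray | None = None
    #: optional ``f(rng, n) -> DataFrame`` overriding independent sampling
    joint_sampler: object = None

    def __post_init__(self) -> None:
        if self.n_children <= 0:
            raise ValueError("n_children must be positive")
        if self.spatial_var < 0 or self.unstructured_var < 0:
            raise ValueError("variances must be non-negative")
        if self.graph is None:
            self.graph = egypt_governorates()
        if set(self.betas) != set(range(1, 8)):
            raise ValueError("betas must be given for every category 1..7")
        self.betas = {k: np.asarray(v, dtype=float) for k, v in self.betas.items()}
        lengths = {v.size for v in self.betas.values()}
        if len(lengths) != 1:
            raise ValueError("all beta vectors must have identical length")
        p_expected = 1 + sum(
            len(c.levels) - 1 if isinstance(c, CategoricalCovariate) else 1
            for c in self.covariates
        )
        if lengths.pop() != p_expected:
            raise ValueError(
                f"beta length must match the design: expected {p_expected} "
                "(intercept + dummies + slopes)"
            )

    def to_dict(self) -> dict:
        return {
            "n_children": int(self.n_children),
            "seed": int(self.seed),
            "spatial_var": float(self.spatial_var),
            "unstructured_var": float(self.unstructured_var),
            "betas": {int(k): [float(x) for x in v] for k, v in self.betas.items()},
            "covariates": [
                {"name": c.name, "levels": list(c.levels), "probs": [float(p) for p in c.probs]}
                if isinstance(c, CategoricalCovariate)
                else {"name": c.name, "range": [float(c.low), float(c.high)]}
                for c in self.covariates
            ],
            "graph_edges": [list(e) for e in self.graph.edges],
        }


@dataclass
class SyntheticSurvey:
    """Generated records plus the truth that produced them."""

    records: pd.DataFrame
    truth: TruthConfig
    theta_true: np.ndarray  # (7, n_regions), each row sums to zero
    phi_true: np.ndarray  # (7, n_regions)
    design: DesignBundle


def sample_icar(
    graph: AdjacencyGraph,
    variance: float,
    rng,
    disconnected: str = "error",
) -> np.ndarray:
    """Draw one intrinsic-CAR region-effect vector.

    The ICAR density is an improper Gaussian with precision ``Q/variance``
    (``Q`` the graph Laplacian).  The draw is realised as a proper Gaussian
    on the orthogonal complement of Q's null space — eigen-decompose Q,
    put variance ``variance / lambda_j`` on each eigenvector with
    ``lambda_j > 0`` and zero mass on the null space — then centred to sum
    exactly to zero.  ``variance = 0`` returns the zero vector.

    Disconnected graphs need an explicit policy: ``disconnected="centre_components"``
    centres each connected component separately; the default raises.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if graph is None or graph.n_regions == 0:
        raise ValueError("empty graph")
    if not graph.is_connected and disconnected != "centre_components":
        raise ValueError(
            "graph is disconnected; pass disconnected='centre_components' "
            "to centre each component separately"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = graph.n_regions
    if variance == 0:
        return np.zeros(n)
    Q = build_icar_precision(graph).Q
    lam, vec = np.linalg.eigh(Q)
    keep = lam > _EIG_TOL * lam.max()
    z = rng.standard_normal(keep.sum()) * np.sqrt(variance / lam[keep])
    x = vec[:, keep] @ z
    labels = graph.component_labels()
    for c in np.unique(labels):
        mask = labels == c
        x[mask] -= x[mask].mean()
    return x


def generate_survey(truth: TruthConfig) -> SyntheticSurvey:
    """Sample a survey from the stated ground truth (deterministic per seed)."""
    rng = np.random.default_rng(truth.seed)
    n = truth.n_children
    graph = truth.graph

    if truth.joint_sampler is not None:
        df = truth.joint_sampler(rng, n).copy()
    else:
        cols = {}
        for cov in truth.covariates:
            if isinstance(cov, CategoricalCovariate):
                draw = rng.choice(len(cov.levels), size=n, p=np.asarray(cov.probs))
                cols[cov.name] = pd.Categorical.from_codes(
                    draw, categories=list(cov.levels)
                )
            else:
                cols[cov.name] = rng.uniform(cov.low, cov.high, size=n)
        df = pd.DataFrame(cols)

    if truth.region_weights is not None:
        w = np.asarray(truth.region_weights, dtype=float)
        w = w / w.sum()
        df["region_id"] = rng.choice(graph.region_ids, size=n, p=w)
    else:
        df["region_id"] = rng.choice(graph.region_ids, size=n)

    design = build_design(df, formula=[c.name for c in truth.covariates], graph=graph)
    p = design.p
    B = np.column_stack([truth.betas[k] for k in range(1, 8)])  # (p, 7)
    if B.shape[0] != p:
        raise ValueError(f"beta length {B.shape[0]} does not match design width {p}")

    theta = np.vstack([sample_icar(graph, truth.spatial_var, rng) for _ in range(7)])
    phi = rng.normal(0.0, np.sqrt(truth.unstructured_var), size=(7, graph.n_regions))

    eta = design.Z @ B + theta[:, design.region_index].T + phi[:, design.region_index].T
    # multinomial-logit probabilities with eta_0 = 0
    full = np.concatenate([np.zeros((n, 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    prob = np.exp(full)
    prob /= prob.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cat = (prob.cumsum(axis=1) < u[:, None]).sum(axis=1)

    flags = np.array([decode_outcome(k) for k in range(8)])  # (8, 3)
    df.insert(0, "child_id", [f"synth{i:06d}" for i in range(n)])
    df["diarrhoea"] = flags[cat, 0]
    df["fever"] = flags[cat, 1]
    df["cough"] = flags[cat, 2]
    df["category"] = cat
    return SyntheticSurvey(records=df, truth=truth, theta_true=theta, phi_true=phi, design=design)


def write_survey(survey: SyntheticSurvey, csv_path, truth_path=None) -> None:
    """Write records as interchange CSV and the truth (with theta/phi) as YAML."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    survey.records.to_csv(csv_path, index=False)
    if truth_path is None:
        truth_path = csv_path.with_suffix(".truth.yaml")
    payload = survey.truth.to_dict()
    payload["theta_true"] = [[float(x) for x in row] for row in survey.theta_true]
    payload["phi_true"] = [[float(x) for x in row] for row in survey.phi_true]
    Path(truth_path).write_text(yaml.safe_dump(payload, sort_keys=False))


def two_binary_truth(
    seed: int,
    n_children: int = 4000,
    spatial_var: float = 0.3,
    unstructured_var: float = 0.1,
    graph: AdjacencyGraph | None = None,
    coefficient_range: tuple[float, float] = (-1.0, 1.0),
) -> TruthConfig:
    """Minimal stated world for recovery experiments: two balanced binary
    covariates, per-category coefficients (incl. intercept) drawn uniformly
    in ``coefficient_range``."""
    rng = np.random.default_rng(seed)
    covs = [
        CategoricalCovariate("x1", ("a", "b"), (0.5, 0.5)),
        CategoricalCovariate("x2", ("a", "b"), (0.5, 0.5)),
    ]
    betas = {k: rng.uniform(*coefficient_range, size=3) for k in range(1, 8)}
    return TruthConfig(
        n_children=n_children,
        betas=betas,
        covariates=covs,
        spatial_var=spatial_var,
        unstructured_var=unstructured_var,
        graph=graph or egypt_governorates(),
        seed=seed,
    )


#: Effects used by :func:`edhs_like_truth`: intercepts set so marginal
#: category frequencies resemble a DHS morbidity table (most children
#: healthy, fever+cough the most common combination), plus a handful of
#: covariate effects on the log-odds scale (young age and urban residence
#: raise the all-three-illnesses odds, etc.).
_EDHS_INTERCEPTS = {1: -3.65, 2: -4.57, 3: -4.86, 4: -2.43, 5: -2.82, 6: -3.25, 7: -2.96}


def edhs_like_truth(seed: int, n_children: int = 10872) -> TruthConfig:
    """A stated world emulating the structure of a 2008 Egyptian DHS round:
    10,872 children, the analysis covariates with realistic marginals, and
    spatially autocorrelated governorate effects on the 27-node graph."""
    covs = [
        # reference level first: contrasts are vs children over 40 months
        CategoricalCovariate("child_age_group", (">40", "<20", "20-40"), (0.33, 0.33, 0.34)),
        CategoricalCovariate("sex", ("female", "male"), (0.49, 0.51)),
        CategoricalCovariate("maternal_age_group", ("<=20", ">20"), (0.37, 0.63)),
        CategoricalCovariate("bmi_group", ("<=18.5", ">18.5"), (0.07, 0.93)),
        CategoricalCovariate("residence", ("rural", "urban"), (0.58, 0.42)),
        CategoricalCovariate("antenatal_visits", ("none", "some"), (0.26, 0.74)),
        CategoricalCovariate(
            "place_of_delivery", ("public_or_private_hospital", "home_or_other"), (0.72, 0.28)
        ),
        CategoricalCovariate("working_status", ("not_working", "working"), (0.84, 0.16)),
        CategoricalCovariate(
            "wealth_quintile",
            ("poorest", "poorer", "middle", "richer", "richest"),
            (0.2, 0.2, 0.2, 0.2, 0.2),
        ),
        CategoricalCovariate(
            "mother_education", ("none_or_primary", "secondary_or_higher"), (0.45, 0.55)
        ),
        MetricalCovariate("household_size", 2, 12),
    ]
    p = 1 + sum(len(c.levels) - 1 for c in covs if isinstance(c, CategoricalCovariate)) + 1
    betas = {}
    names = ["intercept"]
    for c in covs:
        if isinstance(c, CategoricalCovariate):
            names += [f"{c.name}[{lev}]" for lev in c.levels[1:]]
        else:
            names.append(c.name)
    for k in range(1, 8):
        b = np.zeros(p)
        b[0] = _EDHS_INTERCEPTS[k]
        betas[k] = b

    def set_effect(k, col, value):
        betas[k][names.index(col)] = value

    # age effects: young children at higher odds of every combination,
    # strongest for the full triple; log-odds from typical OR magnitudes.
    for k in range(1, 8):
        set_effect(k, "child_age_group[<20]", np.log(
            {1: 6.8, 2: 17.14, 3: 4.9, 4: 2.5, 5: 4.9, 6: 2.0, 7: 2.2}[k]
        ))
        set_effect(k, "child_age_group[20-40]", np.log(
            {1: 2.14, 2: 4.0, 3: 2.0, 4: 1.6, 5: 2.2, 6: 1.4, 7: 1.5}[k]
        ))
    set_effect(1, "residence[urban]", np.log(1.8))
    set_effect(1, "sex[male]", np.log(1.2))
    set_effect(3, "sex[male]", np.log(1.6))
    set_effect(6, "maternal_age_group[>20]", np.log(1.2))
    set_effect(7, "maternal_age_group[>20]", np.log(1.2))
    for k in range(1, 8):
        set_effect(k, "wealth_quintile[richest]", -0.4)
        set_effect(k, "mother_education[secondary_or_higher]", -0.2)
        set_effect(k, "household_size", 0.02)
    return TruthConfig(
        n_children=n_children,
        betas=betas,
        covariates=covs,
        spatial_var=0.3,
        unstructured_var=0.1,
        graph=egypt_governorates(),
        seed=seed,
    )
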