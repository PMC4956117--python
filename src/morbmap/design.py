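"""Design matrices for the geo-additive multinomial model.

Builds everything the sampler consumes: the reference-cell fixed-effect
matrix ``Z``, optional centred P-spline bases with their second-difference
penalties, and the per-child region index into the adjacency graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .graphs import AdjacencyGraph

__all__ = ["SplineBasis", "DesignBundle", "build_spline_basis", "build_design"]


@dataclass
class SplineBasis:
    """B-spline basis with a random-walk (difference) penalty.

    ``B`` is the n x m basis matrix on equidistant knots spanning the data
    range; ``K = D2' D2`` penalises second differences of adjacent
    coefficients, so rank(K) = m - 2 (constants and linear trends are
    unpenalised).
    """

    name: str
    knots: np.ndarray
    degree: int
    B: np.ndarray
    K: np.ndarray
    #: column means subtracted from ``B`` for identifiability (0 if uncentred)
    centring: np.ndarray = field(default=None)

    @property
    def m(self) -> int:
        return self.B.shape[1]


def build_spline_basis(
    x,
    n_interior_knots: int = 20,
    degree: int = 3,
    name: str = "smooth",
    centre: bool = False,
) -> SplineBasis:
    """B-spline basis on equidistant knots over ``[min(x), max(x)]``.

    The knot vector repeats the boundary knots ``degree + 1`` times, so on
    the interior the basis functions sum to one (partition of unity) and
    evaluation agrees with the Cox–de Boor recursion.  ``centre=True``
    subtracts column means so the block is orthogonal-ish to the intercept.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.isfinite(x).all():
        raise ValueError("spline covariate must be finite and non-empty")
    lo, hi = float(x.min()), float(x.max())
    if not lo < hi:
        raise ValueError(f"degenerate covariate for smooth '{name}': min == max")
    if np.unique(x).size < degree + 2:
        raise ValueError(
            f"smooth '{name}' needs at least degree+2={degree + 2} distinct values"
        )
    interior = np.linspace(lo, hi, n_interior_knots + 2)[1:-1]
    knots = np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )
    m = len(knots) - degree - 1
    # extrapolate=False yields NaN only outside [lo, hi]; data is inside.
    B = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    D2 = np.diff(np.eye(m), n=2, axis=0)
    K = D2.T @ D2
    centring = np.zeros(m)
    if centre:
        centring = B.mean(axis=0)
        B = B - centring
    return SplineBasis(name=name, knots=knots, degree=degree, B=B, K=K, centring=centring)


@dataclass
class DesignBundle:
    """All model matrices for one dataset, aligned row-by-row.

    ``Z`` carries an intercept plus reference-cell dummies (and any linear
    metrical covariates); ``splines`` are optional P-spline blocks;
    ``region_index`` maps each child to a position in ``graph.region_ids``.
    """

    Z: np.ndarray
    columns: list[str]
    region_index: np.ndarray
    graph: AdjacencyGraph
    splines: list[SplineBasis] = field(default_factory=list)
    reference_levels: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    def manifest(self) -> dict:
        """Audit record: columns, reference levels, graph summary."""
        return {
            "columns": list(self.columns),
            "reference_levels": dict(self.reference_levels),
            "smooth_terms": [s.name for s in self.splines],
            "n_records": int(self.n),
            "graph": {
                "n_regions": self.graph.n_regions,
                "n_edges": len(self.graph.edges),
                "n_components": self.graph.n_components,
            },
        }


def _aliased_columns(Z: np.ndarray, columns: list[str]) -> list[str]:
    """Names of columns involved in exact linear dependence (via QR pivots)."""
    from scipy.linalg import qr

    _, R, piv = qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Z.shape) * np.finfo(float).eps
    dropped = piv[np.flatnonzero(diag < tol)] if diag.size else []
    return [columns[i] for i in np.sort(dropped)]


def build_design(
    records: pd.DataFrame,
    formula: list[str],
    graph: AdjacencyGraph,
    smooth_terms: list[str] | None = None,
    references: dict[str, str] | None = None,
    spline_options: dict | None = None,
) -> DesignBundle:
    """Build the fixed-effect design and optional smooth blocks.

    Parameters
    ----------
    records
        Complete-case analysis table; must contain ``region_id`` plus every
        term named in ``formula`` and ``smooth_terms``.
    formula
        Covariate columns entering ``Z``.  Categorical/object columns get
        reference-cell dummy coding (L levels -> L-1 columns); numeric
        columns enter as a single linear column.
    smooth_terms
        Metrical covariates to model with centred P-splines (empty by
        default: the final model here uses linear effects only).
    references
        Reference level per categorical term; defaults to the first level
        in sorted order.  Recorded in the bundle for the run manifest.
    """
    smooth_terms = list(smooth_terms or [])
    references = dict(references or {})
    spline_options = dict(spline_options or {})
    if "region_id" not in records.columns:
        raise ValueError("records must contain a 'region_id' column")
    for term in list(formula) + smooth_terms:
        if term not in records.columns:
            raise ValueError(f"formula term '{term}' not found in records")

    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    used_refs: dict[str, str] = {}

    for term in formula:
        col = records[term]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
            continue
        levels = (
            list(col.cat.categories)
            if isinstance(col.dtype, pd.CategoricalDtype)
            else sorted(col.astype(str).unique())
        )
        ref = references.get(term, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not a level of '{term}'")
        used_refs[term] = str(ref)
        vals = col.astype(str).to_numpy()
        for lev in levels:
            if str(lev) == str(ref):
                continue
            cols.append((vals == str(lev)).astype(float))
            names.append(f"{term}[{lev}]")

    Z = np.column_stack(cols)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        aliased = _aliased_columns(Z, names)
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")

    splines = [
        build_spline_basis(
            records[term].to_numpy(dtype=float),
            n_interior_knots=spline_options.get("n_interior_knots", 20),
            degree=spline_options.get("degree", 3),
            name=term,
            centre=True,
        )
        for term in smooth_terms
    ]

    region_index = graph.index_of(records["region_id"].to_numpy())
    return DesignBundle(
        Z=Z,
        columns=names,
        region_index=region_index,
        graph=graph,
        splines=splines,
        reference_levels=used_refs,
    )
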