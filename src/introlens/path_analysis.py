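"""Phylogenetic path analysis: d-separation basis sets, PGLS, Fisher's C, CICc.

A candidate causal structure is a DAG over the predictor-table columns.
Shipley's d-separation test turns the DAG into a minimal basis set of
conditional-independence claims — one per non-adjacent variable pair (x, y),
conditioned on the union of the parents of both.  Each claim is tested by
phylogenetic generalized least squares (PGLS) under a Brownian-motion
covariance on the triad tree; the claim's p-value is the two-sided t-test
on x's coefficient.  Fisher's C = -2 * sum(ln p_i) is chi-squared with 2k
degrees of freedom when the DAG is consistent with the data, and models are
ranked by the small-sample information criterion

    CICc = C + 2 q n / (n - 1 - q),

with q = number of edges plus one intercept per endogenous variable.
Edge coefficients are PGLS fits of each endogenous variable on its parents,
standardized by the GLS-scaled standard deviations of the variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PathModel",
    "IndependenceClaim",
    "PathCoefficient",
    "PathFit",
    "basis_set",
    "fishers_c",
    "cicc",
    "pgls_independence_pvalue",
    "pgls_fit",
    "fit_path_model",
    "rank_models",
    "default_models",
    "parse_model_text",
]

_P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class PathModel:
    """A named DAG over predictor variables."""

    name: str
    edges: tuple[tuple[str, str], ...]
    variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        declared = set(self.variables) | {v for e in self.edges for v in e}
        object.__setattr__(self, "variables", tuple(sorted(declared)))
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"model '{self.name}' is cyclic: {cycle}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {b for _, b in self.edges}
        return tuple(sorted(targets))

    @property
    def q(self) -> int:
        """Parameter count: edges plus one intercept per endogenous variable."""
        return len(self.edges) + len(self.endogenous)


@dataclass(frozen=True)
class IndependenceClaim:
    """x independent of y given the conditioning set; y is the regression response."""

    x: str
    y: str
    conditioning: tuple[str, ...]


@dataclass(frozen=True)
class PathCoefficient:
    source: str
    target: str
    coef: float  # standardized
    se: float  # standardized scale
    pvalue: float


@dataclass(frozen=True)
class PathFit:
    model: PathModel
    claims: tuple[IndependenceClaim, ...]
    claim_pvalues: tuple[float, ...]
    C: float
    C_pvalue: float
    q: int
    n: int
    CICc: float
    coefficients: tuple[PathCoefficient, ...] = field(default=())

    @property
    def k(self) -> int:
        return len(self.claims)

    @property
    def df(self) -> int:
        return 2 * self.k


def basis_set(model: PathModel) -> list[IndependenceClaim]:
    """Shipley's d-separation basis set for a DAG.

    One claim per non-adjacent (unordered) pair, conditioned on
    parents(x) union parents(y) (minus the pair itself).  The pair member
    later in the causal (topological) order is the regression response, so
    colliders never enter their own conditioning set.  Claims are ordered
    by the response's topological position, then lexicographically.
    """
    g = model.graph()
    order = list(nx.lexicographical_topological_sort(g))
    pos = {v: i for i, v in enumerate(order)}
    claims = []
    seen = set()
    for a in order:
        for b in order:
            if pos[b] <= pos[a]:
                continue
            if g.has_edge(a, b) or g.has_edge(b, a):
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            cond = (set(g.predecessors(a)) | set(g.predecessors(b))) - {a, b}
            claims.append(IndependenceClaim(x=a, y=b, conditioning=tuple(sorted(cond))))
    claims.sort(key=lambda c: (pos[c.y], c.x, c.y))
    return claims


def fishers_c(pvalues: Sequence[float]) -> float:
    """Fisher's C = -2 sum(ln p); zero p-values are clamped to the float floor."""
    return -2.0 * sum(math.log(max(p, _P_FLOOR)) for p in pvalues)


def cicc(C: float, q: int, n: int) -> float:
    """Small-sample C-statistic information criterion: C + 2 q n / (n - 1 - q)."""
    if n - 1 - q <= 0:
        raise ValueError(f"CICc undefined: n={n} too small for q={q}")
    return C + 2.0 * q * n / (n - 1 - q)


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"too few observations ({X.shape[0]}) for {X.shape[1]} parameters"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify which columns are linearly dependent on the others
        bad = []
        for j in range(1, X.shape[1]):  # skip intercept
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise ValueError(f"singular design; collinear columns: {bad or names}")


def pgls_fit(
    y: np.ndarray, X: np.ndarray, V: np.ndarray, names: Sequence[str]
):
    """GLS of y on X with covariance proportional to V (statsmodels)."""
    _check_design(X, names)
    return sm.GLS(y, X, sigma=V).fit()


def pgls_independence_pvalue(
    claim: IndependenceClaim,
    data: pd.DataFrame,
    V: np.ndarray,
) -> float:
    """Two-sided p-value for x's coefficient in PGLS of y on x + conditioners.

    ``data`` rows must be aligned with ``V``.  The t test uses
    df = n - parameters, as in ordinary GLS inference.
    """
    cols = [claim.x, *claim.conditioning]
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in cols])
    res = pgls_fit(data[claim.y].to_numpy(float), X, V, ["intercept", *cols])
    return float(res.pvalues[1])


def _gls_scale(v: np.ndarray, Vinv: np.ndarray) -> float:
    """GLS standard deviation of a variable: sqrt((v-mu)' Vinv (v-mu) / (n-1))."""
    ones = np.ones(len(v))
    mu = (ones @ Vinv @ v) / (ones @ Vinv @ ones)
    r = v - mu
    return math.sqrt((r @ Vinv @ r) / (len(v) - 1))


def fit_path_model(
    model: PathModel,
    data: pd.DataFrame,
    V: np.ndarray,
) -> PathFit:
    """Fit one path model: basis-set tests, Fisher's C, CICc, coefficients.

    ``data`` must contain every model variable; rows align with ``V``.
    Basis p-values of exactly zero are clamped to the smallest positive
    float before the log (with the claim retained).
    """
    missing = [v for v in model.variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    n = len(data)
    claims = basis_set(model)
    pvals = [pgls_independence_pvalue(c, data, V) for c in claims]
    C = fishers_c(pvals)
    k = len(claims)
    C_pvalue = float(stats.chi2.sf(C, 2 * k)) if k else 1.0
    q = model.q
    CICc = cicc(C, q, n)

    Vinv = np.linalg.inv(V)
    scales = {v: _gls_scale(data[v].to_numpy(float), Vinv) for v in model.variables}
    g = model.graph()
    coefs = []
    for target in model.endogenous:
        parents = sorted(g.predecessors(target))
        X = np.column_stack(
            [np.ones(n)] + [data[p].to_numpy(float) for p in parents]
        )
        res = pgls_fit(data[target].to_numpy(float), X, V, ["intercept", *parents])
        for j, p in enumerate(parents, start=1):
            ratio = scales[p] / scales[target]
            coefs.append(
                PathCoefficient(
                    source=p,
                    target=target,
                    coef=float(res.params[j]) * ratio,
                    se=float(res.bse[j]) * ratio,
                    pvalue=float(res.pvalues[j]),
                )
            )
    return PathFit(
        model=model,
        claims=tuple(claims),
        claim_pvalues=tuple(pvals),
        C=C,
        C_pvalue=C_pvalue,
        q=q,
        n=n,
        CICc=CICc,
        coefficients=tuple(coefs),
    )


def rank_models(fits: Sequence[PathFit]) -> pd.DataFrame:
    """Rank fitted models by ascending CICc with deltas relative to the best.

    All fits must share the same sample size (same data rows).  Ties are
    broken by fewer parameters, then model name.
    """
    if not fits:
        raise ValueError("no fits to rank")
    sizes = {f.n for f in fits}
    if len(sizes) > 1:
        raise ValueError(f"fits computed on different sample sizes: {sorted(sizes)}")
    ordered = sorted(fits, key=lambda f: (f.CICc, f.q, f.model.name))
    best = ordered[0].CICc
    return pd.DataFrame(
        {
            "model": [f.model.name for f in ordered],
            "k": [f.k for f in ordered],
            "q": [f.q for f in ordered],
            "C": [f.C for f in ordered],
            "C_pvalue": [f.C_pvalue for f in ordered],
            "CICc": [f.CICc for f in ordered],
            "delta_CICc": [f.CICc - best for f in ordered],
        }
    )


def parse_model_text(name: str, text: str) -> PathModel:
    """Parse a plain-text edge list ('a -> b' per line; '#' comments).

    Lines with a bare variable name declare an isolated variable.
    """
    edges = []
    variables = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" in line:
            a, b = (s.strip() for s in line.split("->", 1))
            if not a or not b:
                raise ValueError(f"bad edge line: {raw!r}")
            edges.append((a, b))
        else:
            variables.append(line)
    return PathModel(name=name, edges=tuple(edges), variables=tuple(variables))


def default_models() -> list[PathModel]:
    """The shipped model set: combined, ILS-only, introgression-only.

    The combined structure routes geography, climate and divergence time
    into the introgression signal, which joins the ILS-related variables
    (internode, range size) in predicting sister-node discordance.
    """
    combined = PathModel(
        name="combined",
        edges=(
            ("log_geo_distance", "log_z_signal"),
            ("log_mean_climate_velocity", "log_z_signal"),
            ("log_mean_abs_centroid_latitude", "log_z_signal"),
            ("log_divergence_time", "log_z_signal"),
            ("log_z_signal", "discordance"),
            ("log_internode", "discordance"),
            ("log_mean_range_size", "discordance"),
        ),
    )
    ils_only = PathModel(
        name="ils_only",
        edges=(
            ("log_internode", "discordance"),
            ("log_mean_range_size", "discordance"),
        ),
        variables=(
            "log_geo_distance",
            "log_mean_climate_velocity",
            "log_mean_abs_centroid_latitude",
            "log_divergence_time",
            "log_z_signal",
        ),
    )
    introgression_only = PathModel(
        name="introgression_only",
        edges=(
            ("log_geo_distance", "log_z_signal"),
            ("log_mean_climate_velocity", "log_z_signal"),
            ("log_mean_abs_centroid_latitude", "log_z_signal"),
            ("log_divergence_time", "log_z_signal"),
            ("log_z_signal", "discordance"),
        ),
        variables=("log_internode", "log_mean_range_size"),
    )
    return [combined, ils_only, introgression_only]
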