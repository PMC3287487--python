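"""Hierarchical log-linear graphical models for binary motif-presence tables.

A gene x motif presence matrix is collapsed into a 2^k contingency table
(k binary variables, one per motif).  A hierarchical log-linear model is
defined by its generating class — the maximal interaction terms, which
for a *graphical* model are the cliques of an undirected independence
graph.  Fitting is by iterative proportional fitting (IPF): cycle over
the generators, scaling the fitted table so each generator's marginal
matches the observed one.  Model fit is measured by the deviance

    G^2 = 2 * sum obs * ln(obs / fitted)        (terms with obs = 0 drop)

with degrees of freedom ``(2^k - 1) - rank`` of the model's centered
indicator design matrix, and nested models compared by the chi-square
distribution of the deviance difference.

Backward elimination starts from the full model's complete graph and
repeatedly removes the edge whose single-edge deviance test against the
current model has the largest p-value, while that p-value is at least
``alpha``; the surviving edges form the independence graph whose edges
are the co-occurring motif combinations.

Cell ordering convention: variable 0 is the least significant bit of the
2^k cell index (variable 0 varies fastest).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import OccurrenceMatrix, PRESENT

logger = logging.getLogger(__name__)

MAX_VARIABLES = 16


@dataclass
class BinaryTable:
    """2^k contingency table over binary (absent/present) variables."""

    names: list[str]
    counts: np.ndarray  # length 2^k, variable 0 fastest

    def __post_init__(self) -> None:
        k = len(self.names)
        if k > MAX_VARIABLES:
            raise ValueError(f"at most {MAX_VARIABLES} variables supported, got {k}")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2**k,):
            raise ValueError("counts must have length 2^k")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def tensor(self) -> np.ndarray:
        # reshape with variable 0 fastest -> axis order reversed, then transposed
        return self.counts.reshape((2,) * self.k, order="F")


GeneratingClass = list[frozenset[int]]


def normalize_generators(generators, k: int) -> GeneratingClass:
    """Drop non-maximal generators; ensure every variable is covered."""
    gens = [frozenset(g) for g in generators]
    gens = [g for g in gens if g and not any(g < h for h in gens)]
    covered = set().union(*gens) if gens else set()
    for v in range(k):
        if v not in covered:
            gens.append(frozenset([v]))
    return sorted(set(gens), key=lambda g: (len(g), sorted(g)))


@dataclass
class LogLinearFit:
    generators: GeneratingClass
    fitted: np.ndarray
    deviance: float
    df: int
    converged: bool
    iterations: int
    table: BinaryTable = field(repr=False)


def tabulate(matrix: OccurrenceMatrix) -> BinaryTable:
    """Collapse an occurrence matrix into a 2^k contingency table."""
    if matrix.values.shape[0] == 0 or matrix.values.shape[1] == 0:
        raise ValueError("occurrence matrix is empty")
    names = list(matrix.values.columns)
    k = len(names)
    if k > MAX_VARIABLES:
        raise ValueError(f"too many motifs for exact tabulation (k={k} > {MAX_VARIABLES})")
    bits = (matrix.values.to_numpy() == PRESENT).astype(np.int64)
    idx = bits @ (1 << np.arange(k, dtype=np.int64))
    counts = np.bincount(idx, minlength=2**k).astype(float)
    return BinaryTable(names, counts)


def _marginal(tensor: np.ndarray, gen: frozenset[int], k: int) -> np.ndarray:
    axes = tuple(v for v in range(k) if v not in gen)
    return tensor.sum(axis=axes, keepdims=True)


def model_df(generators: GeneratingClass, k: int) -> int:
    """Residual degrees of freedom: (2^k - 1) minus the design-matrix rank.

    The design uses centered (+1/-1) indicator products, one column per
    non-empty subset of some generator.
    """
    terms: set[frozenset[int]] = set()
    for g in generators:
        for r in range(1, len(g) + 1):
            terms.update(frozenset(c) for c in itertools.combinations(sorted(g), r))
    # Distinct centered (+1/-1) product columns are the characters of Z_2^k
    # and hence exactly orthogonal over the full cell lattice, so the design
    # rank equals the number of distinct terms (verified numerically in the
    # test suite via design_matrix_rank).
    return (2**k - 1) - len(terms)


def design_matrix_rank(generators: GeneratingClass, k: int) -> int:
    """Numeric rank of the centered indicator design (small k; for checks)."""
    terms: set[frozenset[int]] = set()
    for g in generators:
        for r in range(1, len(g) + 1):
            terms.update(frozenset(c) for c in itertools.combinations(sorted(g), r))
    cells = np.arange(2**k)
    signs = np.empty((2**k, k)) if k else np.empty((1, 0))
    for v in range(k):
        signs[:, v] = np.where((cells >> v) & 1, 1.0, -1.0)
    cols = [
        np.prod(signs[:, sorted(t)], axis=1)
        for t in sorted(terms, key=lambda t: (len(t), sorted(t)))
    ]
    return int(np.linalg.matrix_rank(np.column_stack(cols))) if cols else 0


def deviance(observed: np.ndarray, fitted: np.ndarray) -> float:
    obs = observed.ravel()
    fit = fitted.ravel()
    mask = obs > 0
    with np.errstate(divide="ignore"):
        return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / np.maximum(fit[mask], 1e-300))))


def ipf_fit(
    table: BinaryTable,
    generators,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> LogLinearFit:
    """Fit a hierarchical log-linear model by iterative proportional fitting.

    Convergence is declared when the maximum absolute discrepancy between
    fitted and observed generator marginals falls below ``tol``.
    Non-convergence returns the partial fit flagged ``converged=False``.
    """
    k = table.k
    gens = normalize_generators(generators, k)
    obs = table.tensor()
    n = table.n
    fitted = np.full_like(obs, n / obs.size if n > 0 else 0.0)
    obs_margs = {g: _marginal(obs, g, k) for g in gens}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for g in gens:
            fit_marg = _marginal(fitted, g, k)
            ratio = np.divide(
                obs_margs[g], fit_marg, out=np.zeros_like(fit_marg), where=fit_marg > 0
            )
            fitted = fitted * ratio
        disc = max(
            float(np.abs(_marginal(fitted, g, k) - obs_margs[g]).max()) for g in gens
        )
        if disc < tol:
            converged = True
            break
    if not converged:
        logger.warning("IPF did not converge in %d iterations", max_iter)
    dev = deviance(obs, fitted)
    return LogLinearFit(
        generators=gens,
        fitted=fitted.ravel(order="F"),
        deviance=dev,
        df=model_df(gens, k),
        converged=converged,
        iterations=it,
        table=table,
    )


def _is_nested(rm_gens: GeneratingClass, fm_gens: GeneratingClass) -> bool:
    return all(any(g <= h for h in fm_gens) for g in rm_gens)


def deviance_test(rm: LogLinearFit, fm: LogLinearFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model against a fuller model.

    Returns (delta G^2, delta df, upper-tail chi-square p-value).
    """
    if not _is_nested(rm.generators, fm.generators):
        raise ValueError("reduced model is not nested within the full model")
    delta_g2 = max(rm.deviance - fm.deviance, 0.0)
    delta_df = rm.df - fm.df
    if delta_df <= 0:
        p = 1.0 if delta_g2 <= 1e-8 else 0.0
    else:
        p = float(stats.chi2.sf(delta_g2, delta_df))
    return delta_g2, delta_df, p


def chi2_model_pvalue(deviance_value: float, df: int) -> float:
    """Upper-tail chi-square probability of a model deviance."""
    if df <= 0:
        return 1.0 if deviance_value <= 1e-8 else 0.0
    return float(stats.chi2.sf(deviance_value, df))


@dataclass
class EliminationStep:
    edge: tuple[str, str]
    delta_g2: float
    delta_df: int
    p_value: float
    cumulative_g2: float  # deviance of the model after removal, vs FM
    cumulative_df: int
    cumulative_p: float


@dataclass
class EliminationTrace:
    steps: list[EliminationStep]
    final_deviance: float
    final_df: int
    final_p_vs_fm: float

    def to_tsv(self, path) -> None:
        rows = [
            {
                "edge": f"{a}--{b}",
                "delta_g2": s.delta_g2,
                "delta_df": s.delta_df,
                "p_value": s.p_value,
                "cum_g2_vs_fm": s.cumulative_g2,
                "cum_df_vs_fm": s.cumulative_df,
                "cum_p_vs_fm": s.cumulative_p,
            }
            for s in self.steps
            for a, b in [s.edge]
        ]
        pd.DataFrame(
            rows,
            columns=[
                "edge", "delta_g2", "delta_df", "p_value",
                "cum_g2_vs_fm", "cum_df_vs_fm", "cum_p_vs_fm",
            ],
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class IndependenceGraph:
    graph: nx.Graph
    edge_stats: dict[tuple[str, str], dict] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def neighbors(self, node: str) -> list[str]:
        return sorted(self.graph.neighbors(node))

    def to_json(self, path) -> None:
        payload = {
            "nodes": self.nodes,
            "edges": [
                {"a": a, "b": b, **self.edge_stats.get((a, b), {})} for a, b in self.edges
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def to_dot(self, path) -> None:
        lines = ["graph independence {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for a, b in self.edges:
            lines.append(f'  "{a}" -- "{b}";')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


def _graph_generators(g: nx.Graph, names: list[str]) -> GeneratingClass:
    index = {n: i for i, n in enumerate(names)}
    cliques = [frozenset(index[n] for n in c) for c in nx.find_cliques(g)]
    return normalize_generators(cliques, len(names))


def backward_eliminate(
    table: BinaryTable,
    alpha: float = 0.001,
    full: str = "saturated",
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[IndependenceGraph, EliminationTrace]:
    """Backward edge elimination of a graphical log-linear model.

    Starting from the complete graph, each remaining edge's removal is
    tested against the *current* model (single-edge deviance test); the
    edge with the largest p-value is removed while that p-value is at
    least ``alpha``.  The trace also records, at each step, the cumulative
    deviance of the reduced model against the full model (``full`` is
    either the saturated model or the all-two-way model).
    """
    names = table.names
    g = nx.Graph()
    g.add_nodes_from(names)
    g.add_edges_from(itertools.combinations(names, 2))
    if full == "saturated":
        fm_gens: GeneratingClass = [frozenset(range(table.k))]
    elif full == "all_two_way":
        fm_gens = [frozenset(p) for p in itertools.combinations(range(table.k), 2)]
        if table.k == 1:
            fm_gens = [frozenset([0])]
    else:
        raise ValueError("full must be 'saturated' or 'all_two_way'")
    fm_fit = ipf_fit(table, fm_gens, tol, max_iter)
    current_fit = ipf_fit(table, _graph_generators(g, names), tol, max_iter)
    steps: list[EliminationStep] = []
    edge_stats: dict[tuple[str, str], dict] = {}
    while g.number_of_edges() > 0:
        best: tuple | None = None
        for edge in sorted(tuple(sorted(e)) for e in g.edges):
            h = g.copy()
            h.remove_edge(*edge)
            cand_fit = ipf_fit(table, _graph_generators(h, names), tol, max_iter)
            if not cand_fit.converged:
                logger.warning("skipping edge %s: candidate fit did not converge", edge)
                continue
            dg2, ddf, p = deviance_test(cand_fit, current_fit)
            edge_stats[edge] = {"delta_g2": dg2, "delta_df": ddf, "p_value": p}
            if best is None or (p, edge) > (best[0], best[1]):
                best = (p, edge, cand_fit, dg2, ddf)
        if best is None or best[0] < alpha:
            break
        p, edge, cand_fit, dg2, ddf = best
        g.remove_edge(*edge)
        cum_g2, cum_df, cum_p = deviance_test(cand_fit, fm_fit)
        steps.append(EliminationStep(edge, dg2, ddf, p, cum_g2, cum_df, cum_p))
        current_fit = cand_fit
    final_g2, final_df, final_p = deviance_test(current_fit, fm_fit)
    trace = EliminationTrace(steps, final_g2, final_df, final_p)
    stats_on_final = {e: s for e, s in edge_stats.items() if g.has_edge(*e)}
    return IndependenceGraph(g, stats_on_final), trace


def extract_combinations(graph: IndependenceGraph) -> list[dict]:
    """One motif combination per edge, with each endpoint's linked motifs."""
    combos = []
    for a, b in graph.edges:
        combos.append(
            {
                "motifs": (a, b),
                "linked": {a: graph.neighbors(a), b: graph.neighbors(b)},
            }
        )
    return combos


def star_table(
    matrix: OccurrenceMatrix, combinations: list[dict] | list[tuple[str, str]]
) -> pd.DataFrame:
    """Gene x combination incidence table restricted to down-regulated genes.

    A star is set when both motifs of the pair are present in the gene's
    promoter.  Columns are labelled ``"A|B"``.
    """
    pairs = []
    for c in combinations:
        pair = tuple(c["motifs"]) if isinstance(c, dict) else tuple(c)
        pairs.append(pair)
    down = matrix.down_genes()
    data = {}
    for a, b in pairs:
        for m in (a, b):
            if m not in matrix.values.columns:
                raise KeyError(f"combination motif {m!r} not in occurrence matrix")
        col = (matrix.values.loc[down, a] == PRESENT) & (matrix.values.loc[down, b] == PRESENT)
        data[f"{a}|{b}"] = col
    return pd.DataFrame(data, index=pd.Index(down, name="gene"))


def write_star_table(stars: pd.DataFrame, path) -> None:
    out = stars.replace({True: "*", False: ""})
    out.to_csv(path, sep="\t", index_label="gene")


def load_star_table(path) -> pd.DataFrame:
    """Read a star-table TSV with ``motif|linked1,linked2`` column headers."""
    df = pd.read_csv(path, sep="\t", index_col="gene", comment="#", dtype=str)
    return df.notna() & (df != "")


def table5_fixture_path():
    """Path to the bundled 18-gene x 10-combination star matrix fixture."""
    return resources.files("comotif.data").joinpath("table5_stars.tsv")


def _column_motifs(column: str) -> set[str]:
    head, _, linked = column.partition("|")
    motifs = {head.strip()}
    if linked:
        motifs.update(x.strip() for x in linked.split(",") if x.strip())
    return motifs


def count_genes_with_motif(stars: pd.DataFrame | str | Path, motif_name: str) -> int:
    """Genes with >= 1 star in a column whose motif or linked set names ``motif_name``.

    ``stars`` is a boolean star table (or a path to one) whose columns are
    labelled ``motif|linked1,linked2``.
    """
    if not isinstance(stars, pd.DataFrame):
        stars = load_star_table(stars)
    cols = [c for c in stars.columns if motif_name in _column_motifs(c)]
    if not cols and len(stars.columns):
        known = sorted({m for c in stars.columns for m in _column_motifs(c)})
        raise KeyError(f"unknown motif {motif_name!r}; table mentions {known}")
    if not cols:
        return 0
    return int(stars[cols].any(axis=1).sum())
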