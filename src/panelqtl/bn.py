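"""Gaussian Bayesian-network learning for trait matrices.

Structure search is constraint-screened hill climbing: a Semi-Interleaved
HITON-PC pass per node proposes parent/children candidates via partial
correlations, a blacklist encodes the developmental stage ordering, and a
greedy add/delete/reverse search maximizes the Gaussian BIC (larger is
better).  Cross-validated learning reports per-arc selection frequencies and
picks the fold structure with the best full-data score.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from panelqtl.phenostats import TraitMatrix

__all__ = [
    "Blacklist",
    "Dag",
    "BnConfig",
    "partial_corr_test",
    "hiton_pc",
    "stage_blacklist",
    "hill_climb",
    "cv_learn",
]


@dataclass
class Blacklist:
    """Forbidden directed arcs with a reason tag per pair."""

    arcs: dict[tuple[str, str], str] = field(default_factory=dict)

    def forbids(self, u: str, v: str) -> bool:
        return (u, v) in self.arcs

    def add(self, u: str, v: str, reason: str = "user") -> None:
        self.arcs[(u, v)] = reason

    def __len__(self) -> int:
        return len(self.arcs)


@dataclass
class Dag:
    """Directed acyclic trait graph with arc strengths and coefficients."""

    nodes: list[str]
    arcs: dict[tuple[str, str], dict] = field(default_factory=dict)
    score: float = float("nan")

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("arcs contain a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), attrs in self.arcs.items():
            g.add_edge(u, v, **attrs)
        return g

    def parents(self, v: str) -> list[str]:
        return sorted(u for (u, w) in self.arcs if w == v)


@dataclass
class BnConfig:
    alpha: float = 0.1
    folds: int = 10
    validation_size: int | None = 17
    score: str = "bic"
    seed: int = 0
    restarts: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, TraitMatrix):
        return data.values
    return pd.DataFrame(data)


def partial_corr_test(data, x: str, y: str, z: tuple[str, ...] = ()) -> tuple[float, float]:
    """Partial correlation of x and y given z, with a t-test on n-|z|-2 df.

    Computed from regression residuals; with empty z this reduces to the
    plain Pearson correlation test.  Collinear conditioning columns are
    dropped with a warning.
    """
    df = _as_frame(data)[[x, y, *z]].dropna()
    n = len(df)
    if n <= len(z) + 2:
        raise ValueError("need n > |z| + 2 observations")
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    if z:
        Z = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float) for c in z])
        rank = np.linalg.matrix_rank(Z, tol=1e-10)
        if rank < Z.shape[1]:
            warnings.warn("collinear conditioning set; dropping dependent columns")
            keep = [0]
            for j in range(1, Z.shape[1]):
                if np.linalg.matrix_rank(Z[:, keep + [j]], tol=1e-10) == len(keep) + 1:
                    keep.append(j)
            Z = Z[:, keep]
        xv = xv - Z @ np.linalg.lstsq(Z, xv, rcond=None)[0]
        yv = yv - Z @ np.linalg.lstsq(Z, yv, rcond=None)[0]
    else:
        xv = xv - xv.mean()
        yv = yv - yv.mean()
    sx, sy = xv.std(), yv.std()
    if sx <= 1e-300 or sy <= 1e-300:
        warnings.warn("degenerate residuals in partial correlation")
        return float("nan"), 1.0
    r = float(np.clip((xv * yv).mean() / (sx * sy), -1.0, 1.0))
    dof = n - len(z) - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(dof / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=dof)
    return r, float(p)


def hiton_pc(data, target: str, alpha: float = 0.1, max_cond: int | None = None) -> list[str]:
    """Semi-Interleaved HITON-PC parent/children screening for ``target``.

    Candidates enter by marginal-association ranking; after each admission,
    any current member that some conditioning subset of the others renders
    independent of the target (p > alpha) is removed.  Deterministic: ties in
    the ranking break on variable name.
    """
    df = _as_frame(data)
    variables = [c for c in df.columns if c != target]
    assoc = []
    for v in variables:
        if df[v].equals(df[target]) or np.allclose(
            df[v].to_numpy(dtype=float), df[target].to_numpy(dtype=float)
        ):
            warnings.warn(f"variable {v!r} duplicates target {target!r}; degenerate")
        r, p = partial_corr_test(df, target, v)
        assoc.append((p, v))
    assoc.sort(key=lambda e: (e[0], e[1]))
    queue = [v for p, v in assoc if p <= alpha]

    current: list[str] = []
    for v in queue:
        current.append(v)
        for member in list(current):
            others = [c for c in current if c != member]
            limit = len(others) if max_cond is None else min(max_cond, len(others))
            independent = False
            for k in range(0, limit + 1):
                for z in itertools.combinations(others, k):
                    _, p = partial_corr_test(df, target, member, z)
                    if p > alpha:
                        independent = True
                        break
                if independent:
                    break
            if independent:
                current.remove(member)
    return sorted(current)


def stage_blacklist(stages: dict[str, int]) -> Blacklist:
    """Forbid every arc from a later developmental stage to a strictly
    earlier one; arcs within a stage stay unrestricted."""
    bl = Blacklist()
    for u, su in stages.items():
        for v, sv in stages.items():
            if u != v and su > sv:
                bl.add(u, v, reason="stage order")
    return bl


def _node_loglik(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = max(float(resid @ resid) / n, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)


def _node_bic(df: pd.DataFrame, v: str, parents: tuple[str, ...]) -> float:
    y = df[v].to_numpy(dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n)] + [df[p].to_numpy(dtype=float) for p in parents])
    k = len(parents) + 2  # coefficients + intercept + variance
    return _node_loglik(y, X) - 0.5 * math.log(n) * k


def bic_score(df: pd.DataFrame, arcs: set[tuple[str, str]]) -> float:
    """Gaussian BIC of a DAG (larger is better), factorized per node."""
    total = 0.0
    for v in df.columns:
        parents = tuple(sorted(u for (u, w) in arcs if w == v))
        total += _node_bic(df, v, parents)
    return total


def hill_climb(
    data,
    blacklist: Blacklist | None = None,
    restrict: dict[str, list[str]] | None = None,
    seed: int = 0,
    restarts: int = 0,
) -> Dag:
    """Greedy add/delete/reverse search maximizing the Gaussian BIC.

    ``restrict`` limits arcs u->v to pairs where u is among v's candidate set
    (and vice versa for symmetry of the skeleton), as produced by
    :func:`hiton_pc`.  Every accepted move strictly increases the score;
    search starts from the empty graph so the result never scores below it.
    Rows with missing values are dropped (count reported via warning).
    """
    df = _as_frame(data)
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        warnings.warn(f"dropped {n_before - len(df)} incomplete row(s)")
    blacklist = blacklist or Blacklist()
    nodes = list(df.columns)
    rng = np.random.default_rng(seed)

    def allowed(u: str, v: str) -> bool:
        if blacklist.forbids(u, v):
            return False
        if restrict is None:
            return True
        # symmetric OR, as in constraint-restricted scorers: the skeleton
        # edge must be supported from at least one endpoint's candidate set
        return u in restrict.get(v, ()) or v in restrict.get(u, ())

    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def node_bic(v: str, parents: tuple[str, ...]) -> float:
        key = (v, parents)
        if key not in cache:
            cache[key] = _node_bic(df, v, parents)
        return cache[key]

    def climb(initial: set[tuple[str, str]]) -> tuple[set[tuple[str, str]], float]:
        arcs = set(initial)
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(arcs)
        score = sum(node_bic(v, tuple(sorted(g.predecessors(v)))) for v in nodes)
        improved = True
        while improved:
            improved = False
            best_delta, best_move = 0.0, None
            for u in nodes:
                for v in nodes:
                    if u == v:
                        continue
                    pv = tuple(sorted(g.predecessors(v)))
                    if (u, v) in arcs:
                        # delete
                        delta = node_bic(v, tuple(p for p in pv if p != u)) - node_bic(v, pv)
                        if delta > best_delta + 1e-12:
                            best_delta, best_move = delta, ("del", u, v)
                        # reverse
                        if allowed(v, u):
                            pu = tuple(sorted(g.predecessors(u)))
                            delta_r = (
                                node_bic(v, tuple(p for p in pv if p != u)) - node_bic(v, pv)
                                + node_bic(u, tuple(sorted([*pu, v]))) - node_bic(u, pu)
                            )
                            if delta_r > best_delta + 1e-12:
                                g.remove_edge(u, v)
                                creates_cycle = nx.has_path(g, u, v)
                                g.add_edge(u, v)
                                if not creates_cycle:
                                    best_delta, best_move = delta_r, ("rev", u, v)
                    else:
                        if not allowed(u, v):
                            continue
                        if nx.has_path(g, v, u):
                            continue  # would create a cycle
                        delta = node_bic(v, tuple(sorted([*pv, u]))) - node_bic(v, pv)
                        if delta > best_delta + 1e-12:
                            best_delta, best_move = delta, ("add", u, v)
            if best_move is not None:
                op, u, v = best_move
                if op == "add":
                    arcs.add((u, v))
                    g.add_edge(u, v)
                elif op == "del":
                    arcs.discard((u, v))
                    g.remove_edge(u, v)
                else:
                    arcs.discard((u, v))
                    g.remove_edge(u, v)
                    arcs.add((v, u))
                    g.add_edge(v, u)
                score += best_delta
                improved = True
        return arcs, score

    best_arcs, best_score = climb(set())
    for _ in range(restarts):
        # random restart: perturb by a few random allowed arcs
        init: set[tuple[str, str]] = set()
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for _ in range(3):
            u, v = rng.choice(nodes, size=2, replace=False)
            if allowed(u, v) and not nx.has_path(g, v, u):
                init.add((u, v))
                g.add_edge(u, v)
        arcs, score = climb(init)
        if score > best_score:
            best_arcs, best_score = arcs, score

    dag = Dag(nodes=nodes, score=best_score)
    for u, v in sorted(best_arcs):
        coeff = _arc_coefficient(df, u, v, best_arcs)
        dag.arcs[(u, v)] = {"coefficient": coeff, "strength": 1.0}
    return dag


def _arc_coefficient(df: pd.DataFrame, u: str, v: str, arcs: set[tuple[str, str]]) -> float:
    parents = sorted(p for (p, w) in arcs if w == v)
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in parents])
    beta, *_ = np.linalg.lstsq(X, df[v].to_numpy(dtype=float), rcond=None)
    return float(beta[1 + parents.index(u)])


def _validation_loglik(train: pd.DataFrame, valid: pd.DataFrame, arcs: set[tuple[str, str]]) -> float:
    total = 0.0
    for v in train.columns:
        parents = sorted(u for (u, w) in arcs if w == v)
        Xt = np.column_stack([np.ones(len(train))] + [train[p].to_numpy(dtype=float) for p in parents])
        yt = train[v].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        s2 = max(float(np.mean((yt - Xt @ beta) ** 2)), 1e-12)
        Xv = np.column_stack([np.ones(len(valid))] + [valid[p].to_numpy(dtype=float) for p in parents])
        yv = valid[v].to_numpy(dtype=float)
        resid = yv - Xv @ beta
        total += float(-0.5 * np.sum(np.log(2 * np.pi * s2) + resid**2 / s2))
    return total


def cv_learn(
    data,
    config: BnConfig | None = None,
    blacklist: Blacklist | None = None,
) -> tuple[Dag, pd.DataFrame]:
    """Cross-validated structure learning with arc selection frequencies.

    Per fold: HITON-PC screening restricts the arc space and hill climbing
    learns a structure on the training split.  Arc strength is the fraction
    of folds selecting the arc; the returned DAG is the fold structure with
    the best BIC recomputed on the full data, annotated with strengths and
    full-data coefficients.  The per-fold validation predictive
    log-likelihood is returned alongside.
    """
    config = config or BnConfig()
    blacklist = blacklist or Blacklist()
    df = _as_frame(data).dropna()
    n = len(df)
    if n < config.folds:
        raise ValueError("need at least as many rows as folds")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    vs = config.validation_size or max(1, n // config.folds)
    vs = min(vs, n - 2)

    fold_arcs: list[set[tuple[str, str]]] = []
    fold_rows = []
    counts: dict[tuple[str, str], int] = {}
    for fold in range(config.folds):
        start = (fold * vs) % n
        valid_idx = [perm[(start + i) % n] for i in range(vs)]
        train_idx = [i for i in range(n) if i not in set(valid_idx)]
        train = df.iloc[train_idx]
        valid = df.iloc[valid_idx]
        if (train.std(ddof=0) == 0).any():
            warnings.warn(f"fold {fold}: zero-variance trait in training split; skipped")
            continue
        restrict = {t: hiton_pc(train, t, alpha=config.alpha) for t in train.columns}
        dag = hill_climb(train, blacklist=blacklist, restrict=restrict,
                         seed=config.seed + fold, restarts=config.restarts)
        arcs = set(dag.arcs)
        fold_arcs.append(arcs)
        for a in arcs:
            counts[a] = counts.get(a, 0) + 1
        fold_rows.append({
            "fold": fold,
            "n_arcs": len(arcs),
            "train_bic": dag.score,
            "validation_loglik": _validation_loglik(train, valid, arcs),
        })

    if not fold_arcs:
        raise RuntimeError("all folds were skipped")
    n_folds = len(fold_arcs)
    full_scores = [bic_score(df, arcs) for arcs in fold_arcs]
    best = int(np.argmax(full_scores))
    best_arcs = fold_arcs[best]

    dag = Dag(nodes=list(df.columns), score=full_scores[best])
    for u, v in sorted(best_arcs):
        dag.arcs[(u, v)] = {
            "coefficient": _arc_coefficient(df, u, v, best_arcs),
            "strength": counts[(u, v)] / n_folds,
        }
    report = pd.DataFrame(fold_rows)
    return dag, report
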