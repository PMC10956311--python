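"""Logistic regression and classification trees for engraftment prediction.

The regression side is maximum-likelihood logistic regression fitted by
iteratively reweighted least squares (IRLS) with Wald inference, a
univariate screen (candidacy at p < 0.2), and backward stepwise elimination
driven by the Akaike Information Criterion.  The tree side is CART: greedy
binary Gini splits, cost-complexity (weakest-link) pruning with a
cross-validated error table, and Gini-based variable importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

WALD_Z = float(stats.norm.ppf(0.975))  # 95% normal quantile for Wald CIs


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class Design:
    """A model matrix with enough metadata to rebuild itself on new data."""

    matrix: np.ndarray
    names: list[str]
    term_cols: dict[str, list[int]]
    term_levels: dict[str, list[str]]  # categorical term -> [ref, lvl1, ...]


def design_matrix(frame: pd.DataFrame, terms: list[str],
                  reference: dict[str, str] | None = None,
                  term_levels: dict[str, list[str]] | None = None) -> Design:
    """Build an intercept + main-effects model matrix.

    Categorical terms are dummy-coded against a reference level: the first
    level in sorted order unless overridden via ``reference`` (or pinned
    exactly via ``term_levels``, as done when re-applying a fitted model to
    new rows).
    """
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    term_cols: dict[str, list[int]] = {"intercept": [0]}
    levels_out: dict[str, list[str]] = {}
    for term in terms:
        series = frame[term]
        fixed = term_levels.get(term) if term_levels else None
        if fixed is None and pd.api.types.is_numeric_dtype(series):
            term_cols[term] = [len(cols)]
            cols.append(series.to_numpy(dtype=float))
            names.append(term)
            continue
        if fixed is None:
            observed = sorted(str(v) for v in pd.unique(series.dropna()))
            ref = (reference or {}).get(term, observed[0])
            if ref not in observed:
                raise ValueError(f"reference {ref!r} not a level of {term!r}")
            fixed = [ref] + [lvl for lvl in observed if lvl != ref]
        levels_out[term] = fixed
        values = series.astype(str)
        idx = []
        for lvl in fixed[1:]:
            idx.append(len(cols))
            cols.append((values == lvl).to_numpy(dtype=float))
            names.append(f"{term}[{lvl}]")
        term_cols[term] = idx
    return Design(np.column_stack(cols), names, term_cols, levels_out)


def _drop_aliased(design: Design) -> tuple[Design, list[str]]:
    """Drop linearly dependent columns (keeping the earlier ones)."""
    X = design.matrix
    _, r = np.linalg.qr(X)
    keep_mask = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    if keep_mask.all():
        return design, []
    keep = np.flatnonzero(keep_mask)
    dropped = [design.names[j] for j in np.flatnonzero(~keep_mask)]
    remap = {old: new for new, old in enumerate(keep)}
    term_cols = {t: [remap[j] for j in js if j in remap]
                 for t, js in design.term_cols.items()}
    return Design(X[:, keep], [design.names[j] for j in keep],
                  term_cols, design.term_levels), dropped


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    """An IRLS logistic fit with Wald summaries.

    ``coef``/``se``/``p_values`` etc. are indexed by ``names`` (intercept
    first, then one entry per numeric term or non-reference categorical
    level).  ``aic = -2 loglik + 2 k``.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    aic: float
    n: int
    converged: bool
    separation: bool
    terms: list[str]
    term_cols: dict[str, list[int]]
    term_levels: dict[str, list[str]]
    outcome: str
    cov: np.ndarray
    dropped: list[str] = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def conf_int(self) -> np.ndarray:
        lo = np.exp(self.coef - WALD_Z * self.se)
        hi = np.exp(self.coef + WALD_Z * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def coef_for(self, name: str) -> tuple[float, float]:
        """(beta, se) for one design column name."""
        if name not in self.names:
            raise KeyError(f"unknown term {name!r}; have {self.names}")
        j = self.names.index(name)
        return float(self.coef[j]), float(self.se[j])

    def term_p(self, term: str) -> float:
        """Smallest Wald p among the columns belonging to ``term``."""
        cols = self.term_cols.get(term)
        if not cols:
            raise KeyError(f"term {term!r} not in fit")
        return float(self.p_values[cols].min())

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        design = design_matrix(frame, self.terms,
                               term_levels=self.term_levels)
        keep = [design.names.index(nm) for nm in self.names]
        eta = design.matrix[:, keep] @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame({"term": self.names, "coef": self.coef,
                             "se": self.se, "odds_ratio": self.odds_ratios,
                             "ci_low": ci[:, 0], "ci_high": ci[:, 1],
                             "p_value": self.p_values})


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
          max_iter: int = 50) -> tuple[np.ndarray, np.ndarray, bool]:
    beta = np.zeros(X.shape[1])
    converged = False
    info = np.eye(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    return beta, info, converged


def fit_logistic(cohort: pd.DataFrame, outcome: str, terms: list[str],
                 reference: dict[str, str] | None = None,
                 term_levels: dict[str, list[str]] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    Fitting is by IRLS (convergence when every coefficient moves by less
    than 1e-8, at most 50 iterations); standard errors come from the
    observed information at the optimum.  Complete or quasi-complete
    separation is flagged (``separation=True`` plus a warning) rather than
    penalised, so enormous odds-ratio CIs surface as such.
    """
    data = cohort.dropna(subset=[outcome, *terms])
    y = data[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) != 2:
        raise ValueError("outcome must contain both classes coded 0/1")
    design, dropped = _drop_aliased(design_matrix(data, terms, reference,
                                                  term_levels))
    if dropped:
        warnings.warn(f"dropped aliased columns: {dropped}", stacklevel=2)
    X = design.matrix
    if len(y) <= X.shape[1]:
        raise ValueError("need n > number of parameters")
    beta, info, converged = _irls(X, y)
    separation = bool(np.max(np.abs(beta)) > 15.0) or not converged
    if separation:
        warnings.warn("possible complete separation: coefficients diverging",
                      stacklevel=2)
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    mu = np.clip(1.0 / (1.0 + np.exp(-(X @ beta))), 1e-12, 1.0 - 1e-12)
    loglik = float(y @ np.log(mu) + (1.0 - y) @ np.log(1.0 - mu))
    k = X.shape[1]
    return LogisticFit(names=design.names, coef=beta, se=se, loglik=loglik,
                       aic=-2.0 * loglik + 2.0 * k, n=len(y),
                       converged=converged, separation=separation,
                       terms=list(terms), term_cols=design.term_cols,
                       term_levels=design.term_levels, outcome=outcome,
                       cov=cov, dropped=dropped)


def univariate_screen(cohort: pd.DataFrame, outcome: str,
                      variables: list[str],
                      screen_p: float = 0.2,
                      reference: dict[str, str] | None = None
                      ) -> tuple[dict[str, LogisticFit | Exception], list[str]]:
    """One single-predictor logistic fit per variable.

    Returns the per-variable fits (a failed fit is recorded as its
    exception, not raised) and the candidate list for the multivariate
    step: variables whose smallest Wald p is below ``screen_p``.
    """
    if not variables:
        raise ValueError("need at least one variable to screen")
    fits: dict[str, LogisticFit | Exception] = {}
    candidates: list[str] = []
    for var in variables:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_logistic(cohort, outcome, [var], reference)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            fits[var] = exc
            continue
        fits[var] = fit
        if fit.term_cols.get(var) and fit.term_p(var) < screen_p:
            candidates.append(var)
    return fits, candidates


def stepwise_backward_aic(cohort: pd.DataFrame, outcome: str,
                          candidates: list[str],
                          reference: dict[str, str] | None = None
                          ) -> tuple[LogisticFit, pd.DataFrame]:
    """Backward stepwise elimination minimising the AIC.

    Starts from the full candidate model; each step removes the term whose
    removal lowers the AIC the most (ties break to the term with the larger
    Wald p) and stops when no removal lowers it.  Returns the final fit and
    the elimination trace (one row per evaluated model state).
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    current = list(candidates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_logistic(cohort, outcome, current, reference)
    trace = [{"step": 0, "removed": None, "terms": tuple(current),
              "aic": fit.aic}]
    step = 0
    while len(current) > 0:
        best: tuple[float, float, str, LogisticFit] | None = None
        for term in current:
            remaining = [t for t in current if t != term]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if remaining:
                    cand = fit_logistic(cohort, outcome, remaining, reference)
                else:
                    cand = fit_logistic(cohort, outcome, [], reference)
            # order by (aic, -p): lowest AIC wins; on AIC ties the term
            # with the larger Wald p goes first
            key = (cand.aic, -fit.term_p(term))
            if best is None or key < (best[0], best[1]):
                best = (cand.aic, key[1], term, cand)
        assert best is not None
        if best[0] >= fit.aic - 1e-10:
            break
        step += 1
        fit = best[3]
        current = [t for t in current if t != best[2]]
        trace.append({"step": step, "removed": best[2],
                      "terms": tuple(current), "aic": fit.aic})
    return fit, pd.DataFrame(trace)


def scaled_odds_ratio(fit: LogisticFit, name: str,
                      delta: float) -> tuple[float, tuple[float, float]]:
    """Odds ratio (with Wald CI) for a ``delta``-unit covariate change.

    Morphometric proportions live on a x10,000 scale, so reported odds
    ratios are conventionally quoted per 1,000-unit change; ``delta`` makes
    that scaling explicit.
    """
    beta, se = fit.coef_for(name)
    return (float(np.exp(beta * delta)),
            (float(np.exp((beta - WALD_Z * se) * delta)),
             float(np.exp((beta + WALD_Z * se) * delta))))


# ---------------------------------------------------------------------------
# CART


@dataclass
class TreeNode:
    node_id: int
    depth: int
    counts: np.ndarray  # class counts (failure, success)
    gini: float
    split_var: str | None = None
    split_kind: str | None = None          # "num" | "cat"
    threshold: float | None = None         # numeric splits: left if x <= thr
    left_levels: frozenset | None = None   # categorical splits
    improve: float = 0.0                   # realised Gini decrease (n-weighted)
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def pred_class(self) -> int:
        return int(np.argmax(self.counts))

    @property
    def prob(self) -> float:
        return float(self.counts[1] / max(self.counts.sum(), 1))

    @property
    def risk(self) -> int:
        """Misclassification count under majority vote at this node."""
        return int(self.counts.sum() - self.counts.max())


@dataclass
class DecisionTree:
    """A grown CART model with its pruning table and importances.

    ``cp_table`` mirrors the conventional printcp layout: one row per tree
    in the weakest-link pruning sequence with columns CP, n_splits,
    rel_error (training misclassification relative to the root) and, when
    cross-validation was run, xerror and xstd on the same relative scale.
    ``variable_importance`` is the percent share of total realised Gini
    improvement attributable to each variable's primary splits.
    """

    root: TreeNode
    variables: list[str]
    outcome: str
    params: dict
    cp_table: pd.DataFrame
    variable_importance: dict[str, float]
    cat_levels: dict[str, list[str]]

    def leaves(self) -> list[TreeNode]:
        return [nd for nd in _walk(self.root) if nd.is_leaf]

    def n_splits(self) -> int:
        return sum(1 for nd in _walk(self.root) if not nd.is_leaf)

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(frame))
        for i, (_, row) in enumerate(frame.iterrows()):
            out[i] = _leaf_for(self.root, row).prob
        return out

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(frame), dtype=int)
        for i, (_, row) in enumerate(frame.iterrows()):
            out[i] = _leaf_for(self.root, row).pred_class
        return out


def _walk(node: TreeNode):
    yield node
    if not node.is_leaf:
        yield from _walk(node.left)
        yield from _walk(node.right)


def _leaf_for(node: TreeNode, row: pd.Series) -> TreeNode:
    while not node.is_leaf:
        if node.split_kind == "num":
            go_left = float(row[node.split_var]) <= node.threshold
        else:
            go_left = str(row[node.split_var]) in node.left_levels
        node = node.left if go_left else node.right
    return node


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p ** 2).sum())


def _best_numeric_split(x: np.ndarray, y: np.ndarray,
                        minbucket: int) -> tuple[float, float] | None:
    """Best (threshold, Gini-decrease) for one numeric variable, or None."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    n1 = ys.sum()
    cum1 = np.cumsum(ys)
    left_n = np.arange(1, n)
    left1 = cum1[:-1]
    right_n = n - left_n
    right1 = n1 - left1
    valid = (xs[1:] != xs[:-1]) & (left_n >= minbucket) & (right_n >= minbucket)
    if not valid.any():
        return None
    # n-weighted Gini of a binary node: 2 * n1 * n0 / n
    parent = 2.0 * n1 * (n - n1) / n
    child = (2.0 * left1 * (left_n - left1) / left_n
             + 2.0 * right1 * (right_n - right1) / right_n)
    dec = np.where(valid, parent - child, -np.inf)
    j = int(np.argmax(dec))
    thr = 0.5 * (xs[j] + xs[j + 1])
    return thr, float(dec[j])


def _node_split(data: pd.DataFrame, y: np.ndarray, variables: list[str],
                minbucket: int, cat_levels: dict[str, list[str]]):
    """Best split over all variables; returns None or a split description."""
    best = None
    for var in variables:
        col = data[var]
        if pd.api.types.is_numeric_dtype(col):
            found = _best_numeric_split(col.to_numpy(dtype=float), y, minbucket)
            if found is None:
                continue
            thr, dec = found
            cand = (dec, var, "num", thr, None)
        else:
            # binary outcome: ordering categories by success rate reduces
            # the subset search to a threshold scan over that ordering
            values = col.astype(str)
            rates = pd.Series(y).groupby(values.to_numpy()).mean().sort_values(
                kind="stable")
            code = values.map({lvl: i for i, lvl in enumerate(rates.index)})
            found = _best_numeric_split(code.to_numpy(dtype=float), y, minbucket)
            if found is None:
                continue
            thr, dec = found
            left = frozenset(rates.index[: int(np.floor(thr)) + 1])
            cand = (dec, var, "cat", None, left)
        if best is None or cand[0] > best[0] + 1e-12:
            best = cand
    if best is None or best[0] <= 1e-12:
        return None
    return best


def _grow(data: pd.DataFrame, y: np.ndarray, variables: list[str],
          depth: int, params: dict, counter: list[int],
          cat_levels: dict[str, list[str]]) -> TreeNode:
    counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
    node = TreeNode(node_id=counter[0], depth=depth, counts=counts,
                    gini=_gini(counts))
    counter[0] += 1
    if (node.n < params["minsplit"] or depth >= params["maxdepth"]
            or node.gini == 0.0):
        return node
    best = _node_split(data, y, variables, params["minbucket"], cat_levels)
    if best is None:
        return node
    dec, var, kind, thr, left_levels = best
    if kind == "num":
        go_left = data[var].to_numpy(dtype=float) <= thr
    else:
        go_left = data[var].astype(str).isin(left_levels).to_numpy()
    node.split_var, node.split_kind = var, kind
    node.threshold, node.left_levels = thr, left_levels
    node.improve = dec
    node.left = _grow(data[go_left], y[go_left], variables, depth + 1,
                      params, counter, cat_levels)
    node.right = _grow(data[~go_left], y[~go_left], variables, depth + 1,
                       params, counter, cat_levels)
    return node


def _subtree_stats(node: TreeNode) -> tuple[int, int]:
    """(risk of the leaves of the subtree, number of leaves)."""
    if node.is_leaf:
        return node.risk, 1
    rl, nl = _subtree_stats(node.left)
    rr, nr = _subtree_stats(node.right)
    return rl + rr, nl + nr


def _copy_tree(node: TreeNode) -> TreeNode:
    new = TreeNode(node.node_id, node.depth, node.counts.copy(), node.gini,
                   node.split_var, node.split_kind, node.threshold,
                   node.left_levels, node.improve)
    if not node.is_leaf:
        new.left = _copy_tree(node.left)
        new.right = _copy_tree(node.right)
    return new


def _weakest_link_sequence(root: TreeNode,
                           root_risk: float) -> list[tuple[float, TreeNode]]:
    """Cost-complexity sequence [(alpha_k, tree_k)], alpha on the relative
    scale (risk divided by root risk), alpha_0 = 0 for the full tree."""
    tree = _copy_tree(root)
    seq = [(0.0, _copy_tree(tree))]
    while not tree.is_leaf:
        best_g, targets = np.inf, []
        for nd in _walk(tree):
            if nd.is_leaf:
                continue
            risk_sub, leaves = _subtree_stats(nd)
            g = (nd.risk - risk_sub) / (leaves - 1) / root_risk
            if g < best_g - 1e-12:
                best_g, targets = g, [nd]
            elif g <= best_g + 1e-12:
                targets.append(nd)
        for nd in targets:  # collapse every node attaining the minimum
            nd.left = nd.right = None
            nd.split_var = None
        seq.append((best_g, _copy_tree(tree)))
    return seq


def _tree_rel_error(node: TreeNode, root_risk: float) -> float:
    risk_sub, _ = _subtree_stats(node)
    return risk_sub / root_risk


def _prune_at(root: TreeNode, cp: float, root_risk: float) -> TreeNode:
    """Weakest-link pruning: collapse while the weakest g is below cp."""
    tree = _copy_tree(root)
    while not tree.is_leaf:
        weakest_g, weakest = np.inf, []
        for nd in _walk(tree):
            if nd.is_leaf:
                continue
            risk_sub, leaves = _subtree_stats(nd)
            g = (nd.risk - risk_sub) / (leaves - 1) / root_risk
            if g < weakest_g - 1e-12:
                weakest_g, weakest = g, [nd]
            elif g <= weakest_g + 1e-12:
                weakest.append(nd)
        if weakest_g >= cp:
            break
        for nd in weakest:
            nd.left = nd.right = None
            nd.split_var = None
    return tree


def fit_cart(cohort: pd.DataFrame, outcome: str,
             variables: list[str] | None = None,
             minsplit: int = 20, minbucket: int = 7, maxdepth: int = 30,
             xval_folds: int = 10, seed: int = 0) -> DecisionTree:
    """Grow a CART classifier with pruning table and variable importance.

    Splits maximise the decrease in Gini impurity; continuous candidates
    are midpoints between adjacent distinct values, categorical splits use
    the success-rate-ordering reduction (exact for a binary outcome).
    Growth stops at ``minsplit``/``minbucket``/``maxdepth``.  The full
    weakest-link pruning sequence is built on the misclassification-risk
    scale and, with ``xval_folds > 1``, each pruning level's error is
    cross-validated (fold assignment from ``seed``).  Importance is the
    percent share of summed realised impurity decreases at primary splits
    (surrogate splits are not implemented).
    """
    data = cohort.dropna(subset=[outcome]).reset_index(drop=True)
    if variables is None:
        variables = [c for c in data.columns if c not in (outcome, "case_id")]
    data = data.dropna(subset=variables).reset_index(drop=True)
    y = data[outcome].to_numpy(dtype=int)
    params = {"minsplit": minsplit, "minbucket": minbucket,
              "maxdepth": maxdepth}
    cat_levels = {v: sorted(map(str, pd.unique(data[v].dropna())))
                  for v in variables
                  if not pd.api.types.is_numeric_dtype(data[v])}
    if len(np.unique(y)) < 2:
        warnings.warn("outcome has a single class: returning a stump",
                      stacklevel=2)
        counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
        stump = TreeNode(0, 0, counts, 0.0)
        table = pd.DataFrame({"CP": [np.inf], "n_splits": [0],
                              "rel_error": [1.0], "xerror": [np.nan],
                              "xstd": [np.nan]})
        return DecisionTree(stump, variables, outcome, params, table, {},
                            cat_levels)

    root = _grow(data, y, variables, 0, params, [0], cat_levels)
    root_risk = max(root.risk, 1)

    seq = _weakest_link_sequence(root, root_risk)
    cps = [alpha for alpha, _ in seq]
    rows = []
    for k, (alpha, tree_k) in enumerate(seq):
        rows.append({"CP": alpha,
                     "n_splits": sum(1 for nd in _walk(tree_k)
                                     if not nd.is_leaf),
                     "rel_error": _tree_rel_error(tree_k, root_risk)})
    table = pd.DataFrame(rows)

    if xval_folds > 1 and len(data) >= xval_folds:
        xerr, xstd = _cross_validate(data, y, variables, params, cps,
                                     xval_folds, seed, root_risk, cat_levels)
        table["xerror"] = xerr
        table["xstd"] = xstd
    else:
        table["xerror"] = np.nan
        table["xstd"] = np.nan

    importance_raw: dict[str, float] = {}
    for nd in _walk(root):
        if not nd.is_leaf:
            importance_raw[nd.split_var] = (
                importance_raw.get(nd.split_var, 0.0) + nd.improve)
    total = sum(importance_raw.values())
    importance = {v: 100.0 * w / total for v, w in importance_raw.items()} \
        if total > 0 else {}
    return DecisionTree(root, variables, outcome, params, table, importance,
                        cat_levels)


def _cross_validate(data, y, variables, params, cps, folds, seed, root_risk,
                    cat_levels):
    rng = np.random.default_rng(seed)
    assign = rng.permutation(len(data)) % folds
    # evaluate each pruning level at the geometric mean of neighbouring CPs
    eval_cps = []
    for k, cp in enumerate(cps):
        if k + 1 < len(cps):
            lo = max(cp, 1e-12)
            hi = max(cps[k + 1], 1e-12)
            eval_cps.append(float(np.sqrt(lo * hi)))
        else:
            eval_cps.append(np.inf if cp == 0 else cp * 1.0 + 1e-9)
    eval_cps[-1] = max(cps[-1], eval_cps[-1])
    losses = np.zeros((len(cps), len(data)))
    for f in range(folds):
        train = data[assign != f]
        ytr = y[assign != f]
        hold = data[assign == f]
        yho = y[assign == f]
        if len(np.unique(ytr)) < 2 or len(hold) == 0:
            continue
        sub_root = _grow(train.reset_index(drop=True), ytr, variables, 0,
                         params, [0], cat_levels)
        sub_risk = max(sub_root.risk, 1)
        for k, cp in enumerate(eval_cps):
            pruned = _prune_at(sub_root, cp, sub_risk)
            pred = np.array([_leaf_for(pruned, row).pred_class
                             for _, row in hold.iterrows()])
            losses[k, assign == f] = (pred != yho).astype(float)
    xerr = losses.sum(axis=1) / root_risk
    xstd = losses.std(axis=1, ddof=1) * np.sqrt(len(data)) / root_risk
    return xerr, xstd


def prune_tree(tree: DecisionTree, cp: float) -> DecisionTree:
    """Prune a fitted tree at complexity parameter ``cp``.

    Branches whose weakest-link improvement (on the relative risk scale)
    falls below ``cp`` are collapsed; ``cp = 0`` is a no-op and a ``cp``
    above the root split's improvement leaves only the root.  Pruning-table
    rows with CP below the threshold are dropped and importances are
    recomputed from the surviving splits.
    """
    if cp < 0:
        raise ValueError("cp must be >= 0")
    root_risk = max(tree.root.risk, 1)
    pruned_root = _prune_at(tree.root, cp, root_risk)
    table = tree.cp_table[tree.cp_table["CP"] >= cp].reset_index(drop=True)
    if table.empty:
        table = tree.cp_table.tail(1).reset_index(drop=True)
    importance_raw: dict[str, float] = {}
    for nd in _walk(pruned_root):
        if not nd.is_leaf:
            importance_raw[nd.split_var] = (
                importance_raw.get(nd.split_var, 0.0) + nd.improve)
    total = sum(importance_raw.values())
    importance = {v: 100.0 * w / total for v, w in importance_raw.items()} \
        if total > 0 else {}
    return DecisionTree(pruned_root, tree.variables, tree.outcome,
                        dict(tree.params), table, importance,
                        dict(tree.cat_levels))
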