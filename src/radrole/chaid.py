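"""Binary chi-square recursive-partitioning tree inducer.

The inducer grows a binary classification tree for the therapeutic role of
radiotherapy (curative C vs palliative P). At each node, every
classification variable is scanned for binary splits:

* a continuous variable contributes threshold candidates at the midpoints
  between consecutive distinct observed values (evenly subsampled to at
  most ``continuous_threshold_cap`` quantile midpoints);
* a categorical variable contributes the contiguous cuts of its levels
  sorted by palliative rate — for a binary outcome the chi-square-optimal
  binary partition is always among these k-1 cuts, which reduces the
  2^(k-1)-1 subset search to a linear scan.

Each candidate is scored by the Pearson chi-square statistic of its 2x2
split-by-outcome table (1 df, no continuity correction) and its p-value is
Bonferroni-adjusted by the number of candidates evaluated for that
variable. The most significant eligible candidate (adjusted p below
``alpha``, both children at least ``min_node`` records) forms the branch;
recursion stops when no candidate qualifies. Leaves are labelled by
majority outcome, exact ties going to C (the majority class overall).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from pandas.api.types import is_numeric_dtype
from scipy import stats

from .records import CURATIVE, PALLIATIVE

UNSPECIFIED = "unspecified"

KIND_THRESHOLD = "threshold"
KIND_PARTITION = "category-partition"


class MissingVariableError(LookupError):
    """A record lacks a variable needed on its path through the tree."""

    def __init__(self, variable: str):
        super().__init__(f"record is missing variable {variable!r} required on the tree path")
        self.variable = variable


@dataclass(frozen=True)
class InductionParams:
    """Tuning constants of the inducer.

    ``alpha`` is the retention threshold on the Bonferroni-adjusted p-value
    (default 0.2) and ``min_node`` the minimum child size (default 400);
    both defaults follow the Ontario reference analysis.
    """

    alpha: float = 0.2
    min_node: int = 400
    max_depth: int | None = None
    continuous_threshold_cap: int = 64
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.min_node < 1:
            raise ValueError("min_node must be >= 1")
        if self.continuous_threshold_cap < 1:
            raise ValueError("continuous_threshold_cap must be >= 1")


@dataclass(frozen=True)
class SplitCandidate:
    variable: str
    kind: str  # threshold | category-partition
    threshold: float | None
    left_categories: frozenset | None
    chi2: float
    p_raw: float
    bonferroni_multiplier: int
    p_adj: float
    child_sizes: tuple[int, int]

    def goes_left(self, value) -> bool:
        """Routing rule: `< threshold` / `in left set` goes left, so
        `>= threshold` goes right."""
        if self.kind == KIND_THRESHOLD:
            return float(value) < self.threshold
        return value in self.left_categories

    def describe(self) -> str:
        if self.kind == KIND_THRESHOLD:
            return f"{self.variable} >= {self.threshold:g}"
        cats = ", ".join(sorted(self.left_categories))
        return f"{self.variable} in {{{cats}}}"


@dataclass
class TreeNode:
    node_id: int
    n_curative: int
    n_palliative: int
    split: SplitCandidate | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: str | None = None  # set on leaves

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def support(self) -> int:
        return self.n_curative + self.n_palliative

    @property
    def proportions(self):
        n = self.support
        if n == 0:
            return None
        return (self.n_curative / n, self.n_palliative / n)


@dataclass
class ClassificationTree:
    root: TreeNode
    params: InductionParams
    variables: tuple[str, ...]
    provenance: str = ""

    # -- structure ---------------------------------------------------------
    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode):
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())

    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)

    # -- classification ----------------------------------------------------
    def classify(self, record):
        """Classify one record (mapping-like). Returns
        ``(label, leaf_id, proportions)``; raises
        :class:`MissingVariableError` if a variable on the path is missing.
        """
        node = self.root
        while not node.is_leaf:
            value = _get_value(record, node.split.variable)
            if value is None:
                raise MissingVariableError(node.split.variable)
            node = node.left if node.split.goes_left(value) else node.right
        return node.label, node.node_id, node.proportions

    def classify_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Vectorised classification of a complete-on-path record frame.

        Returns a frame aligned with the input with columns ``label`` and
        ``leaf_id``. Rows missing a variable on their path raise.
        """
        labels = pd.Series(index=frame.index, dtype=object)
        leaf_ids = pd.Series(index=frame.index, dtype="int64")

        def descend(node: TreeNode, mask: pd.Series):
            if not mask.any():
                return
            if node.is_leaf:
                labels[mask] = node.label
                leaf_ids[mask] = node.node_id
                return
            col = frame.loc[mask, node.split.variable]
            if col.isna().any():
                raise MissingVariableError(node.split.variable)
            if node.split.kind == KIND_THRESHOLD:
                go_left = col.astype(float) < node.split.threshold
            else:
                go_left = col.isin(node.split.left_categories)
            left_mask = mask.copy()
            left_mask[mask] = go_left.to_numpy()
            right_mask = mask & ~left_mask
            descend(node.left, left_mask)
            descend(node.right, right_mask)

        descend(self.root, pd.Series(True, index=frame.index))
        return pd.DataFrame({"label": labels, "leaf_id": leaf_ids})

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            d = {
                "node_id": node.node_id,
                "n_curative": node.n_curative,
                "n_palliative": node.n_palliative,
            }
            if node.is_leaf:
                d["label"] = node.label
            else:
                s = node.split
                d["split"] = {
                    "variable": s.variable,
                    "kind": s.kind,
                    "threshold": s.threshold,
                    "left_categories": sorted(s.left_categories) if s.left_categories else None,
                    "chi2": s.chi2,
                    "p_raw": s.p_raw,
                    "bonferroni_multiplier": s.bonferroni_multiplier,
                    "p_adj": s.p_adj,
                    "child_sizes": list(s.child_sizes),
                }
                d["left"] = node_dict(node.left)
                d["right"] = node_dict(node.right)
            return d

        return {
            "format": "radrole-tree-v1",
            "params": {
                "alpha": self.params.alpha,
                "min_node": self.params.min_node,
                "max_depth": self.params.max_depth,
                "continuous_threshold_cap": self.params.continuous_threshold_cap,
                "seed": self.params.seed,
            },
            "variables": list(self.variables),
            "provenance": self.provenance,
            "root": node_dict(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassificationTree":
        def build(nd: dict) -> TreeNode:
            if "split" in nd:
                s = nd["split"]
                split = SplitCandidate(
                    variable=s["variable"],
                    kind=s["kind"],
                    threshold=s["threshold"],
                    left_categories=(
                        frozenset(s["left_categories"]) if s["left_categories"] is not None else None
                    ),
                    chi2=s["chi2"],
                    p_raw=s["p_raw"],
                    bonferroni_multiplier=s["bonferroni_multiplier"],
                    p_adj=s["p_adj"],
                    child_sizes=tuple(s["child_sizes"]),
                )
                return TreeNode(
                    node_id=nd["node_id"],
                    n_curative=nd["n_curative"],
                    n_palliative=nd["n_palliative"],
                    split=split,
                    left=build(nd["left"]),
                    right=build(nd["right"]),
                )
            return TreeNode(
                node_id=nd["node_id"],
                n_curative=nd["n_curative"],
                n_palliative=nd["n_palliative"],
                label=nd["label"],
            )

        params = InductionParams(**d["params"])
        return cls(
            root=build(d["root"]),
            params=params,
            variables=tuple(d["variables"]),
            provenance=d.get("provenance", ""),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ClassificationTree":
        if isinstance(source, (str,)) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


def _get_value(record, variable):
    try:
        value = record[variable]
    except (KeyError, IndexError):
        return None
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    return value


# ---------------------------------------------------------------------------
# chi-square machinery
# ---------------------------------------------------------------------------


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 count table, 1 df, no continuity
    correction: ``n (ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))``. A zero marginal is
    a degenerate table and returns ``(0.0, 1.0)``.
    """
    (a, b), (c, d) = np.asarray(table, dtype=float)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if n == 0 or min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    statistic = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(statistic), float(stats.chi2.sf(statistic, 1))


def _chi2_vectorised(a, b, c, d):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    degenerate = (n == 0) | (np.minimum(np.minimum(r1, r2), np.minimum(c1, c2)) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        statistic = np.where(degenerate, 0.0, n * (a * d - b * c) ** 2 / np.where(denom == 0, 1.0, denom))
    p = np.where(degenerate, 1.0, stats.chi2.sf(statistic, 1))
    return statistic, p


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------


def _threshold_candidates(variable, x, y, params) -> list[SplitCandidate]:
    xs = np.sort(x)
    boundary = np.nonzero(np.diff(xs) > 0)[0]
    mids = (xs[boundary] + xs[boundary + 1]) / 2.0
    if len(mids) == 0:
        return []
    cap = params.continuous_threshold_cap
    if len(mids) > cap:
        idx = np.unique(np.round(np.linspace(0, len(mids) - 1, cap)).astype(int))
        mids = mids[idx]
    n = len(x)
    n_pos = int(y.sum())
    x_pos = np.sort(x[y])
    n_left = np.searchsorted(xs, mids)
    n_left_pos = np.searchsorted(x_pos, mids)
    a = n_left - n_left_pos  # curative, left
    b = n_left_pos  # palliative, left
    c = (n - n_left) - (n_pos - n_left_pos)
    d = n_pos - n_left_pos
    statistic, p = _chi2_vectorised(a, b, c, d)
    multiplier = len(mids)
    return [
        SplitCandidate(
            variable=variable,
            kind=KIND_THRESHOLD,
            threshold=float(t),
            left_categories=None,
            chi2=float(s),
            p_raw=float(pv),
            bonferroni_multiplier=multiplier,
            p_adj=float(min(1.0, pv * multiplier)),
            child_sizes=(int(nl), int(n - nl)),
        )
        for t, s, pv, nl in zip(mids, statistic, p, n_left)
    ]


def _partition_candidates(variable, values, y, params) -> list[SplitCandidate]:
    levels, inverse = np.unique(values, return_inverse=True)
    k = len(levels)
    if k < 2:
        return []
    totals = np.bincount(inverse, minlength=k)
    positives = np.bincount(inverse, weights=y.astype(float), minlength=k).astype(int)
    rates = positives / totals
    order = np.lexsort((levels, rates))  # palliative rate, ties by label
    n = len(values)
    n_pos = int(y.sum())
    cum_tot = np.cumsum(totals[order])[:-1]
    cum_pos = np.cumsum(positives[order])[:-1]
    a = cum_tot - cum_pos
    b = cum_pos
    c = (n - cum_tot) - (n_pos - cum_pos)
    d = n_pos - cum_pos
    statistic, p = _chi2_vectorised(a, b, c, d)
    multiplier = k - 1
    ordered_levels = levels[order]
    return [
        SplitCandidate(
            variable=variable,
            kind=KIND_PARTITION,
            threshold=None,
            left_categories=frozenset(ordered_levels[: j + 1]),
            chi2=float(statistic[j]),
            p_raw=float(p[j]),
            bonferroni_multiplier=multiplier,
            p_adj=float(min(1.0, p[j] * multiplier)),
            child_sizes=(int(cum_tot[j]), int(n - cum_tot[j])),
        )
        for j in range(k - 1)
    ]


def enumerate_candidate_splits(
    node_data: pd.DataFrame,
    variable: str,
    params: InductionParams,
    outcome: str = "intent_flag",
) -> list[SplitCandidate]:
    """Enumerate all binary split candidates of ``variable`` on this node.

    Rows must be complete on the variable (induction uses complete rows; the
    cascade handles missingness). A constant variable yields an empty list.
    The Bonferroni multiplier of every returned candidate equals the number
    of candidates evaluated for the variable; candidates whose children
    violate ``min_node`` are still returned (the selector excludes them).
    """
    col = node_data[variable]
    if col.isna().any():
        raise ValueError(f"variable {variable!r} has missing values in node data")
    y = (node_data[outcome] == PALLIATIVE).to_numpy()
    if is_numeric_dtype(col):
        return _threshold_candidates(variable, col.to_numpy(dtype=float), y, params)
    return _partition_candidates(variable, col.astype(str).to_numpy(), y, params)


def _tie_key(candidate: SplitCandidate):
    if candidate.kind == KIND_THRESHOLD:
        return (candidate.threshold,)
    return (len(candidate.left_categories), tuple(sorted(candidate.left_categories)))


def best_split(
    node_data: pd.DataFrame,
    variables,
    params: InductionParams,
    outcome: str = "intent_flag",
) -> SplitCandidate | None:
    """Most significant eligible split over all variables, or ``None``.

    Eligibility: both children >= ``min_node`` and adjusted p strictly below
    ``alpha``. Ties on adjusted p are broken by larger chi-square, then by
    position in ``variables``, then by smaller threshold / smaller left
    category set.
    """
    best = None
    best_key = None
    for vi, variable in enumerate(variables):
        for cand in enumerate_candidate_splits(node_data, variable, params, outcome):
            if min(cand.child_sizes) < params.min_node:
                continue
            if not (cand.p_adj < params.alpha):
                continue
            key = (cand.p_adj, -cand.chi2, vi, _tie_key(cand))
            if best is None or key < best_key:
                best, best_key = cand, key
    return best


def grow_tree(
    training_data: pd.DataFrame,
    variables,
    params: InductionParams | None = None,
    outcome: str = "intent_flag",
    provenance: str = "grown",
) -> ClassificationTree:
    """Grow a classification tree by recursive chi-square splitting.

    ``training_data`` must be complete on ``variables`` with the outcome in
    {C, P}. Deterministic given inputs and params; invariant to row order.
    """
    if params is None:
        params = InductionParams()
    if len(training_data) == 0:
        raise ValueError("training data is empty")
    observed = set(training_data[outcome].dropna().unique())
    if not observed <= {CURATIVE, PALLIATIVE}:
        raise ValueError(f"outcome must be within {{C, P}}, found {sorted(observed)}")
    if training_data[outcome].isna().any():
        raise ValueError("outcome has missing values")
    variables = tuple(variables)

    counter = iter(range(10**9))

    def build(sub: pd.DataFrame, depth: int) -> TreeNode:
        node_id = next(counter)
        n_pos = int((sub[outcome] == PALLIATIVE).sum())
        n_neg = len(sub) - n_pos
        label = PALLIATIVE if n_pos > n_neg else CURATIVE  # tie -> C
        node = TreeNode(node_id=node_id, n_curative=n_neg, n_palliative=n_pos, label=label)
        if n_pos == 0 or n_neg == 0:
            return node
        if params.max_depth is not None and depth >= params.max_depth:
            return node
        if len(sub) < 2 * params.min_node:
            return node
        cand = best_split(sub, variables, params, outcome)
        if cand is None:
            return node
        col = sub[cand.variable]
        if cand.kind == KIND_THRESHOLD:
            go_left = col.astype(float) < cand.threshold
        else:
            go_left = col.isin(cand.left_categories)
        node.split = cand
        node.label = None
        node.left = build(sub[go_left], depth + 1)
        node.right = build(sub[~go_left], depth + 1)
        return node

    root = build(training_data, 0)
    return ClassificationTree(root=root, params=params, variables=variables, provenance=provenance)


def classify(tree: ClassificationTree, record):
    """Functional form of :meth:`ClassificationTree.classify`."""
    return tree.classify(record)
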