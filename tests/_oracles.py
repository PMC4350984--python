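"""Independent oracles used by the test suite.

These deliberately avoid the package's vectorised split-search code paths:
the split oracle enumerates every binary partition / threshold by brute
force with plain Python loops, so it can referee the inducer.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from pandas.api.types import is_numeric_dtype
from scipy import stats

from radrole.chaid import InductionParams, KIND_THRESHOLD


def pearson_2x2(a, b, c, d):
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if n == 0 or min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    s = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return s, float(stats.chi2.sf(s, 1))


def _canonical_partition(levels_left, levels_all):
    left = frozenset(levels_left)
    right = frozenset(levels_all) - left
    return frozenset({left, right})


def brute_force_best_split(df, variables, params: InductionParams, outcome="intent_flag"):
    """Exhaustive best split.

    Returns ``(best_p_adj, optimal_set)`` where ``optimal_set`` contains a
    canonical descriptor of every candidate attaining the optimum within
    1e-9: ``("threshold", var, t)`` or ``("partition", var, {left, right})``.
    Returns ``(None, set())`` when no candidate is eligible. The Bonferroni
    multiplier rule matches the inducer: number of candidates evaluated per
    variable (midpoints for continuous, k-1 for categorical).
    """
    y = (df[outcome] == "P").to_numpy()
    n = len(df)
    n_pos = int(y.sum())
    entries = []  # (p_adj, chi2, descriptor)
    for var in variables:
        col = df[var]
        if is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)
            vals = np.unique(x)
            mids = (vals[:-1] + vals[1:]) / 2.0
            mult = len(mids)
            for t in mids:
                left = x < t
                nl = int(left.sum())
                if min(nl, n - nl) < params.min_node:
                    continue
                b_ = int(y[left].sum())
                a_ = nl - b_
                d_ = n_pos - b_
                c_ = (n - nl) - d_
                s, p = pearson_2x2(a_, b_, c_, d_)
                p_adj = min(1.0, p * mult)
                if p_adj < params.alpha:
                    entries.append((p_adj, s, ("threshold", var, float(t))))
        else:
            vals = col.astype(str).to_numpy()
            levels = sorted(set(vals))
            k = len(levels)
            if k < 2:
                continue
            mult = k - 1  # inducer's multiplier rule
            for r in range(1, k):
                for subset in itertools.combinations(levels, r):
                    if levels[0] not in subset:
                        continue  # each unordered partition once
                    left = np.isin(vals, subset)
                    nl = int(left.sum())
                    if min(nl, n - nl) < params.min_node:
                        continue
                    b_ = int(y[left].sum())
                    a_ = nl - b_
                    d_ = n_pos - b_
                    c_ = (n - nl) - d_
                    s, p = pearson_2x2(a_, b_, c_, d_)
                    p_adj = min(1.0, p * mult)
                    if p_adj < params.alpha:
                        entries.append(
                            (p_adj, s, ("partition", var, _canonical_partition(subset, levels)))
                        )
    if not entries:
        return None, set()
    best_p = min(e[0] for e in entries)
    optimal = {e[2] for e in entries if e[0] <= best_p + 1e-9}
    return best_p, optimal


def describe_candidate(cand, df):
    """Canonical descriptor of an inducer candidate, for oracle comparison."""
    if cand.kind == KIND_THRESHOLD:
        return ("threshold", cand.variable, float(cand.threshold))
    levels = sorted(set(df[cand.variable].astype(str)))
    return ("partition", cand.variable, _canonical_partition(cand.left_categories, levels))


def mc_se_weighted_ratio(df, sample, truth_col, pred_col, target="P"):
    """Monte-Carlo standard error of the expansion-weighted sensitivity (or
    specificity for target 'C') under the realised design: the stratified
    binomial variance evaluated at the *population* stratum rates, so it
    stays positive when a finite sample happens to contain no errors."""
    se2_num = 0.0
    denom_total = 0.0
    terms = []
    for stratum, group in sample.groupby("audit_stratum"):
        w = float(group["weight"].iloc[0])
        in_denom = group[truth_col] == target
        d_h = int(in_denom.sum())
        if d_h == 0:
            continue
        pop = df[df["audit_stratum"] == stratum]
        pop_denom = pop[pop[truth_col] == target]
        if len(pop_denom) == 0:
            continue
        p_h = float((pop_denom[pred_col] == target).mean())
        denom_total += w * d_h
        terms.append((w, d_h, p_h))
    se2 = sum(w**2 * d * p * (1 - p) for w, d, p in terms) / denom_total**2
    return float(np.sqrt(se2))


def random_split_dataset(rng: np.random.Generator):
    """Small random dataset for the split-oracle property: <=200 rows,
    <=3 variables, categorical cardinality <=5, continuous values on a
    small grid (so the threshold cap never binds)."""
    n = int(rng.integers(20, 201))
    n_vars = int(rng.integers(1, 4))
    cols = {}
    variables = []
    signal = np.zeros(n)
    for j in range(n_vars):
        name = f"v{j}"
        if rng.random() < 0.5:
            x = rng.integers(0, 12, n).astype(float)
            signal = signal + rng.normal(0, 0.8) * (x - x.mean()) / (x.std() + 1e-9)
        else:
            k = int(rng.integers(2, 6))
            x = rng.choice(np.array([chr(65 + i) for i in range(k)], dtype=object), size=n)
            effects = rng.normal(0, 0.8, k)
            signal = signal + effects[np.array([ord(v) - 65 for v in x])]
        cols[name] = x
        variables.append(name)
    prob = 1.0 / (1.0 + np.exp(-(signal + rng.normal(0, 1, n))))
    y = rng.random(n) < prob
    df = pd.DataFrame(cols)
    df["intent_flag"] = np.where(y, "P", "C")
    params = InductionParams(
        alpha=float(rng.choice([0.2, 0.5, 1.0])),
        min_node=int(rng.choice([1, 5, 20])),
    )
    return df, variables, params
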