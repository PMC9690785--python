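"""Data-driven treatment-effect-heterogeneity discovery ("fit-the-fit").

Given per-unit individual treatment effect estimates, the procedure

1. fits a sequence of random forests in which candidate covariates enter
   stepwise, at each step keeping the covariate with the largest out-of-bag R^2
   gain and stopping when the percent improvement drops below 1%;
2. interprets the final forest by harvesting, pruning and deduplicating its
   root-to-leaf decision rules (inTrees-style), each rule being a conjunction
   of covariate conditions that defines a subpopulation; and
3. estimates each subgroup's treatment effect by averaging the individual
   effects of the units the rule captures, per posterior draw, yielding a
   credible interval per discovered subgroup.

The forest R^2 is evaluated out of bag: in-sample ensemble R^2 grows almost
mechanically with every added covariate and would rarely trigger the stopping
rule.  Percent improvement is measured relative to the current R^2 (floored at
0.01 so early steps with near-zero baseline do not divide by zero); the first
accepted covariate therefore simply needs an out-of-bag R^2 at least the
threshold above zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .causal_effects import EffectSummary, ITEMatrix

_TIE_EPS = 1e-10


@dataclass
class StepwiseTrace:
    """Record of the stepwise selection path."""

    steps: list[tuple[str, float, float]] = field(default_factory=list)
    # each step: (covariate name, oob R^2 after adding it, percent improvement)
    stopping_reason: str = ""

    @property
    def selected(self) -> list[str]:
        return [name for name, _, _ in self.steps]

    def validate(self, threshold: float) -> None:
        r2s = [r2 for _, r2, _ in self.steps]
        if any(b < a - 1e-12 for a, b in zip(r2s, r2s[1:])):
            raise ValueError("stepwise R^2 sequence must be nondecreasing")
        for _, _, pct in self.steps:
            if pct < threshold:
                raise ValueError("accepted step below the improvement threshold")


Condition = tuple[str, str, float]  # (covariate, "<=" or ">", threshold)


@dataclass
class SubgroupRule:
    """A conjunction of covariate conditions defining a subpopulation."""

    conditions: tuple[Condition, ...]
    support: float
    error: float  # within-rule mean squared deviation of the ITE responses
    effect: EffectSummary | None = None

    def mask(self, X: np.ndarray, names: list[str]) -> np.ndarray:
        m = np.ones(X.shape[0], dtype=bool)
        for name, op, val in self.conditions:
            col = X[:, names.index(name)]
            m &= (col <= val) if op == "<=" else (col > val)
        return m

    def describe(self) -> str:
        if not self.conditions:
            return "(all units)"
        return " AND ".join(f"{n} {op} {v:.4g}" for n, op, v in self.conditions)


def _resolve_leaf_size(min_samples_leaf: int | None, n: int) -> int:
    """Default leaf size scales with n (5% of the sample, floor 5).

    Small fixed leaves make every tree of a small-candidate-set forest carve
    the same deep noise splits; their correlated errors then shrink when any
    extra (even pure-noise) covariate decorrelates the trees, which inflates
    out-of-bag R^2 gains and defeats the stepwise stopping rule.  A leaf size
    proportional to n keeps the forest honest about noise.
    """
    return min_samples_leaf if min_samples_leaf is not None else max(5, -(-n // 20))


def _fit_rf(
    X: np.ndarray, y: np.ndarray, n_estimators: int, min_samples_leaf: int, seed: int
) -> RandomForestRegressor:
    rf = RandomForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        max_features=max(1, math.ceil(X.shape[1] / 3)),
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def stepwise_rf(
    ite_point_estimates: np.ndarray,
    covariates: np.ndarray,
    covariate_names: list[str],
    threshold: float = 1.0,
    n_estimators: int = 500,
    min_samples_leaf: int | None = None,
    seed: int = 0,
) -> tuple[StepwiseTrace, RandomForestRegressor | None, list[str]]:
    """Stepwise random-forest covariate selection on individual treatment effects.

    At each step one forest is fitted per remaining candidate (current set plus
    that candidate); the candidate with the largest out-of-bag R^2 gain wins
    (ties below 1e-10 go to the lower covariate index, for determinism).  The
    procedure stops when the best percent improvement falls below ``threshold``
    (in percent).  Returns the trace, the forest on the final selected set, and
    the selected names.
    """
    y = np.asarray(ite_point_estimates, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate covariates")
    if X.shape[0] != y.size:
        raise ValueError("responses and covariates disagree on the number of units")
    if np.ptp(y) == 0:
        return StepwiseTrace(stopping_reason="no-variance"), None, []
    min_samples_leaf = _resolve_leaf_size(min_samples_leaf, y.size)

    remaining = list(range(X.shape[1]))
    selected: list[int] = []
    trace = StepwiseTrace()
    r2_current = 0.0
    best_rf: RandomForestRegressor | None = None
    step = 0
    while remaining:
        best_j, best_r2, best_fit = None, -np.inf, None
        for j in remaining:
            rf = _fit_rf(
                X[:, selected + [j]], y, n_estimators, min_samples_leaf, seed + step
            )
            r2 = rf.oob_score_
            if r2 > best_r2 + _TIE_EPS:
                best_j, best_r2, best_fit = j, r2, rf
        pct = 100.0 * (best_r2 - r2_current) / max(abs(r2_current), 0.01)
        if pct < threshold or best_r2 <= r2_current:
            trace.stopping_reason = (
                "improvement-below-threshold" if trace.steps else "no-signal"
            )
            break
        selected.append(best_j)
        remaining.remove(best_j)
        trace.steps.append((covariate_names[best_j], float(best_r2), float(pct)))
        r2_current = best_r2
        best_rf = best_fit
        step += 1
    else:
        trace.stopping_reason = "all-covariates-selected"
    return trace, best_rf, [covariate_names[j] for j in selected]


# ---------------------------------------------------------------------------
# rule extraction (inTrees-style)
# ---------------------------------------------------------------------------

def _harvest_paths(tree, feature_names: list[str]) -> list[tuple[Condition, ...]]:
    """All root-to-leaf condition conjunctions of one fitted sklearn tree."""
    t = tree.tree_
    paths: list[tuple[Condition, ...]] = []

    def walk(node: int, conds: list[Condition]):
        if t.children_left[node] == -1:  # leaf
            paths.append(_simplify(conds))
            return
        name = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + [(name, "<=", thr)])
        walk(t.children_right[node], conds + [(name, ">", thr)])

    walk(0, [])
    return paths


def _simplify(conds: list[Condition]) -> tuple[Condition, ...]:
    """Merge repeated conditions on the same (covariate, direction): the
    tightest bound wins (min for <=, max for >)."""
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for name, op, val in conds:
        key = (name, op)
        if key not in best:
            best[key] = val
            order.append(key)
        else:
            best[key] = min(best[key], val) if op == "<=" else max(best[key], val)
    return tuple((name, op, best[(name, op)]) for name, op in order)


def _rule_error(mask: np.ndarray, y: np.ndarray) -> float:
    sub = y[mask]
    return float(np.mean((sub - sub.mean()) ** 2)) if sub.size else np.inf


def _mask_of(conds, X: np.ndarray, names: list[str]) -> np.ndarray:
    m = np.ones(X.shape[0], dtype=bool)
    for name, op, val in conds:
        col = X[:, names.index(name)]
        m &= (col <= val) if op == "<=" else (col > val)
    return m


def extract_rules(
    forest: RandomForestRegressor,
    covariates: np.ndarray,
    covariate_names: list[str],
    responses: np.ndarray,
    pruning_tolerance: float = 1e-3,
    max_trees: int | None = 100,
    max_rules: int | None = 50,
) -> list[SubgroupRule]:
    """Harvest, prune, deduplicate and rank decision rules from a fitted forest.

    Each root-to-leaf path becomes a candidate rule.  Conditions whose removal
    raises the rule's response error by less than ``pruning_tolerance`` are
    dropped (greedy, longest-rule-first within each rule).  Logically identical
    rules are merged, and the survivors are ranked by (error ascending, support
    descending, length ascending).
    """
    if forest is None or not getattr(forest, "estimators_", None):
        raise ValueError("forest is empty or not fitted")
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    y = np.asarray(responses, dtype=float)
    n = X.shape[0]

    estimators = forest.estimators_
    if max_trees is not None:
        estimators = estimators[:max_trees]
    seen: set = set()
    rules: list[SubgroupRule] = []
    for est in estimators:
        for conds in _harvest_paths(est, covariate_names):
            key = tuple(sorted((na, op, round(v, 10)) for na, op, v in conds))
            if key in seen:
                continue
            seen.add(key)
            mask = _mask_of(conds, X, covariate_names)
            if not mask.any():
                continue
            err = _rule_error(mask, y)
            # greedy pruning: drop any condition whose removal barely hurts
            conds_l = list(conds)
            changed = True
            while changed and len(conds_l) > 1:
                changed = False
                for i in range(len(conds_l)):
                    trial = conds_l[:i] + conds_l[i + 1:]
                    m2 = _mask_of(trial, X, covariate_names)
                    e2 = _rule_error(m2, y)
                    if e2 - err < pruning_tolerance:
                        conds_l, mask, err = trial, m2, min(err, e2)
                        changed = True
                        break
            pruned_key = tuple(sorted((na, op, round(v, 10)) for na, op, v in conds_l))
            if pruned_key != key and pruned_key in seen:
                continue
            seen.add(pruned_key)
            rules.append(
                (
                    mask.tobytes(),  # rules capturing the same units are one rule
                    SubgroupRule(
                        conditions=tuple(conds_l),
                        support=float(mask.sum()) / n,
                        error=err,
                    ),
                )
            )
    by_mask: dict[bytes, SubgroupRule] = {}
    for mask_key, rule in rules:
        prev = by_mask.get(mask_key)
        if prev is None or len(rule.conditions) < len(prev.conditions):
            by_mask[mask_key] = rule
    # rank by error quantized in units of 1% of the response variance, so
    # rules that are equally pure compete on support (broad beats narrow),
    # then on brevity; raw error would rank accidental micro-subsets first
    var_y = max(float(np.var(y)), 1e-12)
    rules = sorted(
        by_mask.values(),
        key=lambda r: (round(r.error / var_y, 2), -r.support, len(r.conditions)),
    )
    if max_rules is not None:
        rules = rules[:max_rules]
    return rules


def subgroup_effects(
    rules: list[SubgroupRule],
    ite: ITEMatrix,
    covariates: np.ndarray,
    covariate_names: list[str],
    scale: str = "diff",
) -> list[SubgroupRule]:
    """Attach a subgroup effect estimate and credible interval to each rule.

    Per rule and retained posterior draw, the contrasts of the units the rule
    captures are averaged (geometric mean on the ratio scale); the draws of
    that average give the posterior mean and a 95% equal-tail interval.  The
    rules are FIXED across draws: selection uncertainty is not propagated.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    vals = ite.values(scale)
    out = []
    for rule in rules:
        mask = rule.mask(X, covariate_names)
        if not mask.any():
            raise ValueError(f"rule {rule.describe()!r} matches zero units")
        sub = vals[:, mask]
        per_draw = (
            np.exp(np.log(sub).mean(axis=1)) if scale == "ratio" else sub.mean(axis=1)
        )
        lo, hi = np.percentile(per_draw, [2.5, 97.5])
        eff = EffectSummary(
            estimate=float(np.clip(per_draw.mean(), lo, hi)),
            lower=float(lo),
            upper=float(hi),
            scale=scale,
            pair=ite.pair,
        )
        out.append(replace(rule, effect=eff))
    return out


def discover_teh(
    ite: ITEMatrix,
    covariates: np.ndarray,
    covariate_names: list[str],
    scale: str = "diff",
    threshold: float = 1.0,
    n_estimators: int = 500,
    pruning_tolerance: float = 1e-3,
    seed: int = 0,
) -> tuple[StepwiseTrace, list[SubgroupRule]]:
    """End-to-end fit-the-fit: stepwise selection, rule extraction, subgroup
    effect estimation.  Returns the stepwise trace and the ranked rules."""
    responses = ite.point_estimates(scale)
    trace, forest, selected = stepwise_rf(
        responses, covariates, covariate_names,
        threshold=threshold, n_estimators=n_estimators, seed=seed,
    )
    if forest is None or not selected:
        return trace, []
    cols = [covariate_names.index(s) for s in selected]
    rules = extract_rules(
        forest, covariates[:, cols], selected, responses,
        pruning_tolerance=pruning_tolerance,
    )
    rules = subgroup_effects(rules, ite, covariates[:, cols], selected, scale)
    return trace, rules
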