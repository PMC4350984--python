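"""Tree-to-rule conversion: ordered conjunctive classification rules.

Every leaf of a classification tree yields exactly one rule whose
conditions are the root-to-leaf path, so the rule set partitions the space
of complete records and applying it is equivalent to tree descent. Rules
are deliberately not simplified or merged — that equivalence is the
contract. The plain-text grammar (``render_rules`` / ``parse_rules``) is
versioned and round-trips.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chaid import (
    KIND_THRESHOLD,
    ClassificationTree,
    MissingVariableError,
    TreeNode,
    _get_value,
)

GRAMMAR_HEADER = "# radrole rules v1"

#: units rendered after threshold values, keyed by variable
UNITS = {"fraction_size": "cGy", "days_from_first": "days"}

REL_GE = ">="
REL_LT = "<"
REL_IN = "IN"
REL_NOT_IN = "NOT IN"


@dataclass(frozen=True)
class Condition:
    variable: str
    relation: str  # >= | < | IN | NOT IN
    value: float | frozenset

    def holds(self, value) -> bool:
        if self.relation == REL_GE:
            return float(value) >= self.value
        if self.relation == REL_LT:
            return float(value) < self.value
        if self.relation == REL_IN:
            return value in self.value
        return value not in self.value


@dataclass(frozen=True)
class Rule:
    rule_id: int
    conditions: tuple[Condition, ...]
    label: str
    support: int | None = None
    purity: float | None = None

    def matches(self, record) -> bool:
        """True if every condition holds; raises on a missing variable."""
        for cond in self.conditions:
            value = _get_value(record, cond.variable)
            if value is None:
                raise MissingVariableError(cond.variable)
            if not cond.holds(value):
                return False
        return True


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[Rule, ...]
    variables: tuple[str, ...] = ()
    provenance: str = ""

    def __len__(self):
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_rules(tree: ClassificationTree) -> RuleSet:
    """One rule per leaf, conditions in root-to-leaf order, leaves visited
    left-first so rule ids match leaf order."""
    rules: list[Rule] = []

    def walk(node: TreeNode, path: tuple[Condition, ...]):
        if node.is_leaf:
            support = node.support if node.support > 0 else None
            purity = None
            if support:
                purity = max(node.n_curative, node.n_palliative) / support
            rules.append(
                Rule(
                    rule_id=len(rules) + 1,
                    conditions=path,
                    label=node.label,
                    support=support,
                    purity=purity,
                )
            )
            return
        s = node.split
        if s.kind == KIND_THRESHOLD:
            left_cond = Condition(s.variable, REL_LT, s.threshold)
            right_cond = Condition(s.variable, REL_GE, s.threshold)
        else:
            left_cond = Condition(s.variable, REL_IN, s.left_categories)
            right_cond = Condition(s.variable, REL_NOT_IN, s.left_categories)
        walk(node.left, path + (left_cond,))
        walk(node.right, path + (right_cond,))

    walk(tree.root, ())
    return RuleSet(rules=tuple(rules), variables=tree.variables, provenance=tree.provenance)


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------


def apply_rules(ruleset: RuleSet, record):
    """Classify one record; returns ``(label, rule_id)``.

    Exactly one rule matches any record complete on the variables along its
    path; a missing variable on that path raises
    :class:`~radrole.chaid.MissingVariableError`.
    """
    deferred: MissingVariableError | None = None
    for rule in ruleset.rules:
        try:
            if rule.matches(record):
                return rule.label, rule.rule_id
        except MissingVariableError as exc:
            deferred = exc
    if deferred is not None:
        raise deferred
    raise RuntimeError("no rule matched a complete record; rule set is not a partition")


def apply_rules_frame(ruleset: RuleSet, frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorised rule application; returns columns ``label``/``rule_id``."""
    labels = pd.Series(index=frame.index, dtype=object)
    rule_ids = pd.Series(np.nan, index=frame.index)
    unmatched = pd.Series(True, index=frame.index)
    for rule in ruleset.rules:
        mask = unmatched.copy()
        for cond in rule.conditions:
            col = frame[cond.variable]
            if cond.relation == REL_GE:
                ok = col.astype(float) >= cond.value
            elif cond.relation == REL_LT:
                ok = col.astype(float) < cond.value
            elif cond.relation == REL_IN:
                ok = col.isin(cond.value)
            else:
                ok = ~col.isin(cond.value) & col.notna()
            mask &= ok.fillna(False)
        labels[mask] = rule.label
        rule_ids[mask] = rule.rule_id
        unmatched &= ~mask
    if unmatched.any():
        raise MissingVariableError("<one or more variables>")
    return pd.DataFrame({"label": labels, "rule_id": rule_ids.astype(int)})


# ---------------------------------------------------------------------------
# text grammar
# ---------------------------------------------------------------------------


def _render_value(v) -> str:
    # str(float) round-trips exactly in Python
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def _render_condition(cond: Condition) -> str:
    if cond.relation in (REL_GE, REL_LT):
        unit = UNITS.get(cond.variable)
        suffix = f" {unit}" if unit else ""
        return f"{cond.variable} {cond.relation} {_render_value(cond.value)}{suffix}"
    cats = "; ".join(sorted(cond.value))
    return f"{cond.variable} {cond.relation} {{{cats}}}"


def render_rules(ruleset: RuleSet) -> str:
    """Numbered IF/THEN listing, one line per rule, stable ordering."""
    lines = [GRAMMAR_HEADER]
    if ruleset.provenance:
        lines.append(f"# provenance: {ruleset.provenance}")
    if ruleset.variables:
        lines.append("# variables: " + ", ".join(ruleset.variables))
    for rule in ruleset.rules:
        cond_text = " AND ".join(_render_condition(c) for c in rule.conditions) or "TRUE"
        support = "na" if rule.support is None else str(rule.support)
        purity = "na" if rule.purity is None else _render_value(float(rule.purity))
        lines.append(
            f"RULE {rule.rule_id}: IF {cond_text} THEN {rule.label}"
            f" (support={support}, purity={purity})"
        )
    return "\n".join(lines) + "\n"


_RULE_RE = re.compile(
    r"^RULE (\d+): IF (.*) THEN (\S+) \(support=(\S+), purity=(\S+)\)$"
)
_SET_COND_RE = re.compile(r"^(\w+) (NOT IN|IN) \{(.*)\}$")
_THR_COND_RE = re.compile(r"^(\w+) (>=|<) ([0-9eE.+-]+)(?: (\w+))?$")


def _parse_condition(text: str) -> Condition:
    m = _SET_COND_RE.match(text)
    if m:
        variable, relation, body = m.groups()
        cats = frozenset(c for c in (s.strip() for s in body.split(";")) if c)
        return Condition(variable, relation, cats)
    m = _THR_COND_RE.match(text)
    if m:
        variable, relation, value, unit = m.groups()
        if unit is not None and unit != UNITS.get(variable):
            raise ValueError(f"unexpected unit {unit!r} for variable {variable!r}")
        return Condition(variable, relation, float(value))
    raise ValueError(f"unparseable condition: {text!r}")


def parse_rules(text: str) -> RuleSet:
    """Parse the output of :func:`render_rules`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != GRAMMAR_HEADER:
        raise ValueError(f"expected header {GRAMMAR_HEADER!r}")
    provenance = ""
    declared_variables: tuple[str, ...] | None = None
    rules: list[Rule] = []
    for line in lines[1:]:
        if line.startswith("# provenance: "):
            provenance = line[len("# provenance: "):]
            continue
        if line.startswith("# variables: "):
            declared_variables = tuple(
                v.strip() for v in line[len("# variables: "):].split(",") if v.strip()
            )
            continue
        if line.startswith("#"):
            continue
        m = _RULE_RE.match(line)
        if not m:
            raise ValueError(f"unparseable rule line: {line!r}")
        rule_id, cond_text, label, support, purity = m.groups()
        conditions: tuple[Condition, ...] = ()
        if cond_text != "TRUE":
            conditions = tuple(_parse_condition(c) for c in cond_text.split(" AND "))
        rules.append(
            Rule(
                rule_id=int(rule_id),
                conditions=conditions,
                label=label,
                support=None if support == "na" else int(support),
                purity=None if purity == "na" else float(purity),
            )
        )
    if declared_variables is None:
        seen: list[str] = []
        for rule in rules:
            for cond in rule.conditions:
                if cond.variable not in seen:
                    seen.append(cond.variable)
        declared_variables = tuple(seen)
    return RuleSet(rules=tuple(rules), variables=declared_variables, provenance=provenance)


# ---------------------------------------------------------------------------
# JSON serialisation
# ---------------------------------------------------------------------------


def ruleset_to_dict(ruleset: RuleSet) -> dict:
    return {
        "format": "radrole-rules-v1",
        "provenance": ruleset.provenance,
        "variables": list(ruleset.variables),
        "rules": [
            {
                "rule_id": r.rule_id,
                "label": r.label,
                "support": r.support,
                "purity": r.purity,
                "conditions": [
                    {
                        "variable": c.variable,
                        "relation": c.relation,
                        "value": sorted(c.value) if isinstance(c.value, frozenset) else c.value,
                    }
                    for c in r.conditions
                ],
            }
            for r in ruleset.rules
        ],
    }


def ruleset_from_dict(d: dict) -> RuleSet:
    rules = tuple(
        Rule(
            rule_id=rd["rule_id"],
            label=rd["label"],
            support=rd["support"],
            purity=rd["purity"],
            conditions=tuple(
                Condition(
                    cd["variable"],
                    cd["relation"],
                    frozenset(cd["value"]) if isinstance(cd["value"], list) else float(cd["value"]),
                )
                for cd in rd["conditions"]
            ),
        )
        for rd in d["rules"]
    )
    return RuleSet(rules=rules, variables=tuple(d["variables"]), provenance=d.get("provenance", ""))


def ruleset_to_json(ruleset: RuleSet, path=None) -> str:
    text = json.dumps(ruleset_to_dict(ruleset), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def ruleset_from_json(source) -> RuleSet:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        return ruleset_from_dict(json.loads(source))
    with open(source) as fh:
        return ruleset_from_dict(json.load(fh))
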