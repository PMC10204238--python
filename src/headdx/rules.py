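"""Declarative diagnostic-criteria engine.

The diagnostic criteria for each headache category are shipped as an editable
YAML document (``data/rules_ichd3.yaml``). Each diagnosis carries named
criterion groups (A, B, C, ...) whose predicates are written in a small
expression grammar evaluated over a flat view of the patient record:

* comparisons: ``==  !=  <  <=  >  >=`` (chained comparisons allowed)
* boolean connectives: ``and  or  not``
* set membership: ``'orbital' in locations``
* ``count(e1, e2, ...)`` — number of truthy arguments

Names resolve against the context fields listed in :data:`CONTEXT_FIELDS`.
A name whose value is missing (``None``) makes the group *not assessable*;
not-assessable groups are counted as failed, so incomplete data can at most
yield a probable diagnosis or OTHERS, never a definite label.

Diagnosis proceeds in two steps. ``evaluate_criteria`` scores every
criterion group of every encoded diagnosis; ``diagnose_rules`` then picks
the fully-met candidates (resolving conflicts by a configurable precedence
in which medication-overuse headache outranks everything, in particular
chronic migraine), falls back to the probable categories when exactly one
criterion group is missed on the migraine or tension-type side, and hands
the PM-versus-PTTH differential to case-based reasoning when both sides are
one group short.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

from .records import (
    SHORT_ACTING_CLASSES,
    CriteriaEvaluation,
    DiagnosisLabel,
    PatientRecord,
)

__all__ = [
    "CONTEXT_FIELDS", "CriterionRule", "RuleSet", "RuleSchemaError",
    "Ambiguous", "load_rules", "dump_rules", "default_rules",
    "build_context", "evaluate_criteria", "diagnose_rules", "resolve_priority",
]


class RuleSchemaError(ValueError):
    """Raised when a rule file does not conform to the rule schema."""


class NotAssessable(Exception):
    def __init__(self, name: str):
        super().__init__(name)
        self.name = name


#: names the expression grammar may reference, with a short gloss
CONTEXT_FIELDS: dict[str, str] = {
    "age": "age in years",
    "sex": "'female' or 'male'",
    "disease_duration_months": "months since headaches began",
    "onset_abrupt": "headache began abruptly",
    "daily_from_onset": "headache daily and unremitting since onset",
    "onset_clearly_remembered": "patient clearly remembers the onset",
    "headache_days_per_month": "headache days/month, 3-month average",
    "migraine_like_days_per_month": "days/month with migraine-like features",
    "attack_count": "lifetime number of attacks of this headache",
    "locations": "set of body-map region tokens",
    "unilateral": "strictly one-sided pain",
    "bilateral": "two-sided pain",
    "pulsating": "pulsating/throbbing quality",
    "pressing_tightening": "pressing or tightening quality",
    "stabbing_or_electric": "stabbing or electric-shock quality",
    "orbital_temporal_pain": "orbital, supraorbital or temporal location",
    "vas": "pain intensity, visual analog scale 1-10",
    "duration_minutes": "untreated attack duration in minutes",
    "frequency_per_day": "attacks per day",
    "trigger_evoked": "attacks triggered by innocuous stimuli",
    "nausea": "nausea during attacks",
    "vomiting": "vomiting during attacks",
    "mild_nausea_only": "nausea present but never more than mild",
    "photophobia": "light sensitivity",
    "phonophobia": "sound sensitivity",
    "aggravated": "aggravated by routine physical activity",
    "restlessness": "restlessness or agitation during attacks",
    "autonomic_any": "any cranial autonomic feature",
    "autonomic_ipsilateral": "autonomic features ipsilateral to the pain",
    "aura_present": "aura before or during headache",
    "aura_symptom_count": "number of distinct reversible aura symptoms",
    "aura_duration_5_60": "each aura symptom lasts 5-60 minutes",
    "aura_gradual_spread": "an aura symptom spreads gradually over >=5 min",
    "aura_headache_within_60": "headache follows aura within 60 minutes",
    "overuse_short_acting": "triptan/ergot/opioid/combination >=10 days/month for >3 months",
    "overuse_simple": "simple analgesic or NSAID >=15 days/month for >3 months",
}

_ALLOWED_CALLS = {"count"}


@dataclass(frozen=True)
class CriterionRule:
    rule_id: str
    diagnosis: DiagnosisLabel
    criterion_group: str
    predicate: str
    description: str
    _tree: ast.Expression = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[CriterionRule, ...]
    priority: tuple[DiagnosisLabel, ...]

    def groups_for(self, label: DiagnosisLabel) -> list[CriterionRule]:
        return [r for r in self.rules if r.diagnosis == label]

    @property
    def diagnoses(self) -> list[DiagnosisLabel]:
        seen: list[DiagnosisLabel] = []
        for r in self.rules:
            if r.diagnosis not in seen:
                seen.append(r.diagnosis)
        return seen


@dataclass(frozen=True)
class Ambiguous:
    """Rule engine outcome when the record is one criterion group short of
    both a migraine and a tension-type diagnosis; settled by CBR."""

    candidates: frozenset[DiagnosisLabel]


# ---------------------------------------------------------------------------
# expression grammar
# ---------------------------------------------------------------------------

def _validate_expr(expr: str, rule_id: str) -> ast.Expression:
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise RuleSchemaError(f"{rule_id}: cannot parse {expr!r}: {exc}") from None
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            if node.id not in CONTEXT_FIELDS and node.id not in _ALLOWED_CALLS:
                raise RuleSchemaError(
                    f"{rule_id}: undeclared field {node.id!r} in clause {expr!r}")
        elif isinstance(node, ast.Call):
            if not (isinstance(node.func, ast.Name) and node.func.id in _ALLOWED_CALLS):
                raise RuleSchemaError(f"{rule_id}: only count(...) may be called")
        elif isinstance(node, (ast.Expression, ast.BoolOp, ast.UnaryOp, ast.Not,
                               ast.Compare, ast.Constant, ast.And, ast.Or,
                               ast.Load, ast.Eq, ast.NotEq, ast.Lt, ast.LtE,
                               ast.Gt, ast.GtE, ast.In, ast.NotIn)):
            continue
        else:
            raise RuleSchemaError(
                f"{rule_id}: construct {type(node).__name__} not allowed in {expr!r}")
    return tree


def _eval_node(node: ast.AST, ctx: Mapping[str, object]):
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, ctx)
    if isinstance(node, ast.Constant):
        return node.value
    if isinstance(node, ast.Name):
        value = ctx[node.id]
        if value is None:
            raise NotAssessable(node.id)
        return value
    if isinstance(node, ast.BoolOp):
        is_and = isinstance(node.op, ast.And)
        pending = None
        for sub in node.values:
            try:
                val = bool(_eval_node(sub, ctx))
            except NotAssessable as exc:
                pending = exc
                continue
            if is_and and not val:
                return False
            if not is_and and val:
                return True
        if pending is not None:
            raise pending
        return is_and
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
        return not _eval_node(node.operand, ctx)
    if isinstance(node, ast.Compare):
        left = _eval_node(node.left, ctx)
        for op, comparator in zip(node.ops, node.comparators):
            right = _eval_node(comparator, ctx)
            ok = {
                ast.Eq: lambda a, b: a == b,
                ast.NotEq: lambda a, b: a != b,
                ast.Lt: lambda a, b: a < b,
                ast.LtE: lambda a, b: a <= b,
                ast.Gt: lambda a, b: a > b,
                ast.GtE: lambda a, b: a >= b,
                ast.In: lambda a, b: a in b,
                ast.NotIn: lambda a, b: a not in b,
            }[type(op)](left, right)
            if not ok:
                return False
            left = right
        return True
    if isinstance(node, ast.Call):  # count(...)
        total = 0
        for arg in node.args:
            if bool(_eval_node(arg, ctx)):
                total += 1
        return total
    raise AssertionError(f"unreachable node {node!r}")


def build_context(record: PatientRecord) -> dict[str, object]:
    """Flatten a record into the name space the rule grammar evaluates over."""
    overuse_short = any(
        m.drug_class in SHORT_ACTING_CLASSES
        and m.intake_days_per_month >= 10 and m.months_of_regular_use > 3
        for m in record.medication)
    overuse_simple = any(
        m.drug_class in ("simple_analgesic", "nsaid")
        and m.intake_days_per_month >= 15 and m.months_of_regular_use > 3
        for m in record.medication)
    pain, assoc, aura = record.pain, record.associated, record.aura
    return {
        "age": record.demographics.age,
        "sex": record.demographics.sex,
        "disease_duration_months": record.course.disease_duration_months,
        "onset_abrupt": record.course.onset_abrupt,
        "daily_from_onset": record.course.daily_from_onset,
        "onset_clearly_remembered": record.course.onset_clearly_remembered,
        "headache_days_per_month": record.course.headache_days_per_month,
        "migraine_like_days_per_month": record.course.migraine_like_days_per_month,
        "attack_count": record.course.lifetime_attack_count,
        "locations": pain.locations,
        "unilateral": pain.laterality == "unilateral",
        "bilateral": pain.laterality == "bilateral",
        "pulsating": "pulsating" in pain.qualities,
        "pressing_tightening": "pressing_tightening" in pain.qualities,
        "stabbing_or_electric": bool(pain.qualities & {"stabbing", "electric_shock"}),
        "orbital_temporal_pain": bool(
            pain.locations & {"orbital", "supraorbital", "temporal"}),
        "vas": pain.vas,
        "duration_minutes": record.attack.duration_minutes_untreated,
        "frequency_per_day": record.attack.frequency_per_day,
        "trigger_evoked": record.attack.trigger_evoked,
        "nausea": assoc.nausea,
        "vomiting": assoc.vomiting,
        "mild_nausea_only": assoc.mild_nausea_only,
        "photophobia": assoc.photophobia,
        "phonophobia": assoc.phonophobia,
        "aggravated": assoc.aggravated_by_routine_activity,
        "restlessness": assoc.restlessness_agitation,
        "autonomic_any": record.autonomic.any_feature,
        "autonomic_ipsilateral": record.autonomic.ipsilateral,
        "aura_present": aura.present,
        "aura_symptom_count": len(aura.symptoms),
        "aura_duration_5_60": aura.each_symptom_5_to_60_min,
        "aura_gradual_spread": aura.gradual_spread_ge_5_min,
        "aura_headache_within_60": aura.headache_within_60_min,
        "overuse_short_acting": overuse_short,
        "overuse_simple": overuse_simple,
    }


# ---------------------------------------------------------------------------
# loading / dumping
# ---------------------------------------------------------------------------

def _parse_ruleset(doc: dict, origin: str) -> RuleSet:
    if not isinstance(doc, dict):
        raise RuleSchemaError(f"{origin}: top level must be a mapping")
    unknown = set(doc) - {"priority", "diagnoses"}
    if unknown:
        raise RuleSchemaError(f"{origin}: unknown top-level keys {sorted(unknown)}")
    try:
        priority = tuple(DiagnosisLabel(t) for t in doc["priority"])
    except (KeyError, ValueError) as exc:
        raise RuleSchemaError(f"{origin}: bad priority list: {exc}") from None
    if set(priority) != set(DiagnosisLabel):
        raise RuleSchemaError(f"{origin}: priority must rank every label exactly once")
    rules: list[CriterionRule] = []
    for diag_token, groups in doc.get("diagnoses", {}).items():
        try:
            diag = DiagnosisLabel(diag_token)
        except ValueError:
            raise RuleSchemaError(f"{origin}: unknown diagnosis {diag_token!r}") from None
        if not isinstance(groups, dict) or len(groups) < 2:
            raise RuleSchemaError(
                f"{origin}: {diag_token} must define at least two criterion groups")
        for group, body in groups.items():
            rid = f"{diag_token}.{group}"
            if not isinstance(body, dict) or set(body) - {"expr", "description"}:
                raise RuleSchemaError(
                    f"{rid}: groups carry exactly 'expr' and 'description'")
            expr = body.get("expr")
            if not isinstance(expr, str):
                raise RuleSchemaError(f"{rid}: missing expr")
            tree = _validate_expr(expr, rid)
            rules.append(CriterionRule(
                rule_id=rid, diagnosis=diag, criterion_group=str(group),
                predicate=expr, description=str(body.get("description", "")),
                _tree=tree))
    if not rules:
        raise RuleSchemaError(f"{origin}: no diagnoses defined")
    return RuleSet(rules=tuple(rules), priority=priority)


def load_rules(path: Union[str, Path]) -> RuleSet:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_ruleset(doc, str(path))


def dump_rules(rules: RuleSet, path: Union[str, Path]) -> None:
    doc: dict = {"priority": [p.value for p in rules.priority], "diagnoses": {}}
    for r in rules.rules:
        doc["diagnoses"].setdefault(r.diagnosis.value, {})[r.criterion_group] = {
            "expr": r.predicate, "description": r.description}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


_DEFAULT_CACHE: RuleSet | None = None


def default_rules() -> RuleSet:
    """The packaged criteria transcription (cached)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        text = resources.files("headdx.data").joinpath("rules_ichd3.yaml").read_text()
        _DEFAULT_CACHE = _parse_ruleset(yaml.safe_load(text), "rules_ichd3.yaml")
    return _DEFAULT_CACHE


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_criteria(record: PatientRecord,
                      rules: RuleSet | None = None) -> list[CriteriaEvaluation]:
    """Score every criterion group of every encoded diagnosis.

    Pure function of the record: returns one :class:`CriteriaEvaluation` per
    diagnosis. Groups whose predicate touches a missing field are recorded
    as not assessable and counted among the failed groups.
    """
    rules = rules or default_rules()
    ctx = build_context(record)
    out: list[CriteriaEvaluation] = []
    for diag in rules.diagnoses:
        met, failed, na = set(), set(), set()
        for rule in rules.groups_for(diag):
            try:
                ok = bool(_eval_node(rule._tree, ctx))
            except NotAssessable:
                failed.add(rule.criterion_group)
                na.add(rule.criterion_group)
                continue
            (met if ok else failed).add(rule.criterion_group)
        out.append(CriteriaEvaluation(
            diagnosis=diag, groups_met=frozenset(met),
            groups_failed=frozenset(failed), not_assessable=frozenset(na)))
    return out


def resolve_priority(candidates: Iterable[DiagnosisLabel],
                     rules: RuleSet | None = None) -> DiagnosisLabel:
    """Collapse co-occurring candidate labels to the single highest-priority
    one. Medication-overuse headache outranks chronic migraine by design."""
    rules = rules or default_rules()
    cand = list(candidates)
    if not cand:
        raise ValueError("resolve_priority requires at least one candidate")
    order = {label: i for i, label in enumerate(rules.priority)}
    return min(cand, key=lambda lbl: order[lbl])


_MIGRAINE_SIDE = (DiagnosisLabel.MO, DiagnosisLabel.MA)
_TTH_SIDE = (DiagnosisLabel.iETTH, DiagnosisLabel.fETTH, DiagnosisLabel.CTTH)


def diagnose_rules(record: PatientRecord,
                   rules: RuleSet | None = None,
                   ) -> Union["DiagnosisResultLike", Ambiguous]:
    """Single-label rule diagnosis with probable fallback.

    Fully-met diagnoses win outright (ties broken by precedence). With no
    fully-met diagnosis, a migraine label one group short yields probable
    migraine and a tension-type label one group short yields probable TTH;
    when both hold the outcome is :class:`Ambiguous` for the CBR stage, and
    when neither holds the record lands in OTHERS.
    """
    from .records import DiagnosisResult  # local to avoid cycle in typing

    rules = rules or default_rules()
    evals = evaluate_criteria(record, rules)
    by_label = {ev.diagnosis: ev for ev in evals}
    definite = [ev.diagnosis for ev in evals if ev.fully_met]
    if definite:
        label = resolve_priority(definite, rules)
        return DiagnosisResult(label=label, method="rule", trace=evals)
    pm = any(lbl in by_label and by_label[lbl].n_failed == 1
             for lbl in _MIGRAINE_SIDE)
    ptth = any(lbl in by_label and by_label[lbl].n_failed == 1
               for lbl in _TTH_SIDE)
    if pm and ptth:
        return Ambiguous(frozenset({DiagnosisLabel.PM, DiagnosisLabel.PTTH}))
    if pm:
        return DiagnosisResult(label=DiagnosisLabel.PM, method="rule", trace=evals)
    if ptth:
        return DiagnosisResult(label=DiagnosisLabel.PTTH, method="rule", trace=evals)
    return DiagnosisResult(label=DiagnosisLabel.OTHERS, method="rule", trace=evals)
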