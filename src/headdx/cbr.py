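"""Weighted case-based reasoning with genetic-algorithm feature weighting.

Settles the records the rule engine cannot: when a presentation is one
criterion group short of both a migraine and a tension-type diagnosis, the
probable-migraine / probable-TTH differential is decided by the nearest
labelled case in a reference case base.

Similarity is a weighted Gower-style mean over a mixed-type feature vector:
``sim(x, y) = sum_i w_i * s_i`` with ``s_i = 1 - |x_i - y_i|`` for numeric
(min-max scaled to [0, 1]) and binary features and ``s_i = [x_i == y_i]``
for categorical ones. Weights are non-negative and sum to one; they are
fitted by a small generational GA whose fitness is the leave-one-out
accuracy of the 1-nearest-neighbour classifier on the case base.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .records import DiagnosisLabel, DiagnosisResult, PatientRecord
from .rules import Ambiguous, RuleSet, build_context, default_rules, diagnose_rules, resolve_priority

__all__ = [
    "Feature", "FeatureSchema", "CaseBase", "FeatureWeights", "GAParams",
    "default_schema", "featurize", "similarity", "classify_cbr",
    "loo_accuracy", "optimize_weights_ga", "hybrid_diagnose",
]


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str  # numeric | binary | categorical
    range: tuple[float, float] | None = None
    categories: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("numeric", "binary", "categorical"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "numeric":
            if self.range is None or not np.isfinite(self.range).all() \
                    or self.range[0] >= self.range[1]:
                raise ValueError(f"feature {self.name}: finite range required")
        if self.kind == "categorical" and not self.categories:
            raise ValueError(f"feature {self.name}: categories required")


@dataclass(frozen=True)
class FeatureSchema:
    features: tuple[Feature, ...]

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    @classmethod
    def from_dict(cls, doc: dict) -> "FeatureSchema":
        feats = []
        for item in doc["features"]:
            feats.append(Feature(
                name=item["name"], kind=item["kind"],
                range=tuple(item["range"]) if "range" in item else None,
                categories=tuple(item["categories"]) if "categories" in item else None,
            ))
        return cls(tuple(feats))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: Union[str, Path]) -> None:
        doc = {"features": []}
        for f in self.features:
            item: dict = {"name": f.name, "kind": f.kind}
            if f.range is not None:
                item["range"] = list(f.range)
            if f.categories is not None:
                item["categories"] = list(f.categories)
            doc["features"].append(item)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_schema() -> FeatureSchema:
    text = resources.files("headdx.data").joinpath("feature_schema.yaml").read_text()
    return FeatureSchema.from_dict(yaml.safe_load(text))


@dataclass
class CaseBase:
    schema: FeatureSchema
    vectors: list[list]              # per-schema values, mixed types
    labels: list[DiagnosisLabel]
    _tensor: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.vectors) != len(self.labels):
            raise ValueError("one label per case required")
        if len(self.vectors) < 2:
            raise ValueError("a case base needs at least two cases")
        for vec in self.vectors:
            _check_vector(vec, self.schema)

    def __len__(self) -> int:
        return len(self.vectors)

    def restrict(self, labels: set[DiagnosisLabel]) -> "CaseBase | None":
        keep = [i for i, lbl in enumerate(self.labels) if lbl in labels]
        if len(keep) < 2:
            return None
        return CaseBase(self.schema,
                        [self.vectors[i] for i in keep],
                        [self.labels[i] for i in keep])

    def to_csv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(self.vectors, columns=self.schema.names)
        df["label"] = [lbl.value for lbl in self.labels]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path], schema: FeatureSchema) -> "CaseBase":
        df = pd.read_csv(path)
        missing = set(schema.names + ["label"]) - set(df.columns)
        if missing:
            raise ValueError(f"case-base CSV missing columns {sorted(missing)}")
        vectors = df[schema.names].to_numpy(dtype=object).tolist()
        # numeric/binary columns arrive as numpy scalars; normalize types
        for vec in vectors:
            for i, f in enumerate(schema.features):
                vec[i] = str(vec[i]) if f.kind == "categorical" else float(vec[i])
        labels = [DiagnosisLabel(t) for t in df["label"]]
        return cls(schema, vectors, labels)

    def feature_sim_tensor(self) -> np.ndarray:
        """(F, N, N) per-feature pairwise similarity; cached."""
        if self._tensor is None:
            n, schema = len(self), self.schema
            t = np.empty((len(schema), n, n))
            for i, f in enumerate(schema.features):
                if f.kind == "categorical":
                    col = np.array([v[i] for v in self.vectors], dtype=object)
                    t[i] = (col[:, None] == col[None, :]).astype(float)
                else:
                    col = np.array([v[i] for v in self.vectors], dtype=float)
                    t[i] = 1.0 - np.abs(col[:, None] - col[None, :])
            self._tensor = t
        return self._tensor


@dataclass(frozen=True)
class FeatureWeights:
    w: tuple[float, ...]

    def __post_init__(self):
        arr = np.asarray(self.w, dtype=float)
        if (arr < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.isclose(arr.sum(), 1.0):
            raise ValueError("weights must sum to one")

    @classmethod
    def uniform(cls, n: int) -> "FeatureWeights":
        return cls(tuple([1.0 / n] * n))

    @classmethod
    def normalized(cls, raw: Sequence[float]) -> "FeatureWeights":
        arr = np.clip(np.asarray(raw, dtype=float), 0.0, None)
        s = arr.sum()
        arr = arr / s if s > 0 else np.full(len(arr), 1.0 / len(arr))
        return cls(tuple(arr.tolist()))

    def to_json(self, path: Union[str, Path], names: Sequence[str]) -> None:
        with open(path, "w") as fh:
            json.dump({"features": list(names), "weights": list(self.w)}, fh,
                      indent=2)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FeatureWeights":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(tuple(doc["weights"]))


@dataclass(frozen=True)
class GAParams:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_sigma: float = 0.1
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# featurization and similarity
# ---------------------------------------------------------------------------

def _check_vector(vec: Sequence, schema: FeatureSchema) -> None:
    if len(vec) != len(schema):
        raise ValueError(
            f"vector length {len(vec)} != schema length {len(schema)}")
    for value, f in zip(vec, schema.features):
        if f.kind == "categorical":
            if value not in f.categories:
                raise ValueError(f"{f.name}: {value!r} not in categories")
        elif not (-1e-9 <= float(value) <= 1 + 1e-9):
            raise ValueError(f"{f.name}: scaled value {value} outside [0, 1]")


def featurize(record: PatientRecord, schema: FeatureSchema | None = None) -> list:
    """Project a record onto the schema: numeric features min-max scaled to
    [0, 1], binary mapped to {0, 1}, categorical kept symbolic."""
    schema = schema or default_schema()
    ctx = build_context(record)
    ctx["laterality"] = record.pain.laterality
    out = []
    for f in schema.features:
        if f.name not in ctx or ctx[f.name] is None:
            raise ValueError(f"cannot resolve feature {f.name!r} from record")
        value = ctx[f.name]
        if f.kind == "numeric":
            lo, hi = f.range
            out.append(float(np.clip((float(value) - lo) / (hi - lo), 0.0, 1.0)))
        elif f.kind == "binary":
            out.append(float(bool(value)))
        else:
            out.append(str(value))
    return out


def similarity(x: Sequence, y: Sequence, weights: FeatureWeights,
               schema: FeatureSchema) -> float:
    """Weighted Gower similarity in [0, 1]; symmetric; 1 iff x == y."""
    _check_vector(x, schema)
    _check_vector(y, schema)
    total = 0.0
    for wi, xi, yi, f in zip(weights.w, x, y, schema.features):
        if f.kind == "categorical":
            s = 1.0 if xi == yi else 0.0
        else:
            s = 1.0 - abs(float(xi) - float(yi))
        total += wi * s
    return float(total)


def _similarities_to_base(vec: Sequence, base: CaseBase,
                          weights: FeatureWeights) -> np.ndarray:
    sims = np.zeros(len(base))
    for wi, f, xi, col_idx in zip(weights.w, base.schema.features, vec,
                                  range(len(base.schema))):
        col = [v[col_idx] for v in base.vectors]
        if f.kind == "categorical":
            s = np.array([1.0 if xi == c else 0.0 for c in col])
        else:
            s = 1.0 - np.abs(float(xi) - np.asarray(col, dtype=float))
        sims += wi * s
    return sims


def classify_cbr(record: Union[PatientRecord, Sequence], casebase: CaseBase,
                 weights: FeatureWeights | None = None, k: int = 1,
                 ) -> DiagnosisLabel:
    """Majority label among the k most similar cases (k odd, default 1).

    Label ties are broken by the larger summed similarity of the tied
    labels' neighbours, then by the diagnostic precedence order.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd number")
    weights = weights or FeatureWeights.uniform(len(casebase.schema))
    vec = featurize(record, casebase.schema) if isinstance(record, PatientRecord) else record
    _check_vector(vec, casebase.schema)
    sims = _similarities_to_base(vec, casebase, weights)
    k = min(k, len(casebase))
    order = np.lexsort((np.arange(len(sims)), -sims))[:k]
    votes = Counter(casebase.labels[i] for i in order)
    top = max(votes.values())
    tied = [lbl for lbl, c in votes.items() if c == top]
    if len(tied) > 1:
        summed = {lbl: sum(sims[i] for i in order if casebase.labels[i] == lbl)
                  for lbl in tied}
        best = max(summed.values())
        tied = [lbl for lbl in tied if np.isclose(summed[lbl], best)]
    if len(tied) > 1:
        return resolve_priority(tied)
    return tied[0]


def _loo_hits_k1(S: np.ndarray, labels: np.ndarray) -> np.ndarray:
    S = S.copy()
    np.fill_diagonal(S, -np.inf)
    nearest = np.argmax(S, axis=1)
    return labels[nearest] == labels


def loo_accuracy(casebase: CaseBase, weights: FeatureWeights | None = None,
                 k: int = 1) -> float:
    """Fraction of cases whose label is recovered by k-NN on the remaining
    cases; this is the GA's fitness function."""
    weights = weights or FeatureWeights.uniform(len(casebase.schema))
    if k == 1:
        t = casebase.feature_sim_tensor()
        S = np.tensordot(np.asarray(weights.w), t, axes=1)
        labels = np.array([lbl.value for lbl in casebase.labels])
        return float(np.mean(_loo_hits_k1(S, labels)))
    hits = 0
    for i in range(len(casebase)):
        rest = CaseBase(casebase.schema,
                        casebase.vectors[:i] + casebase.vectors[i + 1:],
                        casebase.labels[:i] + casebase.labels[i + 1:])
        if classify_cbr(casebase.vectors[i], rest, weights, k) == casebase.labels[i]:
            hits += 1
    return hits / len(casebase)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

def _normalize_rows(pop: np.ndarray) -> np.ndarray:
    pop = np.clip(pop, 0.0, None)
    sums = pop.sum(axis=1, keepdims=True)
    bad = (sums[:, 0] <= 0)
    pop[bad] = 1.0
    sums[bad] = pop.shape[1]
    return pop / sums


def optimize_weights_ga(casebase: CaseBase, params: GAParams | None = None,
                        ) -> tuple[FeatureWeights, list[dict]]:
    """Fit feature weights by a generational GA.

    Chromosomes are weight vectors (renormalized after every operator);
    fitness is the leave-one-out 1-NN accuracy on the case base; selection
    is by tournament, recombination by uniform crossover, variation by
    clipped Gaussian mutation, with single-individual elitism. Ties between
    equal-accuracy chromosomes are broken by the mean leave-one-out
    similarity margin (nearest same-label minus nearest other-label case),
    so the returned optimum is the most separating of the most accurate
    weightings. Fully reproducible for a fixed seed. Returns the best-ever
    chromosome and a per-generation fitness log.
    """
    params = params or GAParams()
    if len(casebase) < 2:
        raise ValueError("GA needs a case base with at least two cases")
    rng = np.random.default_rng(params.seed)
    nfeat = len(casebase.schema)
    labels = np.array([lbl.value for lbl in casebase.labels])
    t = casebase.feature_sim_tensor()
    flat = t.reshape(nfeat, -1)
    n = len(casebase)
    same = (labels[:, None] == labels[None, :])
    np.fill_diagonal(same, False)
    diff = ~(labels[:, None] == labels[None, :])
    # cases without a same-label partner are excluded from the margin
    margin_mask = same.any(axis=1) & diff.any(axis=1)

    def fitnesses(pop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        S = (pop @ flat).reshape(len(pop), n, n)
        S[:, np.arange(n), np.arange(n)] = -np.inf
        nearest = np.argmax(S, axis=2)
        acc = (labels[nearest] == labels[None, :]).mean(axis=1)
        if margin_mask.any():
            near_same = np.where(same[None, :, :], S, -np.inf).max(axis=2)
            near_diff = np.where(diff[None, :, :], S, -np.inf).max(axis=2)
            margin = (near_same - near_diff)[:, margin_mask].mean(axis=1)
        else:
            margin = np.zeros(len(pop))
        return acc, margin

    def better(a: tuple[float, float], b: tuple[float, float]) -> bool:
        return a[0] > b[0] or (a[0] == b[0] and a[1] > b[1])

    pop = _normalize_rows(rng.random((params.population_size, nfeat)))
    fit, marg = fitnesses(pop)
    best_idx = int(np.lexsort((-marg, -fit))[0])
    best_w = pop[best_idx].copy()
    best_fit, best_marg = float(fit[best_idx]), float(marg[best_idx])
    history = [{"generation": 0, "best": best_fit, "mean": float(fit.mean())}]

    for gen in range(1, params.generations + 1):
        # tournament selection on accuracy, margin as the tie-breaker (the
        # margin bonus is far below one accuracy quantum of 1/n)
        score = fit + 1e-3 * marg
        idx = rng.integers(0, len(pop),
                           size=(params.population_size, params.tournament_size))
        winners = idx[np.arange(len(idx)), np.argmax(score[idx], axis=1)]
        parents = pop[winners]
        # uniform crossover on consecutive pairs
        children = parents.copy()
        for a in range(0, len(children) - 1, 2):
            if rng.random() < params.crossover_rate:
                mask = rng.random(nfeat) < 0.5
                children[a, mask], children[a + 1, mask] = (
                    parents[a + 1, mask], parents[a, mask])
        # Gaussian mutation, clipped at zero
        mmask = rng.random(children.shape) < params.mutation_rate
        children = children + mmask * rng.normal(0.0, params.mutation_sigma,
                                                 children.shape)
        children = _normalize_rows(children)
        # elitism: best-ever replaces the first slot
        children[0] = best_w
        pop = children
        fit, marg = fitnesses(pop)
        gen_best = int(np.lexsort((-marg, -fit))[0])
        if better((float(fit[gen_best]), float(marg[gen_best])),
                  (best_fit, best_marg)):
            best_fit, best_marg = float(fit[gen_best]), float(marg[gen_best])
            best_w = pop[gen_best].copy()
        history.append({"generation": gen, "best": best_fit,
                        "mean": float(fit.mean())})

    return FeatureWeights.normalized(best_w), history


# ---------------------------------------------------------------------------
# hybrid reasoning
# ---------------------------------------------------------------------------

def hybrid_diagnose(record: PatientRecord, rules: RuleSet | None = None,
                    casebase: CaseBase | None = None,
                    weights: FeatureWeights | None = None,
                    k: int = 1) -> DiagnosisResult:
    """Rule-based reasoning first; case-based reasoning supplements it for
    the probable-migraine / probable-TTH differential. Red-flag warnings are
    attached on every path."""
    from .redflags import screen

    rules = rules or default_rules()
    warnings = screen(record)
    outcome = diagnose_rules(record, rules)
    if isinstance(outcome, Ambiguous):
        notes = []
        restricted = casebase.restrict(outcome.candidates) if casebase else None
        if restricted is None:
            label = DiagnosisLabel.OTHERS
            notes.append("differential diagnosis requested but the case base "
                         "holds no PM/PTTH cases")
            method = "rule"
        else:
            label = classify_cbr(record, restricted, weights, k)
            method = "cbr"
        from .rules import evaluate_criteria
        trace = evaluate_criteria(record, rules)
        return DiagnosisResult(label=label, method=method, trace=trace,
                               warnings=warnings, notes=notes)
    outcome.warnings.extend(warnings)
    return outcome
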