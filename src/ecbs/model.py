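"""Random-forest pair classifiers over fingerprint features.

The binding-similarity score of a compound pair is the positive-class
probability of a random forest trained on labeled chemical pairs. A pair
(a, b) is featurized symmetrically: for each configured fingerprint kind,
the AND of the two bit vectors (shared substructure) is concatenated with
their XOR (differing substructure); kinds are concatenated in a fixed
declared order, so the vector length is twice the summed fingerprint
lengths and featurize(a, b) == featurize(b, a) element-wise.

One forest is trained per evolutionary scope (target scope plus one family
scope per family database); an ensemble averages the member probabilities.
Forest defaults follow the cited R package's defaults: 500 trees,
sqrt-of-features candidate variables per split, probability output.

Scoring a library compound against a panel of reference actives takes the
maximum pair score over the panel ("best supporting active"), which is the
quantity thresholded during virtual screening.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .chemio import Compound, Fingerprint, FingerprintKind, fingerprint_length
from .pairgen import ChemicalPair, PairScheme

MODEL_FORMAT_VERSION = 1

#: Fingerprint kinds used by the pair model unless configured otherwise
#: (MACCS keys plus the substructure-pattern fingerprint).
DEFAULT_MODEL_KINDS = (FingerprintKind.MACCS166, FingerprintKind.SUBSTRUCT_FP4)


class ModelError(ValueError):
    pass


class ModelPersistenceError(ModelError):
    pass


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (defaults mirror ranger's defaults)."""

    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    min_samples_leaf: int = 1
    n_jobs: int = 1

    def build(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            random_state=seed,
            n_jobs=self.n_jobs,
        )


@dataclass(frozen=True)
class FeatureSpec:
    """Declared pair-feature layout: kinds in order and their bit lengths."""

    kinds: tuple[FingerprintKind, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "kinds", tuple(FingerprintKind(k) for k in self.kinds)
        )
        if not self.kinds:
            raise ModelError("feature spec needs at least one fingerprint kind")

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(fingerprint_length(k) for k in self.kinds)

    @property
    def n_features(self) -> int:
        return 2 * sum(self.lengths)


def featurize_pair(
    fp_set_a: Mapping[FingerprintKind, Fingerprint],
    fp_set_b: Mapping[FingerprintKind, Fingerprint],
    spec: FeatureSpec,
) -> np.ndarray:
    """Symmetric pair features: per kind, AND segment then XOR segment."""
    segments = []
    for kind in spec.kinds:
        if kind not in fp_set_a or kind not in fp_set_b:
            raise ModelError(f"missing fingerprint kind {kind.value} on one compound")
        a, b = fp_set_a[kind].bits, fp_set_b[kind].bits
        segments.append(a & b)
        segments.append(a ^ b)
    return np.concatenate(segments).astype(np.float32)


def _pair_matrix(
    pairs: Sequence[ChemicalPair],
    compounds: Mapping[str, Compound],
    spec: FeatureSpec,
) -> tuple[np.ndarray, np.ndarray]:
    X = np.empty((len(pairs), spec.n_features), dtype=np.float32)
    y = np.empty(len(pairs), dtype=np.int64)
    fp_cache: dict[str, dict[FingerprintKind, Fingerprint]] = {}

    def fps(cid: str) -> dict[FingerprintKind, Fingerprint]:
        got = fp_cache.get(cid)
        if got is None:
            comp = compounds.get(cid)
            if comp is None:
                raise ModelError(f"unresolvable compound id {cid!r}")
            got = {k: comp.fingerprint(k) for k in spec.kinds}
            fp_cache[cid] = got
        return got

    for i, p in enumerate(pairs):
        X[i] = featurize_pair(fps(p.compound_a), fps(p.compound_b), spec)
        y[i] = p.label
    return X, y


@dataclass
class EcbsModel:
    """A trained pair classifier for one evolutionary scope."""

    scope: str
    forest: RandomForestClassifier
    feature_spec: FeatureSpec
    training_meta: dict = field(default_factory=dict)

    def _positive_column(self) -> int:
        classes = list(self.forest.classes_)
        return classes.index(1)

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict_proba(X)[:, self._positive_column()]

    def score_pair(self, a: Compound, b: Compound) -> float:
        fa = {k: a.fingerprint(k) for k in self.feature_spec.kinds}
        fb = {k: b.fingerprint(k) for k in self.feature_spec.kinds}
        X = featurize_pair(fa, fb, self.feature_spec)[None, :]
        return float(self.score_matrix(X)[0])

    def score_pairs(
        self, pairs: Sequence[ChemicalPair], compounds: Mapping[str, Compound]
    ) -> np.ndarray:
        X, _ = _pair_matrix(pairs, compounds, self.feature_spec)
        return self.score_matrix(X)


@dataclass
class EnsembleModel:
    """Mean-combined ensemble of per-scope pair models."""

    members: list[EcbsModel]
    combine: str = "mean"

    def __post_init__(self):
        if not self.members:
            raise ModelError("ensemble needs at least one member")
        if self.combine != "mean":
            raise ModelError("only mean combination is supported")
        specs = {m.feature_spec.kinds for m in self.members}
        if len(specs) != 1:
            raise ModelError("ensemble members must share a feature spec")

    @property
    def feature_spec(self) -> FeatureSpec:
        return self.members[0].feature_spec

    @property
    def training_meta(self) -> dict:
        return {
            "members": {m.scope: m.training_meta for m in self.members},
            "combine": self.combine,
        }

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.score_matrix(X) for m in self.members], axis=0)

    def score_pair(self, a: Compound, b: Compound) -> float:
        return float(np.mean([m.score_pair(a, b) for m in self.members]))

    def score_pairs(
        self, pairs: Sequence[ChemicalPair], compounds: Mapping[str, Compound]
    ) -> np.ndarray:
        X, _ = _pair_matrix(pairs, compounds, self.feature_spec)
        return self.score_matrix(X)


def _scheme_counts(pairs: Sequence[ChemicalPair]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.scheme.value] = counts.get(p.scheme.value, 0) + 1
    return counts


def train_member(
    pairs: Sequence[ChemicalPair],
    compounds: Mapping[str, Compound],
    scope: str,
    config: ForestConfig | None = None,
    seed: int = 0,
    kinds: Sequence[FingerprintKind] = DEFAULT_MODEL_KINDS,
) -> EcbsModel:
    """Fit one random-forest pair model; deterministic for a fixed seed."""
    config = config or ForestConfig()
    spec = FeatureSpec(tuple(kinds))
    if not pairs:
        raise ModelError("no training pairs")
    labels = {p.label for p in pairs}
    if labels != {0, 1}:
        raise ModelError(
            f"training pairs must contain both classes, got labels {sorted(labels)}"
        )
    # canonical row order: training is invariant to input pair order
    pairs = sorted(pairs, key=lambda p: (p.ids, p.scheme.value))
    X, y = _pair_matrix(pairs, compounds, spec)
    forest = config.build(seed)
    forest.fit(X, y)
    meta = {
        "scope": scope,
        "seed": seed,
        "n_pairs": len(pairs),
        "scheme_counts": _scheme_counts(pairs),
        "forest": asdict(config),
        "kinds": [k.value for k in spec.kinds],
        "kind_lengths": list(spec.lengths),
        "trained_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return EcbsModel(scope=scope, forest=forest, feature_spec=spec, training_meta=meta)


def train_ensemble(
    per_scope_pairs: Mapping[str, Sequence[ChemicalPair]],
    compounds: Mapping[str, Compound],
    config: ForestConfig | None = None,
    seed: int = 0,
    kinds: Sequence[FingerprintKind] = DEFAULT_MODEL_KINDS,
) -> EnsembleModel:
    """Train one member per evolutionary scope and combine by mean."""
    if not per_scope_pairs:
        raise ModelError("no scopes to train")
    members = []
    for i, (scope, pairs) in enumerate(sorted(per_scope_pairs.items())):
        try:
            members.append(
                train_member(pairs, compounds, scope, config, seed + i, kinds)
            )
        except ModelError as e:
            raise ModelError(f"scope {scope!r}: {e}") from e
    return EnsembleModel(members=members)


def score_pair(model: EcbsModel | EnsembleModel, a: Compound, b: Compound) -> float:
    """Positive-class probability that (a, b) is an evolutionarily related pair."""
    return model.score_pair(a, b)


def compound_score(
    model: EcbsModel | EnsembleModel,
    query: Compound,
    reference_actives: Sequence[Compound],
) -> tuple[float, str]:
    """Max pair score of a query against reference actives, with the argmax id.

    Ties are broken by lexicographic active id.
    """
    scores = compound_scores(model, [query], reference_actives)
    return scores[0]


def compound_scores(
    model: EcbsModel | EnsembleModel,
    queries: Sequence[Compound],
    reference_actives: Sequence[Compound],
) -> list[tuple[float, str]]:
    """Vectorized :func:`compound_score` over many queries."""
    if not reference_actives:
        raise ModelError("reference active list is empty")
    spec = model.feature_spec
    refs = sorted(reference_actives, key=lambda c: c.id)
    ref_fps = [{k: r.fingerprint(k) for k in spec.kinds} for r in refs]
    out: list[tuple[float, str]] = []
    # score in blocks of queries to bound the feature matrix size
    block = max(1, 8192 // max(1, len(refs)))
    for start in range(0, len(queries), block):
        chunk = queries[start : start + block]
        X = np.empty((len(chunk) * len(refs), spec.n_features), dtype=np.float32)
        row = 0
        for q in chunk:
            qf = {k: q.fingerprint(k) for k in spec.kinds}
            for rf in ref_fps:
                X[row] = featurize_pair(qf, rf, spec)
                row += 1
        scores = model.score_matrix(X).reshape(len(chunk), len(refs))
        for i in range(len(chunk)):
            best = int(np.argmax(scores[i]))  # argmax returns first max: lexicographic tie-break
            out.append((float(scores[i, best]), refs[best].id))
    return out


def retrain(
    base_pairs: Sequence[ChemicalPair],
    new_pairs: Sequence[ChemicalPair],
    compounds: Mapping[str, Compound],
    scope: str = "target",
    config: ForestConfig | None = None,
    seed: int = 0,
    kinds: Sequence[FingerprintKind] = DEFAULT_MODEL_KINDS,
) -> EcbsModel:
    """Full refit on the union of base and new pairs (duplicates dropped).

    The returned model's metadata records the retraining scheme composition,
    e.g. ``"PP-NP"``.
    """
    import warnings

    merged: dict[tuple[str, str], ChemicalPair] = {p.ids: p for p in base_pairs}
    dups = 0
    for p in new_pairs:
        if p.ids in merged:
            dups += 1
            continue
        merged[p.ids] = p
    if dups:
        warnings.warn(f"dropped {dups} new pairs duplicating base pairs")
    union = [merged[k] for k in sorted(merged)]
    model = train_member(union, compounds, scope, config, seed, kinds)
    new_schemes = sorted(
        {p.scheme.value for p in new_pairs if p.scheme in
         {PairScheme.PP, PairScheme.NP, PairScheme.NN, PairScheme.PN}}
    )
    model.training_meta["retrain_schemes"] = "-".join(new_schemes) if new_schemes else "None"
    model.training_meta["n_base_pairs"] = len(base_pairs)
    model.training_meta["n_new_pairs"] = len(new_pairs)
    model.training_meta["n_duplicates_dropped"] = dups
    return model


@dataclass
class SingleCompoundModel:
    """Benchmark baseline: forest over individual compound fingerprints."""

    forest: RandomForestClassifier
    feature_spec: FeatureSpec
    training_meta: dict = field(default_factory=dict)

    def predict_proba_active(self, compounds: Sequence[Compound]) -> np.ndarray:
        X = np.stack(
            [
                np.concatenate([c.fingerprint(k).bits for k in self.feature_spec.kinds])
                for c in compounds
            ]
        ).astype(np.float32)
        col = list(self.forest.classes_).index(1)
        return self.forest.predict_proba(X)[:, col]


def train_single_compound_baseline(
    actives: Sequence[Compound],
    inactives: Sequence[Compound],
    config: ForestConfig | None = None,
    seed: int = 0,
    kinds: Sequence[FingerprintKind] = DEFAULT_MODEL_KINDS,
) -> SingleCompoundModel:
    """Standard single-chemical classifier used for benchmarking the pair model."""
    config = config or ForestConfig()
    spec = FeatureSpec(tuple(kinds))
    if not actives or not inactives:
        raise ModelError("baseline needs both active and inactive compounds")
    X = np.stack(
        [
            np.concatenate([c.fingerprint(k).bits for k in spec.kinds])
            for c in list(actives) + list(inactives)
        ]
    ).astype(np.float32)
    y = np.array([1] * len(actives) + [0] * len(inactives))
    forest = config.build(seed)
    forest.fit(X, y)
    return SingleCompoundModel(
        forest=forest,
        feature_spec=spec,
        training_meta={"n_actives": len(actives), "n_inactives": len(inactives),
                       "seed": seed},
    )


# ---------------------------------------------------------------------------
# Persistence


def persist_model(model: EcbsModel | EnsembleModel, path: str | Path) -> None:
    """Save a model to a versioned container file (joblib serialization)."""
    payload = {"format_version": MODEL_FORMAT_VERSION}
    if isinstance(model, EnsembleModel):
        payload["type"] = "ensemble"
        payload["combine"] = model.combine
        payload["members"] = [
            {
                "scope": m.scope,
                "forest": m.forest,
                "kinds": [k.value for k in m.feature_spec.kinds],
                "training_meta": m.training_meta,
            }
            for m in model.members
        ]
    elif isinstance(model, EcbsModel):
        payload["type"] = "single"
        payload["scope"] = model.scope
        payload["forest"] = model.forest
        payload["kinds"] = [k.value for k in model.feature_spec.kinds]
        payload["training_meta"] = model.training_meta
    else:
        raise ModelPersistenceError(f"cannot persist object of type {type(model)}")
    joblib.dump(payload, path)


def load_model(path: str | Path) -> EcbsModel | EnsembleModel:
    try:
        payload = joblib.load(path)
    except Exception as e:
        raise ModelPersistenceError(f"corrupted or unreadable model file {path}: {e}") from e
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelPersistenceError(f"not a model file: {path}")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelPersistenceError(
            f"model format version {payload['format_version']} != "
            f"{MODEL_FORMAT_VERSION}"
        )
    if payload["type"] == "single":
        return EcbsModel(
            scope=payload["scope"],
            forest=payload["forest"],
            feature_spec=FeatureSpec(tuple(payload["kinds"])),
            training_meta=payload["training_meta"],
        )
    if payload["type"] == "ensemble":
        members = [
            EcbsModel(
                scope=m["scope"],
                forest=m["forest"],
                feature_spec=FeatureSpec(tuple(m["kinds"])),
                training_meta=m["training_meta"],
            )
            for m in payload["members"]
        ]
        return EnsembleModel(members=members, combine=payload["combine"])
    raise ModelPersistenceError(f"unknown model type {payload['type']!r}")
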