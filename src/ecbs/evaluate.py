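"""Compound-level cross-validation and precision-recall evaluation.

Because pair models see every compound many times (once per pair), plain
pair-level cross-validation leaks information: both members of a test pair
may appear in training pairs. The protocol here therefore splits
*compounds* into k folds (sevenfold by default) and, per fold, takes every
pair containing a held-out compound as the test set. That test set is
*common* across all pairing-scheme combinations being compared — only the
training data varies with the combination — so AUCPR values are directly
comparable (the AUCPR baseline depends on the test prevalence, which is
held fixed this way).

AUCPR is estimated as step-wise average precision, sum of
(recall increment) x (precision) over distinct score thresholds in
descending order, with tied scores grouped at a single threshold. No
interpolation is applied, so a random ranking scores close to the positive
prevalence rather than being optimistically inflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chemio import Compound, FingerprintKind
from .model import DEFAULT_MODEL_KINDS, ForestConfig, train_member
from .pairgen import ChemicalPair, PairGenError, PairScheme, PairingInput, make_pairing_data


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class FoldPlan:
    """A balanced random partition of compounds into k folds."""

    k: int
    assignments: dict[str, int]
    seed: int

    def fold(self, index: int) -> frozenset[str]:
        return frozenset(c for c, f in self.assignments.items() if f == index)


def split_compounds_kfold(
    compounds: Iterable[str],
    k: int = 7,
    seed: int = 0,
    strata: Mapping[str, object] | None = None,
) -> FoldPlan:
    """Randomly partition compound ids into k folds with sizes differing by <= 1.

    With ``strata`` (a map id -> group label), compounds are dealt to folds
    group by group so each group is spread as evenly as possible across
    folds (e.g. keeping at least one active in every fold) while overall
    fold sizes still differ by at most one.
    """
    ids = sorted(set(compounds))
    if k < 2:
        raise EvaluationError(f"k must be >= 2, got {k}")
    if k > len(ids):
        raise EvaluationError(f"k={k} exceeds number of compounds ({len(ids)})")
    rng = np.random.default_rng(seed)
    if strata is None:
        ordered = [ids[int(i)] for i in rng.permutation(len(ids))]
    else:
        groups: dict[object, list[str]] = {}
        for cid in ids:
            groups.setdefault(strata.get(cid), []).append(cid)
        ordered = []
        for key in sorted(groups, key=str):
            members = groups[key]
            ordered.extend(members[int(i)] for i in rng.permutation(len(members)))
    offset = int(rng.integers(k))
    assignments = {cid: (pos + offset) % k for pos, cid in enumerate(ordered)}
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def build_common_test_set(
    all_pairs: Sequence[ChemicalPair], test_compounds: Iterable[str]
) -> tuple[list[ChemicalPair], list[ChemicalPair]]:
    """Split pairs into (test, train): test pairs touch a held-out compound."""
    test_set = frozenset(test_compounds)
    test_pairs, train_pairs = [], []
    for p in all_pairs:
        if p.compound_a in test_set or p.compound_b in test_set:
            test_pairs.append(p)
        else:
            train_pairs.append(p)
    return test_pairs, train_pairs


def aucpr(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Precision-recall curve and its area (step-wise average precision).

    Returns ``(curve, area)`` where ``curve`` is an array of
    ``(recall, precision)`` rows, one per distinct score threshold in
    descending order. Requires at least one positive and one negative label.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise EvaluationError("scores and labels must be equal-length 1-D sequences")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise EvaluationError("labels must contain both classes")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n_pos = int(np.sum(y == 1))

    # group tied scores: indices of the last element of each tie block
    distinct = np.flatnonzero(np.diff(s) != 0)
    block_ends = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y == 1)[block_ends]
    n_seen = block_ends + 1
    precision = tp / n_seen
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    area = float(np.sum((recall - prev_recall) * precision))
    curve = np.column_stack([recall, precision])
    return curve, area


@dataclass
class EvaluationReport:
    """Cross-validated AUCPR for one pairing-scheme combination."""

    scheme_combo: str
    per_fold_aucpr: list[float]
    mean_aucpr: float
    pos_count: int
    neg_count: int
    per_fold_detail: list[dict] = field(default_factory=list)


def _combo_label(combo: Sequence[PairScheme] | None) -> str:
    if not combo:
        return "None"
    return "-".join(PairScheme(s).value for s in combo)


def cross_validate_schemes(
    base_pairs: Sequence[ChemicalPair],
    compounds: Mapping[str, Compound],
    pairing_input: PairingInput | None,
    scheme_combos: Sequence[Sequence[PairScheme] | None],
    k: int = 7,
    seed: int = 0,
    config: ForestConfig | None = None,
    kinds: Sequence[FingerprintKind] = DEFAULT_MODEL_KINDS,
) -> list[EvaluationReport]:
    """Compare retraining scheme combinations under a common pair test set.

    The pair universe is the base pairs (ERCPs plus random negatives) plus
    the pairs of every scheme appearing in any requested combination, so the
    per-fold common test set is identical for all combinations — including
    the "None" (no retraining) baseline. Per fold, each combination trains
    on the non-test base pairs plus its own scheme pairs, with any scheme
    pair touching a held-out compound excluded from training (leakage
    guard). Reported AUCPR is the mean over folds.
    """
    if pairing_input is None:
        pairing_input = PairingInput(
            P_new=frozenset(), N_new=frozenset(), P_prv=frozenset(), N_prv=frozenset()
        )
    combos = [tuple(PairScheme(s) for s in c) if c else tuple() for c in scheme_combos]
    all_schemes = sorted({s for c in combos for s in c}, key=lambda s: s.value)
    scheme_pairs: dict[PairScheme, list[ChemicalPair]] = {
        s: make_pairing_data(pairing_input, [s]) for s in all_schemes
    }

    base_keys = {p.ids for p in base_pairs}
    universe: list[ChemicalPair] = list(base_pairs)
    for s in all_schemes:
        universe.extend(p for p in scheme_pairs[s] if p.ids not in base_keys)

    all_ids = sorted({cid for p in universe for cid in p.ids})
    missing = [cid for cid in all_ids if cid not in compounds]
    if missing:
        raise EvaluationError(f"pairs reference unknown compounds: {missing[:5]}")

    # Split only the target's own chemicals (members of positive pairs plus
    # the newly assayed compounds); the random-negative pool stays in
    # training, mirroring per-target compound splits. Actives form their own
    # stratum so every fold's common test set contains positive pairs.
    positive_ids = {cid for p in universe if p.label == 1 for cid in p.ids}
    split_ids = sorted(
        positive_ids | set(pairing_input.P_new) | set(pairing_input.N_new)
        | set(pairing_input.P_prv)
    )
    strata = {cid: ("pos" if cid in positive_ids else "other") for cid in split_ids}
    plan = split_compounds_kfold(split_ids, k=k, seed=seed, strata=strata)

    per_combo_folds: dict[tuple, list[float]] = {c: [] for c in combos}
    per_combo_detail: dict[tuple, list[dict]] = {c: [] for c in combos}
    pos_count = neg_count = 0
    for fold_idx in range(k):
        test_compounds = plan.fold(fold_idx)
        test_pairs, _ = build_common_test_set(universe, test_compounds)
        base_train = [
            p
            for p in base_pairs
            if p.compound_a not in test_compounds and p.compound_b not in test_compounds
        ]
        base_train_keys = {p.ids for p in base_train}
        labels = [p.label for p in test_pairs]
        if fold_idx == 0:
            pos_count = sum(labels)
            neg_count = len(labels) - pos_count
        for combo in combos:
            extra = [
                p
                for s in combo
                for p in scheme_pairs[s]
                if p.compound_a not in test_compounds
                and p.compound_b not in test_compounds
            ]
            train = base_train + [p for p in extra if p.ids not in base_train_keys]
            # leakage guard: no training pair may touch a held-out compound
            assert not any(
                p.compound_a in test_compounds or p.compound_b in test_compounds
                for p in train
            )
            try:
                mdl = train_member(
                    train, compounds, scope="target", config=config,
                    seed=seed + fold_idx, kinds=kinds,
                )
                scores = mdl.score_pairs(test_pairs, compounds)
                _, area = aucpr(scores, labels)
            except (EvaluationError, PairGenError, ValueError) as e:
                raise EvaluationError(
                    f"combo {_combo_label(combo)!r}, fold {fold_idx}: {e}"
                ) from e
            per_combo_folds[combo].append(area)
            per_combo_detail[combo].append(
                {"fold": fold_idx, "aucpr": area, "n_train": len(train),
                 "n_test": len(test_pairs)}
            )

    return [
        EvaluationReport(
            scheme_combo=_combo_label(combo),
            per_fold_aucpr=per_combo_folds[combo],
            mean_aucpr=float(np.mean(per_combo_folds[combo])),
            pos_count=pos_count,
            neg_count=neg_count,
            per_fold_detail=per_combo_detail[combo],
        )
        for combo in combos
    ]


def reports_to_frame(reports: Sequence[EvaluationReport]):
    """Tabulate reports (rows = scheme combos) as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "scheme_combo": [r.scheme_combo for r in reports],
            "mean_aucpr": [r.mean_aucpr for r in reports],
            "pos_count": [r.pos_count for r in reports],
            "neg_count": [r.neg_count for r in reports],
            **{
                f"fold{i}": [
                    r.per_fold_aucpr[i] if i < len(r.per_fold_aucpr) else np.nan
                    for r in reports
                ]
                for i in range(max(len(r.per_fold_aucpr) for r in reports))
            },
        }
    )
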