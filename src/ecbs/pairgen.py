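"""Labeled chemical-pair construction.

Similarity learning over compound pairs needs two classes of pairs:

* **ERCPs** (evolutionarily related chemical pairs) — compounds binding a
  common target (target scope) or targets sharing a protein family in some
  family database such as PFAM/SMART/SUPFAM (family scope). These are the
  positive class.
* **Random negatives** — active compounds paired with randomly drawn,
  most-likely-inactive compounds.

After a round of experimental validation, four retraining schemes combine
newly measured compounds with the previous training compounds:

=======  ======================  =========
scheme   pairs                   label
=======  ======================  =========
PP       P_new x P_prv           positive
NP       N_new x P_prv           negative
NN       N_new x N_prv           negative
PN       P_new x N_new           negative
=======  ======================  =========

where P_new / N_new are the new actives / inactives (labeled from percent
of control at 10 uM: POC < 20 active, POC > 80 inactive, in between
ambiguous and excluded) and P_prv / N_prv are the previous actives and
previous random negatives. Only PP is positive: NP, NN and PN pairs have no
shared target-binding activity.

Pairs are canonicalized by lexicographic id order so pair lists have set
semantics across runs.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class PairGenError(ValueError):
    pass


class PairScheme(str, Enum):
    ERCP_TARGET = "ERCP_TARGET"
    ERCP_FAMILY = "ERCP_FAMILY"
    RAND_NEG = "RAND_NEG"
    PP = "PP"
    NP = "NP"
    NN = "NN"
    PN = "PN"


#: Schemes whose pairs are positive training samples.
POSITIVE_SCHEMES = frozenset(
    {PairScheme.ERCP_TARGET, PairScheme.ERCP_FAMILY, PairScheme.PP}
)

RETRAIN_SCHEMES = frozenset(
    {PairScheme.PP, PairScheme.NP, PairScheme.NN, PairScheme.PN}
)


@dataclass(frozen=True)
class ChemicalPair:
    """An unordered compound pair with a label implied by its scheme."""

    compound_a: str
    compound_b: str
    scheme: PairScheme

    def __post_init__(self):
        if self.compound_a == self.compound_b:
            raise PairGenError(f"self-pair not allowed: {self.compound_a!r}")
        if self.compound_a > self.compound_b:
            a, b = self.compound_b, self.compound_a
            object.__setattr__(self, "compound_a", a)
            object.__setattr__(self, "compound_b", b)
        object.__setattr__(self, "scheme", PairScheme(self.scheme))

    @property
    def label(self) -> int:
        """1 for positive pairs (ERCP or PP), 0 otherwise."""
        return 1 if self.scheme in POSITIVE_SCHEMES else 0

    @property
    def ids(self) -> tuple[str, str]:
        return (self.compound_a, self.compound_b)


@dataclass(frozen=True)
class TargetProtein:
    """A protein target with family memberships per family database."""

    id: str
    families: dict[str, frozenset[str]] = field(default_factory=dict)

    def family_ids(self, db: str) -> frozenset[str]:
        return self.families.get(db, frozenset())


@dataclass(frozen=True)
class Interaction:
    compound_id: str
    target_id: str
    affinity_nM: float | None = None

    def __post_init__(self):
        if self.affinity_nM is not None and not self.affinity_nM > 0:
            raise PairGenError(
                f"affinity must be positive, got {self.affinity_nM} for "
                f"({self.compound_id}, {self.target_id})"
            )


@dataclass(frozen=True)
class ExperimentalResult:
    """Single-concentration binding result: percent of control at 10 uM."""

    compound_id: str
    target_id: str
    poc_percent: float
    kd_nM: float | None = None

    def __post_init__(self):
        if self.poc_percent < 0:
            raise PairGenError(f"POC must be >= 0, got {self.poc_percent}")
        if self.kd_nM is not None and not self.kd_nM > 0:
            raise PairGenError(f"Kd must be positive, got {self.kd_nM}")


@dataclass(frozen=True)
class PairingInput:
    """The four compound sets that drive retraining; pairwise disjoint."""

    P_new: frozenset[str]
    N_new: frozenset[str]
    P_prv: frozenset[str]
    N_prv: frozenset[str]

    def __post_init__(self):
        sets = {
            "P_new": frozenset(self.P_new),
            "N_new": frozenset(self.N_new),
            "P_prv": frozenset(self.P_prv),
            "N_prv": frozenset(self.N_prv),
        }
        for name, s in sets.items():
            object.__setattr__(self, name, s)
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                overlap = sets[a] & sets[b]
                if overlap:
                    raise PairGenError(
                        f"PairingInput sets {a} and {b} overlap: {sorted(overlap)}"
                    )


def label_from_poc(
    poc_percent: float, active_max: float = 20.0, inactive_min: float = 80.0
) -> str:
    """Classify a percent-of-control value as active / inactive / ambiguous.

    POC below ``active_max`` (default 20%) means strong competitive binding
    (active); above ``inactive_min`` (default 80%) means no binding
    (inactive); the band in between is ambiguous and excluded from pairing.
    """
    if poc_percent < 0:
        raise PairGenError(f"POC must be >= 0, got {poc_percent}")
    if not active_max < inactive_min:
        raise PairGenError("active_max must be below inactive_min")
    if poc_percent < active_max:
        return "active"
    if poc_percent > inactive_min:
        return "inactive"
    return "ambiguous"


def build_ercps(
    interactions: Sequence[Interaction],
    targets: Sequence[TargetProtein],
    focus_target: str,
    scope: str,
) -> list[ChemicalPair]:
    """Positive ERCP pairs for a focus target at target or family scope.

    ``scope="target"`` pairs all distinct compounds binding the focus target.
    ``scope="family:<db>"`` first expands the focus target to every target
    sharing at least one ``<db>`` family id with it, then pairs all distinct
    compounds binding any related target (target-specific confinement).
    """
    by_id = {t.id: t for t in targets}
    if focus_target not in by_id:
        raise PairGenError(f"unknown focus target {focus_target!r}")

    if scope == "target":
        related = {focus_target}
        scheme = PairScheme.ERCP_TARGET
    elif scope.startswith("family:"):
        db = scope.split(":", 1)[1]
        known_dbs = {d for t in targets for d in t.families}
        if db not in known_dbs:
            raise PairGenError(
                f"unknown family database {db!r}; known: {sorted(known_dbs)}"
            )
        focus_fams = by_id[focus_target].family_ids(db)
        related = {
            t.id for t in targets if t.family_ids(db) & focus_fams
        } | {focus_target}
        scheme = PairScheme.ERCP_FAMILY
    else:
        raise PairGenError(f"scope must be 'target' or 'family:<db>', got {scope!r}")

    binders = sorted({i.compound_id for i in interactions if i.target_id in related})
    pairs = [
        ChemicalPair(binders[i], binders[j], scheme)
        for i in range(len(binders))
        for j in range(i + 1, len(binders))
    ]
    return pairs


def sample_negative_pairs(
    actives: Iterable[str],
    random_pool: Iterable[str],
    neg_per_pos: float,
    n_positives: int,
    seed: int,
) -> list[ChemicalPair]:
    """Draw active x random-compound pairs as negatives, without replacement.

    The requested count is ``round(neg_per_pos * n_positives)`` (capped at
    the number of available cross pairs, with a warning). A negative:positive
    ratio around 6 reflects the typical class imbalance of pair training
    sets. Reproducible for a fixed seed.
    """
    actives = sorted(set(actives))
    pool = sorted(set(random_pool))
    if not actives:
        raise PairGenError("no active compounds to pair")
    if not pool:
        raise PairGenError("random pool is empty")
    overlap = set(actives) & set(pool)
    if overlap:
        raise PairGenError(f"random pool overlaps actives: {sorted(overlap)}")
    if not neg_per_pos > 0:
        raise PairGenError("neg_per_pos must be positive")

    n_requested = int(round(neg_per_pos * n_positives))
    n_total = len(actives) * len(pool)
    if n_requested > n_total:
        warnings.warn(
            f"requested {n_requested} negative pairs but only {n_total} "
            f"active x pool pairs exist; returning all of them"
        )
        n_requested = n_total
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_total, size=n_requested, replace=False)
    chosen.sort()
    n_pool = len(pool)
    return [
        ChemicalPair(actives[int(k) // n_pool], pool[int(k) % n_pool], PairScheme.RAND_NEG)
        for k in chosen
    ]


def make_pairing_data(
    pairing_input: PairingInput,
    schemes: Iterable[PairScheme | str],
    *,
    include_new_active_internal_pairs: bool = False,
) -> list[ChemicalPair]:
    """Build the retraining pair set for the requested schemes.

    PP = P_new x P_prv (positive); NP = N_new x P_prv, NN = N_new x N_prv,
    PN = P_new x N_new (all negative). The union over schemes is
    deduplicated and returned in canonical order. By default PP does not
    include pairs among the new actives themselves (new actives are paired
    with *known* actives); ``include_new_active_internal_pairs`` adds them.
    """
    schemes = {PairScheme(s) for s in schemes}
    bad = schemes - RETRAIN_SCHEMES
    if bad:
        raise PairGenError(
            f"schemes must be within {sorted(s.value for s in RETRAIN_SCHEMES)}, "
            f"got {sorted(s.value for s in bad)}"
        )
    pairs: dict[tuple[str, str], ChemicalPair] = {}

    def add(aset: Iterable[str], bset: Iterable[str], scheme: PairScheme):
        for a in sorted(aset):
            for b in sorted(bset):
                if a == b:
                    continue
                p = ChemicalPair(a, b, scheme)
                pairs.setdefault(p.ids, p)

    if PairScheme.PP in schemes:
        add(pairing_input.P_new, pairing_input.P_prv, PairScheme.PP)
        if include_new_active_internal_pairs:
            add(pairing_input.P_new, pairing_input.P_new, PairScheme.PP)
    if PairScheme.NP in schemes:
        add(pairing_input.N_new, pairing_input.P_prv, PairScheme.NP)
    if PairScheme.NN in schemes:
        add(pairing_input.N_new, pairing_input.N_prv, PairScheme.NN)
    if PairScheme.PN in schemes:
        add(pairing_input.P_new, pairing_input.N_new, PairScheme.PN)
    return [pairs[k] for k in sorted(pairs)]


def pairing_input_from_experiments(
    results: Sequence[ExperimentalResult],
    previous_actives: Iterable[str],
    previous_negatives: Iterable[str],
    *,
    active_max: float = 20.0,
    inactive_min: float = 80.0,
) -> PairingInput:
    """Turn assay results into a PairingInput, dropping ambiguous compounds.

    Compounds already among the previous actives/negatives are not
    re-labeled as new.
    """
    prv_p = frozenset(previous_actives)
    prv_n = frozenset(previous_negatives)
    p_new, n_new = set(), set()
    for r in results:
        if r.compound_id in prv_p or r.compound_id in prv_n:
            continue
        lab = label_from_poc(r.poc_percent, active_max, inactive_min)
        if lab == "active":
            p_new.add(r.compound_id)
        elif lab == "inactive":
            n_new.add(r.compound_id)
    return PairingInput(
        P_new=frozenset(p_new), N_new=frozenset(n_new), P_prv=prv_p, N_prv=prv_n
    )


# ---------------------------------------------------------------------------
# Tabular I/O


def read_interactions(path: str | Path) -> list[Interaction]:
    """CSV columns: compound_id, target_id, affinity_nM (blank allowed)."""
    out, seen = [], set()
    with Path(path).open(newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            key = (row["compound_id"], row["target_id"])
            if key in seen:
                raise PairGenError(f"duplicate interaction {key} at line {i}")
            seen.add(key)
            aff = row.get("affinity_nM", "")
            out.append(
                Interaction(
                    compound_id=row["compound_id"],
                    target_id=row["target_id"],
                    affinity_nM=float(aff) if aff not in ("", None) else None,
                )
            )
    return out


def read_family_table(path: str | Path) -> list[TargetProtein]:
    """CSV columns: target_id, family_db, family_id → TargetProtein list."""
    fams: dict[str, dict[str, set[str]]] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            fams.setdefault(row["target_id"], {}).setdefault(
                row["family_db"], set()
            ).add(row["family_id"])
    return [
        TargetProtein(id=tid, families={db: frozenset(s) for db, s in dbs.items()})
        for tid, dbs in sorted(fams.items())
    ]


def read_experimental_results(path: str | Path) -> list[ExperimentalResult]:
    """CSV columns: compound_id, target_id, poc_percent, kd_nM (optional)."""
    out = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            kd = row.get("kd_nM", "")
            out.append(
                ExperimentalResult(
                    compound_id=row["compound_id"],
                    target_id=row["target_id"],
                    poc_percent=float(row["poc_percent"]),
                    kd_nM=float(kd) if kd not in ("", None) else None,
                )
            )
    return out


def write_pairs(pairs: Sequence[ChemicalPair], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_a", "compound_b", "label", "scheme"])
        for p in pairs:
            writer.writerow([p.compound_a, p.compound_b, p.label, p.scheme.value])


def read_pairs(path: str | Path) -> list[ChemicalPair]:
    out = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            p = ChemicalPair(row["compound_a"], row["compound_b"], row["scheme"])
            if int(row["label"]) != p.label:
                raise PairGenError(
                    f"label/scheme mismatch for pair {p.ids}: scheme "
                    f"{p.scheme.value} implies label {p.label}"
                )
            out.append(p)
    return out
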