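"""Virtual screening, novelty filtering, clustering and novelty reports.

The screening pipeline scores every library compound against a panel of
reference actives (taking the best pair score), keeps compounds at or above
a score cutoff (0.8 by default), then triages the hits:

1. **Similarity filter** — hits whose maximum Tanimoto similarity to any
   known active exceeds 0.47 (strictly) are flagged as insufficiently
   novel; 0.47 corresponds to an empirical p ~ 0.01 for FCFP-style
   fingerprints. Equality at the cutoff keeps the hit.
2. **External exclusion hooks** — arbitrary predicates (e.g. a
   pharmacophore-match filter computed elsewhere) flag hits for exclusion;
   the built-in PAINS hook flags pan-assay interference substructures but
   does not exclude by default.
3. **Butina clustering** of the surviving hits and selection of cluster
   centers (leaders) as the minimal, most conserved scaffolds to carry into
   experimental validation.

A novelty report ranks a candidate's Tanimoto similarity to reference
compounds under several fingerprint kinds, and a substructure search checks
whether the candidate's core (optionally with substituent positions
ignored) occurs in previously tested molecules.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import FilterCatalog

from .chemio import Compound, FingerprintKind, tanimoto
from .model import EcbsModel, EnsembleModel, compound_scores


class ScreenError(ValueError):
    pass


@dataclass
class ScreeningHit:
    compound_id: str
    ecbs_score: float
    best_active_id: str
    excluded_by: set[str] = field(default_factory=set)
    pains_flag: bool = False
    cluster_id: int | None = None
    is_center: bool = False

    @property
    def excluded(self) -> bool:
        return bool(self.excluded_by)


@dataclass(frozen=True)
class Cluster:
    members: tuple[str, ...]
    center_id: str

    def __post_init__(self):
        if not self.members:
            raise ScreenError("cluster must be non-empty")
        if self.center_id not in self.members:
            raise ScreenError(f"center {self.center_id!r} not among members")


def screen_library(
    model: EcbsModel | EnsembleModel,
    library: Sequence[Compound],
    reference_actives: Sequence[Compound],
    score_cutoff: float = 0.8,
) -> list[ScreeningHit]:
    """Score a library and keep compounds with best-pair score >= cutoff.

    Hits are sorted by score descending, ties by compound id. An empty
    library yields an empty hit list; an empty reference panel is an error.
    """
    if not reference_actives:
        raise ScreenError("reference active list is empty")
    if not library:
        return []
    scored = compound_scores(model, library, reference_actives)
    hits = [
        ScreeningHit(compound_id=c.id, ecbs_score=s, best_active_id=best)
        for c, (s, best) in zip(library, scored)
        if s >= score_cutoff
    ]
    hits.sort(key=lambda h: (-h.ecbs_score, h.compound_id))
    return hits


def similarity_filter(
    hits: Sequence[ScreeningHit],
    compounds: Mapping[str, Compound],
    known_actives: Sequence[Compound],
    fp_kind: FingerprintKind = FingerprintKind.FCFP6_LIKE,
    cutoff: float = 0.47,
) -> list[ScreeningHit]:
    """Flag hits too similar to known actives (max Tanimoto strictly > cutoff).

    The maximum similarity over the active panel is taken as representative.
    Hits exactly at the cutoff are kept. Returns the same hit objects with
    ``excluded_by`` updated.
    """
    if not known_actives:
        raise ScreenError("known active list is empty")
    active_fps = [a.fingerprint(fp_kind) for a in known_actives]
    for hit in hits:
        comp = compounds.get(hit.compound_id)
        if comp is None:
            raise ScreenError(f"hit {hit.compound_id!r} missing from compound map")
        fp = comp.fingerprint(fp_kind)
        max_sim = max(tanimoto(fp, afp) for afp in active_fps)
        if max_sim > cutoff:
            hit.excluded_by.add("similarity")
    return list(hits)


def apply_exclusion_hook(
    hits: Sequence[ScreeningHit],
    predicate: Callable[[Compound], bool],
    hook_name: str,
    compounds: Mapping[str, Compound],
    *,
    flag_only: bool = False,
) -> list[ScreeningHit]:
    """Apply an external predicate filter (e.g. a pharmacophore match).

    Hits for which the predicate is true get ``excluded_by += {hook_name}``,
    or — with ``flag_only`` — are merely flagged (used for PAINS). A
    predicate exception aborts with the offending hit id.
    """
    for hit in hits:
        comp = compounds.get(hit.compound_id)
        if comp is None:
            raise ScreenError(f"hit {hit.compound_id!r} missing from compound map")
        try:
            flagged = bool(predicate(comp))
        except Exception as e:
            raise ScreenError(
                f"exclusion hook {hook_name!r} failed on {hit.compound_id!r}: {e}"
            ) from e
        if flagged:
            if flag_only:
                hit.pains_flag = True
            else:
                hit.excluded_by.add(hook_name)
    return list(hits)


_PAINS_CATALOG: "FilterCatalog.FilterCatalog | None" = None


def pains_predicate(compound: Compound) -> bool:
    """True when the compound matches a PAINS substructure filter."""
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS_CATALOG = FilterCatalog.FilterCatalog(params)
    if compound.mol is None:
        raise ScreenError(f"compound {compound.id!r} has no structure for PAINS check")
    return _PAINS_CATALOG.HasMatch(compound.mol)


def flag_pains(
    hits: Sequence[ScreeningHit], compounds: Mapping[str, Compound]
) -> list[ScreeningHit]:
    """Set ``pains_flag`` on hits matching PAINS patterns (flag, not exclude)."""
    return apply_exclusion_hook(hits, pains_predicate, "pains", compounds, flag_only=True)


def butina_cluster(
    compounds: Sequence[Compound],
    fp_kind: FingerprintKind = FingerprintKind.PATH5_2048,
    sim_cutoff: float = 0.6,
) -> list[Cluster]:
    """Leader (Butina-style) clustering at a Tanimoto similarity cutoff.

    Two compounds are neighbors when their Tanimoto similarity is >= the
    cutoff. Repeatedly, the unassigned compound with the most unassigned
    neighbors (ties by lexicographic id) becomes a leader and claims itself
    plus its unassigned neighbors as a cluster; singletons form their own
    clusters. The leader is the cluster center. Clusters partition the
    input.
    """
    if not compounds:
        raise ScreenError("nothing to cluster")
    if not 0 < sim_cutoff <= 1:
        raise ScreenError(f"sim_cutoff must be in (0, 1], got {sim_cutoff}")
    ids = [c.id for c in compounds]
    if len(set(ids)) != len(ids):
        raise ScreenError("duplicate compound ids in clustering input")
    fps = [c.fingerprint(fp_kind) for c in compounds]
    n = len(compounds)
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if tanimoto(fps[i], fps[j]) >= sim_cutoff:
                neighbors[i].add(j)
                neighbors[j].add(i)

    unassigned = set(range(n))
    clusters: list[Cluster] = []
    while unassigned:
        leader = min(
            unassigned,
            key=lambda i: (-len(neighbors[i] & unassigned), ids[i]),
        )
        members = {leader} | (neighbors[leader] & unassigned)
        unassigned -= members
        clusters.append(
            Cluster(members=tuple(sorted(ids[i] for i in members)),
                    center_id=ids[leader])
        )
    return clusters


def select_cluster_centers(
    clusters: Sequence[Cluster], hits: Sequence[ScreeningHit]
) -> list[ScreeningHit]:
    """Mark exactly one hit per cluster (the leader) as the cluster center.

    Excluded hits never become centers; clusters must cover the unexcluded
    hits.
    """
    by_id = {h.compound_id: h for h in hits}
    clustered: set[str] = set()
    for ci, cluster in enumerate(clusters):
        for member in cluster.members:
            if member not in by_id:
                raise ScreenError(f"cluster references unknown hit {member!r}")
            by_id[member].cluster_id = ci
            clustered.add(member)
        center = by_id[cluster.center_id]
        if center.excluded:
            raise ScreenError(
                f"cluster center {cluster.center_id!r} is an excluded hit"
            )
        center.is_center = True
    uncovered = {h.compound_id for h in hits if not h.excluded} - clustered
    if uncovered:
        raise ScreenError(f"clusters do not cover unexcluded hits: {sorted(uncovered)}")
    return list(hits)


def novelty_report(
    query: Compound,
    references: Sequence[Compound],
    fp_kinds: Sequence[FingerprintKind] = (
        FingerprintKind.MORGAN_R2_1024,
        FingerprintKind.MACCS166,
    ),
    activities: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Ranked Tanimoto similarity of a query to reference compounds per kind.

    Returns a DataFrame with columns ``kind, reference_id, tanimoto,
    activity`` sorted by descending similarity within each kind — the table
    used to argue structural novelty of a new hit.
    """
    if not references:
        raise ScreenError("reference list is empty")
    activities = activities or {}
    rows = []
    for kind in fp_kinds:
        kind = FingerprintKind(kind)
        qfp = query.fingerprint(kind)
        for ref in references:
            rows.append(
                {
                    "kind": kind.value,
                    "reference_id": ref.id,
                    "tanimoto": tanimoto(qfp, ref.fingerprint(kind)),
                    "activity": activities.get(ref.id, ""),
                }
            )
    frame = pd.DataFrame(rows)
    return (
        frame.sort_values(["kind", "tanimoto", "reference_id"],
                          ascending=[True, False, True])
        .reset_index(drop=True)
    )


def substructure_match(
    core: Compound | str,
    candidates: Sequence[Compound],
    ignore_atom_indices: Iterable[int] | None = None,
) -> list[str]:
    """Ids of candidates containing the core as a substructure.

    ``core`` is a Compound or SMILES/SMARTS string. ``ignore_atom_indices``
    deletes the given core atoms before matching (e.g. ignoring amino and
    halo substituents to search for the bare scaffold); if deletion
    fragments the core, a candidate must contain every fragment.
    """
    if isinstance(core, Compound):
        mol = core.mol
        if mol is None:
            raise ScreenError(f"core compound {core.id!r} has no structure")
    else:
        mol = Chem.MolFromSmiles(core) or Chem.MolFromSmarts(core)
        if mol is None:
            raise ScreenError(f"unparsable core pattern {core!r}")
    if ignore_atom_indices:
        idx = sorted(set(int(i) for i in ignore_atom_indices), reverse=True)
        if idx and (idx[0] >= mol.GetNumAtoms() or idx[-1] < 0):
            raise ScreenError(
                f"ignore indices {idx} out of range for core with "
                f"{mol.GetNumAtoms()} atoms"
            )
        rw = Chem.RWMol(mol)
        for i in idx:
            rw.RemoveAtom(i)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol, catchErrors=True)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    matched = []
    for cand in candidates:
        if cand.mol is None:
            raise ScreenError(f"candidate {cand.id!r} has no structure")
        if all(cand.mol.HasSubstructMatch(f) for f in frags):
            matched.append(cand.id)
    return matched


def write_hits(hits: Sequence[ScreeningHit], path: str | Path) -> None:
    """Hit table CSV: compound_id,score,best_active,excluded_by,pains_flag,cluster_id,is_center."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["compound_id", "score", "best_active", "excluded_by", "pains_flag",
             "cluster_id", "is_center"]
        )
        for h in hits:
            writer.writerow(
                [
                    h.compound_id,
                    f"{h.ecbs_score:.6f}",
                    h.best_active_id,
                    ";".join(sorted(h.excluded_by)),
                    int(h.pains_flag),
                    "" if h.cluster_id is None else h.cluster_id,
                    int(h.is_center),
                ]
            )
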