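"""Synthetic compound universes for end-to-end testing without downloads.

The generator emulates the data regime an iterative pair-similarity screen
operates in:

* **Actives** for a target share that target's scaffold: a core ring system
  decorated with random substituents. Compounds of family-related targets
  carry different scaffolds but become positives at family scope.
* **Near-miss inactives** carry the same scaffold as the actives plus an
  activity-breaking substituent — structurally similar to actives but
  experimentally inactive. These are exactly the false positives an initial
  random-negative-trained model retrieves, and the compounds whose NP pairs
  should teach a retrained model to reject them.
* **Decoys** are random assemblies of unrelated fragments, standing in for
  a drug-like screening library background.

Two generation modes share this structure:

``smiles``
    Real molecules assembled with RDKit from fragment libraries; exercises
    the full chemistry stack (parsing, fingerprints, clustering, PAINS).
``abstract``
    Direct fingerprint bit-vector sampling (shared scaffold bits, breaker
    bits, background noise) bypassing chemistry entirely; fast and exactly
    reproducible across toolkit versions, used for model and evaluation
    tests.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem

from .chemio import (
    Compound,
    Fingerprint,
    FingerprintKind,
    abstract_compound,
    fingerprint_length,
    parse_compound,
    write_compound_table,
)
from .model import DEFAULT_MODEL_KINDS
from .pairgen import (
    ChemicalPair,
    ExperimentalResult,
    Interaction,
    PairingInput,
    TargetProtein,
    build_ercps,
    sample_negative_pairs,
)


class SynthDataError(ValueError):
    pass


#: Scaffold cores, one per synthetic target (two attachment points each).
DEFAULT_SCAFFOLDS = (
    "[*:1]c1nc2ccccc2c([*:2])n1",        # quinazoline
    "[*:1]c1nc2ccccc2n1[*:2]",           # benzimidazole
    "[*:1]c1ccc2cc([*:2])ccc2n1",        # quinoline
    "[*:1]c1nc(-c2ccc([*:2])cc2)cs1",    # phenylthiazole
    "O=C1C=C([*:1])Oc2cc([*:2])ccc12",   # chromenone
    "[*:1]c1cc2ccccc2n1[*:2]",           # indole
)

#: Ordinary substituents used to decorate scaffolds and decoy cores.
DEFAULT_DECORATIONS = (
    "[*:1]C",
    "[*:1]CC",
    "[*:1]C(C)C",
    "[*:1]OC",
    "[*:1]O",
    "[*:1]N",
    "[*:1]N(C)C",
    "[*:1]F",
    "[*:1]Cl",
    "[*:1]Br",
    "[*:1]CCO",
    "[*:1]C(=O)N",
    "[*:1]C(=O)OC",
    "[*:1]c1ccccc1",
    "[*:1]C#N",
    "[*:1]CO",
)

#: Activity-breaking substituents given to near-miss inactives.
DEFAULT_BREAKERS = (
    "[*:1]CC(=O)O",
    "[*:1]S(=O)(=O)N",
    "[*:1]S(=O)(=O)C",
    "[*:1]C(=O)NCCN",
    "[*:1]CC[N+](C)(C)C",
)

#: Cores for decoy assembly (deliberately unlike the target scaffolds).
DEFAULT_DECOY_CORES = (
    "[*:1]c1ccc([*:2])cc1",
    "[*:1]C1CCC([*:2])CC1",
    "[*:1]c1ccc([*:2])o1",
    "[*:1]c1cccc([*:2])n1",
    "[*:1]C1CCN([*:2])CC1",
    "[*:1]CCOCC[*:2]",
    "[*:1]c1ccc([*:2])s1",
    "[*:1]C1CCOC1[*:2]",
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic universe.

    ``actives_per_target`` and ``n_near_miss`` are per target; ``n_decoys``
    is global. ``noise_rate`` is the probability of dropping an individual
    scaffold bit (abstract mode only; the SMILES mode gets its variability
    from random decorations). ``families_per_db`` maps a family database
    name to its number of families; targets are assigned round-robin so
    family-level related pairs exist.
    """

    n_targets: int = 2
    families_per_db: Mapping[str, int] = field(
        default_factory=lambda: {"PFAM": 1, "SMART": 1}
    )
    actives_per_target: int = 12
    n_decoys: int = 60
    n_near_miss: int = 12
    scaffold_library: tuple[str, ...] = DEFAULT_SCAFFOLDS
    decoration_library: tuple[str, ...] = DEFAULT_DECORATIONS
    breaker_library: tuple[str, ...] = DEFAULT_BREAKERS
    decoy_core_library: tuple[str, ...] = DEFAULT_DECOY_CORES
    noise_rate: float = 0.05
    mode: str = "smiles"
    fp_kinds: tuple[FingerprintKind, ...] = DEFAULT_MODEL_KINDS
    seed: int = 0

    def __post_init__(self):
        if min(self.n_targets, self.actives_per_target, self.n_decoys,
               self.n_near_miss) < 0:
            raise SynthDataError("counts must be non-negative")
        if not 0 <= self.noise_rate <= 1:
            raise SynthDataError("noise_rate must be in [0, 1]")
        if self.mode not in ("smiles", "abstract"):
            raise SynthDataError("mode must be 'smiles' or 'abstract'")
        if self.mode == "smiles":
            for name in ("scaffold_library", "decoration_library",
                         "breaker_library", "decoy_core_library"):
                if not getattr(self, name):
                    raise SynthDataError(f"{name} must be non-empty in SMILES mode")
        if self.mode == "smiles" and self.n_targets > len(self.scaffold_library):
            raise SynthDataError(
                f"need {self.n_targets} scaffolds, library has "
                f"{len(self.scaffold_library)}"
            )


@dataclass
class SyntheticUniverse:
    """A generated compound universe with ground truth."""

    config: SynthConfig
    compounds: dict[str, Compound]
    targets: list[TargetProtein]
    interactions: list[Interaction]
    truth: dict[str, str]  # id -> "active@<target>" | "near_miss@<target>" | "decoy"

    def actives(self, target_id: str | None = None) -> list[str]:
        tag = "active@" + target_id if target_id else "active@"
        return sorted(c for c, t in self.truth.items() if t.startswith(tag))

    def near_misses(self, target_id: str | None = None) -> list[str]:
        tag = "near_miss@" + target_id if target_id else "near_miss@"
        return sorted(c for c, t in self.truth.items() if t.startswith(tag))

    def decoys(self) -> list[str]:
        return sorted(c for c, t in self.truth.items() if t == "decoy")


# ---------------------------------------------------------------------------
# SMILES-mode assembly


def _attach(core: "Chem.Mol", site: int, decoration_smiles: str) -> "Chem.Mol":
    dec = Chem.MolFromSmiles(decoration_smiles)
    if dec is None:
        raise SynthDataError(f"bad decoration SMILES {decoration_smiles!r}")
    dec = Chem.RWMol(dec)
    for atom in dec.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == 1:
            atom.SetAtomMapNum(site)
    return Chem.molzip(Chem.CombineMols(core, dec.GetMol()))


def _assemble(core_smiles: str, dec1: str, dec2: str) -> str:
    core = Chem.MolFromSmiles(core_smiles)
    if core is None:
        raise SynthDataError(f"bad core SMILES {core_smiles!r}")
    mol = _attach(_attach(core, 1, dec1), 2, dec2)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _draw_decoration_pairs(
    rng: np.random.Generator, decorations: Sequence[str], n: int
) -> list[tuple[str, str]]:
    """n distinct (site1, site2) decoration combinations, random order."""
    combos = [(d1, d2) for d1 in decorations for d2 in decorations]
    if n > len(combos):
        raise SynthDataError(
            f"cannot draw {n} distinct decoration pairs from "
            f"{len(decorations)} decorations"
        )
    idx = rng.choice(len(combos), size=n, replace=False)
    return [combos[int(i)] for i in idx]


# ---------------------------------------------------------------------------
# Abstract-mode bit sampling

_BG_RATE = 0.08           # background on-rate per bit
_SCAFFOLD_FRACTION = 0.15  # fraction of bits reserved as a target's scaffold
_BREAKER_FRACTION = 0.08   # fraction of bits acting as activity breakers


def _abstract_fp(
    rng: np.random.Generator,
    kind: FingerprintKind,
    scaffold_bits: np.ndarray | None,
    breaker_bits: np.ndarray | None,
    noise_rate: float,
) -> Fingerprint:
    n = fingerprint_length(kind)
    bits = (rng.random(n) < _BG_RATE).astype(np.uint8)
    if scaffold_bits is not None:
        keep = rng.random(scaffold_bits.shape[0]) >= noise_rate
        bits[scaffold_bits[keep]] = 1
    if breaker_bits is not None:
        keep = rng.random(breaker_bits.shape[0]) >= noise_rate
        bits[breaker_bits[keep]] = 1
    return Fingerprint(kind, bits)


def generate_universe(config: SynthConfig) -> SyntheticUniverse:
    """Generate a deterministic universe of actives, near-misses and decoys."""
    rng = np.random.default_rng(config.seed)
    targets = []
    target_ids = [f"T{i + 1}" for i in range(config.n_targets)]
    for i, tid in enumerate(target_ids):
        families = {
            db: frozenset({f"{db}_F{i % n_fam}"})
            for db, n_fam in config.families_per_db.items()
            if n_fam > 0
        }
        targets.append(TargetProtein(id=tid, families=families))

    compounds: dict[str, Compound] = {}
    truth: dict[str, str] = {}
    interactions: list[Interaction] = []

    if config.mode == "smiles":
        for ti, tid in enumerate(target_ids):
            scaffold = config.scaffold_library[ti]
            combos = _draw_decoration_pairs(
                rng, config.decoration_library,
                config.actives_per_target + config.n_near_miss,
            )
            for j in range(config.actives_per_target):
                cid = f"ACT_{tid}_{j:03d}"
                d1, d2 = combos[j]
                compounds[cid] = parse_compound(cid, _assemble(scaffold, d1, d2))
                truth[cid] = f"active@{tid}"
                affinity = float(10 ** rng.uniform(0, 3))  # 1 nM .. 1 uM
                interactions.append(Interaction(cid, tid, affinity))
            for j in range(config.n_near_miss):
                cid = f"NM_{tid}_{j:03d}"
                d1, _ = combos[config.actives_per_target + j]
                breaker = config.breaker_library[
                    int(rng.integers(len(config.breaker_library)))
                ]
                compounds[cid] = parse_compound(cid, _assemble(scaffold, d1, breaker))
                truth[cid] = f"near_miss@{tid}"
        for j in range(config.n_decoys):
            cid = f"DEC_{j:04d}"
            core = config.decoy_core_library[
                int(rng.integers(len(config.decoy_core_library)))
            ]
            d1 = config.decoration_library[
                int(rng.integers(len(config.decoration_library)))
            ]
            d2 = config.decoration_library[
                int(rng.integers(len(config.decoration_library)))
            ]
            compounds[cid] = parse_compound(cid, _assemble(core, d1, d2))
            truth[cid] = "decoy"
    else:
        kinds = tuple(FingerprintKind(k) for k in config.fp_kinds)
        scaffold_bits: dict[str, dict[FingerprintKind, np.ndarray]] = {}
        breaker_bits: dict[str, dict[FingerprintKind, np.ndarray]] = {}
        for tid in target_ids:
            scaffold_bits[tid] = {}
            breaker_bits[tid] = {}
            for kind in kinds:
                n = fingerprint_length(kind)
                n_scaf = max(4, int(round(_SCAFFOLD_FRACTION * n)))
                n_break = max(3, int(round(_BREAKER_FRACTION * n)))
                chosen = rng.choice(n, size=n_scaf + n_break, replace=False)
                scaffold_bits[tid][kind] = np.sort(chosen[:n_scaf])
                breaker_bits[tid][kind] = np.sort(chosen[n_scaf:])
        for tid in target_ids:
            for j in range(config.actives_per_target):
                cid = f"ACT_{tid}_{j:03d}"
                fps = {
                    k: _abstract_fp(rng, k, scaffold_bits[tid][k], None,
                                    config.noise_rate)
                    for k in kinds
                }
                compounds[cid] = abstract_compound(cid, fps)
                truth[cid] = f"active@{tid}"
                interactions.append(Interaction(cid, tid, float(10 ** rng.uniform(0, 3))))
            for j in range(config.n_near_miss):
                cid = f"NM_{tid}_{j:03d}"
                fps = {
                    k: _abstract_fp(rng, k, scaffold_bits[tid][k],
                                    breaker_bits[tid][k], config.noise_rate)
                    for k in kinds
                }
                compounds[cid] = abstract_compound(cid, fps)
                truth[cid] = f"near_miss@{tid}"
        for j in range(config.n_decoys):
            cid = f"DEC_{j:04d}"
            fps = {k: _abstract_fp(rng, k, None, None, config.noise_rate)
                   for k in kinds}
            compounds[cid] = abstract_compound(cid, fps)
            truth[cid] = "decoy"

    return SyntheticUniverse(
        config=config,
        compounds=compounds,
        targets=targets,
        interactions=interactions,
        truth=truth,
    )


def generate_new_experimental_data(
    universe: SyntheticUniverse,
    n_true_pos: int,
    n_false_pos: int,
    seed: int,
    focus_target: str | None = None,
    n_prv_per_active: float = 4.0,
    n_prv_actives: int | None = None,
) -> tuple[PairingInput, list[ExperimentalResult]]:
    """Emulate one round of experimental validation for a focus target.

    Samples ``n_true_pos`` new actives and ``n_false_pos`` new inactives
    (from the near-miss pool); the remaining focus-target actives become
    P_prv and a decoy sample of about ``n_prv_per_active x |P_prv|``
    becomes N_prv. POC values are drawn from [0, 15]% for actives and
    [85, 100]% for inactives, consistent with the 20/80 labeling bounds.

    ``n_prv_actives`` caps the size of P_prv (a random sample of the
    remaining actives); actives outside P_new and P_prv stay unused and can
    later be planted into a screening library.
    """
    focus = focus_target or universe.targets[0].id
    actives = universe.actives(focus)
    near = universe.near_misses(focus)
    decoys = universe.decoys()
    if n_true_pos > len(actives):
        raise SynthDataError(
            f"requested {n_true_pos} new actives, universe has {len(actives)}"
        )
    if n_false_pos > len(near):
        raise SynthDataError(
            f"requested {n_false_pos} new inactives, universe has {len(near)}"
        )
    rng = np.random.default_rng(seed)
    p_new = sorted(
        np.asarray(actives)[rng.choice(len(actives), size=n_true_pos, replace=False)]
    )
    n_new = sorted(
        np.asarray(near)[rng.choice(len(near), size=n_false_pos, replace=False)]
    )
    p_prv = sorted(set(actives) - set(p_new))
    if n_prv_actives is not None and n_prv_actives < len(p_prv):
        p_prv = sorted(
            np.asarray(p_prv)[
                rng.choice(len(p_prv), size=n_prv_actives, replace=False)
            ]
        )
    n_prv_count = min(len(decoys), int(round(n_prv_per_active * max(1, len(p_prv)))))
    n_prv = sorted(
        np.asarray(decoys)[rng.choice(len(decoys), size=n_prv_count, replace=False)]
    )
    pairing = PairingInput(
        P_new=frozenset(p_new),
        N_new=frozenset(n_new),
        P_prv=frozenset(p_prv),
        N_prv=frozenset(n_prv),
    )
    results = [
        ExperimentalResult(cid, focus, poc_percent=float(rng.uniform(0, 15)))
        for cid in p_new
    ] + [
        ExperimentalResult(cid, focus, poc_percent=float(rng.uniform(85, 100)))
        for cid in n_new
    ]
    return pairing, results


def generate_screening_library(
    universe: SyntheticUniverse,
    n_background: int,
    n_planted_hits: int,
    seed: int,
    exclude: Iterable[str] = (),
    focus_target: str | None = None,
) -> tuple[list[Compound], dict[str, str]]:
    """A shuffled screening library of fresh decoys plus planted actives.

    Planted hits are universe actives of the focus target not listed in
    ``exclude`` (e.g. the ids already used for training); backgrounds are
    newly generated decoys. Returns the library and a truth map of the
    planted ids.
    """
    focus = focus_target or universe.targets[0].id
    excluded = set(exclude)
    available = [c for c in universe.actives(focus) if c not in excluded]
    if n_planted_hits > len(available):
        raise SynthDataError(
            f"cannot plant {n_planted_hits} hits; only {len(available)} unused "
            f"actives available"
        )
    rng = np.random.default_rng(seed)
    planted_ids = sorted(
        np.asarray(available)[
            rng.choice(len(available), size=n_planted_hits, replace=False)
        ]
    )
    config = universe.config
    background: list[Compound] = []
    if config.mode == "smiles":
        for j in range(n_background):
            cid = f"LIB_{j:05d}"
            core = config.decoy_core_library[
                int(rng.integers(len(config.decoy_core_library)))
            ]
            d1 = config.decoration_library[
                int(rng.integers(len(config.decoration_library)))
            ]
            d2 = config.decoration_library[
                int(rng.integers(len(config.decoration_library)))
            ]
            background.append(parse_compound(cid, _assemble(core, d1, d2)))
    else:
        kinds = tuple(FingerprintKind(k) for k in config.fp_kinds)
        for j in range(n_background):
            cid = f"LIB_{j:05d}"
            fps = {k: _abstract_fp(rng, k, None, None, config.noise_rate)
                   for k in kinds}
            background.append(abstract_compound(cid, fps))

    library = background + [universe.compounds[c] for c in planted_ids]
    order = rng.permutation(len(library))
    library = [library[int(i)] for i in order]
    planted_truth = {cid: universe.truth[cid] for cid in planted_ids}
    return library, planted_truth


def make_retraining_scenario(
    universe: SyntheticUniverse,
    n_true_pos: int = 4,
    n_false_pos: int = 12,
    neg_per_pos: float = 6.0,
    seed: int = 0,
    focus_target: str | None = None,
    n_prv_actives: int | None = None,
) -> tuple[list[ChemicalPair], PairingInput]:
    """Base training pairs plus a PairingInput for retraining experiments.

    The base set contains the target-scope positive pairs among the
    previous actives (P_prv) and sampled random negatives against the
    previous-negative pool, i.e. the state of a model *before* the new
    experimental round.
    """
    pairing, _ = generate_new_experimental_data(
        universe, n_true_pos, n_false_pos, seed, focus_target,
        n_prv_actives=n_prv_actives,
    )
    focus = focus_target or universe.targets[0].id
    prv_interactions = [
        i for i in universe.interactions if i.compound_id in pairing.P_prv
    ]
    positives = build_ercps(prv_interactions, universe.targets, focus, "target")
    negatives = sample_negative_pairs(
        pairing.P_prv, pairing.N_prv, neg_per_pos, len(positives), seed
    )
    return positives + negatives, pairing


def write_universe(universe: SyntheticUniverse, outdir: str | Path) -> dict[str, Path]:
    """Write the universe in the same formats the real pipeline reads.

    Emits ``compounds.csv`` (+ ``compounds.smi`` in SMILES mode),
    ``interactions.csv``, ``families.csv`` and ``truth.csv``; returns the
    paths.
    """
    import csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ordered = [universe.compounds[c] for c in sorted(universe.compounds)]
    paths["compounds"] = outdir / "compounds.csv"
    write_compound_table(ordered, paths["compounds"])
    if universe.config.mode == "smiles":
        paths["smi"] = outdir / "compounds.smi"
        with paths["smi"].open("w") as fh:
            for c in ordered:
                fh.write(f"{c.smiles} {c.id}\n")

    paths["interactions"] = outdir / "interactions.csv"
    with paths["interactions"].open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "target_id", "affinity_nM"])
        for i in universe.interactions:
            writer.writerow([i.compound_id, i.target_id,
                             "" if i.affinity_nM is None else f"{i.affinity_nM:.4f}"])

    paths["families"] = outdir / "families.csv"
    with paths["families"].open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target_id", "family_db", "family_id"])
        for t in universe.targets:
            for db in sorted(t.families):
                for fam in sorted(t.families[db]):
                    writer.writerow([t.id, db, fam])

    paths["truth"] = outdir / "truth.csv"
    with paths["truth"].open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "truth"])
        for cid in sorted(universe.truth):
            writer.writerow([cid, universe.truth[cid]])
    return paths
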