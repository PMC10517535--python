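"""Compound parsing, binary fingerprints and Tanimoto similarity.

This module is the chemistry layer of the package: it turns SMILES/SDF/CSV
records into :class:`Compound` objects with canonical SMILES, computes the
binary fingerprints the pair models and filters consume, and measures
Tanimoto similarity between fingerprints of the same kind.

Fingerprint kinds
-----------------
``MACCS166``
    The 166 public MACCS keys (RDKit's implementation; RDKit's bit 0 is a
    placeholder and is dropped so the vector length is exactly 166).
``SUBSTRUCT_FP4``
    A substructure fingerprint in the spirit of functional-group pattern
    fingerprints: an ordered catalog of SMARTS patterns shipped with the
    package (``data/substruct_patterns.smarts``); bit *i* is set when
    pattern *i* matches. The catalog length is fixed per build and recorded
    in model metadata.
``MORGAN_R2_1024``
    Morgan circular fingerprint, radius 2, hashed to 1024 bits.
``PATH5_2048``
    Path/subgraph fingerprint with paths up to 5 bonds hashed to 2048 bits
    (the "RDK5" fingerprint used for clustering tested molecules).
``FCFP6_LIKE``
    Functional-class circular fingerprint: Morgan radius 3, 1024 bits, with
    pharmacophoric feature atom invariants. A stand-in for proprietary
    FCFP_6; declared in model metadata so filters are self-consistent.

Multi-fragment (salt form) SMILES are reduced to the largest organic
fragment before canonicalization and fingerprinting, because screening
libraries commonly contain salts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")  # rdkit warnings are noise at library scale


class ChemIOError(ValueError):
    """Base class for compound parsing / fingerprinting errors."""


class SmilesParseError(ChemIOError):
    """A SMILES string could not be parsed; carries the offending id."""

    def __init__(self, compound_id: str, smiles: str):
        self.compound_id = compound_id
        self.smiles = smiles
        super().__init__(f"unparsable SMILES for compound {compound_id!r}: {smiles!r}")


class DuplicateIdError(ChemIOError):
    pass


class FingerprintKind(str, Enum):
    MACCS166 = "MACCS166"
    SUBSTRUCT_FP4 = "SUBSTRUCT_FP4"
    MORGAN_R2_1024 = "MORGAN_R2_1024"
    PATH5_2048 = "PATH5_2048"
    FCFP6_LIKE = "FCFP6_LIKE"


def _load_substruct_catalog() -> list[tuple[str, "Chem.Mol"]]:
    text = (
        resources.files("ecbs").joinpath("data/substruct_patterns.smarts").read_text()
    )
    catalog = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:  # pragma: no cover - catalog is validated by tests
            raise ChemIOError(f"invalid SMARTS in catalog: {name}")
        catalog.append((name, patt))
    return catalog


_SUBSTRUCT_CATALOG: list[tuple[str, "Chem.Mol"]] | None = None


def substruct_catalog() -> list[tuple[str, "Chem.Mol"]]:
    """The ordered SMARTS pattern catalog backing SUBSTRUCT_FP4 (cached)."""
    global _SUBSTRUCT_CATALOG
    if _SUBSTRUCT_CATALOG is None:
        _SUBSTRUCT_CATALOG = _load_substruct_catalog()
    return _SUBSTRUCT_CATALOG


def fingerprint_length(kind: FingerprintKind) -> int:
    """Fixed bit-vector length for a fingerprint kind in this build."""
    kind = FingerprintKind(kind)
    if kind is FingerprintKind.MACCS166:
        return 166
    if kind is FingerprintKind.SUBSTRUCT_FP4:
        return len(substruct_catalog())
    if kind is FingerprintKind.MORGAN_R2_1024:
        return 1024
    if kind is FingerprintKind.PATH5_2048:
        return 2048
    if kind is FingerprintKind.FCFP6_LIKE:
        return 1024
    raise ChemIOError(  # pragma: no cover
        f"unsupported fingerprint kind {kind!r}; supported: "
        f"{[k.value for k in FingerprintKind]}"
    )


@dataclass(frozen=True)
class Fingerprint:
    """An immutable fixed-length binary fingerprint."""

    kind: FingerprintKind
    bits: np.ndarray  # uint8 0/1, read-only

    def __post_init__(self):
        arr = np.ascontiguousarray(self.bits, dtype=np.uint8)
        expected = fingerprint_length(self.kind)
        if arr.ndim != 1 or arr.shape[0] != expected:
            raise ChemIOError(
                f"{self.kind.value} fingerprint must have {expected} bits, "
                f"got shape {arr.shape}"
            )
        arr.flags.writeable = False
        object.__setattr__(self, "bits", arr)

    def __len__(self) -> int:
        return int(self.bits.shape[0])

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    @property
    def on_bits(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.bits))

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_bitstring(cls, kind: FingerprintKind, s: str) -> "Fingerprint":
        return cls(kind, np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))

    @classmethod
    def from_on_bits(
        cls, kind: FingerprintKind, on: Iterable[int]
    ) -> "Fingerprint":
        bits = np.zeros(fingerprint_length(kind), dtype=np.uint8)
        idx = list(on)
        if idx:
            bits[idx] = 1
        return cls(kind, bits)


_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
_FCFP_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=3,
    fpSize=1024,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
)
_PATH5_GEN = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=5, fpSize=2048)
_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)


def _fingerprint_mol(mol: "Chem.Mol", kind: FingerprintKind) -> Fingerprint:
    kind = FingerprintKind(kind)
    if kind is FingerprintKind.MACCS166:
        bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
        bits = np.zeros(167, dtype=np.uint8)
        bits[list(bv.GetOnBits())] = 1
        return Fingerprint(kind, bits[1:])
    if kind is FingerprintKind.SUBSTRUCT_FP4:
        bits = np.fromiter(
            (1 if mol.HasSubstructMatch(p) else 0 for _, p in substruct_catalog()),
            dtype=np.uint8,
        )
        return Fingerprint(kind, bits)
    if kind is FingerprintKind.MORGAN_R2_1024:
        gen = _MORGAN_GEN
    elif kind is FingerprintKind.FCFP6_LIKE:
        gen = _FCFP_GEN
    elif kind is FingerprintKind.PATH5_2048:
        gen = _PATH5_GEN
    else:  # pragma: no cover
        raise ChemIOError(f"unsupported fingerprint kind {kind!r}")
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(bv.GetNumBits(), dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(kind, bits)


@dataclass
class Compound:
    """An identified chemical structure with lazily cached fingerprints.

    ``smiles`` holds the canonical SMILES. Synthetic "abstract" compounds
    (used by the chemistry-free generator mode) may carry ``smiles=None``
    together with pre-populated fingerprints; requesting an uncached
    fingerprint of such a compound is an error.
    """

    id: str
    smiles: str | None
    _mol: "Chem.Mol | None" = field(default=None, repr=False, compare=False)
    _fps: dict[FingerprintKind, Fingerprint] = field(
        default_factory=dict, repr=False, compare=False
    )

    def fingerprint(self, kind: FingerprintKind) -> Fingerprint:
        kind = FingerprintKind(kind)
        fp = self._fps.get(kind)
        if fp is None:
            if self._mol is None:
                raise ChemIOError(
                    f"compound {self.id!r} has no structure and no cached "
                    f"{kind.value} fingerprint"
                )
            fp = _fingerprint_mol(self._mol, kind)
            self._fps[kind] = fp
        return fp

    @property
    def mol(self) -> "Chem.Mol | None":
        return self._mol


def parse_compound(compound_id: str, smiles: str, *, strip_salts: bool = True) -> Compound:
    """Parse a SMILES into a Compound with canonical SMILES.

    Multi-fragment inputs keep only the largest organic fragment when
    ``strip_salts`` is set (the default). Raises :class:`SmilesParseError`
    naming the compound when the SMILES does not parse.
    """
    if not compound_id:
        raise ChemIOError("compound id must be non-empty")
    if not smiles:
        raise SmilesParseError(compound_id, smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(compound_id, smiles)
    if strip_salts and len(Chem.GetMolFrags(mol)) > 1:
        mol = _LARGEST_FRAGMENT.choose(mol)
    return Compound(id=compound_id, smiles=Chem.MolToSmiles(mol), _mol=mol)


def compute_fingerprint(compound: Compound, kind: FingerprintKind) -> Fingerprint:
    """Compute (or fetch from cache) a fingerprint of the given kind."""
    try:
        kind = FingerprintKind(kind)
    except ValueError:
        raise ChemIOError(
            f"unsupported fingerprint kind {kind!r}; supported kinds: "
            f"{[k.value for k in FingerprintKind]}"
        ) from None
    return compound.fingerprint(kind)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| between same-kind fingerprints.

    Defined as 0.0 when both vectors are all-zero so that degenerate
    molecules cannot poison a screen with NaNs.
    """
    if a.kind != b.kind:
        raise ChemIOError(
            f"fingerprint kind mismatch: {a.kind.value} vs {b.kind.value}"
        )
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 0.0
    return inter / union


# ---------------------------------------------------------------------------
# Tables of compounds


def read_compound_table(
    path: str | Path,
    fmt: str | None = None,
    *,
    on_error: str = "raise",
) -> list[Compound]:
    """Read compounds from a ``.smi``, SDF or CSV file, order preserved.

    ``fmt`` is one of ``{"smi", "sdf", "csv"}``; when omitted it is inferred
    from the file suffix. ``on_error="skip"`` drops unparsable records with a
    warning instead of raising; duplicate ids always raise.
    """
    import warnings

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".smi": "smi", ".sdf": "sdf", ".csv": "csv"}.get(path.suffix.lower())
        if fmt is None:
            raise ChemIOError(f"cannot infer format from suffix of {path.name!r}")
    if on_error not in ("raise", "skip"):
        raise ChemIOError("on_error must be 'raise' or 'skip'")

    records: list[tuple[str, str, int]] = []  # (id, smiles, line_no)
    if fmt == "smi":
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{i}"
            records.append((cid, smiles, i))
    elif fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"id", "smiles"} <= set(
                reader.fieldnames
            ):
                raise ChemIOError(f"{path.name}: CSV must have 'id' and 'smiles' columns")
            for i, row in enumerate(reader, start=2):
                records.append((row["id"], row["smiles"], i))
    elif fmt == "sdf":
        compounds: list[Compound] = []
        seen: set[str] = set()
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                if on_error == "skip":
                    warnings.warn(f"{path.name}: skipping unparsable SDF record {i}")
                    continue
                raise SmilesParseError(f"sdf_record_{i}", "<SDF>")
            cid = (
                mol.GetProp("_Name")
                if mol.HasProp("_Name") and mol.GetProp("_Name")
                else f"sdf_record_{i}"
            )
            if cid in seen:
                raise DuplicateIdError(f"{path.name}: duplicate compound id {cid!r}")
            seen.add(cid)
            if len(Chem.GetMolFrags(mol)) > 1:
                mol = _LARGEST_FRAGMENT.choose(mol)
            compounds.append(Compound(id=cid, smiles=Chem.MolToSmiles(mol), _mol=mol))
        return compounds
    else:
        raise ChemIOError(f"unsupported format {fmt!r}; use smi, sdf or csv")

    compounds = []
    seen = set()
    bad_lines: list[int] = []
    for cid, smiles, line_no in records:
        if cid in seen:
            raise DuplicateIdError(
                f"{path.name}: duplicate compound id {cid!r} at line {line_no}"
            )
        try:
            compounds.append(parse_compound(cid, smiles))
        except SmilesParseError:
            if on_error == "skip":
                bad_lines.append(line_no)
                continue
            raise ChemIOError(
                f"{path.name}: unparsable SMILES at line {line_no} (id {cid!r})"
            ) from None
        seen.add(cid)
    if bad_lines:
        warnings.warn(f"{path.name}: skipped unparsable lines {bad_lines}")
    return compounds


def write_compound_table(compounds: Sequence[Compound], path: str | Path) -> None:
    """Write canonical SMILES to CSV (columns ``id,smiles``)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles"])
        for c in compounds:
            writer.writerow([c.id, c.smiles if c.smiles is not None else ""])


def write_fingerprint_cache(
    compounds: Sequence[Compound], kinds: Sequence[FingerprintKind], path: str | Path
) -> None:
    """Persist fingerprints as a CSV of bitstrings (id, kind, bits)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "kind", "bits"])
        for c in compounds:
            for kind in kinds:
                writer.writerow([c.id, FingerprintKind(kind).value,
                                 c.fingerprint(kind).to_bitstring()])


def read_fingerprint_cache(path: str | Path) -> dict[str, dict[FingerprintKind, Fingerprint]]:
    out: dict[str, dict[FingerprintKind, Fingerprint]] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            kind = FingerprintKind(row["kind"])
            out.setdefault(row["id"], {})[kind] = Fingerprint.from_bitstring(
                kind, row["bits"]
            )
    return out


def abstract_compound(
    compound_id: str, fingerprints: Mapping[FingerprintKind, Fingerprint]
) -> Compound:
    """Build a structure-free compound from pre-computed fingerprints.

    Used by the chemistry-free synthetic-data mode; such compounds support
    every fingerprint-consuming operation but have no SMILES or mol.
    """
    if not fingerprints:
        raise ChemIOError("abstract compound needs at least one fingerprint")
    return Compound(
        id=compound_id, smiles=None, _mol=None,
        _fps={FingerprintKind(k): v for k, v in fingerprints.items()},
    )
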