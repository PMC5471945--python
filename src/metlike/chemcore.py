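"""Structure ingestion, molecular fingerprints, and Tanimoto similarity.

Drugs and metabolites are represented as :class:`Compound` records parsed
with RDKit from SDF files or delimited SMILES tables.  Each compound is
encoded as a binary substructure fingerprint (default: the 166-key MACCS
set, stored RDKit-style in a 167-slot vector with index 0 unused), and
pairs are compared with the Tanimoto coefficient

    T_c(A, B) = C / (A + B - C)

where ``A`` and ``B`` are the numbers of bits set in the two fingerprints
and ``C`` the number of shared bits.  This coefficient is the Jaccard index
on bit sets and is the single similarity measure used by every downstream
stage of the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit import RDLogger

logger = logging.getLogger("metlike")

# Silence per-record RDKit parse chatter; failures are counted and logged
# by our loaders instead.
RDLogger.DisableLog("rdApp.error")

#: Known fingerprint schemes and their vector lengths.  MACCS keys are
#: numbered 1..166; RDKit emits a 167-bit vector whose slot 0 is never set.
FP_SCHEMES: dict[str, int] = {"maccs": 167}

ROLES = ("drug", "metabolite")


class ChemError(Exception):
    """Base class for structure/fingerprint errors."""


class FingerprintError(ChemError):
    """Raised when a compound cannot be fingerprinted (names the id)."""


class SchemeMismatchError(ChemError):
    """Raised when two fingerprints of different schemes are compared."""


class EmptyFingerprintWarning(UserWarning):
    """Both fingerprints are empty; similarity defined as 1.0."""


# ---------------------------------------------------------------------------
# Compounds
# ---------------------------------------------------------------------------

@dataclass
class Compound:
    """A drug or metabolite with an identifier and a parsed structure.

    ``mol`` is ``None`` (and ``failed`` True) when the structure record
    could not be parsed; such compounds are excluded from fingerprinting
    but never silently dropped from bookkeeping.
    """

    id: str
    name: str
    role: str
    smiles: str | None = None
    mol: object | None = field(default=None, repr=False)
    annotations: dict = field(default_factory=dict)
    failed: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


def _largest_organic_fragment(mol):
    """Keep the largest fragment, preferring carbon-containing ones.

    Database SDF records frequently carry counter-ions and water of
    crystallisation; reference similarity values are computed on parent
    structures, so salts are stripped by default before fingerprinting.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol

    def key(frag):
        has_c = any(a.GetSymbol() == "C" for a in frag.GetAtoms())
        return (has_c, frag.GetNumHeavyAtoms())

    return max(frags, key=key)


def compound_from_smiles(
    id: str,
    smiles: str,
    role: str,
    name: str | None = None,
    strip_salts: bool = True,
    annotations: dict | None = None,
) -> Compound:
    """Parse one SMILES into a :class:`Compound`; parse failure flags it."""
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
    if mol is not None and strip_salts:
        mol = _largest_organic_fragment(mol)
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - fragment of a valid mol
            mol = None
    return Compound(
        id=id,
        name=name if name is not None else id,
        role=role,
        smiles=smiles,
        mol=mol,
        annotations=annotations or {},
        failed=mol is None,
    )


class CompoundSet:
    """An ordered collection of compounds with unique ids.

    Parse failures are retained (flagged ``failed``) so that callers can
    report them; iteration and ``len`` cover only valid compounds.
    """

    def __init__(self, compounds: Iterable[Compound]):
        self._all: list[Compound] = list(compounds)
        seen: set[str] = set()
        for c in self._all:
            if c.id in seen:
                raise ValueError(f"duplicate compound id: {c.id!r}")
            seen.add(c.id)
        self._valid = [c for c in self._all if not c.failed]
        self._by_id = {c.id: c for c in self._valid}

    def __len__(self) -> int:
        return len(self._valid)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._valid)

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    def __getitem__(self, cid: str) -> Compound:
        return self._by_id[cid]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self._valid]

    @property
    def failures(self) -> list[Compound]:
        return [c for c in self._all if c.failed]

    @property
    def n_failed(self) -> int:
        return len(self.failures)


def load_compounds(
    path: str | Path,
    format: str | None = None,
    role: str = "drug",
    strip_salts: bool = True,
) -> CompoundSet:
    """Load a compound collection from an SDF file or a SMILES table.

    Parameters
    ----------
    path:
        SDF (V2000) file, or a delimited table with header columns
        ``id``, ``name``, ``smiles`` (tab- or comma-separated, auto-detected
        from the ``.csv`` extension).
    format:
        ``"sdf"`` or ``"smiles_table"``; inferred from the extension when
        omitted.
    role:
        Role assigned to every record (``"drug"`` or ``"metabolite"``).

    Unparseable records are counted and logged, never silently dropped.
    A missing file or a file with zero parseable records is a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smiles_table"
    if format not in ("sdf", "smiles_table"):
        raise ValueError(f"unsupported format: {format!r}")

    compounds: list[Compound] = []
    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                compounds.append(
                    Compound(id=f"__failed_{i}", name=f"record {i}", role=role,
                             failed=True)
                )
                continue
            cid = (mol.GetProp("_Name") or f"record_{i}") if mol.HasProp("_Name") else f"record_{i}"
            if strip_salts:
                mol = _largest_organic_fragment(mol)
            compounds.append(
                Compound(id=cid, name=cid, role=role,
                         smiles=Chem.MolToSmiles(mol), mol=mol)
            )
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        table = pd.read_csv(path, sep=sep)
        required = {"id", "name", "smiles"}
        if not required.issubset(table.columns):
            raise ValueError(
                f"smiles table needs columns {sorted(required)}, "
                f"got {list(table.columns)}"
            )
        for _, row in table.iterrows():
            compounds.append(
                compound_from_smiles(
                    str(row["id"]), row["smiles"], role,
                    name=str(row["name"]), strip_salts=strip_salts,
                )
            )

    cs = CompoundSet(compounds)
    if cs.n_failed:
        logger.warning(
            "%s: %d of %d records failed to parse (%s)",
            path.name, cs.n_failed, len(compounds),
            ", ".join(c.id for c in cs.failures[:5]),
        )
    if len(cs) == 0:
        raise ChemError(
            f"{path}: zero parseable records ({cs.n_failed} failures)"
        )
    return cs


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint.

    ``n_on`` (the popcount, the ``A`` or ``B`` of the Tanimoto formula)
    is derived from ``bits`` and always consistent with it.
    """

    bits: np.ndarray
    scheme: str

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=bool)
        object.__setattr__(self, "bits", bits)
        if bits.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        expected = FP_SCHEMES.get(self.scheme)
        if expected is not None and bits.size != expected:
            raise ValueError(
                f"scheme {self.scheme!r} expects {expected} bits, "
                f"got {bits.size}"
            )

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())

    def __len__(self) -> int:
        return self.bits.size

    def to_hex(self) -> str:
        """Hex encoding of the bit vector (MSB-first packing)."""
        return np.packbits(self.bits.astype(np.uint8)).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstr: str, length: int, scheme: str) -> "Fingerprint":
        raw = np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))
        return cls(bits=raw[:length].astype(bool), scheme=scheme)


def fingerprint(compound: Compound, scheme: str = "maccs") -> Fingerprint:
    """Compute the binary fingerprint of a parsed compound.

    Deterministic: the same structure under the same scheme always yields
    an identical bit vector.
    """
    if scheme not in FP_SCHEMES:
        raise ValueError(f"unknown fingerprint scheme: {scheme!r}")
    if compound.mol is None or compound.failed:
        raise FingerprintError(
            f"compound {compound.id!r} has no parsed structure"
        )
    bv = MACCSkeys.GenMACCSKeys(compound.mol)
    bits = np.zeros(FP_SCHEMES[scheme], dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return Fingerprint(bits=bits, scheme=scheme)


def tanimoto(fa: Fingerprint, fb: Fingerprint) -> float:
    """Tanimoto coefficient ``C / (A + B - C)`` of two fingerprints.

    Both fingerprints must share the same scheme and length.  The pair of
    empty fingerprints (A = B = 0) is defined to have similarity 1.0 —
    identical, if empty, feature sets — and emits a warning.
    """
    if fa.scheme != fb.scheme or len(fa) != len(fb):
        raise SchemeMismatchError(
            f"cannot compare {fa.scheme!r}({len(fa)}) with "
            f"{fb.scheme!r}({len(fb)})"
        )
    a = fa.n_on
    b = fb.n_on
    if a == 0 and b == 0:
        warnings.warn(
            "Tanimoto of two empty fingerprints defined as 1.0",
            EmptyFingerprintWarning,
            stacklevel=2,
        )
        return 1.0
    c = int(np.count_nonzero(fa.bits & fb.bits))
    return c / (a + b - c)


def fingerprint_table(
    compounds: Sequence[Compound], scheme: str = "maccs"
) -> pd.DataFrame:
    """Fingerprints of a collection as a table of id + hex bit string."""
    rows = []
    for c in compounds:
        fp = fingerprint(c, scheme)
        rows.append({"id": c.id, "scheme": scheme, "n_on": fp.n_on,
                     "bits_hex": fp.to_hex()})
    return pd.DataFrame(rows, columns=["id", "scheme", "n_on", "bits_hex"])
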