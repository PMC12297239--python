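"""Elemental masses, molecular formulas, ion m/z, substructure matching and fingerprints.

This module is the numeric foundation of the package: every reaction mass
shift, every computed ion m/z and every Tanimoto similarity used by the
linking and reranking machinery goes through the functions defined here.

Monoisotopic atomic masses are hard-coded from the CODATA/AME2020 evaluation
(most-abundant isotope, Da).  Structure handling (SMILES, SMARTS,
fingerprints) is delegated to RDKit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ChemError",
    "FormulaError",
    "StructureError",
    "ElementMassTable",
    "MolecularFormula",
    "Fingerprint",
    "DEFAULT_MASS_TABLE",
    "ADDUCT_REGISTRY",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "canonical_smiles",
    "match_substructure",
    "fingerprint",
    "tanimoto",
]


class ChemError(ValueError):
    """Base class for chemistry-layer errors."""


class FormulaError(ChemError):
    """Raised when a molecular-formula string cannot be parsed."""


class StructureError(ChemError):
    """Raised when a SMILES or SMARTS string cannot be parsed."""


# Monoisotopic masses of the most abundant isotope (Da), CODATA/AME2020.
_MONOISOTOPIC: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "F": 18.99840322,
    "I": 126.904473,
    "Se": 79.9165213,
    "Si": 27.9769265325,
}

ELECTRON_MASS = 0.00054857990907  # Da


@dataclass(frozen=True)
class ElementMassTable:
    """Monoisotopic element masses plus the electron mass, all in Da."""

    entries: dict[str, float] = field(default_factory=lambda: dict(_MONOISOTOPIC))
    electron_mass: float = ELECTRON_MASS

    def __post_init__(self) -> None:
        required = {"C", "H", "N", "O", "S", "P", "Na", "Cl"}
        missing = required - self.entries.keys()
        if missing:
            raise ChemError(f"mass table missing required elements: {sorted(missing)}")
        if any(m <= 0 for m in self.entries.values()):
            raise ChemError("element masses must be positive")

    def mass(self, symbol: str) -> float:
        try:
            return self.entries[symbol]
        except KeyError:
            raise FormulaError(f"unknown element symbol: {symbol!r}") from None


DEFAULT_MASS_TABLE = ElementMassTable()


@dataclass(frozen=True)
class MolecularFormula:
    """Signed element counts plus a formal charge.

    Negative counts express net elemental changes (e.g. the oximation
    net change +NH2OH -H2O, which collapses to +NH).  Zero counts are
    dropped so equal formulas compare equal.
    """

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    @classmethod
    def from_counts(cls, counts: dict[str, int], charge: int = 0) -> "MolecularFormula":
        clean = {el: n for el, n in counts.items() if n != 0}
        for el in clean:
            if el not in DEFAULT_MASS_TABLE.entries:
                raise FormulaError(f"unknown element symbol: {el!r}")
        return cls(tuple(sorted(clean.items())), charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula.from_counts(merged, self.charge + other.charge)

    def __neg__(self) -> "MolecularFormula":
        return MolecularFormula.from_counts(
            {el: -n for el, n in self.counts}, -self.charge
        )

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        return self + (-other)

    def to_string(self) -> str:
        """Text form; round-trips through :func:`parse_formula`."""
        pos = {el: n for el, n in self.counts if n > 0}
        neg = {el: -n for el, n in self.counts if n < 0}
        parts = []
        if pos or not neg:
            parts.append(_hill_order(pos))
        if neg:
            parts.append("-" + _hill_order(neg))
        text = "".join(parts)
        if self.charge:
            text += ("+" if self.charge > 0 else "-") * abs(self.charge)
        return text

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


EMPTY_FORMULA = MolecularFormula((), 0)


def _hill_order(counts: dict[str, int]) -> str:
    """Hill-system element ordering: C, H, then alphabetical."""
    order = sorted(counts, key=lambda el: (el != "C", el != "H", el))
    return "".join(
        f"{el}{counts[el] if counts[el] != 1 else ''}" for el in order if counts[el]
    )


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
# trailing run of identical sign characters is the charge ("+", "--", ...);
# digit-magnitude charges are not supported, they collide with element counts
_CHARGE = re.compile(r"(\++|-+)$")


def _parse_segment(text: str, offset: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos:
            raise FormulaError(
                f"malformed formula token at position {offset + pos}: {text[pos:]!r}"
            )
        el, num = m.group(1), m.group(2)
        if el not in DEFAULT_MASS_TABLE.entries:
            raise FormulaError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return counts


def parse_formula(text: str) -> MolecularFormula:
    """Parse a molecular-formula string, with optional signed segments.

    Grammar: ``[+|-]SEGMENT ([+|-]SEGMENT)* [charge]`` where a SEGMENT is a
    run of ``Element[count]`` tokens and the trailing charge is a run of
    identical sign characters (``+`` = +1, ``--`` = -2).  Examples:
    ``"C6H12O6"``, ``"+NH2OH-H2O"`` (net change collapsing to NH),
    ``"C43H64N3O15+"`` (cation).

    Raises :class:`FormulaError` on unknown element symbols or malformed
    tokens, naming the offending symbol/position.
    """
    text = text.strip().replace("−", "-")  # tolerate unicode minus
    charge = 0
    m = _CHARGE.search(text)
    if m is not None:
        run = m.group(1)
        charge = len(run) * (1 if run[0] == "+" else -1)
        text = text[: m.start()]
    if not text:
        return MolecularFormula((), charge)

    counts: dict[str, int] = {}
    sign = 1
    pos = 0
    seg_start = 0
    if text[0] in "+-":
        sign = 1 if text[0] == "+" else -1
        pos = seg_start = 1
    while True:
        nxt = min(
            (i for i in (text.find("+", pos), text.find("-", pos)) if i != -1),
            default=len(text),
        )
        segment = text[seg_start:nxt]
        if not segment:
            raise FormulaError(f"empty formula segment at position {seg_start}")
        for el, n in _parse_segment(segment, seg_start).items():
            counts[el] = counts.get(el, 0) + sign * n
        if nxt >= len(text):
            break
        sign = 1 if text[nxt] == "+" else -1
        pos = seg_start = nxt + 1
    return MolecularFormula.from_counts(counts, charge)


def monoisotopic_mass(
    formula: MolecularFormula, table: ElementMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Monoisotopic mass in Da: sum of count*mass(element) minus charge*m_e.

    Signed counts subtract, so net-change formulas give net mass shifts.
    """
    total = sum(n * table.mass(el) for el, n in formula.counts)
    return total - formula.charge * table.electron_mass


# Adduct registry: descriptor -> (formula change, charge).  Small on purpose;
# the workflow observes protonated species.
ADDUCT_REGISTRY: dict[str, tuple[MolecularFormula, int]] = {
    "[M+H]+": (MolecularFormula.from_counts({"H": 1}), 1),
    "[M+Na]+": (MolecularFormula.from_counts({"Na": 1}), 1),
    "[M+2H]2+": (MolecularFormula.from_counts({"H": 2}), 2),
    "[M-H]-": (MolecularFormula.from_counts({"H": -1}), -1),
}


def ion_mz(
    neutral: MolecularFormula,
    adduct: str,
    table: ElementMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """m/z of ``neutral`` under the given adduct, electron-mass corrected.

    ``(mass(M) + mass(adduct change) - z*m_e) / |z|``; e.g. C43H63N3O15 with
    [M+H]+ gives 862.4332 at 4 dp.
    """
    try:
        change, z = ADDUCT_REGISTRY[adduct]
    except KeyError:
        raise ChemError(
            f"unknown adduct {adduct!r}; registry: {sorted(ADDUCT_REGISTRY)}"
        ) from None
    m = monoisotopic_mass(neutral, table) + monoisotopic_mass(change, table)
    return (m - z * table.electron_mass) / abs(z)


# ---------------------------------------------------------------------------
# Structure handling (RDKit-backed)
# ---------------------------------------------------------------------------

_mol_cache: dict[str, Chem.Mol] = {}
_patt_cache: dict[str, Chem.Mol] = {}


def _mol(smiles: str) -> Chem.Mol:
    mol = _mol_cache.get(smiles)
    if mol is None:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise StructureError(f"unparseable SMILES: {smiles!r}")
        _mol_cache[smiles] = mol
    return mol


def _pattern(smarts: str) -> Chem.Mol:
    patt = _patt_cache.get(smarts)
    if patt is None:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise StructureError(f"unparseable SMARTS: {smarts!r}")
        _patt_cache[smarts] = patt
    return patt


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES form; two spellings of one molecule compare equal."""
    return Chem.MolToSmiles(_mol(smiles))


def match_substructure(structure: str, pattern: str) -> int:
    """Count symmetry-deduplicated embeddings of a SMARTS pattern.

    Matches covering the same atom set (in any order) count once; 0 means
    the pattern is absent.
    """
    mol = _mol(structure)
    patt = _pattern(pattern)
    matches = mol.GetSubstructMatches(patt, uniquify=True)
    return len({frozenset(m) for m in matches})


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary molecular fingerprint."""

    bits: bytes  # packed bitset, little-bit-first within each byte
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if len(self.bits) * 8 < self.n_bits:
            raise ChemError("bitset shorter than n_bits")

    def to_array(self) -> np.ndarray:
        arr = np.unpackbits(np.frombuffer(self.bits, dtype=np.uint8), bitorder="little")
        return arr[: self.n_bits].astype(bool)

    @property
    def popcount(self) -> int:
        return int(self.to_array().sum())


def fingerprint(structure: str, n_bits: int = 2048) -> Fingerprint:
    """Path-based (RDKit daylight-like) fingerprint at default settings."""
    bv = Chem.RDKFingerprint(_mol(structure), fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return Fingerprint(bytes(np.packbits(arr, bitorder="little")), n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard similarity |a&b|/|a|b| of two equal-length fingerprints.

    Two all-zero fingerprints are defined to be identical (similarity 1.0),
    keeping the measure reflexive; this convention is documented rather than
    raising on degenerate inputs.
    """
    if a.n_bits != b.n_bits:
        raise ChemError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")
    va, vb = a.to_array(), b.to_array()
    union = int(np.logical_or(va, vb).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(va, vb).sum()) / union


def structure_tanimoto(a: str, b: str, n_bits: int = 2048) -> float:
    """Tanimoto similarity of two structures given as SMILES."""
    return tanimoto(fingerprint(a, n_bits), fingerprint(b, n_bits))
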