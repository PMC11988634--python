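"""Molecular compositions: formula parsing, valence tables, masses.

A molecular formula such as ``C18H12Cl2N2O`` is parsed into an
element → count multiset (:class:`MolecularComposition`), the substrate on
which the quasi-valence descriptors in :mod:`eiipkit.eiip` operate.

Grammar: a sequence of ``ElementSymbol [count]`` tokens, with one level of
parenthesised groups (``CH3(CH2)2OH``). Counts default to 1 and must be
positive. Isotope brackets, charges and hydrate dots are rejected
explicitly — they are out of scope for the descriptor.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    ConfigError,
    FormulaError,
    MissingEntryError,
    StructureBackendUnavailable,
    StructureError,
    UnknownElementError,
)

# All IUPAC element symbols (Z = 1..118); parsing accepts any real element,
# valence/mass lookups fail later with a named error if no entry exists.
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe
    Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn
    Sb Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W
    Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf
    Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)


@dataclass
class MolecularComposition:
    """Element → count multiset for one compound.

    ``elements`` maps IUPAC symbols (case-sensitive) to positive counts;
    ``source`` keeps the input text verbatim and does not take part in
    equality.
    """

    elements: dict[str, int]
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.elements:
            raise FormulaError("empty composition")
        for symbol, count in self.elements.items():
            if symbol not in ELEMENT_SYMBOLS:
                raise UnknownElementError(symbol)
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"count for {symbol} must be a positive integer, got {count!r}")

    @property
    def n_atoms(self) -> int:
        """Total number of atoms N."""
        return sum(self.elements.values())

    def hill_formula(self) -> str:
        """Canonical Hill-notation string: C, H, then others alphabetically.

        Without carbon, all symbols are ordered alphabetically.
        """
        items = dict(self.elements)
        parts: list[str] = []
        if "C" in items:
            for symbol in ("C", "H"):
                if symbol in items:
                    n = items.pop(symbol)
                    parts.append(symbol if n == 1 else f"{symbol}{n}")
        for symbol in sorted(items):
            n = items[symbol]
            parts.append(symbol if n == 1 else f"{symbol}{n}")
        return "".join(parts)

    def scaled(self, k: int) -> "MolecularComposition":
        """Composition with every count multiplied by positive integer k."""
        if k < 1:
            raise FormulaError(f"scale factor must be >= 1, got {k}")
        return MolecularComposition({s: n * k for s, n in self.elements.items()}, self.source)


@dataclass(frozen=True)
class ValenceTable:
    """Element → valence number map (the Z_i convention).

    The default convention assigns each atom the number of electrons it
    contributes to the quasi-valence sum: H 1, C 4, N 5, O 6, S 6, P 5 and
    — notably — halogens 1. The halogen choice is what reproduces the
    published descriptor values for chlorinated and brominated pesticides
    (boscalid, chlorantraniliprole); a "valence-electron" convention with
    halogens at 7 does not. User tables may override it.
    """

    valences: dict[str, int]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        for symbol, z in self.valences.items():
            if symbol not in ELEMENT_SYMBOLS:
                raise ConfigError(f"valence table: unknown element {symbol!r}")
            if not isinstance(z, int) or z < 1:
                raise ConfigError(f"valence table: valence for {symbol} must be a positive integer")

    def __getitem__(self, element: str) -> int:
        try:
            return self.valences[element]
        except KeyError:
            raise MissingEntryError(element, f"valence table {self.provenance!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "ValenceTable":
        """Load a two-column (element, valence) CSV, validated on load."""
        path = Path(path)
        valences: dict[str, int] = {}
        with path.open(newline="") as fh:
            for row_no, row in enumerate(csv.reader(fh), start=1):
                if not row or row[0].strip().startswith("#"):
                    continue
                if row_no == 1 and row[0].strip().lower() == "element":
                    continue  # optional header
                if len(row) < 2:
                    raise ConfigError(f"{path}:{row_no}: expected 'element,valence'")
                symbol = row[0].strip()
                try:
                    z = int(row[1])
                except ValueError:
                    raise ConfigError(f"{path}:{row_no}: valence {row[1]!r} is not an integer") from None
                if symbol in valences:
                    raise ConfigError(f"{path}:{row_no}: duplicate element {symbol!r}")
                valences[symbol] = z
        if not valences:
            raise ConfigError(f"{path}: empty valence table")
        return cls(valences, provenance=str(path))


#: Default quasi-valence convention (see :class:`ValenceTable`).
DEFAULT_VALENCES = ValenceTable(
    {"H": 1, "C": 4, "N": 5, "O": 6, "S": 6, "P": 5, "F": 1, "Cl": 1, "Br": 1, "I": 1},
    provenance="eiip-default-v1",
)


@dataclass(frozen=True)
class AtomicMassTable:
    """Element → standard average atomic mass (Da)."""

    masses: dict[str, float]

    def __getitem__(self, element: str) -> float:
        try:
            return self.masses[element]
        except KeyError:
            raise MissingEntryError(element, "atomic mass table") from None


#: IUPAC standard atomic weights (2021, conventional values), Da.
DEFAULT_MASSES = AtomicMassTable(
    {
        "H": 1.008,
        "C": 12.011,
        "N": 14.007,
        "O": 15.999,
        "S": 32.06,
        "P": 30.974,
        "F": 18.998,
        "Cl": 35.45,
        "Br": 79.904,
        "I": 126.904,
    }
)

_TOKEN = re.compile(
    r"""(?P<ws>\s+)
      | (?P<open>\()
      | (?P<close>\))(?P<gcount>\d*)
      | (?P<elem>[A-Z][a-z]?)(?P<count>\d*)
      | (?P<bad>.)""",
    re.VERBOSE,
)


def parse_formula(formula: str) -> MolecularComposition:
    """Parse a molecular formula into a :class:`MolecularComposition`.

    Whitespace is ignored; repeated element tokens are summed
    (``CH3CH3`` → C2H6); one level of parenthesised groups is allowed.

    Raises :class:`FormulaError` (with position) for malformed input and
    :class:`UnknownElementError` for tokens that are not element symbols.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")

    totals: dict[str, int] = {}
    group: dict[str, int] | None = None
    group_start = -1

    def add(target: dict[str, int], symbol: str, n: int) -> None:
        target[symbol] = target.get(symbol, 0) + n

    pos = 0
    for match in _TOKEN.finditer(formula):
        pos = match.start()
        if match.group("ws"):
            continue
        if match.group("bad"):
            ch = match.group("bad")
            if ch in "[]":
                raise FormulaError("isotope notation is not supported", pos)
            if ch in "+-":
                raise FormulaError("charge notation is not supported", pos)
            if ch in "·.*":
                raise FormulaError("hydrate/adduct notation is not supported", pos)
            raise FormulaError(f"unexpected character {ch!r}", pos)
        if match.group("open"):
            if group is not None:
                raise FormulaError("nested parentheses are not supported", pos)
            group = {}
            group_start = pos
            continue
        if match.group("close") is not None:
            if group is None:
                raise FormulaError("unbalanced ')'", pos)
            if not group:
                raise FormulaError("empty group '()'", group_start)
            mult = int(match.group("gcount") or "1")
            if mult < 1:
                raise FormulaError("group count must be >= 1", pos)
            for symbol, n in group.items():
                add(totals, symbol, n * mult)
            group = None
            continue
        symbol = match.group("elem")
        if symbol not in ELEMENT_SYMBOLS:
            raise UnknownElementError(symbol, pos)
        count_text = match.group("count")
        count = int(count_text) if count_text else 1
        if count < 1:
            raise FormulaError(f"count for {symbol} must be >= 1", pos)
        add(group if group is not None else totals, symbol, count)

    if group is not None:
        raise FormulaError("unbalanced '('", group_start)
    if not totals:
        raise FormulaError("formula contains no atoms")
    return MolecularComposition(totals, source=formula)


def composition_from_structure(line_notation: str) -> MolecularComposition:
    """Composition (implicit hydrogens included) from a SMILES string.

    Optional convenience backed by rdkit; equals ``parse_formula`` of the
    compound's molecular formula.
    """
    try:
        from rdkit import Chem, RDLogger
    except ImportError:  # pragma: no cover - environment-dependent
        raise StructureBackendUnavailable(
            "structure input requires rdkit; supply a molecular formula instead"
        ) from None

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(line_notation)
    if mol is None:
        raise StructureError(f"could not parse structure notation {line_notation!r}")
    mol = Chem.AddHs(mol)
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        counts[symbol] = counts.get(symbol, 0) + 1
    return MolecularComposition(counts, source=line_notation)


def molecular_weight(
    comp: MolecularComposition, masses: AtomicMassTable = DEFAULT_MASSES
) -> float:
    """Average molecular weight Σ count_i · mass_i in Da."""
    return sum(n * masses[symbol] for symbol, n in comp.elements.items())
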