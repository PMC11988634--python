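"""AQVN and EIIP molecular descriptors.

The average quasi-valence number (AQVN) of a molecule is the
atom-count-weighted mean of valence numbers,

    Z* = (1/N) Σ_i n_i Z_i,

with n_i the count of the i-th atomic component, Z_i its valence number and
N the total atom count. The electron–ion interaction potential (EIIP), a
pseudopotential-derived scalar used as a long-range molecular-recognition
descriptor, follows as

    EIIP = 0.25 · (Z*/(2π)) · sin(1.04 π Z*)

with the sine taken in radians. Both are conventionally labelled in Rydberg
units (Ry) even though Z* is arithmetically dimensionless. Values are
computed in full double precision; 4 decimals is the display convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .composition import DEFAULT_VALENCES, MolecularComposition, ValenceTable
from .errors import DataError

#: Columns of a descriptor table, in output order.
DESCRIPTOR_COLUMNS = [
    "id",
    "formula",
    "n_atoms",
    "quasi_valence_sum",
    "aqvn",
    "eiip_signed",
    "eiip_abs",
]


@dataclass(frozen=True)
class DescriptorResult:
    """AQVN/EIIP descriptor set for one compound.

    ``quasi_valence_sum`` is the integer Σ n_i Z_i, so
    ``aqvn == quasi_valence_sum / n_atoms`` exactly (a rational number
    before any rounding) and ``eiip_abs == |eiip_signed|``.
    """

    aqvn: float
    eiip_signed: float
    eiip_abs: float
    n_atoms: int
    quasi_valence_sum: int


def quasi_valence_sum(
    comp: MolecularComposition, valences: ValenceTable = DEFAULT_VALENCES
) -> int:
    """Integer quasi-valence electron sum Σ n_i Z_i."""
    return sum(n * valences[symbol] for symbol, n in comp.elements.items())


def aqvn(comp: MolecularComposition, valences: ValenceTable = DEFAULT_VALENCES) -> float:
    """Average quasi-valence number Z* = (Σ n_i Z_i) / N."""
    return quasi_valence_sum(comp, valences) / comp.n_atoms


def eiip(z_star: float) -> float:
    """Signed EIIP in Ry: 0.25 · (Z*/(2π)) · sin(1.04 π Z*).

    Raises :class:`DataError` for non-positive Z* (no physical molecule has
    a non-positive mean valence).
    """
    if not z_star > 0:
        raise DataError(f"AQVN must be positive, got {z_star}")
    return 0.25 * (z_star / (2.0 * math.pi)) * math.sin(1.04 * math.pi * z_star)


def describe(
    comp: MolecularComposition, valences: ValenceTable = DEFAULT_VALENCES
) -> DescriptorResult:
    """Full descriptor set (AQVN, signed and absolute EIIP, counts)."""
    qvs = quasi_valence_sum(comp, valences)
    n = comp.n_atoms
    z_star = qvs / n
    e = eiip(z_star)
    return DescriptorResult(
        aqvn=z_star, eiip_signed=e, eiip_abs=abs(e), n_atoms=n, quasi_valence_sum=qvs
    )


@dataclass(frozen=True)
class BatchError:
    """One unparseable row of a batch run, reported instead of dropped."""

    row: int
    id: str
    message: str


def batch_describe(
    records: Iterable, valences: ValenceTable = DEFAULT_VALENCES
) -> tuple[pd.DataFrame, list[BatchError]]:
    """Descriptor table for a sequence of compound records.

    ``records`` are :class:`~eiipkit.cli_io.CompoundRecord`-like objects with
    ``id``, ``formula`` (and optionally ``structure``) attributes. Input
    order is preserved; rows that fail to parse are collected as
    :class:`BatchError` entries, never silently dropped. An empty input
    yields an empty table with a warning.
    """
    from .composition import composition_from_structure, parse_formula

    rows: list[dict] = []
    errors: list[BatchError] = []
    n_in = 0
    for i, rec in enumerate(records):
        n_in += 1
        row_no = getattr(rec, "row", i + 1)
        try:
            if getattr(rec, "formula", None):
                comp = parse_formula(rec.formula)
            elif getattr(rec, "structure", None):
                comp = composition_from_structure(rec.structure)
            else:
                raise DataError("record has neither formula nor structure")
            res = describe(comp, valences)
        except DataError as exc:
            errors.append(BatchError(row=row_no, id=str(rec.id), message=str(exc)))
            continue
        rows.append(
            {
                "id": rec.id,
                "formula": comp.hill_formula(),
                "n_atoms": res.n_atoms,
                "quasi_valence_sum": res.quasi_valence_sum,
                "aqvn": res.aqvn,
                "eiip_signed": res.eiip_signed,
                "eiip_abs": res.eiip_abs,
            }
        )
    if n_in == 0:
        warnings.warn("batch_describe received an empty table", stacklevel=2)
    table = pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS)
    return table, errors


@dataclass(frozen=True)
class SimilarityRanking:
    """Compounds ordered by |ΔAQVN| from a reference compound.

    Motivated by the screening heuristic that molecules with close AQVN
    show similar long-range recognition behaviour. Ties on |ΔAQVN| break
    lexicographically by id.
    """

    reference_id: str
    entries: list[tuple[str, float, float]]  # (id, aqvn, |delta|), ascending


def rank_by_aqvn(table: pd.DataFrame, reference_id: str) -> SimilarityRanking:
    """Rank a descriptor table by AQVN proximity to ``reference_id``."""
    ids = table["id"].astype(str).tolist()
    if str(reference_id) not in ids:
        raise DataError(f"reference id {reference_id!r} not found in table")
    ref_aqvn = float(table.loc[table["id"].astype(str) == str(reference_id), "aqvn"].iloc[0])
    entries = sorted(
        (
            (str(row.id), float(row.aqvn), abs(float(row.aqvn) - ref_aqvn))
            for row in table.itertuples()
        ),
        key=lambda t: (t[2], t[0]),
    )
    return SimilarityRanking(reference_id=str(reference_id), entries=entries)
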