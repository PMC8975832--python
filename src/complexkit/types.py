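"""Core in-memory containers shared across modules.

The central objects are:

* :class:`MonomerMSA` — one protein's alignment (query + homologs) over match
  columns only; A3M lowercase insertions are stored separately.
* :class:`StoichiometrySpec` — copy numbers of each distinct monomer in a
  complex (e.g. A2B2).
* :class:`StructureModel` — a multi-chain heavy-atom coordinate set of one
  predicted complex model.
* :class:`PAEMatrix` — the predicted-aligned-error surface <e_ij> (Å) over all
  complex residues, row = reference frame i, column = assessed residue j.
* :class:`InterfaceSet` — inter-chain residue contacts and interface residues
  at a heavy-atom distance cutoff.
* :class:`ScoreReport` — the per-model confidence summary (piTM,
  interface-score, clash indicator chi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ConsistencyError, FormatError, ParameterError

#: Residues are identified by (chain_id, residue_number).
ResidueKey = tuple[str, int]

GAP = "-"


# ---------------------------------------------------------------------------
# Sequence containers
# ---------------------------------------------------------------------------


@dataclass
class MonomerMSA:
    """One protein's aligned sequence set over match columns.

    ``rows[0]`` is the query; every row has the same length L (the query
    length). Insertions relative to the query (lowercase in A3M) are kept in
    ``insertions``: for row r, ``insertions[r]`` maps a match-column boundary
    k (the number of match columns preceding the insertion) to the inserted
    residue string.
    """

    monomer_id: str
    rows: list[str]
    insertions: list[dict[int, str]] | None = None
    descriptions: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError(f"MSA {self.monomer_id!r} has no rows")
        L = len(self.rows[0])
        if L == 0:
            raise FormatError(f"MSA {self.monomer_id!r} has an empty query")
        for i, row in enumerate(self.rows):
            if len(row) != L:
                raise FormatError(
                    f"MSA {self.monomer_id!r}: row {i} has {len(row)} aligned "
                    f"columns, expected {L}"
                )
        if self.insertions is not None and len(self.insertions) != len(self.rows):
            raise ConsistencyError("insertions list length must equal row count")

    @property
    def query(self) -> str:
        return self.rows[0]

    @property
    def length(self) -> int:
        """Number of match columns, L."""
        return len(self.rows[0])

    @property
    def depth(self) -> int:
        """Number of aligned rows, D."""
        return len(self.rows)


@dataclass(frozen=True)
class StoichiometrySpec:
    """Ordered (monomer_id, copies) components of a target complex."""

    components: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ParameterError("stoichiometry needs at least one component")
        seen: set[str] = set()
        for mid, copies in self.components:
            if copies < 1:
                raise ParameterError(f"copies for {mid!r} must be >= 1, got {copies}")
            if mid in seen:
                raise ParameterError(f"duplicate monomer id {mid!r} in stoichiometry")
            seen.add(mid)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def total_chains(self) -> int:
        return sum(c for _, c in self.components)

    def __str__(self) -> str:
        return "/".join(
            mid if c == 1 else f"{mid}:{c}" for mid, c in self.components
        )


# ---------------------------------------------------------------------------
# Structure containers
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    name: str
    xyz: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise FormatError(f"atom {self.name!r} has invalid coordinates")


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom]
    het: bool = False

    @property
    def is_water(self) -> bool:
        return self.name in ("HOH", "WAT", "DOD")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]


@dataclass
class StructureModel:
    """Multi-chain heavy-atom model; chain and residue order follow the file."""

    chains: list[Chain]

    def __post_init__(self) -> None:
        if not self.chains:
            raise FormatError("structure model has no chains")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def residue_order(self) -> list[ResidueKey]:
        """Positional (chain_id, residue_number) order, matching PAE rows."""
        return [
            (chain.chain_id, res.number)
            for chain in self.chains
            for res in chain.residues
        ]

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


# ---------------------------------------------------------------------------
# PAE
# ---------------------------------------------------------------------------


@dataclass
class PAEMatrix:
    """Square predicted-aligned-error matrix (Å) with its residue order.

    ``values[i, j]`` is the estimated error of residue j's position when the
    model is aligned on residue i's local frame; asymmetry is expected.
    """

    values: np.ndarray
    residue_order: list[ResidueKey]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise FormatError(
                f"PAE matrix must be square, got shape {self.values.shape}"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise FormatError("PAE entries must be finite and >= 0")
        if len(self.residue_order) != self.values.shape[0]:
            raise ConsistencyError(
                f"PAE dimension {self.values.shape[0]} does not match "
                f"residue order length {len(self.residue_order)}"
            )

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def index_map(self) -> dict[ResidueKey, int]:
        return {key: i for i, key in enumerate(self.residue_order)}


# ---------------------------------------------------------------------------
# Interface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterfaceSet:
    """Inter-chain residue contacts and the interface residue set they span."""

    contacts: frozenset[tuple[ResidueKey, ResidueKey]]

    def __post_init__(self) -> None:
        for a, b in self.contacts:
            if a[0] == b[0]:
                raise ConsistencyError(f"intra-chain contact {a}-{b} is not allowed")

    @staticmethod
    def from_pairs(pairs) -> "InterfaceSet":
        """Canonicalize unordered residue pairs (sorted within the pair)."""
        return InterfaceSet(
            frozenset(tuple(sorted((a, b))) for a, b in pairs)
        )

    @property
    def interface_residues(self) -> frozenset[ResidueKey]:
        out: set[ResidueKey] = set()
        for a, b in self.contacts:
            out.add(a)
            out.add(b)
        return frozenset(out)

    @property
    def per_chain(self) -> dict[str, frozenset[ResidueKey]]:
        """Partition of the interface residues by chain (I_p)."""
        bychain: dict[str, set[ResidueKey]] = {}
        for key in self.interface_residues:
            bychain.setdefault(key[0], set()).add(key)
        return {cid: frozenset(s) for cid, s in sorted(bychain.items())}

    @property
    def n_interface_residues(self) -> int:
        """N_iRes."""
        return len(self.interface_residues)

    @property
    def n_contacts(self) -> int:
        """N_iCnt."""
        return len(self.contacts)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class ScoreReport:
    """Confidence summary for one complex model.

    ``clash_indicator`` is None (reported NA) when the model has no
    inter-chain contacts. ``per_chain_terms`` are the chain terms of the
    interface-score and sum to ``interface_score``.
    """

    model_id: str
    pitm: float
    interface_score: float
    clash_indicator: float | None
    interface_size: int
    n_contacts: int
    per_chain_terms: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (-eps <= self.pitm <= 1 + eps):
            raise ConsistencyError(f"piTM {self.pitm} outside [0, 1]")
        if not (-eps <= self.interface_score <= 1 + eps):
            raise ConsistencyError(
                f"interface-score {self.interface_score} outside [0, 1]"
            )
        if self.clash_indicator is not None and not (
            0 < self.clash_indicator <= 2 + eps
        ):
            raise ConsistencyError(
                f"clash indicator {self.clash_indicator} outside (0, 2]"
            )
        if self.per_chain_terms:
            total = math.fsum(t for _, t in self.per_chain_terms)
            if abs(total - self.interface_score) > 1e-6:
                raise ConsistencyError(
                    "per-chain terms do not sum to the interface-score"
                )

    def to_dict(self) -> dict[str, Any]:
        return {
            "model_id": self.model_id,
            "piTM": self.pitm,
            "interface_score": self.interface_score,
            "clash_indicator": self.clash_indicator,
            "interface_size": self.interface_size,
            "n_contacts": self.n_contacts,
            "per_chain_terms": {cid: t for cid, t in self.per_chain_terms},
        }


# ---------------------------------------------------------------------------
# Feature assembly containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainEntry:
    """One chain of the assembled complex and its MSA column window."""

    chain_id: str
    monomer_id: str
    copy_number: int  # 1-based within the monomer
    start_col: int
    end_col: int  # half-open

    @property
    def length(self) -> int:
        return self.end_col - self.start_col


@dataclass
class TemplateFeature:
    """A monomer structural template; positions are 0-based residue indices.

    Before re-indexing, positions are monomer-local; after, they are complex
    column coordinates and ``chain_id`` names the owning chain. ``payload``
    (coordinates, one-hot encodings, ...) is carried through untouched.
    """

    monomer_id: str
    source_id: str
    positions: np.ndarray
    payload: Any = None
    chain_id: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)


@dataclass
class ComplexFeatures:
    """Assembled complex input features (MSA, residue index, chain table)."""

    msa: list[str]
    residue_index: np.ndarray
    chain_table: list[ChainEntry]
    templates: list[TemplateFeature] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def msa_depth(self) -> int:
        return len(self.msa)

    @property
    def msa_length(self) -> int:
        return len(self.msa[0]) if self.msa else 0


# ---------------------------------------------------------------------------
# Screening containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabeledScore:
    """A scored protein pair with its interaction label.

    The pair is canonicalized (lexicographically sorted) so (a, b) and (b, a)
    compare equal.
    """

    pair: tuple[str, str]
    score: float
    label: bool  # True = positive (interacting)

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ParameterError(f"score for pair {self.pair} is not finite")
        a, b = self.pair
        if a > b:
            object.__setattr__(self, "pair", (b, a))


@dataclass(frozen=True)
class CurvePoint:
    """One operating point of the ROC / precision-recall sweep."""

    threshold: float
    tpr: float
    fpr: float
    precision: float | None

    @property
    def recall(self) -> float:
        return self.tpr
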