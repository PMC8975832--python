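"""Complex input-feature assembly from monomer features, without MSA pairing.

The complex MSA is block-diagonal: each copy of each monomer owns a private
row block and column block filled with that monomer's alignment, everything
else is gaps. No cross-species pairing of alignment rows is ever attempted —
that independence is the point of the approach. Chain breaks are signalled to
a monomer-trained network through the residue-index feature: each subsequent
chain's indices are shifted by b*(p-1) with b = 200 by default, comfortably
beyond the relative positional-encoding reach of 32, so the network treats
the chains as covalently disconnected. Monomer structural templates are
re-indexed into the same complex coordinate system; complex (cross-chain)
templates are never constructed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import ConsistencyError, ParameterError
from .types import (
    GAP,
    ChainEntry,
    ComplexFeatures,
    MonomerMSA,
    StoichiometrySpec,
    TemplateFeature,
)

#: Default inter-chain residue-index shift; must exceed the relative
#: positional-encoding window (|i-j| <= 32) of the monomer network.
DEFAULT_CHAIN_OFFSET = 200
_POSITIONAL_ENCODING_REACH = 32

_CHAIN_IDS = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + [
    chr(a) + chr(b)
    for a in range(ord("A"), ord("Z") + 1)
    for b in range(ord("A"), ord("Z") + 1)
]


def build_chain_table(
    msas: list[MonomerMSA], stoich: StoichiometrySpec
) -> list[ChainEntry]:
    """Lay out one chain per copy, monomers outer / copies inner, and assign
    each its half-open MSA column window."""
    if len(msas) != stoich.n_components:
        raise ConsistencyError(
            f"{len(msas)} MSAs supplied for {stoich.n_components} stoichiometry "
            "components"
        )
    for msa, (mid, _) in zip(msas, stoich.components):
        if msa.monomer_id != mid:
            raise ConsistencyError(
                f"MSA order mismatch: got {msa.monomer_id!r}, expected {mid!r}"
            )
    table: list[ChainEntry] = []
    col = 0
    chain_idx = 0
    for msa, (mid, copies) in zip(msas, stoich.components):
        for copy in range(1, copies + 1):
            table.append(
                ChainEntry(
                    chain_id=_CHAIN_IDS[chain_idx],
                    monomer_id=mid,
                    copy_number=copy,
                    start_col=col,
                    end_col=col + msa.length,
                )
            )
            col += msa.length
            chain_idx += 1
    return table


def make_complex_msa(
    msas: list[MonomerMSA],
    stoich: StoichiometrySpec,
    include_query_row: bool = False,
) -> list[str]:
    """Assemble the block-diagonal complex MSA.

    The output has sum(L_i * S_i) columns and sum(D_i * S_i) rows: a gap
    canvas on which copy j of monomer i occupies its own row block and column
    block, blocks laid out monomers-outer / copies-inner. Homo-oligomer
    copies get duplicated blocks — a complex with multiple copies of one
    sequence is treated as if the copies were distinct sequences.

    With ``include_query_row`` an extra first row spelling the concatenated
    complex query is prepended (depth becomes sum(D_i * S_i) + 1), since
    downstream feature pipelines conventionally expect row 0 to be the full
    query; the default is the literal block layout.
    """
    table = build_chain_table(msas, stoich)
    msa_by_id = {m.monomer_id: m for m in msas}
    msa_length = table[-1].end_col
    msa_depth = sum(m.depth * c for m, (_, c) in zip(msas, stoich.components))
    canvas = np.full((msa_depth, msa_length), GAP, dtype="<U1")
    row = 0
    for entry in table:
        m = msa_by_id[entry.monomer_id]
        block = np.array([list(r) for r in m.rows], dtype="<U1")
        canvas[row : row + m.depth, entry.start_col : entry.end_col] = block
        row += m.depth
    rows = ["".join(r) for r in canvas]
    if include_query_row:
        query = "".join(msa_by_id[e.monomer_id].query for e in table)
        rows.insert(0, query)
    return rows


def make_residue_index(
    lengths_per_chain: list[int], b: int = DEFAULT_CHAIN_OFFSET
) -> np.ndarray:
    """Residue-index feature with inter-chain shifts of b*(p-1).

    Chain p (1-based, concatenation order) keeps internally consecutive
    indices continuing from the running concatenated position, shifted by
    b*(p-1); every inter-chain gap therefore exceeds the positional-encoding
    reach of 32.
    """
    if b <= _POSITIONAL_ENCODING_REACH:
        warnings.warn(
            f"chain offset b={b} does not exceed the relative positional-"
            f"encoding reach of {_POSITIONAL_ENCODING_REACH}; chains would not "
            "be seen as separate",
            stacklevel=2,
        )
        raise ParameterError(f"chain offset b must be > {_POSITIONAL_ENCODING_REACH}")
    if not lengths_per_chain or any(L < 1 for L in lengths_per_chain):
        raise ParameterError("chain lengths must be positive")
    chunks = []
    start = 0
    for p, L in enumerate(lengths_per_chain, start=1):
        chunks.append(np.arange(start + b * (p - 1), start + b * (p - 1) + L))
        start += L
    return np.concatenate(chunks)


def reindex_templates(
    templates: list[TemplateFeature], chain_table: list[ChainEntry]
) -> list[TemplateFeature]:
    """Map monomer-local template positions into complex column coordinates.

    Each monomer template is emitted once per copy of that monomer, shifted
    by the copy's column start; payloads pass through untouched. Cross-chain
    (complex) templates are never constructed.
    """
    by_monomer: dict[str, list[ChainEntry]] = {}
    for entry in chain_table:
        by_monomer.setdefault(entry.monomer_id, []).append(entry)
    out: list[TemplateFeature] = []
    for tpl in templates:
        entries = by_monomer.get(tpl.monomer_id)
        if not entries:
            raise ConsistencyError(
                f"template {tpl.source_id!r} references monomer "
                f"{tpl.monomer_id!r} absent from the chain table"
            )
        L = entries[0].length
        if tpl.positions.size and (
            tpl.positions.min() < 0 or tpl.positions.max() >= L
        ):
            raise ConsistencyError(
                f"template {tpl.source_id!r} has positions outside the "
                f"length-{L} monomer {tpl.monomer_id!r}"
            )
        for entry in entries:
            out.append(
                TemplateFeature(
                    monomer_id=tpl.monomer_id,
                    source_id=tpl.source_id,
                    positions=tpl.positions + entry.start_col,
                    payload=tpl.payload,
                    chain_id=entry.chain_id,
                )
            )
    return out


def crop_domain_features(
    msa: MonomerMSA, ranges: list[tuple[int, int]]
) -> MonomerMSA:
    """Crop an MSA to query-coordinate ranges, reusing the full-length search.

    ``ranges`` are half-open [start, end) intervals in query (match-column)
    coordinates, ascending and non-overlapping; the returned MSA is the
    concatenation of the column slices, same depth. Insertion records are
    dropped: domain features are defined over match columns.
    """
    L = msa.length
    prev_end = 0
    for start, end in ranges:
        if not (0 <= start < end <= L):
            raise ParameterError(f"range [{start}, {end}) outside [0, {L})")
        if start < prev_end:
            raise ParameterError("ranges must be ascending and non-overlapping")
        prev_end = end
    if not ranges:
        raise ParameterError("at least one crop range required")
    new_rows = [
        "".join(row[s:e] for s, e in ranges) for row in msa.rows
    ]
    return MonomerMSA(
        monomer_id=msa.monomer_id,
        rows=new_rows,
        insertions=None,
        descriptions=list(msa.descriptions) if msa.descriptions else None,
    )


def assemble_complex_features(
    msas: list[MonomerMSA],
    stoich: StoichiometrySpec,
    b: int = DEFAULT_CHAIN_OFFSET,
    include_query_row: bool = True,
    templates: list[TemplateFeature] | None = None,
) -> ComplexFeatures:
    """Full assembly: complex MSA + residue-index + chain table + templates."""
    table = build_chain_table(msas, stoich)
    msa_rows = make_complex_msa(msas, stoich, include_query_row=include_query_row)
    lengths = [e.length for e in table]
    residue_index = make_residue_index(lengths, b=b)
    tpls = reindex_templates(templates, table) if templates else []
    return ComplexFeatures(
        msa=msa_rows,
        residue_index=residue_index,
        chain_table=table,
        templates=tpls,
    )
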