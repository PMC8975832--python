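"""Readers and writers for the external formats the toolkit touches.

Formats: A3M / aligned FASTA alignments (read + write), PDB and mmCIF models
(read; gemmi does the parsing), AF-style PAE JSON in its two common dialects,
the ``id:copies/id:copies`` stoichiometry mini-language, score reports as JSON
or flat TSV, and screening tables as TSV.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import gemmi
import numpy as np

from .errors import ConsistencyError, FormatError, ParameterError
from .types import (
    Atom,
    Chain,
    LabeledScore,
    MonomerMSA,
    PAEMatrix,
    Residue,
    ResidueKey,
    ScoreReport,
    StoichiometrySpec,
    StructureModel,
)

# ---------------------------------------------------------------------------
# A3M / aligned FASTA
# ---------------------------------------------------------------------------


def _parse_fasta_records(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    header: str | None = None
    seq_parts: list[str] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(seq_parts)))
            header = line[1:].strip()
            seq_parts = []
        else:
            if header is None:
                raise FormatError("sequence data before the first FASTA header")
            seq_parts.append(line.strip())
    if header is not None:
        records.append((header, "".join(seq_parts)))
    return records


def _split_a3m_row(seq: str) -> tuple[str, dict[int, str]]:
    """Split an A3M row into match columns and lowercase insertions.

    Uppercase letters and ``-`` are match columns; lowercase letters are
    insertions keyed by the number of match columns preceding them. ``.`` is
    an alternative gap-in-insertion notation and is dropped.
    """
    match_cols: list[str] = []
    insertions: dict[int, str] = {}
    for ch in seq:
        if ch == ".":
            continue
        if ch.islower():
            k = len(match_cols)
            insertions[k] = insertions.get(k, "") + ch.upper()
        else:
            match_cols.append(ch)
    return "".join(match_cols), insertions


def read_a3m(path: str | Path, monomer_id: str | None = None) -> MonomerMSA:
    """Read an A3M (or aligned FASTA) file into a :class:`MonomerMSA`.

    The first record is the query. Lowercase insertion columns are removed
    from the aligned representation and recorded separately, so every row of
    the returned MSA has exactly the query's match-column length.
    """
    path = Path(path)
    records = _parse_fasta_records(path.read_text())
    if not records:
        raise FormatError(f"{path}: no sequences found")
    rows: list[str] = []
    insertions: list[dict[int, str]] = []
    descriptions: list[str] = []
    for header, seq in records:
        aligned, ins = _split_a3m_row(seq)
        rows.append(aligned)
        insertions.append(ins)
        descriptions.append(header)
    L = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != L:
            raise FormatError(
                f"{path}: row {i} ({descriptions[i][:30]!r}) has {len(row)} "
                f"match columns, query has {L}"
            )
    return MonomerMSA(
        monomer_id=monomer_id or path.stem,
        rows=rows,
        insertions=insertions,
        descriptions=descriptions,
    )


def write_a3m(msa: MonomerMSA, path: str | Path) -> None:
    """Write a :class:`MonomerMSA` back to A3M, re-inserting lowercase runs."""
    path = Path(path)
    lines: list[str] = []
    for r in range(msa.depth):
        desc = (
            msa.descriptions[r]
            if msa.descriptions is not None
            else f"{msa.monomer_id}_{r}"
        )
        ins = msa.insertions[r] if msa.insertions is not None else {}
        row = msa.rows[r]
        parts: list[str] = []
        for k in range(len(row) + 1):
            if k in ins:
                parts.append(ins[k].lower())
            if k < len(row):
                parts.append(row[k])
        lines.append(f">{desc}")
        lines.append("".join(parts))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Structures (PDB / mmCIF via gemmi)
# ---------------------------------------------------------------------------


def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: per atom name keep the highest occupancy,
    ties broken by first occurrence."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF model, keeping heavy atoms only.

    Hydrogens are dropped; alternate locations resolve to the highest
    occupancy (ties to the first seen); chains and residues keep file order.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse structure ({exc})") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models in file")
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            atoms = [
                Atom(name=a.name, xyz=np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in _pick_altlocs(gres)
                if not a.is_hydrogen()
            ]
            if not atoms:
                continue
            residues.append(
                Residue(
                    number=gres.seqid.num,
                    name=gres.name,
                    atoms=atoms,
                    het=(gres.het_flag == "H"),
                )
            )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if not chains:
        raise FormatError(f"{path}: zero parsable heavy atoms")
    return StructureModel(chains=chains)


def to_gemmi_structure(model: StructureModel, name: str = "model") -> gemmi.Structure:
    """Convert a :class:`StructureModel` into a gemmi Structure for writing."""
    st = gemmi.Structure()
    st.name = name
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, " ")
            gres.het_flag = "H" if res.het else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.name[0])
                ga.pos = gemmi.Position(*atom.xyz)
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_pdb(model: StructureModel, path: str | Path) -> None:
    to_gemmi_structure(model).write_pdb(str(path))


# ---------------------------------------------------------------------------
# PAE JSON
# ---------------------------------------------------------------------------


def _extract_pae_payload(data) -> list:
    """Accept the two common AF-style PAE encodings: a bare list-of-lists or
    an object keyed 'predicted_aligned_error' (possibly inside a one-element
    list wrapper)."""
    if isinstance(data, list) and len(data) == 1 and isinstance(data[0], dict):
        data = data[0]
    if isinstance(data, dict):
        if "predicted_aligned_error" not in data:
            raise FormatError("PAE JSON object lacks 'predicted_aligned_error'")
        data = data["predicted_aligned_error"]
    if not isinstance(data, list):
        raise FormatError("PAE JSON is neither a matrix nor a keyed object")
    return data


def read_pae(path: str | Path, residue_order: list[ResidueKey]) -> PAEMatrix:
    """Read a PAE JSON file and bind it to a model's residue order.

    Residue matching is positional: row/column i of the matrix is residue i
    of ``residue_order`` (chain-then-residue file order).
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    rows = _extract_pae_payload(data)
    n = len(rows)
    if n == 0 or any(not isinstance(r, list) or len(r) != n for r in rows):
        raise FormatError(f"{path}: PAE matrix is not square")
    values = np.asarray(rows, dtype=float)
    if len(residue_order) != n:
        raise ConsistencyError(
            f"{path}: PAE dimension {n} != model residue count {len(residue_order)}"
        )
    return PAEMatrix(values=values, residue_order=list(residue_order))


def write_pae(pae: PAEMatrix, path: str | Path, dialect: str = "object") -> None:
    """Write PAE JSON; dialect 'object' or 'list'."""
    payload = pae.values.tolist()
    if dialect == "object":
        data = {"predicted_aligned_error": payload}
    elif dialect == "list":
        data = payload
    else:
        raise ParameterError(f"unknown PAE dialect {dialect!r}")
    Path(path).write_text(json.dumps(data))


# ---------------------------------------------------------------------------
# Stoichiometry mini-language
# ---------------------------------------------------------------------------


def parse_stoichiometry(spec_string: str) -> StoichiometrySpec:
    """Parse ``"idA:2/idB:1"`` (copies default to 1 when ``:n`` is omitted)."""
    if not spec_string or not spec_string.strip():
        raise ParameterError("empty stoichiometry string")
    components: list[tuple[str, int]] = []
    for token in spec_string.strip().split("/"):
        token = token.strip()
        if not token:
            raise ParameterError(f"empty component in {spec_string!r}")
        if ":" in token:
            mid, _, copies_str = token.partition(":")
            try:
                copies = int(copies_str)
            except ValueError as exc:
                raise ParameterError(
                    f"bad copy count {copies_str!r} in {spec_string!r}"
                ) from exc
        else:
            mid, copies = token, 1
        if not mid:
            raise ParameterError(f"missing monomer id in {spec_string!r}")
        components.append((mid, copies))
    return StoichiometrySpec(tuple(components))


# ---------------------------------------------------------------------------
# Score reports
# ---------------------------------------------------------------------------


def write_report_json(reports: ScoreReport | list[ScoreReport], path: str | Path) -> None:
    if isinstance(reports, ScoreReport):
        reports = [reports]
    Path(path).write_text(json.dumps([r.to_dict() for r in reports], indent=1))


_REPORT_COLUMNS = [
    "model_id",
    "piTM",
    "interface_score",
    "clash_indicator",
    "interface_size",
    "n_contacts",
]


def write_reports_tsv(reports: list[ScoreReport], path: str | Path) -> None:
    """Flat TSV, one row per model; NA for an undefined clash indicator."""
    lines = ["\t".join(_REPORT_COLUMNS)]
    for r in reports:
        chi = "NA" if r.clash_indicator is None else f"{r.clash_indicator:.6g}"
        lines.append(
            "\t".join(
                [
                    r.model_id,
                    f"{r.pitm:.6g}",
                    f"{r.interface_score:.6g}",
                    chi,
                    str(r.interface_size),
                    str(r.n_contacts),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Screening tables
# ---------------------------------------------------------------------------

_PAIR_SEP = ":"


def pair_id_to_string(pair: tuple[str, str]) -> str:
    return f"{pair[0]}{_PAIR_SEP}{pair[1]}"


def read_screening_table(path: str | Path) -> list[LabeledScore]:
    """Read a ``pair_id<TAB>score<TAB>label`` TSV.

    ``pair_id`` is ``a:b``; labels may be 1/0 or positive/negative.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty screening table")
    start = 1 if lines[0].lower().startswith("pair_id") else 0
    out: list[LabeledScore] = []
    for ln in lines[start:]:
        fields = ln.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}: expected 3 tab-separated fields: {ln!r}")
        pair_id, score_str, label_str = fields
        a, sep, b = pair_id.partition(_PAIR_SEP)
        if not sep:
            raise FormatError(f"{path}: pair id {pair_id!r} lacks separator")
        try:
            score = float(score_str)
        except ValueError as exc:
            raise FormatError(f"{path}: bad score {score_str!r}") from exc
        label_str = label_str.strip().lower()
        if label_str in ("1", "positive", "true", "pos"):
            label = True
        elif label_str in ("0", "negative", "false", "neg"):
            label = False
        else:
            raise FormatError(f"{path}: bad label {label_str!r}")
        out.append(LabeledScore(pair=(a, b), score=score, label=label))
    return out


def write_screening_table(scores: list[LabeledScore], path: str | Path) -> None:
    lines = ["pair_id\tscore\tlabel"]
    for s in scores:
        lines.append(
            f"{pair_id_to_string(s.pair)}\t{s.score:.6g}\t{1 if s.label else 0}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
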