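"""Inter-chain contact detection and the interface clash indicator.

A residue-residue contact exists when any heavy atom of a residue on one
chain lies within 4.5 Å (inclusive) of any heavy atom of a residue on another
chain. The interface residues are the union of contact endpoints. The clash
indicator chi = N_iRes / N_iCnt summarises interface physicality: each
contact can introduce at most two new interface residues, so chi is in
(0, 2]; interpenetrating (unphysical) interfaces pile many contacts onto few
residues and drive chi toward 0, while experimental interfaces typically
fall between 0.6 and 1.2. Because chi needs only distances it applies
directly to un-relaxed models, making it a cheap pre-filter.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .types import InterfaceSet, ResidueKey, StructureModel

#: Heavy-atom distance cutoff (Å) defining an inter-chain residue contact.
DEFAULT_CONTACT_CUTOFF = 4.5


def _gather_atoms(
    model: StructureModel, include_hetero: bool
) -> tuple[np.ndarray, list[ResidueKey]]:
    coords: list[np.ndarray] = []
    owners: list[ResidueKey] = []
    for chain in model.chains:
        for res in chain.residues:
            if not include_hetero and (res.het or res.is_water):
                continue
            for atom in res.atoms:
                coords.append(atom.xyz)
                owners.append((chain.chain_id, res.number))
    if not coords:
        return np.empty((0, 3)), []
    return np.asarray(coords, dtype=float), owners


def find_interface(
    model: StructureModel,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    include_hetero: bool = False,
) -> InterfaceSet:
    """Detect inter-chain residue contacts at a heavy-atom distance cutoff.

    The comparison is inclusive (min inter-residue heavy-atom distance
    <= cutoff). Waters and hetero residues are skipped unless
    ``include_hetero``. A single-chain model yields an empty interface, not
    an error. The neighbor search uses a k-d tree; results are identical to
    an all-pairs scan.
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    coords, owners = _gather_atoms(model, include_hetero)
    if len(owners) == 0 or len(model.chains) < 2:
        return InterfaceSet.from_pairs([])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    contacts: set[tuple[ResidueKey, ResidueKey]] = set()
    for ia, ib in pairs:
        ra, rb = owners[ia], owners[ib]
        if ra[0] != rb[0]:
            contacts.add(tuple(sorted((ra, rb))))
    return InterfaceSet.from_pairs(contacts)


def clash_indicator(iface: InterfaceSet) -> float | None:
    """chi = N_iRes / N_iCnt, or None (NA) when there are no contacts.

    Values near 2 mean each contact brings its own residue pair (a sparse,
    physical interface); values near 0 flag interpenetrating chains.
    """
    if iface.n_contacts == 0:
        return None
    return iface.n_interface_residues / iface.n_contacts


def flag_clashing(iface: InterfaceSet, threshold: float) -> bool:
    """True iff chi is defined and below ``threshold``.

    A model without an interface is never flagged: there is nothing to
    judge. Thresholds around 0.6 (the low end of the experimental range)
    are a sensible starting point for discarding unphysical models early.
    """
    if not (0 < threshold <= 2):
        raise ParameterError(f"threshold must be in (0, 2], got {threshold}")
    chi = clash_indicator(iface)
    return chi is not None and chi < threshold
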