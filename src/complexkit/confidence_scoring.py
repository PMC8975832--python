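"""Interface-aware complex confidence metrics from a PAE matrix.

Both metrics restrict a TM-score-style confidence to the interface residue
set I observed in the predicted model, using the network's predicted aligned
errors <e_ij> (the estimated error of residue j's position in the local
frame of residue i) in place of real distances:

    piTM = max_{i in I} (1/I) sum_{j in I} 1 / (1 + [<e_ij> / d0(I)]^2)

The max over reference residues i plays the role of the optimal
superposition in a real TM-score. d0(I) is the TM-score distance
normalization adapted to small interfaces:

    d0(I) = 1.24 * (I - 15)^(1/3) - 1.8   if I >= 22
            0.02 * I                       if I <  22

The interface-score S scores each chain p separately and sums the terms;
chain p's reference frame may only be drawn from interface residues NOT on
chain p, so a chain cannot vouch for its own placement:

    S = sum_p (1/I) max_{i in I \\ I_p} sum_{j in I_p} 1/(1 + [<e_ij>/d0(I)]^2)

Both scores live in [0, 1]; an empty interface scores 0 by convention. For
ranking candidate models, the interface-score is the primary key.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, ParameterError
from .interface_analysis import DEFAULT_CONTACT_CUTOFF, clash_indicator, find_interface
from .types import (
    InterfaceSet,
    PAEMatrix,
    ResidueKey,
    ScoreReport,
    StructureModel,
)

#: Interface-score above which a predicted interaction is called confident.
CONFIDENT_INTERFACE_SCORE = 0.45

#: Reference operating points from all-against-all interaction screening:
#: interface-score 0.55 gives ~45% recall at ~90% precision, 0.45 gives
#: ~70% recall at ~45% precision (documentation only, nothing is gated).
SCREENING_OPERATING_POINTS = {"high_precision": 0.55, "high_recall": 0.45}


def d0(n_interface_residues: int) -> float:
    """Interface-size-dependent distance normalization (Å).

    Piecewise: the classic TM-score form for I >= 22, and a linear 0.02*I
    branch for small interfaces where the cube-root form misbehaves. The
    function is deliberately discontinuous at I = 22 (0.42 -> ~0.572).
    """
    I = n_interface_residues
    if I <= 0:
        raise ParameterError(f"d0 needs at least one interface residue, got {I}")
    if I >= 22:
        return 1.24 * (I - 15) ** (1.0 / 3.0) - 1.8
    return 0.02 * I


@dataclass
class MetricInputs:
    """PAE + interface bundle feeding the two confidence metrics."""

    pae: PAEMatrix
    iface: InterfaceSet
    chain_count: int
    index_map: dict[ResidueKey, int]

    @classmethod
    def build(
        cls,
        pae: PAEMatrix,
        iface: InterfaceSet,
        chain_count: int | None = None,
    ) -> "MetricInputs":
        index_map = pae.index_map()
        if chain_count is None:
            chain_count = len({cid for cid, _ in pae.residue_order})
        return cls(pae=pae, iface=iface, chain_count=chain_count, index_map=index_map)

    def _indices(self, residues) -> np.ndarray:
        try:
            return np.array(
                [self.index_map[r] for r in sorted(residues)], dtype=int
            )
        except KeyError as exc:
            raise ConsistencyError(
                f"interface residue {exc.args[0]} missing from the PAE residue order"
            ) from exc


def _tm_terms(pae_values: np.ndarray, idx_ref, idx_tgt, d0_val: float) -> np.ndarray:
    """Matrix of 1/(1 + (e_ij/d0)^2) for reference rows x target columns."""
    E = pae_values[np.ix_(idx_ref, idx_tgt)]
    return 1.0 / (1.0 + (E / d0_val) ** 2)


def pitm(inputs: MetricInputs) -> float:
    """Predicted interface TM-score (in [0, 1]); 0 for an empty interface."""
    residues = inputs.iface.interface_residues
    I = len(residues)
    if I == 0:
        return 0.0
    idx = inputs._indices(residues)
    terms = _tm_terms(inputs.pae.values, idx, idx, d0(I))
    return float(terms.sum(axis=1).max() / I)


def interface_score(inputs: MetricInputs) -> float:
    """Interface-score S (in [0, 1]); see module docstring for the form."""
    return sum(t for _, t in interface_score_terms(inputs))


def interface_score_terms(inputs: MetricInputs) -> list[tuple[str, float]]:
    """Per-chain terms of S, one per chain in the complex (zeros included).

    A chain with no interface residues contributes 0, as does a chain whose
    complement I \\ I_p is empty (guarded; cannot occur with contacts across
    two or more chains).
    """
    residues = inputs.iface.interface_residues
    I = len(residues)
    chain_ids = sorted({cid for cid, _ in inputs.pae.residue_order})
    if I == 0:
        return [(cid, 0.0) for cid in chain_ids]
    per_chain = inputs.iface.per_chain
    d0_val = d0(I)
    terms: list[tuple[str, float]] = []
    for cid in chain_ids:
        own = per_chain.get(cid, frozenset())
        others = residues - own
        if not own or not others:
            terms.append((cid, 0.0))
            continue
        idx_ref = inputs._indices(others)
        idx_tgt = inputs._indices(own)
        f = _tm_terms(inputs.pae.values, idx_ref, idx_tgt, d0_val)
        terms.append((cid, float(f.sum(axis=1).max() / I)))
    return terms


def score_model(
    model: StructureModel,
    pae: PAEMatrix,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    model_id: str = "model",
) -> ScoreReport:
    """Full confidence report for one model: piTM, S, chi and interface size."""
    order = model.residue_order()
    if pae.residue_order != order:
        raise ConsistencyError(
            "PAE residue order does not match the model's chain/residue order"
        )
    iface = find_interface(model, cutoff=cutoff)
    inputs = MetricInputs.build(pae, iface, chain_count=len(model.chains))
    chain_terms = interface_score_terms(inputs)
    return ScoreReport(
        model_id=model_id,
        pitm=pitm(inputs),
        interface_score=sum(t for _, t in chain_terms),
        clash_indicator=clash_indicator(iface),
        interface_size=iface.n_interface_residues,
        n_contacts=iface.n_contacts,
        per_chain_terms=chain_terms,
    )


def rank_models(reports: list[ScoreReport]) -> list[ScoreReport]:
    """Rank candidate models by interface-score, descending.

    Ties break by piTM (descending), then model_id (lexicographic); the
    ordering is total and deterministic. This is the selection rule used to
    pick the overall top model from repeated prediction runs.
    """
    if not reports:
        raise ParameterError("rank_models needs at least one report")
    return sorted(
        reports, key=lambda r: (-r.interface_score, -r.pitm, r.model_id)
    )
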