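"""Synthetic inputs with known ground truth for the whole pipeline.

Nothing here pretends to be physically realistic protein geometry: the point
is controlled contact topology. Toy chains are poly-glycine with a single
heavy atom per residue (so residue-residue distances are trivially the
placed-point distances), except for the helix-pair geometry which builds a
four-atom backbone per residue for a little realism. Every generator is
deterministic given its seed, and every toy complex comes with its expected
interface computed from the constructed coordinates themselves — the
independent ground truth the contact detector is tested against.

PAE surfaces come in four flavours (zero, constant, two-block, noisy); values
are clipped at 31.75 Å, mirroring the value ceiling of typical AF-style PAE
output (a fixture-realism constant, configurable).
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .types import (
    Atom,
    Chain,
    InterfaceSet,
    LabeledScore,
    MonomerMSA,
    PAEMatrix,
    Residue,
    ResidueKey,
    StructureModel,
)

#: Clip ceiling (Å) for generated PAE values, mimicking AF output quantization.
PAE_CEILING = 31.75

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------


def _point_chain(chain_id: str, points: np.ndarray) -> Chain:
    """Poly-glycine chain with one CA heavy atom per residue."""
    return Chain(
        chain_id=chain_id,
        residues=[
            Residue(number=i + 1, name="GLY", atoms=[Atom("CA", p)])
            for i, p in enumerate(points)
        ],
    )


def _scan_expected_interface(
    model: StructureModel, cutoff: float
) -> InterfaceSet:
    """Ground-truth contacts from the constructed coordinates: a direct
    all-pairs minimum-distance scan over the generator's own geometry."""
    entries: list[tuple[ResidueKey, np.ndarray]] = []
    for chain in model.chains:
        for res in chain.residues:
            entries.append(((chain.chain_id, res.number), res.coords()))
    pairs = []
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            (ka, ca), (kb, cb) = entries[i], entries[j]
            if ka[0] == kb[0]:
                continue
            d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
            if np.sqrt(d2.min()) <= cutoff:
                pairs.append((ka, kb))
    return InterfaceSet.from_pairs(pairs)


def ladder_complex(
    k: int = 5, rung: float = 4.0, spacing: float = 10.0, cutoff: float = 4.5
) -> tuple[StructureModel, InterfaceSet]:
    """Two parallel rails of k residues; rung i pairs residue i of each chain.

    With rung <= cutoff < sqrt(spacing^2 + rung^2) each residue contacts only
    its opposite partner: exactly k contacts, 2k interface residues, chi = 2.
    """
    if k < 1:
        raise ParameterError("ladder needs k >= 1")
    if np.hypot(spacing, rung) <= cutoff:
        raise ParameterError(
            "spacing too small: neighbouring rungs would also be in contact"
        )
    xs = np.arange(k) * spacing
    a = np.column_stack([xs, np.zeros(k), np.zeros(k)])
    b = np.column_stack([xs, np.full(k, rung), np.zeros(k)])
    model = StructureModel([_point_chain("A", a), _point_chain("B", b)])
    if rung <= cutoff:
        expected = InterfaceSet.from_pairs(
            [(("A", i + 1), ("B", i + 1)) for i in range(k)]
        )
    else:
        expected = InterfaceSet.from_pairs([])
    return model, expected


def interpenetrating_complex(
    m: int = 6, lateral: float = 0.3, gap: float = 0.5, cutoff: float = 4.5
) -> tuple[StructureModel, InterfaceSet]:
    """Two tightly interleaved chains of m residues each.

    Every residue of one chain contacts every residue of the other: m^2
    contacts over 2m residues, so chi = 2m/m^2 = 2/m -> 0 as m grows —
    the signature of an interpenetrating, unphysical interface.
    """
    if m < 1:
        raise ParameterError("interpenetrating fixture needs m >= 1")
    span = lateral * (m - 1)
    if np.hypot(span, gap) > cutoff:
        raise ParameterError(
            f"m={m} at lateral={lateral} spreads beyond the cutoff; "
            "reduce lateral spacing"
        )
    xs = np.arange(m) * lateral
    a = np.column_stack([xs, np.zeros(m), np.zeros(m)])
    b = np.column_stack([xs, np.full(m, gap), np.zeros(m)])
    model = StructureModel([_point_chain("A", a), _point_chain("B", b)])
    expected = InterfaceSet.from_pairs(
        [(("A", i + 1), ("B", j + 1)) for i in range(m) for j in range(m)]
    )
    return model, expected


def separated_complex(
    n: int = 5, gap: float = 50.0
) -> tuple[StructureModel, InterfaceSet]:
    """Two chains too far apart for any contact; the expected interface is empty."""
    xs = np.arange(n) * 4.0
    a = np.column_stack([xs, np.zeros(n), np.zeros(n)])
    b = np.column_stack([xs, np.full(n, gap), np.zeros(n)])
    model = StructureModel([_point_chain("A", a), _point_chain("B", b)])
    return model, InterfaceSet.from_pairs([])


def _ideal_helix(n_res: int, origin: np.ndarray) -> Chain:
    """Poly-glycine alpha-helix backbone (N, CA, C, O) along +z."""
    rise, twist, radius = 1.5, np.deg2rad(100.0), 2.3
    residues = []
    for i in range(n_res):
        theta = i * twist
        ca = origin + np.array(
            [radius * np.cos(theta), radius * np.sin(theta), i * rise]
        )
        # crude but fixed intra-residue offsets; geometry only needs heavy atoms
        n_at = ca + np.array([-0.6, 0.8, -0.9])
        c_at = ca + np.array([0.9, -0.4, 0.8])
        o_at = c_at + np.array([0.4, 1.0, 0.3])
        residues.append(
            Residue(
                number=i + 1,
                name="GLY",
                atoms=[
                    Atom("N", n_at),
                    Atom("CA", ca),
                    Atom("C", c_at),
                    Atom("O", o_at),
                ],
            )
        )
    return Chain(chain_id="?", residues=residues)


def helix_pair_complex(
    n_res: int = 15, axis_sep: float = 9.0, cutoff: float = 4.5
) -> tuple[StructureModel, InterfaceSet]:
    """Two parallel ideal helices with axes ``axis_sep`` Å apart.

    The contact pattern is irregular (it depends on which side chains of the
    wheel face each other), so the expected interface is computed by the
    generator's own all-pairs scan of the constructed coordinates.
    """
    h1 = _ideal_helix(n_res, np.zeros(3))
    h1.chain_id = "A"
    h2 = _ideal_helix(n_res, np.array([axis_sep, 0.0, 0.0]))
    h2.chain_id = "B"
    model = StructureModel([h1, h2])
    return model, _scan_expected_interface(model, cutoff)


def perturbed_ladder_complex(
    k: int = 5,
    rung: float = 4.0,
    spacing: float = 10.0,
    sigma: float = 0.5,
    seed: int = 0,
    cutoff: float = 4.5,
) -> tuple[StructureModel, InterfaceSet]:
    """Ladder with Gaussian coordinate jitter; ground truth re-derived by the
    generator's all-pairs scan of the jittered coordinates."""
    model, _ = ladder_complex(k=k, rung=rung, spacing=spacing, cutoff=cutoff)
    rng = np.random.default_rng(seed)
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.xyz = atom.xyz + rng.normal(0.0, sigma, size=3)
    return model, _scan_expected_interface(model, cutoff)


_GEOMETRIES = {
    "ladder": ladder_complex,
    "interpenetrating": interpenetrating_complex,
    "separated": separated_complex,
    "helix-pair": helix_pair_complex,
    "perturbed-ladder": perturbed_ladder_complex,
}


def make_toy_complex(
    geometry: str, **params
) -> tuple[StructureModel, InterfaceSet]:
    """Dispatch on geometry name: ladder, interpenetrating, separated,
    helix-pair, perturbed-ladder. Returns (model, expected interface)."""
    try:
        fn = _GEOMETRIES[geometry]
    except KeyError:
        raise ParameterError(
            f"unknown geometry {geometry!r}; choose from {sorted(_GEOMETRIES)}"
        ) from None
    return fn(**params)


# ---------------------------------------------------------------------------
# PAE surfaces
# ---------------------------------------------------------------------------


def make_pae(
    residue_order: list[ResidueKey],
    model: str = "zero",
    e: float = 0.0,
    e_intra: float = 1.0,
    e_inter: float = 20.0,
    mu: float = 10.0,
    sigma: float = 2.0,
    seed: int = 0,
    ceiling: float = PAE_CEILING,
) -> PAEMatrix:
    """Parametric PAE surface over ``residue_order``.

    Models: ``zero``; ``constant`` (all entries e); ``two-block`` (e_intra
    within a chain, e_inter across chains); ``noisy`` (|N(mu, sigma)| drawn
    independently per entry, hence asymmetric). Values are clipped to
    [0, ceiling].
    """
    T = len(residue_order)
    if T < 1:
        raise ParameterError("residue order must be non-empty")
    if min(e, e_intra, e_inter, mu) < 0 or sigma < 0:
        raise ParameterError("PAE parameters must be nonnegative")
    if model == "zero":
        values = np.zeros((T, T))
    elif model == "constant":
        values = np.full((T, T), float(e))
    elif model == "two-block":
        chains = np.array([cid for cid, _ in residue_order])
        same = chains[:, None] == chains[None, :]
        values = np.where(same, e_intra, e_inter).astype(float)
    elif model == "noisy":
        rng = np.random.default_rng(seed)
        values = np.abs(rng.normal(mu, sigma, size=(T, T)))
    else:
        raise ParameterError(f"unknown PAE model {model!r}")
    return PAEMatrix(values=np.clip(values, 0.0, ceiling), residue_order=list(residue_order))


# ---------------------------------------------------------------------------
# Random MSAs
# ---------------------------------------------------------------------------


def make_msa_set(
    msa_spec: list[tuple[int, int]],
    seed: int = 0,
    mutation_rate: float = 0.1,
    gap_rate: float = 0.05,
    ids: list[str] | None = None,
) -> list[MonomerMSA]:
    """Random monomer MSAs of the given (L_i, D_i) shapes.

    Row 0 is the query; homolog rows carry point mutations and gaps at the
    given per-column rates. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    out: list[MonomerMSA] = []
    for k, (L, D) in enumerate(msa_spec):
        if L < 1 or D < 1:
            raise ParameterError(f"MSA spec ({L}, {D}) invalid")
        query = rng.choice(aa, size=L)
        rows = ["".join(query)]
        for _ in range(D - 1):
            row = query.copy()
            mutate = rng.random(L) < mutation_rate
            row[mutate] = rng.choice(aa, size=int(mutate.sum()))
            gaps = rng.random(L) < gap_rate
            row[gaps] = "-"
            rows.append("".join(row))
        mid = ids[k] if ids else f"m{k + 1}"
        out.append(MonomerMSA(monomer_id=mid, rows=rows))
    return out


# ---------------------------------------------------------------------------
# Screening tables
# ---------------------------------------------------------------------------


def make_screening_table(
    n_pos: int,
    n_neg: int,
    separation: float,
    seed: int = 0,
) -> list[LabeledScore]:
    """Labeled pair scores emulating a screening run.

    Negative scores are N(0, 1); positive scores are N(separation, 1), so
    separation = 0 is the random-classifier null and large separations give
    near-perfect discrimination. Pair ids are synthetic placeholders.
    """
    if n_pos < 1 or n_neg < 1:
        raise ParameterError("need at least one positive and one negative")
    rng = np.random.default_rng(seed)
    out: list[LabeledScore] = []
    for i, s in enumerate(rng.normal(separation, 1.0, size=n_pos)):
        out.append(
            LabeledScore(pair=(f"pos{i:05d}a", f"pos{i:05d}b"), score=float(s), label=True)
        )
    for i, s in enumerate(rng.normal(0.0, 1.0, size=n_neg)):
        out.append(
            LabeledScore(pair=(f"neg{i:05d}a", f"neg{i:05d}b"), score=float(s), label=False)
        )
    return out
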