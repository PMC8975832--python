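"""Shared independent oracles and fixtures.

The oracles here deliberately use the dumbest possible formulations (explicit
Python loops, full quadratic scans) so they share no code path with the
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from complexkit.types import InterfaceSet


def brute_force_interface(model, cutoff=4.5, include_hetero=False) -> InterfaceSet:
    """Quadratic all-pairs residue contact scan (the contact-detector oracle)."""
    entries = []
    for chain in model.chains:
        for res in chain.residues:
            if not include_hetero and (res.het or res.is_water):
                continue
            entries.append(((chain.chain_id, res.number), res.coords()))
    pairs = []
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            (ka, ca), (kb, cb) = entries[i], entries[j]
            if ka[0] == kb[0]:
                continue
            dmin = min(
                float(np.linalg.norm(pa - pb)) for pa in ca for pb in cb
            )
            if dmin <= cutoff:
                pairs.append((ka, kb))
    return InterfaceSet.from_pairs(pairs)


def brute_force_pitm(pae_values, index_map, residues, d0_val) -> float:
    """Exhaustive reference-frame enumeration of the interface TM-score."""
    residues = sorted(residues)
    I = len(residues)
    best = -1.0
    for ri in residues:
        total = 0.0
        for rj in residues:
            e = pae_values[index_map[ri], index_map[rj]]
            total += 1.0 / (1.0 + (e / d0_val) ** 2)
        best = max(best, total / I)
    return best


def brute_force_interface_score(pae_values, index_map, residues, d0_val) -> float:
    """Exhaustive per-chain enumeration of the interface-score.

    For each chain p the reference frame ranges over interface residues not
    on p; each candidate frame sums the terms over p's interface residues.
    """
    residues = sorted(residues)
    I = len(residues)
    chains = sorted({cid for cid, _ in residues})
    total = 0.0
    for p in chains:
        own = [r for r in residues if r[0] == p]
        others = [r for r in residues if r[0] != p]
        if not own or not others:
            continue
        best = 0.0
        for ri in others:
            s = 0.0
            for rj in own:
                e = pae_values[index_map[ri], index_map[rj]]
                s += 1.0 / (1.0 + (e / d0_val) ** 2)
            best = max(best, s)
        total += best / I
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
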