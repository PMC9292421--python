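"""CASP-style interface accuracy measures and accuracy categories.

ICS (Interface Contact Similarity) is the F1-score over sets of cross-chain
residue contacts; IPS (Interface Patch Similarity) is the Jaccard coefficient
over sets of interface residues.  A residue pair is an interface contact when
any heavy-atom cross-chain distance is strictly below the cutoff (5.0 A by
default).  Quaternary-structure (QS) scores supplied from outside are mapped
to the usual accuracy categories: high (>= 0.7), medium ([0.3, 0.7)),
low ([0.1, 0.3)), incorrect (< 0.1).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .contacts import ResidueKey
from .errors import DomainError, NeedsMultimerError
from .structures import Structure

__all__ = [
    "InterfaceContacts",
    "interface_contacts",
    "ics",
    "ips",
    "qs_category",
    "count_categories",
    "CATEGORIES",
]

CATEGORIES = ("high", "medium", "low", "incorrect")

ResiduePair = tuple[ResidueKey, ResidueKey]


@dataclasses.dataclass
class InterfaceContacts:
    """Cross-chain residue contact pairs and the interface residue set."""

    pairs: set[ResiduePair]
    residues: set[ResidueKey]
    cutoff: float


def interface_contacts(s: Structure, cutoff: float = 5.0) -> InterfaceContacts:
    """Cross-chain residue pairs with any heavy-atom distance < cutoff."""
    if s.n_chains < 2:
        raise NeedsMultimerError("interface contacts need at least two chains")
    coords = s.coords()
    keys = [(a.chain_id, a.residue_index) for a in s.atoms]
    tree = cKDTree(coords)
    pairs: set[ResiduePair] = set()
    for i, j in tree.query_pairs(cutoff):
        if keys[i][0] == keys[j][0]:
            continue
        if np.linalg.norm(coords[i] - coords[j]) < cutoff:
            a, b = keys[i], keys[j]
            pairs.add((a, b) if a <= b else (b, a))
    residues: set[ResidueKey] = set()
    for a, b in pairs:
        residues.add(a)
        residues.add(b)
    return InterfaceContacts(pairs=pairs, residues=residues, cutoff=cutoff)


def ics(target: InterfaceContacts, model: InterfaceContacts) -> float:
    """F1-score of the model's cross-chain contact pairs against the target's."""
    if not target.pairs or not model.pairs:
        return 0.0
    shared = len(target.pairs & model.pairs)
    precision = shared / len(model.pairs)
    recall = shared / len(target.pairs)
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def ips(target: InterfaceContacts, model: InterfaceContacts) -> float:
    """Jaccard coefficient of the interface residue sets."""
    union = target.residues | model.residues
    if not union:
        return 0.0
    return len(target.residues & model.residues) / len(union)


def qs_category(qs: float) -> str:
    """Map a QS-score to an accuracy category label."""
    if not 0.0 <= qs <= 1.0:
        raise DomainError(f"QS-score {qs} outside [0, 1]")
    if qs >= 0.7:
        return "high"
    if qs >= 0.3:
        return "medium"
    if qs >= 0.1:
        return "low"
    return "incorrect"


def count_categories(values) -> dict[str, int]:
    """Tally QS-scores per category; also reports ``medium_or_better``."""
    counts = {c: 0 for c in CATEGORIES}
    for v in values:
        counts[qs_category(v)] += 1
    counts["medium_or_better"] = counts["high"] + counts["medium"]
    return counts
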