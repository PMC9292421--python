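"""Contact-area-difference (CAD) similarity scores.

All variants compare residue-level contact maps of a model against a target
through the bounded difference

    score = 1 - min(1, sum_G |T_ij - M_ij| / sum_G T_ij),

where G is the set of residue pairs with positive target area.  The score is
target-referenced: contacts present only in the model do not enter the
denominator, so a model with no contacts scores exactly 0 and an identical
model scores exactly 1.

Variants:

* global  -- all residue pairs,
* local   -- per residue, restricted to pairs containing it,
* interface -- inter-chain pairs only,
* binding site -- partner-agnostic: each residue's total inter-chain area is
  compared, ignoring which residue across the interface provides it.  A model
  that places the right residues at the interface but pairs them up wrongly
  (e.g. a subunit spun in place) keeps a high binding-site score while its
  interface score collapses.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping

from .contacts import ResidueContactMap, ResidueKey, interchain_subset
from .errors import CombinatorialLimitError, MappingError, UndefinedScoreError
from .structures import Structure

__all__ = [
    "CadResult",
    "relabel_chains",
    "cad_global",
    "cad_local",
    "cad_interface",
    "cad_binding_site",
    "match_chains",
    "cad_compare",
]


@dataclasses.dataclass
class CadResult:
    """Bundle of CAD scores for one model/target comparison."""

    global_score: float
    per_residue: dict[ResidueKey, float]
    variant: str
    chain_mapping: dict[str, str]


def _bounded_difference(
    target: Mapping[tuple[ResidueKey, ResidueKey], float],
    model: ResidueContactMap,
) -> float:
    denom = 0.0
    num = 0.0
    for pair, t in target.items():
        if t <= 0:
            continue
        denom += t
        num += abs(t - model.contacts.get(pair, 0.0))
    if denom <= 0:
        raise UndefinedScoreError("target has zero total contact area")
    return 1.0 - min(1.0, num / denom)


def cad_global(target: ResidueContactMap, model: ResidueContactMap) -> float:
    """Global CAD-score over all residue pairs with positive target area."""
    return _bounded_difference(target.contacts, model)


def cad_local(
    target: ResidueContactMap, model: ResidueContactMap
) -> dict[ResidueKey, float]:
    """Per-residue CAD-scores; residues without target contact area are omitted."""
    per_res_pairs: dict[ResidueKey, list[tuple[tuple[ResidueKey, ResidueKey], float]]] = {}
    for pair, t in target.contacts.items():
        if t <= 0:
            continue
        for res in pair:
            per_res_pairs.setdefault(res, []).append((pair, t))
    out: dict[ResidueKey, float] = {}
    for res, entries in per_res_pairs.items():
        denom = sum(t for _, t in entries)
        num = sum(abs(t - model.contacts.get(pair, 0.0)) for pair, t in entries)
        out[res] = 1.0 - min(1.0, num / denom)
    return out


def cad_interface(target: ResidueContactMap, model: ResidueContactMap) -> float:
    """CAD-score restricted to inter-chain residue pairs."""
    t_sub = interchain_subset(target)
    if not t_sub.contacts:
        raise UndefinedScoreError("target has no inter-chain contacts")
    return _bounded_difference(t_sub.contacts, interchain_subset(model))


def cad_binding_site(target: ResidueContactMap, model: ResidueContactMap) -> float:
    """Partner-agnostic interface comparison of per-residue inter-chain areas."""
    t_sub = interchain_subset(target)
    if not t_sub.contacts:
        raise UndefinedScoreError("target has no inter-chain contacts")
    m_sub = interchain_subset(model)

    def per_residue_totals(rcm: ResidueContactMap) -> dict[ResidueKey, float]:
        totals: dict[ResidueKey, float] = {}
        for (a, b), area in rcm.contacts.items():
            totals[a] = totals.get(a, 0.0) + area
            totals[b] = totals.get(b, 0.0) + area
        return totals

    t_tot = per_residue_totals(t_sub)
    m_tot = per_residue_totals(m_sub)
    denom = sum(t_tot.values())
    num = sum(abs(t - m_tot.get(res, 0.0)) for res, t in t_tot.items())
    return 1.0 - min(1.0, num / denom)


def relabel_chains(rcm: ResidueContactMap, mapping: Mapping[str, str]) -> ResidueContactMap:
    """Return a copy of ``rcm`` with chain ids renamed according to ``mapping``."""
    def remap(key: ResidueKey) -> ResidueKey:
        return (mapping.get(key[0], key[0]), key[1])

    contacts: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for (a, b), area in rcm.contacts.items():
        pk = ResidueContactMap.pair_key(remap(a), remap(b))
        contacts[pk] = contacts.get(pk, 0.0) + area
    solvent = {remap(k): v for k, v in rcm.solvent.items()}
    return ResidueContactMap(contacts=contacts, solvent=solvent)


def match_chains(
    target: Structure,
    model: Structure,
    target_rcm: ResidueContactMap | None = None,
    model_rcm: ResidueContactMap | None = None,
    probe: float = 1.4,
    n_samples: int = 256,
    seed: int = 0,
) -> dict[str, str]:
    """Best model-to-target chain mapping for interchangeable (equal-length) chains.

    Chains are grouped into classes by residue count; all permutations within
    classes are enumerated (at most 8 chains per class) and the mapping
    maximizing the interface CAD-score wins, ties broken lexicographically.
    Residue contact maps are computed on demand when not supplied.
    """
    if target_rcm is None or model_rcm is None:
        from .contacts import aggregate_residues, compute_contact_map

        if target_rcm is None:
            target_rcm = aggregate_residues(
                compute_contact_map(target, probe=probe, n_samples=n_samples, seed=seed),
                target,
            )
        if model_rcm is None:
            model_rcm = aggregate_residues(
                compute_contact_map(model, probe=probe, n_samples=n_samples, seed=seed),
                model,
            )
    t_len = target.chain_lengths()
    m_len = model.chain_lengths()
    classes: dict[int, tuple[list[str], list[str]]] = {}
    for c, n in t_len.items():
        classes.setdefault(n, ([], []))[0].append(c)
    for c, n in m_len.items():
        classes.setdefault(n, ([], []))[1].append(c)
    for n, (tc, mc) in classes.items():
        if len(tc) != len(mc):
            raise MappingError(
                f"chain multiset mismatch for length {n}: target {tc} vs model {mc}"
            )
        if len(tc) > 8:
            raise CombinatorialLimitError(
                f"{len(tc)} interchangeable chains of length {n}: too many to enumerate"
            )
    class_list = sorted(classes.items())
    best_mapping: dict[str, str] | None = None
    best_score = -math.inf
    perm_iters = [
        itertools.permutations(sorted(mc)) for _, (tc, mc) in class_list
    ]
    for combo in itertools.product(*perm_iters):
        mapping: dict[str, str] = {}
        for (_, (tc, _)), perm in zip(class_list, combo):
            for t_chain, m_chain in zip(sorted(tc), perm):
                mapping[m_chain] = t_chain
        try:
            score = cad_interface(target_rcm, relabel_chains(model_rcm, mapping))
        except UndefinedScoreError:
            score = -1.0
        key = tuple(sorted(mapping.items()))
        if score > best_score + 1e-12 or (
            best_mapping is not None
            and abs(score - best_score) <= 1e-12
            and key < tuple(sorted(best_mapping.items()))
        ):
            best_score = score
            best_mapping = mapping
    assert best_mapping is not None
    return best_mapping


def cad_compare(
    target_rcm: ResidueContactMap,
    model_rcm: ResidueContactMap,
    variant: str = "all",
    chain_mapping: Mapping[str, str] | None = None,
) -> CadResult:
    """Convenience wrapper returning a :class:`CadResult` for one variant."""
    if chain_mapping:
        model_rcm = relabel_chains(model_rcm, chain_mapping)
    if variant == "all":
        g = cad_global(target_rcm, model_rcm)
        locals_ = cad_local(target_rcm, model_rcm)
    elif variant == "interface":
        g = cad_interface(target_rcm, model_rcm)
        locals_ = cad_local(interchain_subset(target_rcm), interchain_subset(model_rcm))
    elif variant == "binding_site":
        g = cad_binding_site(target_rcm, model_rcm)
        locals_ = {}
    else:
        raise ValueError(f"unknown CAD variant {variant!r}")
    return CadResult(
        global_score=g,
        per_residue=locals_,
        variant=variant,
        chain_mapping=dict(chain_mapping or {}),
    )
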