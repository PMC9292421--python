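"""Contact-area statistical potential and quality scores.

Two scoring layers share the same geometric substrate (contact areas from
:mod:`camqa.contacts`):

* the *light* layer: a knowledge-based contact potential over coarse atom
  classes (including a solvent pseudo-type), derived from reference
  structures as centered observed-vs-expected log-odds; a pseudo-energy
  functional linear in contact areas; the inter-chain restriction of that
  functional (the interface pseudo-energy, lower = more favorable); and a
  bounded global score obtained by a sigmoid of the mean energy density.

* the *dark* layer: a small feed-forward network trained to predict local
  (per-residue) CAD-scores from per-residue contact-area and potential
  features; the global dark score is the arithmetic mean of the predicted
  local scores, exactly.

Atom typing is a deliberately coarse nine-class vocabulary (backbone N/C/O,
CA, CB, side-chain C/N/O, S): enough classes for the potential to separate
packing environments, few enough to be learnable from fixture-scale
reference sets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from typing import Sequence

import numpy as np

from .contacts import (
    ContactMap,
    ResidueContactMap,
    ResidueKey,
    aggregate_residues,
    compute_contact_map,
)
from .errors import (
    InsufficientDataError,
    StateError,
    UndefinedScoreError,
)
from .structures import Atom, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "SOLVENT",
    "ATOM_TYPES",
    "atom_type",
    "Potential",
    "derive_potential",
    "potential_from_observed_areas",
    "pseudo_energy",
    "interface_energy",
    "light_global",
    "FEATURE_NAMES",
    "dark_features",
    "DarkModel",
    "dark_train",
    "dark_score",
    "ModelScores",
    "score_structure",
]

SOLVENT = "solvent"

_BACKBONE = {"N": "bb-N", "C": "bb-C", "O": "bb-O", "OXT": "bb-O", "CA": "CA", "CB": "CB"}

ATOM_TYPES = (
    "bb-N",
    "bb-C",
    "bb-O",
    "CA",
    "CB",
    "sc-C",
    "sc-N",
    "sc-O",
    "S",
)

_warned_atoms: set[str] = set()


def atom_type(a: Atom) -> str:
    """Coarse atom class of a standard amino-acid atom.

    Unknown atoms fall back to a generic side-chain class by element (with a
    one-time warning); sulfur is always class ``S``.
    """
    name = a.atom_name.upper()
    if name in _BACKBONE:
        return _BACKBONE[name]
    el = a.element.upper()
    if el == "S":
        return "S"
    if el in ("C", "N", "O"):
        return f"sc-{el}"
    if name not in _warned_atoms:
        _warned_atoms.add(name)
        logger.warning("unknown atom %s (element %s): using generic sc-C class", name, el)
    return "sc-C"


@dataclasses.dataclass
class Potential:
    """Symmetric map from atom-class pairs (incl. solvent) to pseudo-energies."""

    entries: dict[tuple[str, str], float]

    @staticmethod
    def pair_key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> float:
        return self.entries.get(self.pair_key(a, b), 0.0)

    def save(self, path) -> None:
        from . import __version__

        with open(path, "w") as fh:
            fh.write(f"# camqa {__version__} contact potential\n")
            fh.write("# type_a\ttype_b\tenergy\n")
            for (a, b), e in sorted(self.entries.items()):
                fh.write(f"{a}\t{b}\t{e:.6f}\n")

    @classmethod
    def load(cls, path) -> "Potential":
        entries: dict[tuple[str, str], float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b, e = line.split("\t")
                entries[cls.pair_key(a, b)] = float(e)
        return cls(entries=entries)


def _accumulate_type_areas(
    cm: ContactMap, s: Structure, totals: dict[tuple[str, str], float]
) -> None:
    types = [atom_type(a) for a in s.atoms]
    for i, j, area in cm.iter_contacts():
        key = Potential.pair_key(types[i], types[j])
        totals[key] = totals.get(key, 0.0) + area
    for i, a in enumerate(cm.solvent_areas):
        key = Potential.pair_key(types[i], SOLVENT)
        totals[key] = totals.get(key, 0.0) + float(a)


def derive_potential(
    refs: Sequence[Structure],
    pseudocount: float = 1.0,
    probe: float = 1.4,
    n_samples: int = 256,
    seed: int = 0,
) -> Potential:
    """Derive a contact potential from reference structures.

    ``e(a, b) = -ln[(O(a,b) + pc) / (E(a,b) + pc)]`` where O is the observed
    contact area between classes a and b over all references and E the area
    expected if class endpoints paired independently in proportion to their
    total areas.  The potential is then centered so that the observed-area
    weighted mean energy is zero, making the reference set itself score
    neutrally (the reference-state convention).
    """
    if not refs:
        raise InsufficientDataError("need at least one reference structure")
    observed: dict[tuple[str, str], float] = {}
    for s in refs:
        cm = compute_contact_map(s, probe=probe, n_samples=n_samples, seed=seed)
        _accumulate_type_areas(cm, s, observed)
    return potential_from_observed_areas(observed, pseudocount=pseudocount)


def potential_from_observed_areas(
    observed: dict[tuple[str, str], float], pseudocount: float = 1.0
) -> Potential:
    """Convert an observed type-pair area table into a centered potential.

    The independence null is the quasi-independence model (solvent cannot
    contact itself): expected areas ``E(a,b) = u_a * u_b * (2 - delta_ab)``
    with type weights ``u`` fitted by iterative proportional scaling to the
    observed endpoint margins.  An observed table that itself follows the
    null therefore yields zero energies exactly (up to the pseudocount).
    """
    total_area = sum(observed.values())
    if total_area <= 0:
        raise InsufficientDataError("reference structures have no contacts")
    # endpoint margins: each contact contributes its area to both endpoints
    share: dict[str, float] = {}
    for (a, b), area in observed.items():
        share[a] = share.get(a, 0.0) + area
        share[b] = share.get(b, 0.0) + area
    types = sorted(share)
    # iterative proportional fitting of the margin equations
    u = {t: math.sqrt(max(share[t], 1e-12) / 2.0) for t in types}
    for _ in range(200):
        max_rel = 0.0
        total_u = sum(u.values())
        for t in types:
            if t == SOLVENT:
                denom = 2.0 * (total_u - u[t])
            else:
                denom = 2.0 * total_u
            if denom <= 0:
                continue
            new = share[t] / denom
            max_rel = max(max_rel, abs(new - u[t]) / max(u[t], 1e-12))
            total_u += new - u[t]
            u[t] = new
        if max_rel < 1e-12:
            break
    entries: dict[tuple[str, str], float] = {}
    for ia, a in enumerate(types):
        for b in types[ia:]:
            if a == SOLVENT and b == SOLVENT:
                continue
            expected = u[a] * u[b] * (1.0 if a == b else 2.0)
            obs = observed.get(Potential.pair_key(a, b), 0.0)
            entries[Potential.pair_key(a, b)] = -math.log(
                (obs + pseudocount) / (expected + pseudocount)
            )
    # center: reference set scores zero on average
    weighted = sum(observed.get(k, 0.0) * e for k, e in entries.items())
    shift = weighted / total_area
    entries = {k: e - shift for k, e in entries.items()}
    return Potential(entries=entries)


def pseudo_energy(
    cm: ContactMap, s: Structure, p: Potential
) -> tuple[np.ndarray, float]:
    """Per-atom pseudo-energies and their total.

    Each contact contributes ``area * e(type_i, type_j)``, split half/half
    between its two atoms; each atom's solvent area contributes
    ``area * e(type, solvent)`` to that atom alone.
    """
    types = [atom_type(a) for a in s.atoms]
    per_atom = np.zeros(s.n_atoms)
    for i, j, area in cm.iter_contacts():
        e = area * p.get(types[i], types[j])
        per_atom[i] += 0.5 * e
        per_atom[j] += 0.5 * e
    for i, a in enumerate(cm.solvent_areas):
        per_atom[i] += float(a) * p.get(types[i], SOLVENT)
    return per_atom, float(per_atom.sum())


def interface_energy(cm: ContactMap, s: Structure, p: Potential) -> float:
    """Pseudo-energy summed over cross-chain atom contacts only."""
    if s.n_chains < 2:
        logger.warning("interface energy of a monomer is 0 by definition")
        return 0.0
    types = [atom_type(a) for a in s.atoms]
    chains = [a.chain_id for a in s.atoms]
    total = 0.0
    for i, j, area in cm.iter_contacts():
        if chains[i] != chains[j]:
            total += area * p.get(types[i], types[j])
    return total


def light_global(per_atom: np.ndarray, cm: ContactMap, k: float = 1.0) -> float:
    """Bounded global quality score: sigmoid of the mean per-atom energy density.

    ``score = 1 / (1 + exp(k * ebar))`` with ``ebar`` the area-weighted mean
    energy density (total energy / total per-atom area); decreasing in ebar,
    0.5 when all energies vanish.
    """
    areas = cm.per_atom_area()
    total_area = float(areas.sum())
    if total_area <= 0:
        raise UndefinedScoreError("structure has zero total contact+solvent area")
    ebar = float(per_atom.sum()) / total_area
    return 1.0 / (1.0 + math.exp(k * ebar))


# ---------------------------------------------------------------------------
# Dark layer: learned per-residue quality
# ---------------------------------------------------------------------------

FEATURE_VERSION = 1

FEATURE_NAMES = (
    "total_contact_area",
    "solvent_area",
    "same_chain_area",
    "cross_chain_area",
    *(f"area_{t}" for t in ATOM_TYPES),
    "residue_energy",
    "energy_density",
    "neighbor_energy",
    "burial_fraction",
    "sidechain_solvation",
)


def dark_features(
    s: Structure,
    rcm: ResidueContactMap,
    cm: ContactMap,
    p: Potential,
) -> dict[ResidueKey, np.ndarray]:
    """Fixed-length per-residue feature vectors (see ``FEATURE_NAMES``).

    Features mix geometry (contact/solvent areas, burial, chain split,
    per-atom-class areas) with energetics (residue pseudo-energy and the
    contact-area weighted mean energy density of neighbouring residues).
    """
    keys = [(a.chain_id, a.residue_index) for a in s.atoms]
    types = [atom_type(a) for a in s.atoms]
    per_atom_energy, _ = pseudo_energy(cm, s, p)
    per_atom_area = cm.per_atom_area()

    res_list = s.residue_keys()
    res_index = {r: i for i, r in enumerate(res_list)}
    n = len(res_list)
    energy = np.zeros(n)
    area = np.zeros(n)
    sc_solvation = np.zeros(n)
    type_area = np.zeros((n, len(ATOM_TYPES)))
    t_idx = {t: i for i, t in enumerate(ATOM_TYPES)}
    sidechain_types = {"CB", "sc-C", "sc-N", "sc-O", "S"}
    atom_contact_area = np.zeros(s.n_atoms)
    for i, j, a in cm.iter_contacts():
        atom_contact_area[i] += 0.5 * a
        atom_contact_area[j] += 0.5 * a
    for i in range(s.n_atoms):
        r = res_index[keys[i]]
        energy[r] += per_atom_energy[i]
        area[r] += per_atom_area[i]
        type_area[r, t_idx[types[i]]] += atom_contact_area[i]
        if types[i] in sidechain_types:
            sc_solvation[r] += float(cm.solvent_areas[i])

    same = np.zeros(n)
    cross = np.zeros(n)
    neighbor_num = np.zeros(n)
    neighbor_den = np.zeros(n)
    for (ka, kb), a in rcm.contacts.items():
        ra, rb = res_index[ka], res_index[kb]
        if ka[0] == kb[0]:
            same[ra] += a
            same[rb] += a
        else:
            cross[ra] += a
            cross[rb] += a
        for r, other in ((ra, rb), (rb, ra)):
            if area[other] > 0:
                neighbor_num[r] += a * (energy[other] / area[other])
                neighbor_den[r] += a

    out: dict[ResidueKey, np.ndarray] = {}
    for r, key in enumerate(res_list):
        solvent = rcm.solvent.get(key, 0.0)
        contact_total = same[r] + cross[r]
        denom = contact_total + solvent
        burial = 1.0 - solvent / denom if denom > 0 else 0.0
        neighbor = neighbor_num[r] / neighbor_den[r] if neighbor_den[r] > 0 else 0.0
        vec = np.array(
            [
                contact_total,
                solvent,
                same[r],
                cross[r],
                *type_area[r],
                energy[r],
                energy[r] / denom if denom > 0 else 0.0,
                neighbor,
                burial,
                sc_solvation[r],
            ]
        )
        out[key] = vec
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclasses.dataclass
class DarkModel:
    """Feed-forward per-residue quality predictor (one tanh hidden layer).

    Output is squashed to (0, 1); inputs are standardized with the stored
    training statistics.  Fully determined by the training seed.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    mean: np.ndarray
    std: np.ndarray
    feature_version: int = FEATURE_VERSION
    seed: int = 0
    final_loss: float = float("nan")

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = (np.atleast_2d(features) - self.mean) / self.std
        h = np.tanh(x @ self.w1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)

    def save(self, path) -> None:
        payload = {
            "feature_version": self.feature_version,
            "feature_names": list(FEATURE_NAMES),
            "seed": self.seed,
            "final_loss": self.final_loss,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "DarkModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            w1=np.array(d["w1"]),
            b1=np.array(d["b1"]),
            w2=np.array(d["w2"]),
            b2=float(d["b2"]),
            mean=np.array(d["mean"]),
            std=np.array(d["std"]),
            feature_version=int(d["feature_version"]),
            seed=int(d["seed"]),
            final_loss=float(d["final_loss"]),
        )


def dark_train(
    examples: Sequence[tuple[np.ndarray, float]],
    hidden: int = 20,
    iterations: int = 2000,
    learning_rate: float = 0.02,
    seed: int = 0,
) -> DarkModel:
    """Train the per-residue predictor by full-batch Adam on squared error.

    ``examples`` are (feature vector, local CAD-score target in [0,1]) pairs.
    Training is bit-deterministic for a given seed and iteration budget.
    """
    if len(examples) == 0:
        raise InsufficientDataError("no training examples")
    X = np.array([f for f, _ in examples], dtype=float)
    y = np.array([t for _, t in examples], dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-9] = 1.0
    Xn = (X - mean) / std

    rng = np.random.default_rng(seed)
    n_feat = X.shape[1]
    w1 = rng.normal(0.0, 1.0 / math.sqrt(n_feat), size=(n_feat, hidden))
    b1 = np.zeros(hidden)
    w2 = rng.normal(0.0, 1.0 / math.sqrt(hidden), size=hidden)
    b2 = 0.0

    params = [w1, b1, w2, np.array(b2)]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    loss = float("nan")
    for t in range(1, iterations + 1):
        h_pre = Xn @ params[0] + params[1]
        h = np.tanh(h_pre)
        o_pre = h @ params[2] + params[3]
        pred = _sigmoid(o_pre)
        err = pred - y
        loss = float(np.mean(err**2))
        d_o = 2.0 * err * pred * (1.0 - pred) / len(y)
        g_w2 = h.T @ d_o
        g_b2 = np.array(d_o.sum())
        d_h = np.outer(d_o, params[2]) * (1.0 - h**2)
        g_w1 = Xn.T @ d_h
        g_b1 = d_h.sum(axis=0)
        grads = [g_w1, g_b1, g_w2, g_b2]
        for k in range(4):
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
            mhat = m[k] / (1 - beta1**t)
            vhat = v[k] / (1 - beta2**t)
            params[k] = params[k] - learning_rate * mhat / (np.sqrt(vhat) + eps)
    return DarkModel(
        w1=params[0],
        b1=params[1],
        w2=params[2],
        b2=float(params[3]),
        mean=mean,
        std=std,
        seed=seed,
        final_loss=loss,
    )


def dark_score(
    model: DarkModel,
    s: Structure,
    rcm: ResidueContactMap,
    cm: ContactMap,
    p: Potential,
) -> tuple[dict[ResidueKey, float], float]:
    """Per-residue dark scores and their arithmetic mean (the global score)."""
    if model.w1 is None:  # pragma: no cover - defensive
        raise StateError("dark model is untrained")
    if model.feature_version != FEATURE_VERSION:
        raise StateError(
            f"dark model feature version {model.feature_version} != {FEATURE_VERSION}"
        )
    feats = dark_features(s, rcm, cm, p)
    keys = list(feats)
    X = np.array([feats[k] for k in keys])
    pred = model.predict(X)
    local = {k: float(v) for k, v in zip(keys, pred)}
    global_dark = float(np.mean(list(local.values())))
    return local, global_dark


# ---------------------------------------------------------------------------
# Bundled scoring
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ModelScores:
    """Per-model score bundle used by the ranking layer."""

    model_id: str
    global_light: float
    global_dark: float
    local_dark: dict[ResidueKey, float]
    interface_energy: float


def score_structure(
    s: Structure,
    p: Potential,
    dark: DarkModel | None = None,
    model_id: str = "model",
    probe: float = 1.4,
    n_samples: int = 256,
    seed: int = 0,
) -> ModelScores:
    """Compute the full score bundle for one structure.

    Without a dark model the light score doubles as the global score so the
    ranking layer still has a well-defined comparison key.
    """
    cm = compute_contact_map(s, probe=probe, n_samples=n_samples, seed=seed)
    rcm = aggregate_residues(cm, s)
    per_atom, _ = pseudo_energy(cm, s, p)
    light = light_global(per_atom, cm)
    iface = interface_energy(cm, s, p)
    if dark is not None:
        local, global_dark = dark_score(dark, s, rcm, cm, p)
    else:
        local, global_dark = {}, light
    return ModelScores(
        model_id=model_id,
        global_light=light,
        global_dark=global_dark,
        local_dark=local,
        interface_energy=iface,
    )
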