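"""End-to-end recovery experiments on synthetic fixtures.

These routines wire the fixture generators, the contact estimator, the
potential, the learned per-residue predictor, the ranking protocol and the
ring-docking enumerator into the self-contained experiments the package is
validated with: estimator oracles, decoy-ladder score recovery, selection
enrichment and two-ring re-docking.  Every routine is fully determined by an
integer seed.
"""

from __future__ import annotations

import math

import numpy as np

from .cad import cad_interface, cad_local, relabel_chains
from .contacts import aggregate_residues, compute_contact_map
from .errors import UndefinedScoreError
from .ranking import RankingConfig, tournament_rank
from .ringdock import enumerate_poses, pose_structure, score_poses
from .structures import (
    Atom,
    Structure,
    make_decoys,
    make_dimer,
    make_two_ring_complex,
)
from .voromqa import (
    DarkModel,
    ModelScores,
    Potential,
    dark_features,
    dark_score,
    dark_train,
    derive_potential,
    interface_energy,
    light_global,
    pseudo_energy,
)

__all__ = [
    "two_ball_bridge_area",
    "default_potential",
    "train_default_dark",
    "decoy_ladder_correlation",
    "selection_enrichment",
    "ringdock_recovery",
]

N_SAMPLES = 128  # estimator lattice size for fixture-scale experiments


def two_ball_bridge_area(n_samples: int = 4096, seed: int = 1) -> tuple[float, float]:
    """Estimated and analytic bridge area for two r=2 A balls at d=2 A.

    The analytic value is the radical-plane disc area pi*(r^2 - d^2/4).
    """
    s = Structure(
        [
            Atom("A", 1, "ALA", "CA", "C", np.array([0.0, 0.0, 0.0]), 2.0),
            Atom("A", 2, "ALA", "CA", "C", np.array([2.0, 0.0, 0.0]), 2.0),
        ]
    )
    cm = compute_contact_map(s, probe=0.0, n_samples=n_samples, seed=seed)
    return cm.get(0, 1), 3.0 * math.pi


def default_potential(seed: int = 0, n_samples: int = N_SAMPLES) -> Potential:
    """Contact potential derived from six amphipathic reference dimers."""
    refs = [make_dimer(16, seed=seed + i) for i in range(6)]
    return derive_potential(refs, n_samples=n_samples, seed=seed)


def _score_decoy(
    decoy: Structure,
    potential: Potential,
    dark: DarkModel | None,
    model_id: str,
    n_samples: int,
    contact_seed: int = 0,
    maps=None,
) -> ModelScores:
    if maps is not None:
        cm, rcm = maps
    else:
        cm = compute_contact_map(decoy, n_samples=n_samples, seed=contact_seed)
        rcm = aggregate_residues(cm, decoy)
    per_atom, _ = pseudo_energy(cm, decoy, potential)
    light = light_global(per_atom, cm)
    iface = interface_energy(cm, decoy, potential)
    if dark is not None:
        local, global_dark = dark_score(dark, decoy, rcm, cm, potential)
    else:
        local, global_dark = {}, light
    return ModelScores(
        model_id=model_id,
        global_light=light,
        global_dark=global_dark,
        local_dark=local,
        interface_energy=iface,
    )


def train_default_dark(
    potential: Potential,
    seed: int = 3,
    n_samples: int = N_SAMPLES,
    n_decoys: int = 12,
    iterations: int = 1000,
) -> DarkModel:
    """Train the per-residue predictor on decoy sets of four dimer targets.

    Training targets (lengths 14-22) are disjoint from the evaluation
    fixtures used elsewhere; decoys are rigid-body perturbations only.
    """
    examples = []
    for length, t_seed, d_seed in [(14, 5, 10), (16, 9, 12), (18, 7, 11), (22, 13, 14)]:
        target = make_dimer(length, seed=t_seed)
        ladder = make_decoys(
            target, n_decoys, max_shift=6.0, max_rot=60.0, noise_sigma=0.0,
            seed=d_seed, n_samples=n_samples,
        )
        t_cm = compute_contact_map(target, n_samples=n_samples, seed=0)
        t_rcm = aggregate_residues(t_cm, target)
        for decoy, (cm, rcm) in zip(ladder.decoys, ladder.decoy_maps):
            feats = dark_features(decoy, rcm, cm, potential)
            labels = cad_local(t_rcm, rcm)
            for key, vec in feats.items():
                if key in labels:
                    examples.append((vec, labels[key]))
    return dark_train(examples, hidden=20, iterations=iterations, seed=seed)


def decoy_ladder_correlation(
    potential: Potential,
    dark: DarkModel,
    seed: int = 42,
    n_decoys: int = 16,
    n_samples: int = N_SAMPLES,
) -> float:
    """Spearman rank correlation of global dark score vs. true interface CAD.

    Evaluated on a graded decoy ladder of a target disjoint from the
    training fixtures; perturbation bounds ramp from 0 (near-native) to
    fully interface-breaking.
    """
    from scipy.stats import spearmanr

    from .structures import make_decoy_ladder

    target = make_dimer(20, seed=seed)
    ladder = make_decoy_ladder(
        target, n_decoys, max_shift=6.0, max_rot=60.0, noise_sigma=0.0,
        seed=seed + 1, n_samples=n_samples,
    )
    globals_ = []
    for i, decoy in enumerate(ladder.decoys):
        ms = _score_decoy(
            decoy, potential, dark, f"d{i}", n_samples,
            maps=ladder.decoy_maps[i] if ladder.decoy_maps else None,
        )
        globals_.append(ms.global_dark)
    rho = spearmanr(globals_, ladder.true_similarity).statistic
    return float(rho)


def selection_enrichment(
    potential: Potential,
    dark: DarkModel | None,
    n_trials: int = 50,
    n_decoys: int = 8,
    seed: int = 1000,
    n_samples: int = N_SAMPLES,
    cfg: RankingConfig | None = None,
) -> float:
    """Fraction of seeded decoy sets where the top-ranked decoy is at or
    above the set's median true interface similarity.

    Each trial builds a graded decoy ladder of a fresh dimer target, scores
    every decoy, tournament-ranks the set and checks the winner's
    ground-truth interface CAD against the set median.
    """
    from .structures import make_decoy_ladder

    if cfg is None:
        cfg = RankingConfig()
    hits = 0
    for trial in range(n_trials):
        trial_seed = seed + trial
        target = make_dimer(14, seed=trial_seed)
        ladder = make_decoy_ladder(
            target, n_decoys, max_shift=6.0, max_rot=60.0, noise_sigma=0.0,
            seed=trial_seed + 7, n_samples=n_samples,
        )
        scored = [
            _score_decoy(
                d, potential, dark, f"d{i}", n_samples,
                maps=ladder.decoy_maps[i] if ladder.decoy_maps else None,
            )
            for i, d in enumerate(ladder.decoys)
        ]
        ranked = tournament_rank(scored, cfg)
        top_idx = int(ranked.order[0][1:])
        if ladder.true_similarity[top_idx] >= float(
            np.median(ladder.true_similarity)
        ):
            hits += 1
    return hits / n_trials


def _cyclic_interface_cad(target_rcm, model_rcm, lower_chains: list[str]) -> float:
    """Interface CAD maximized over cyclic relabelings of the ring-B chains.

    Chains of a Cn ring are interchangeable; a pose rotated by a multiple of
    the symmetry angle is the same arrangement with shifted chain labels.
    """
    best = 0.0
    n = len(lower_chains)
    for shift in range(n):
        mapping = {
            lower_chains[i]: lower_chains[(i + shift) % n] for i in range(n)
        }
        try:
            score = cad_interface(target_rcm, relabel_chains(model_rcm, mapping))
        except UndefinedScoreError:
            score = 0.0
        best = max(best, score)
    return best


def ringdock_recovery(
    potential: Potential,
    seed: int = 100,
    trans_step: float = 1.0,
    rot_step: float = 2.0,
    n_samples: int = 96,
) -> tuple[float, int]:
    """Split a two-ring fixture complex, re-dock, and report the interface
    CAD of the best-scoring pose against the original assembly, plus the
    size of the enumerated pose grid."""
    cplx, ring_a, ring_b = make_two_ring_complex(seed=seed)
    poses, aligned_a, aligned_b = enumerate_poses(
        ring_a, ring_b, trans_step=trans_step, rot_step=rot_step
    )
    ranked = score_poses(poses, potential, aligned_a, aligned_b, n_samples=n_samples)
    if not ranked:
        return 0.0, len(poses)
    best = pose_structure(ranked[0], aligned_a, aligned_b)
    t_rcm = aggregate_residues(
        compute_contact_map(cplx, n_samples=n_samples, seed=0), cplx
    )
    m_rcm = aggregate_residues(
        compute_contact_map(best, n_samples=n_samples, seed=0), best
    )
    lower = [c for c in best.chain_ids if c.islower()]
    return _cyclic_interface_cad(t_rcm, m_rcm, lower), len(poses)
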