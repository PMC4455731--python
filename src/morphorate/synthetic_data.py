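"""Study-shaped synthetic data: trees, characters with known histories, and
specimen-level landmark data evolved under group-specific Brownian motion.

The generator emulates the design of a comparative study of head-shape
evolution in Lake Tanganyika cichlids: 37 species, head shape captured by 9
fixed landmarks plus 7 semilandmarks along the forehead outline (16 points,
32 coordinates), a binary brood-care character (substrate guarding vs
mouthbrooding, a single origin of mouthbrooding) and, nested within
mouthbrooders, a care-provider character (maternal vs bi-parental, several
transitions). Shape rate heterogeneity is painted onto branches through the
true care-form history: segments in the ancestral substrate-guarding state
evolve ``rate_ratio_true`` times faster than mouthbrooding segments, which
is the state-dependent model the downstream tip-group rate test presumes.

Specimen configurations are the species mean plus isotropic digitizing
noise, then randomly rotated, scaled and translated before being written to
TPS, so superimposition has real work to do. Everything is deterministic
given the config seed.
"""
from __future__ import annotations

import dataclasses
import json
import os
import random
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .morphometrics import LandmarkSet, SliderSpec, write_tps
from .phylorates import _bm_batch
from .simmap import CharacterHistory, DiscreteCharacter, QMatrix
from .trees import PhyloTree, write_newick

__all__ = [
    "SyntheticStudyConfig", "SyntheticTruth", "simulate_tree",
    "simulate_character", "simulate_shapes", "generate_study",
    "BASE_HEAD_TEMPLATE", "DEFAULT_SLIDERS",
]

# Hand-laid 16-point lateral fish-head template (image units). Points 1-9 are
# the fixed landmarks (snout tip, maxilla, jaw corner, ventral head margin,
# lower opercular edge, posterior opercular edge, pectoral-fin insertion,
# dorsal-fin origin, nape); points 10-16 are semilandmarks along the forehead
# outline from the snout to the dorsal-fin origin. Arbitrary but fixed.
BASE_HEAD_TEMPLATE = np.array([
    [0.00, 0.55],   # 1 snout tip
    [0.06, 0.42],   # 2 posterior maxilla
    [0.16, 0.30],   # 3 corner of jaw
    [0.38, 0.12],   # 4 ventral head margin
    [0.62, 0.05],   # 5 lower opercular edge
    [0.88, 0.18],   # 6 posterior opercular edge
    [0.92, 0.38],   # 7 pectoral-fin insertion
    [1.00, 0.72],   # 8 dorsal-fin origin
    [0.78, 0.80],   # 9 nape
    [0.07, 0.68],   # 10 forehead semilandmarks ...
    [0.16, 0.77],
    [0.27, 0.83],
    [0.39, 0.86],
    [0.51, 0.87],
    [0.63, 0.86],
    [0.71, 0.84],   # 16
])

# each semilandmark slides along the chord of its curve neighbours
# (snout -> forehead points -> nape), 0-based
DEFAULT_SLIDERS = SliderSpec(
    indices=tuple(range(9, 16)),
    neighbors=((0, 10),) + tuple((i - 1, i + 1) for i in range(10, 15))
    + ((14, 8),),
)

CARE_STATES = ("substrate_guarding", "mouthbrooding")
PROVIDER_STATES = ("biparental", "maternal")


@dataclasses.dataclass
class SyntheticStudyConfig:
    """Defaults emulate the study design (37 species, 16 x 2 landmarks).

    ``rate_slow`` is the per-coordinate BM variance per unit tree depth in
    the mouthbrooding (slow) state; substrate-guarding segments run at
    ``rate_slow * rate_ratio_true``.
    """
    n_species: int = 37
    n_fixed_landmarks: int = 9
    n_semilandmarks: int = 7
    specimens_per_species_per_sex: int = 5
    birth_rate: float = 1.0
    care_q: tuple[float, float] = (0.15, 0.05)       # sg->mb, mb->sg
    provider_q: tuple[float, float] = (0.9, 0.6)     # bp->mat, mat->bp
    care_transitions: int | None = 1
    provider_transitions: int | None = 5
    min_care_minority: int = 6
    care_derived_fraction: tuple[float, float] = (0.45, 0.9)
    min_provider_minority: int = 5
    rate_slow: float = 2.5e-4
    rate_ratio_true: float = 2.0
    digitizing_noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        if self.rate_slow <= 0 or self.rate_ratio_true < 1:
            raise ValueError("rates must be > 0 and rate_ratio_true >= 1")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth paired with the emitted files."""
    tree: PhyloTree
    care: DiscreteCharacter
    care_history: CharacterHistory
    provider: DiscreteCharacter                  # on the mouthbrooder subtree
    provider_history: CharacterHistory
    provider_subtree: PhyloTree
    membership_care: dict[str, str]
    membership_provider: dict[str, str]          # mouthbrooders only
    rate_by_state: dict[str, float]
    species_mean_shapes: dict[str, np.ndarray]
    config: SyntheticStudyConfig

    def to_dict(self) -> dict:
        return {
            "tree_newick": self.tree.to_newick(),
            "care_states": dict(self.care.data),
            "care_n_transitions": self.care_history.n_transitions,
            "provider_states": dict(self.provider.data),
            "provider_n_transitions": self.provider_history.n_transitions,
            "provider_subtree_newick": self.provider_subtree.to_newick(),
            "rate_by_state": self.rate_by_state,
            "species_mean_shapes": {
                t: s.tolist() for t, s in self.species_mean_shapes.items()},
            "config": dataclasses.asdict(self.config),
        }


# --------------------------------------------------------------------- #

def simulate_tree(n: int, birth_rate: float = 1.0,
                  rng: np.random.Generator | int | None = None) -> PhyloTree:
    """Pure-birth (Yule) tree with n extant tips, rescaled to unit depth.

    The birth-death simulator stops exactly at the n-th speciation, leaving
    the newest tips with zero-length branches; all terminal branches are
    therefore extended by a draw of the waiting time to the (unrealized)
    next speciation, Exp(n * birth_rate), before rescaling.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(rng)
    pyrng = random.Random(int(rng.integers(2 ** 31)))
    dt = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n, rng=pyrng)
    extra = rng.exponential(1.0 / (n * birth_rate))
    for i, leaf in enumerate(dt.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:02d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree = PhyloTree.from_dendropy(dt)
    depth = tree.depths()[: tree.n_tips].max()
    tree = PhyloTree(tree.parent, tree.blen / depth, tree.children,
                     tree.tip_labels)
    return tree


def _forward_ctmc(tree: PhyloTree, Q: QMatrix, root_state: int,
                  rng: np.random.Generator) -> CharacterHistory:
    node_states = np.full(tree.n_nodes, -1, dtype=int)
    node_states[tree.root] = root_state
    segments: list[list[tuple[int, float]]] = [None] * tree.n_nodes
    segments[tree.root] = [(root_state, 0.0)]
    k = Q.k
    for i in tree.preorder:
        for c in tree.children[i]:
            s = int(node_states[i])
            remaining = float(tree.blen[c])
            segs: list[tuple[int, float]] = []
            while True:
                out = -Q.rates[s, s]
                wait = rng.exponential(1.0 / out) if out > 0 else np.inf
                if wait >= remaining:
                    segs.append((s, remaining))
                    break
                segs.append((s, wait))
                remaining -= wait
                probs = Q.rates[s].copy()
                probs[s] = 0.0
                s = int(rng.choice(k, p=probs / probs.sum()))
            # merge zero-rate artefacts
            merged: list[tuple[int, float]] = []
            for st, d in segs:
                if merged and merged[-1][0] == st:
                    merged[-1] = (st, merged[-1][1] + d)
                else:
                    merged.append((st, d))
            segments[c] = merged
            node_states[c] = merged[-1][0]
    return CharacterHistory(node_states=node_states, segments=segments,
                            states=Q.states)


def simulate_character(tree: PhyloTree, Q: QMatrix,
                       rng: np.random.Generator | int | None = None,
                       root_state: int = 0,
                       condition_on: int | None = None,
                       min_minority: int = 0,
                       state_ranges: dict[int, tuple[int, int]] | None = None,
                       max_attempts: int = 5000
                       ) -> tuple[DiscreteCharacter, CharacterHistory]:
    """Forward CTMC simulation of a character, with optional conditioning.

    ``condition_on`` resimulates until the realized total transition count
    equals the target; ``min_minority`` additionally requires both states at
    that many tips (0 disables) and ``state_ranges`` bounds the tip count of
    individual states (index -> (lo, hi)). Raises if the target is not
    reached within ``max_attempts``.
    """
    rng = np.random.default_rng(rng)
    for _ in range(max_attempts):
        hist = _forward_ctmc(tree, Q, root_state, rng)
        if condition_on is not None and hist.n_transitions != condition_on:
            continue
        tip_states = hist.node_states[: tree.n_tips]
        counts = np.bincount(tip_states, minlength=Q.k)
        if min_minority and counts.min() < min_minority:
            continue
        if state_ranges and any(not lo <= counts[s] <= hi
                                for s, (lo, hi) in state_ranges.items()):
            continue
        char = DiscreteCharacter(
            {t: Q.states[s] for t, s in zip(tree.tip_labels, tip_states)},
            Q.states)
        return char, hist
    raise RuntimeError(
        f"could not realize target transition count {condition_on} "
        f"(minority >= {min_minority}) in {max_attempts} attempts; "
        "adjust rates or constraints")


def _branch_variance_scale(tree: PhyloTree, hist: CharacterHistory,
                           rate_multiplier: dict[int, float]) -> np.ndarray:
    """Effective per-node rate so that rate * blen = painted variance."""
    scale = np.zeros(tree.n_nodes)
    for i in range(tree.n_nodes):
        if tree.parent[i] < 0:
            continue
        var = sum(d * rate_multiplier[s] for s, d in hist.segments[i])
        scale[i] = var / tree.blen[i] if tree.blen[i] > 0 else 0.0
    return scale


def _random_similarity(rng: np.random.Generator):
    """Nuisance digitizing transform: rotation U(-pi,pi), log-scale N(0,0.1^2),
    translation U(-10,10) per axis."""
    th = rng.uniform(-np.pi, np.pi)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    s = float(np.exp(rng.normal(0.0, 0.1)))
    t = rng.uniform(-10.0, 10.0, size=2)
    return R, s, t


def simulate_shapes(tree: PhyloTree, care_hist: CharacterHistory,
                    config: SyntheticStudyConfig,
                    rng: np.random.Generator | int | None = None
                    ) -> tuple[list[LandmarkSet], dict[str, np.ndarray]]:
    """Species mean shapes under state-dependent BM, plus noisy specimens.

    Mean shapes evolve as 32 independent coordinates with per-branch variance
    integrated over the care-form history's segments; specimens add isotropic
    digitizing noise and a random similarity transform before being written,
    emulating arbitrary digitizing frames.
    """
    rng = np.random.default_rng(rng)
    base = BASE_HEAD_TEMPLATE.copy()
    base -= base.mean(axis=0)
    fast = care_hist.states.index("substrate_guarding") \
        if "substrate_guarding" in care_hist.states else 0
    mult = {s: (config.rate_ratio_true if s == fast else 1.0)
            for s in range(len(care_hist.states))}
    rate_nodes = _branch_variance_scale(tree, care_hist, mult) * \
        config.rate_slow
    p = 2 * base.shape[0]
    dev = _bm_batch(tree, rate_nodes, p, 1, rng)[0]      # tips x 32
    means = {t: base + dev[i].reshape(-1, 2)
             for i, t in enumerate(tree.tip_labels)}

    specimens: list[LandmarkSet] = []
    for t in tree.tip_labels:
        for sex in ("male", "female"):
            for j in range(config.specimens_per_species_per_sex):
                cfg = means[t] + rng.normal(
                    0.0, config.digitizing_noise_sd, size=means[t].shape)
                R, s, tr = _random_similarity(rng)
                img = (cfg @ R.T) * s + tr
                sid = f"{t}_{'M' if sex == 'male' else 'F'}{j + 1}"
                specimens.append(LandmarkSet(
                    sid, img, species=t, sex=sex, sliders=DEFAULT_SLIDERS))
    return specimens, means


def generate_study(config: SyntheticStudyConfig,
                   outdir: str | None = None
                   ) -> tuple[SyntheticTruth, list[LandmarkSet], dict]:
    """Generate a full synthetic study; optionally write all files.

    Returns the truth object, the specimen list and (when ``outdir`` is
    given) a dict of written paths: tps, metadata, groups, tree, care/provider
    character CSVs, slider spec, truth JSON.
    """
    ss = np.random.SeedSequence(config.seed)
    r_tree, r_care, r_prov, r_shape = \
        [np.random.default_rng(s) for s in ss.spawn(4)]

    # redraw tree + care until both characters can realize their constraints
    care_Q = QMatrix.binary(*config.care_q, states=CARE_STATES)
    prov_Q = QMatrix.binary(*config.provider_q, states=PROVIDER_STATES)
    lo = int(np.ceil(config.care_derived_fraction[0] * config.n_species))
    hi = int(np.floor(config.care_derived_fraction[1] * config.n_species))
    for _ in range(200):
        tree = simulate_tree(config.n_species, config.birth_rate, r_tree)
        try:
            care, care_hist = simulate_character(
                tree, care_Q, r_care, root_state=0,
                condition_on=config.care_transitions,
                min_minority=config.min_care_minority,
                state_ranges={1: (lo, hi)}, max_attempts=1000)
            mouthbrooders = [t for t in tree.tip_labels
                             if care.data[t] == "mouthbrooding"]
            if len(mouthbrooders) < 2 * config.min_provider_minority:
                continue
            sub = tree.subtree(mouthbrooders)
            provider, prov_hist = simulate_character(
                sub, prov_Q, r_prov, root_state=0,
                condition_on=config.provider_transitions,
                min_minority=config.min_provider_minority,
                max_attempts=2000)
            break
        except RuntimeError:
            continue
    else:
        raise RuntimeError("no admissible tree/character draw in 200 tries")

    specimens, means = simulate_shapes(tree, care_hist, config, r_shape)

    membership_care = dict(care.data)
    membership_provider = dict(provider.data)
    truth = SyntheticTruth(
        tree=tree, care=care, care_history=care_hist, provider=provider,
        provider_history=prov_hist, provider_subtree=sub,
        membership_care=membership_care,
        membership_provider=membership_provider,
        rate_by_state={
            "substrate_guarding": config.rate_slow * config.rate_ratio_true,
            "mouthbrooding": config.rate_slow},
        species_mean_shapes=means, config=config)

    paths: dict[str, str] = {}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        paths["tps"] = os.path.join(outdir, "landmarks.tps")
        write_tps(specimens, paths["tps"])
        paths["metadata"] = os.path.join(outdir, "specimens.csv")
        pd.DataFrame(
            {"specimen_id": [s.specimen_id for s in specimens],
             "species": [s.species for s in specimens],
             "sex": [s.sex for s in specimens]},
        ).to_csv(paths["metadata"], index=False)
        paths["groups"] = os.path.join(outdir, "groups.csv")
        pd.DataFrame(
            {"taxon": tree.tip_labels,
             "care_form": [care.data[t] for t in tree.tip_labels],
             "provider": [membership_provider.get(t, "not_applicable")
                          for t in tree.tip_labels]},
        ).to_csv(paths["groups"], index=False)
        paths["tree"] = os.path.join(outdir, "tree.nwk")
        write_newick(tree, paths["tree"])
        paths["care_character"] = os.path.join(outdir, "character_care.csv")
        pd.DataFrame({"taxon": tree.tip_labels,
                      "state": [care.data[t] for t in tree.tip_labels]},
                     ).to_csv(paths["care_character"], index=False)
        paths["provider_character"] = os.path.join(
            outdir, "character_provider.csv")
        pd.DataFrame({"taxon": sub.tip_labels,
                      "state": [provider.data[t] for t in sub.tip_labels]},
                     ).to_csv(paths["provider_character"], index=False)
        paths["sliders"] = os.path.join(outdir, "sliders.yaml")
        with open(paths["sliders"], "w") as fh:
            fh.write("sliders:\n")
            for i, (a, b) in zip(DEFAULT_SLIDERS.indices,
                                 DEFAULT_SLIDERS.neighbors):
                fh.write(f"  - [{a + 1}, {i + 1}, {b + 1}]\n")
        paths["truth"] = os.path.join(outdir, "truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
    return truth, specimens, paths
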