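"""Seeded generators for synthetic ontologies and diagnosis-labelled cohorts.

The generator emulates the statistical structure of a findings-coded
neurology cohort: a test group of 8 competing diagnoses, roughly a dozen
patients per diagnosis, and about 6-7 findings per patient drawn from a
diagnosis-specific archetype set plus uniform noise. It stands in for
manually abstracted case data so every downstream stage (distance matrices,
classification, clustering, statistics) runs with no external download.

Defaults: a complete 4-ary tree of depth 4 (340 non-root concepts, 256
leaves) as the ontology stand-in; archetypes of 8 leaf findings each,
included with probability 0.7, plus Poisson(1.0) uniform-leaf noise, giving
an expected 8*0.7 + 1 = 6.6 findings per patient.

All randomness flows from the explicit seed; a single RNG stream per
generator call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import yaml

from .ontology import Ontology
from .patients import Cohort, Patient

__all__ = ["SyntheticConfig", "generate_ontology", "generate_archetypes",
           "generate_cohort", "simulate"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study conditions.

    ``p_core`` is the per-finding inclusion probability of a diagnosis's
    archetype findings; ``noise_rate`` the Poisson mean count of extra
    uniform-leaf noise findings per patient.
    """

    tree_depth: int = 4
    branching: int = 4
    n_diagnoses: int = 8
    archetype_size: int = 8
    p_core: float = 0.7
    noise_rate: float = 1.0
    patients_per_diagnosis: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.tree_depth < 2:
            raise ValueError("tree_depth must be >= 2")
        if self.branching < 2:
            raise ValueError("branching must be >= 2")
        if self.n_diagnoses < 2:
            raise ValueError("n_diagnoses must be >= 2")
        if not 0 < self.p_core <= 1:
            raise ValueError("p_core must be in (0, 1]")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        if self.archetype_size < 1 or self.patients_per_diagnosis < 1:
            raise ValueError("sizes must be positive")
        if self.archetype_size > self.branching ** self.tree_depth:
            raise ValueError("archetype_size exceeds leaf count of the tree")

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Read a flat key-value (YAML) config file; keys match the fields."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)


def generate_ontology(depth: int, branching: int, seed: int = 0) -> Ontology:
    """Complete ``branching``-ary tree of the given depth under one root.

    Concept ids are synthetic ("S000001", ...), assigned breadth-first, so
    the structure is deterministic; the seed is accepted for interface
    symmetry with the other generators.
    """
    if depth < 1 or branching < 2:
        raise ValueError("require depth >= 1 and branching >= 2")
    parent_of: dict[str, str] = {}
    counter = 0
    root = "ROOT"
    frontier = [root]
    for _ in range(depth):
        nxt = []
        for node in frontier:
            for _ in range(branching):
                counter += 1
                cid = f"S{counter:06d}"
                parent_of[cid] = node
                nxt.append(cid)
        frontier = nxt
    labels = {root: "finding (root)"}
    labels.update({c: f"synthetic finding {c[1:]}" for c in parent_of})
    return Ontology(parent_of, labels)


def generate_archetypes(ontology: Ontology,
                        cfg: SyntheticConfig) -> dict[str, set[str]]:
    """Diagnosis-specific characteristic finding sets (leaves only).

    Each diagnosis samples ``archetype_size`` distinct leaves with a bias
    toward one randomly chosen depth-1 subtree, so its findings cohere;
    archetypes may overlap across diagnoses (shared findings are emergent).
    """
    rng = np.random.default_rng(cfg.seed)
    leaves = np.array(ontology.leaves())
    if cfg.archetype_size > len(leaves):
        raise ValueError("archetype_size exceeds available leaves")
    top = [c for c in ontology.non_root_concepts()
           if ontology.depth_of(c) == 1]
    leaf_top = np.array([ontology.ancestors(c)[-2] for c in leaves])
    archetypes: dict[str, set[str]] = {}
    for d in range(cfg.n_diagnoses):
        home = top[rng.integers(len(top))]
        in_home = leaf_top == home
        # 4:1 sampling bias toward the home subtree
        w = np.where(in_home, 4.0, 1.0)
        w /= w.sum()
        chosen = rng.choice(leaves, size=cfg.archetype_size, replace=False,
                            p=w)
        archetypes[f"DX{d + 1:02d}"] = set(chosen.tolist())
    return archetypes


def generate_cohort(ontology: Ontology, archetypes: dict[str, set[str]],
                    cfg: SyntheticConfig) -> Cohort:
    """Sample patients from the archetypes.

    Each patient keeps every archetype finding independently with
    probability ``p_core`` and gains Poisson(``noise_rate``) extra findings
    drawn uniformly from the leaves; empty draws are resampled.
    """
    if cfg.p_core == 0 and cfg.noise_rate == 0:
        raise ValueError("p_core = 0 with noise_rate = 0 yields no findings")
    rng = np.random.default_rng(cfg.seed + 1)
    leaves = ontology.leaves()
    patients = []
    for diagnosis, core in sorted(archetypes.items()):
        core = sorted(core)
        for i in range(cfg.patients_per_diagnosis):
            while True:
                keep = [c for c in core if rng.random() < cfg.p_core]
                n_noise = rng.poisson(cfg.noise_rate)
                noise = [leaves[k] for k in
                         rng.integers(len(leaves), size=n_noise)]
                findings = frozenset(keep) | frozenset(noise)
                if findings:
                    break
            patients.append(Patient(
                id=f"{diagnosis}_P{i + 1:03d}", diagnosis=diagnosis,
                findings=findings))
    return Cohort(patients, ontology)


def simulate(cfg: SyntheticConfig) -> tuple[Ontology, Cohort]:
    """End-to-end convenience: ontology + archetypes + cohort from one config."""
    ontology = generate_ontology(cfg.tree_depth, cfg.branching, cfg.seed)
    archetypes = generate_archetypes(ontology, cfg)
    cohort = generate_cohort(ontology, archetypes, cfg)
    return ontology, cohort
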