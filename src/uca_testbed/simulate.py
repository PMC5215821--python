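"""Synthetic protein-sequence evolution under common-ancestry or
independent-origins scenarios.

Sequences evolve along a tree by drawing the root from the model's
equilibrium frequencies and applying the transition kernel
``P(Q, t*r)`` down every branch, with a discrete-gamma rate category
assigned to each site once and held fixed across the whole tree
(rates-across-sites).  Indels are not simulated in any replication
preset; sequence length is conserved, which is what makes the
"unaligned" control mode of the test well defined.

An independent-origins (IO) scenario evolves each group of taxa on its
own tree, with independent root draws, so between-group similarity is
at the random-matching level expected from the equilibrium frequencies.

The two study presets:

* ``fig2`` — two quartets ("E" and "B") under rtREV+Γ+F, 6591 sites,
  200 replicates (a ``fig2-scaled`` variant runs 20 x 1000).
* ``fig3`` — the same design at 500 sites under LG+Γ, 100 replicates
  (a ``fig3-scaled`` variant runs 20 x 100).

The original study's true trees and branch lengths are not published in
print; the presets use stand-in quartets of the form
``((X1:0.4,X2:0.4):0.2,(X3:0.4,X4:0.4):0.2)`` — deep but alignable —
so reproduction of the study's figures is qualitative/proportional
rather than parameter-exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .models import ReversibleEigensystem, SubstitutionModel, get_model
from .phylo import PhyloTree, parse_newick
from .seqs import SequenceSet, decode

__all__ = [
    "ScenarioConfig",
    "ReplicateSet",
    "evolve",
    "generate_scenario",
    "preset",
    "PRESETS",
]

# Stand-in quartets: terminal branches 0.4, internal 0.2 expected
# substitutions/site — deep divergence, still alignable.
_E_TREE = "((E1:0.4,E2:0.4):0.2,(E3:0.4,E4:0.4):0.2);"
_B_TREE = "((B1:0.4,B2:0.4):0.2,(B3:0.4,B4:0.4):0.2);"
_DEFAULT_ALPHA = 0.8  # stand-in gamma shape for the simulation presets


@dataclass
class ScenarioConfig:
    """One simulation scenario: trees per origin group, model, size, seed."""

    trees: dict[str, PhyloTree]
    model: SubstitutionModel
    n_sites: int
    n_replicates: int
    seed: int = 0
    indels: bool = False
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.indels:
            raise NotImplementedError("indel simulation is not part of the replication presets")
        seen: set[str] = set()
        for label, tree in self.trees.items():
            leaves = set(tree.leaf_labels())
            if leaves & seen:
                raise ValueError(f"group {label!r} shares taxa with another group")
            seen |= leaves

    @property
    def groups(self) -> dict[str, list[str]]:
        return {label: tree.leaf_labels() for label, tree in self.trees.items()}

    def to_yaml(self, path=None) -> str:
        import yaml

        payload = {
            "name": self.name,
            "model": self.model.name,
            "gamma_shape": self.model.gamma_shape,
            "n_categories": self.model.n_categories,
            "plus_f": self.model.plus_f,
            "n_sites": self.n_sites,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "trees": {k: t.to_newick() for k, t in self.trees.items()},
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "ScenarioConfig":
        import os

        import yaml

        text = path_or_text
        if os.path.exists(str(path_or_text)):
            with open(path_or_text) as fh:
                text = fh.read()
        payload = yaml.safe_load(text)
        model = get_model(
            payload["model"],
            gamma_shape=payload.get("gamma_shape"),
            n_categories=payload.get("n_categories", 4),
            plus_f=payload.get("plus_f", False),
        )
        return cls(
            trees={k: parse_newick(v) for k, v in payload["trees"].items()},
            model=model,
            n_sites=int(payload["n_sites"]),
            n_replicates=int(payload["n_replicates"]),
            seed=int(payload.get("seed", 0)),
            name=payload.get("name", "custom"),
        )

    def provenance_hash(self) -> str:
        payload = json.dumps(
            {
                "trees": {k: t.to_newick() for k, t in sorted(self.trees.items())},
                "model": self.model.name,
                "alpha": self.model.gamma_shape,
                "n_sites": self.n_sites,
                "n_replicates": self.n_replicates,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReplicateSet:
    """One simulated replicate: per-group sequences plus the pooled set."""

    index: int
    groups: dict[str, SequenceSet]
    combined: SequenceSet
    seed: int
    config_hash: str
    true_trees: dict[str, str]


def evolve(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    rng: np.random.Generator,
) -> SequenceSet:
    """Evolve one sequence set along *tree* under *model*.

    Each site gets a gamma-category rate fixed across the tree; the root
    sequence is drawn from the equilibrium frequencies; each branch
    applies the transition matrix for its length times the site rate.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    eig = ReversibleEigensystem.from_model(model)
    rates = model.category_rates()
    n_cat = len(rates)
    site_cat = rng.integers(0, n_cat, size=n_sites)
    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[root] = _draw_from(rng.random(n_sites), np.tile(model.frequencies, (n_sites, 1)))
    for node in tree.preorder():
        if node == root:
            continue
        t = float(tree.lengths[node])
        parent_states = states[tree.parent[node]]
        child = np.empty(n_sites, dtype=np.int64)
        if t == 0.0:
            child[:] = parent_states
        else:
            for k in range(n_cat):
                mask = site_cat == k
                if not mask.any():
                    continue
                p = eig.expm(t * rates[k])
                rows = p[parent_states[mask]]
                child[mask] = _draw_from(rng.random(int(mask.sum())), rows)
        states[node] = child
    leaves = tree.leaves()
    return SequenceSet(
        [tree.names[i] for i in leaves],
        [decode(states[i]) for i in leaves],
    )


def _draw_from(u: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw: one uniform per row of probabilities."""
    cum = np.cumsum(rows, axis=1)
    cum[:, -1] = 1.0
    return (u[:, None] > cum).sum(axis=1)


def generate_scenario(config: ScenarioConfig) -> Iterator[ReplicateSet]:
    """Yield replicates deterministically from the config's master seed.

    Per-replicate seeds are derived with ``SeedSequence.spawn`` (a
    counter-based scheme), so replicate *i* is reproducible on its own.
    """
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_replicates)
    chash = config.provenance_hash()
    true_trees = {k: t.to_newick() for k, t in config.trees.items()}
    for i, child_seq in enumerate(children):
        rep_seed = int(child_seq.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seq)
        groups: dict[str, SequenceSet] = {}
        combined: SequenceSet | None = None
        for label in sorted(config.trees):
            ss = evolve(config.trees[label], config.model, config.n_sites, rng)
            groups[label] = ss
            combined = ss if combined is None else combined.concat(ss)
        yield ReplicateSet(
            index=i,
            groups=groups,
            combined=combined,
            seed=rep_seed,
            config_hash=chash,
            true_trees=true_trees,
        )


def _two_domain_config(
    model: SubstitutionModel, n_sites: int, n_replicates: int, seed: int, name: str
) -> ScenarioConfig:
    return ScenarioConfig(
        trees={"E": parse_newick(_E_TREE), "B": parse_newick(_B_TREE)},
        model=model,
        n_sites=n_sites,
        n_replicates=n_replicates,
        seed=seed,
        name=name,
    )


def preset(name: str, seed: int = 0, n_replicates: int | None = None) -> ScenarioConfig:
    """Named study presets (see module docstring)."""
    key = name.lower()
    if key not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    sites, reps, model_name = PRESETS[key]
    model = get_model(model_name, gamma_shape=_DEFAULT_ALPHA, n_categories=4,
                      plus_f=(model_name == "rtREV"))
    return _two_domain_config(model, sites, n_replicates or reps, seed, key)


#: preset name -> (n_sites, n_replicates, model)
PRESETS: dict[str, tuple[int, int, str]] = {
    "fig2": (6591, 200, "rtREV"),
    "fig2-scaled": (1000, 20, "rtREV"),
    "fig3": (500, 100, "LG"),
    "fig3-scaled": (100, 20, "LG"),
}
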