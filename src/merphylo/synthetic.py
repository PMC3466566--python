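"""Synthetic gene trees and operon catalogs with the structure the analysis assumes.

The generator emulates the processes the comparative analysis is designed to
detect: vertical inheritance of gene content (a Brownian liability thresholded
to presence/absence), lateral transfer events that copy a donor tip's state
onto a recipient, independent gene loss, and a plasmid-borne subset of operons
with an elevated transfer rate. The species tree is an ultrametric Yule (or
birth-death) chronogram; the gene tree is the same topology with per-branch
lognormal rate jitter, giving the rate smoother a realistic non-clock input.

Everything is reproducible from the master seed; per-stage streams are spawned
from it so stages stay independent.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from math import ceil
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .chronos import Chronogram
from .traits import TraitMatrix, write_operon_table
from .treeio import Tree, write_newick

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_bm",
    "threshold_binary",
    "inject_lgt",
    "inject_loss",
    "generate_dataset",
    "write_dataset",
]

DEFAULT_TRAITS = ("merP", "merT", "merC", "merD", "merB")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the conditions every stage is tested at.

    Rates are per unit branch length on a tree of root age 1. The plasmid
    multiplier scales the lateral-transfer rate experienced by plasmid-borne
    operons relative to chromosomal ones.
    """

    n_tips: int = 64
    tree_model: str = "yule"
    birth_rate: float = 1.0
    death_rate: float = 0.0
    bm_sigma2: float = 1.0
    prevalence: float = 0.5
    lgt_rate: float = 0.0
    loss_rate: float = 0.0
    plasmid_fraction: float = 0.2
    plasmid_lgt_multiplier: float = 1.0
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    rate_jitter_sdlog: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if self.tree_model not in ("yule", "birth-death"):
            raise ValueError("tree_model must be 'yule' or 'birth-death'")
        if self.bm_sigma2 < 0:
            raise ValueError("bm_sigma2 must be >= 0")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.lgt_rate < 0:
            raise ValueError("lgt_rate must be >= 0")
        if not 0 <= self.loss_rate < 1:
            raise ValueError("loss_rate must be in [0, 1)")
        if not 0 <= self.plasmid_fraction < 1:
            raise ValueError("plasmid_fraction must be in [0, 1)")
        if self.plasmid_lgt_multiplier < 1:
            raise ValueError("plasmid_lgt_multiplier must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory for any emitted dataset")


@dataclass(frozen=True)
class SyntheticDataset:
    gene_tree: Tree
    species_tree: Chronogram
    matrix: TraitMatrix
    config: SyntheticConfig = field(repr=False)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


def simulate_tree(config: SyntheticConfig) -> Chronogram:
    """Ultrametric chronogram with ``n_tips`` extant tips, root age 1."""
    death = 0.0 if config.tree_model == "yule" else config.death_rate
    rng = random.Random(int(config.seed))
    dtree = birthdeath.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=death,
        num_extant_tips=config.n_tips,
        rng=rng,
        repeat_until_success=True,
    )
    # the simulator stops at the instant of the n-th speciation, leaving a
    # zero-length cherry; run time forward by the waiting time to the next
    # event so all pendant edges are positive (valid conditioning on n tips)
    extra = rng.expovariate(config.n_tips * (config.birth_rate + death))
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # deterministic tip labels in first-encounter order
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        if leaf.taxon is None:
            leaf.taxon = dtree.taxon_namespace.new_taxon(label="")
        leaf.taxon.label = f"t{i + 1:03d}"
    dtree.seed_node.edge.length = None
    tree = Tree(dtree)
    depth = float(tree.tip_depths().max())
    if depth <= 0:
        raise RuntimeError("degenerate simulated tree")
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.edge.length / depth
    tree = Tree(tree.dendropy_tree)
    return Chronogram.from_ultrametric_tree(tree, tol=1e-8)


def simulate_bm(tree, sigma2: float, seed) -> np.ndarray:
    """Brownian motion along the tree: root value 0, increments ~ N(0, sigma2*t).

    Returns tip values in tip order. ``tree`` may be a Tree or a Chronogram.
    """
    if isinstance(tree, Chronogram):
        tree = tree.tree
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    value: dict[int, float] = {id(dtree.seed_node): 0.0}
    out: dict[str, float] = {}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            parent_val = value[id(node.parent_node)]
            t = float(node.edge.length)
            value[id(node)] = parent_val + (
                rng.normal(0.0, np.sqrt(sigma2 * t)) if sigma2 * t > 0 else 0.0
            )
        if node.is_leaf():
            out[node.taxon.label] = value[id(node)]
    return np.array([out[lab] for lab in tree.tip_labels])


def threshold_binary(values, prevalence: float) -> np.ndarray:
    """Liability threshold: the ceil(prevalence * n) largest values become 1.

    Ties break by tip order (stable sort), so the result is deterministic.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    n = len(values)
    k = ceil(prevalence * n)
    order = np.argsort(-values, kind="stable")
    trait = np.zeros(n, dtype=int)
    trait[order[:k]] = 1
    return trait


def inject_lgt(
    tree, trait, lgt_rate: float, recipient_mask, seed, return_events: bool = False
):
    """Lateral transfer on trait states: Poisson(rate * total branch length) events.

    Each event copies the current state of a uniformly chosen donor tip onto a
    uniformly chosen recipient among the masked tips (events are sequential, so
    later events can propagate earlier transfers). Rate 0 is the identity.
    Topology is untouched: transfer acts on gene content only. With
    ``return_events`` the realized event count is returned alongside the trait.
    """
    if isinstance(tree, Chronogram):
        tree = tree.tree
    if lgt_rate < 0:
        raise ValueError("lgt_rate must be >= 0")
    trait = np.asarray(trait, dtype=int).copy()
    mask = np.asarray(recipient_mask, dtype=bool)
    if mask.shape != trait.shape:
        raise ValueError("recipient mask length does not match trait length")
    if lgt_rate == 0:
        return (trait, 0) if return_events else trait
    recipients = np.flatnonzero(mask)
    if len(recipients) == 0:
        raise ValueError("positive lgt_rate with an empty recipient mask")
    rng = np.random.default_rng(seed)
    n_events = int(rng.poisson(lgt_rate * tree.total_branch_length()))
    n = len(trait)
    for _ in range(n_events):
        donor = rng.integers(n)
        recipient = recipients[rng.integers(len(recipients))]
        trait[recipient] = trait[donor]
    return (trait, n_events) if return_events else trait


def inject_loss(trait, loss_rate: float, seed) -> np.ndarray:
    """Independent gene loss: each presence flips to absence with prob loss_rate."""
    if not 0 <= loss_rate < 1:
        raise ValueError("loss_rate must be in [0, 1)")
    trait = np.asarray(trait, dtype=int).copy()
    if loss_rate == 0:
        return trait
    rng = np.random.default_rng(seed)
    present = np.flatnonzero(trait == 1)
    flips = rng.random(len(present)) < loss_rate
    trait[present[flips]] = 0
    return trait


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Species chronogram + non-clock gene tree + operon catalog, all seeded.

    Per trait: Brownian liability on the species chronogram -> threshold to
    the target prevalence -> lateral transfer (background rate to all tips,
    extra plasmid-targeted events bringing plasmid operons to
    multiplier * rate) -> loss. merA is present in every operon by
    construction (the catalog is anchored on it).
    """
    seeds = _spawn_seeds(config.seed, 4 + 3 * len(config.trait_names))
    tree_seed, jitter_seed, plasmid_seed = seeds[0], seeds[1], seeds[2]
    species = simulate_tree(
        SyntheticConfig(**{**asdict(config), "seed": tree_seed})
    )

    # gene tree: same topology, branch-specific lognormal rate factors
    jrng = np.random.default_rng(jitter_seed)
    gene = species.tree.copy()
    for nd in gene.dendropy_tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(
                nd.edge.length * jrng.lognormal(0.0, config.rate_jitter_sdlog)
            )
    gene = Tree(gene.dendropy_tree)

    taxa = list(species.tree.tip_labels)
    n = len(taxa)
    prng = np.random.default_rng(plasmid_seed)
    n_plasmid = round(config.plasmid_fraction * n)
    plasmid_idx = prng.choice(n, size=n_plasmid, replace=False)
    plasmid_mask = np.zeros(n, dtype=bool)
    plasmid_mask[plasmid_idx] = True

    columns: dict[str, np.ndarray] = {"merA": np.ones(n, dtype=int)}
    all_mask = np.ones(n, dtype=bool)
    for k, trait_name in enumerate(config.trait_names):
        bm_seed, lgt_seed, loss_seed = seeds[3 + 3 * k : 6 + 3 * k]
        liab = simulate_bm(species, config.bm_sigma2, bm_seed)
        trait = threshold_binary(liab, config.prevalence)
        if config.lgt_rate > 0:
            trait = inject_lgt(species, trait, config.lgt_rate, all_mask, lgt_seed)
            extra = config.lgt_rate * (config.plasmid_lgt_multiplier - 1.0)
            if extra > 0 and plasmid_mask.any():
                trait = inject_lgt(
                    species, trait, extra, plasmid_mask, lgt_seed + 1
                )
        trait = inject_loss(trait, config.loss_rate, loss_seed)
        columns[trait_name] = trait

    df = pd.DataFrame(
        {
            "operon_id": [f"op_{t}" for t in taxa],
            "taxon_label": taxa,
            "genome_id": [f"g_{t}" for t in taxa],
            "replicon": np.where(plasmid_mask, "plasmid", "chromosome"),
            **columns,
        }
    )
    matrix = TraitMatrix(df)
    return SyntheticDataset(
        gene_tree=gene, species_tree=species, matrix=matrix, config=config
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Emit Newick trees, the operon catalog, and a provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_tree": outdir / "gene_tree.nwk",
        "species_tree": outdir / "species_tree.nwk",
        "catalog": outdir / "operon_catalog.tsv",
        "provenance": outdir / "provenance.json",
    }
    paths["gene_tree"].write_text(write_newick(dataset.gene_tree) + "\n")
    paths["species_tree"].write_text(write_newick(dataset.species_tree.tree) + "\n")
    write_operon_table(dataset.matrix, paths["catalog"])
    paths["provenance"].write_text(
        json.dumps(asdict(dataset.config), indent=2, default=str) + "\n"
    )
    return {k: str(v) for k, v in paths.items()}
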