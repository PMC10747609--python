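"""Synthetic data with known truth for the delimitation pipeline.

The generator reproduces the statistical structure the analysis assumes:

* a Yule (pure birth) species tree — between-species divergence,
* an independent constant-size coalescent grafted below each species tip —
  within-species genealogy, kept shallower than the species divergence by a
  required gap factor so a true threshold exists,
* K80 sequence evolution along the resulting genealogy (time in expected
  substitutions per site),
* species-specific subprovince occupancy profiles along a thermal (BIO11)
  gradient, with haplogroup and ploidy labels tied to species.

The default scenario emulates a three-species complex: one narrow-endemic
diploid confined to a single warm subprovince, a second diploid spread over
the warm south-western/eastern subprovinces, and a cold-adapted tetraploid
across the colder subprovinces — five haplogroups, 41 populations, twelve
subprovinces, around four sequenced individuals per sampled population and
on the order of 14 distinct haplotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rand import derive_seed
from .errors import DelimError
from .seqdata import Alignment
from .trees import Node, UltrametricTree

BASES = "ACGT"


# ---------------------------------------------------------------------------
# tree simulators


def _join_random_pairs(
    n: int, labels: list[str], waiting_rate, rng: np.random.Generator
) -> UltrametricTree:
    """Backward construction: repeatedly join a random pair of lineages.

    ``waiting_rate(k)`` gives the total event rate while k lineages remain.
    """
    nodes: list[Node] = [Node(0.0, label=lab) for lab in labels]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / waiting_rate(k))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(t, children=[a, b]))
    return UltrametricTree(nodes[0])


def simulate_yule_tree(
    s: int, birth_rate: float, seed: int, labels: list[str] | None = None
) -> UltrametricTree:
    """Yule genealogy over ``s`` extant species.

    Constructed backwards: while k lineages remain, the waiting time to the
    next join is Exponential(k * birth_rate), so the expected depth of a
    2-species tree is 1 / (2 * birth_rate).
    """
    if s < 2:
        raise ValueError("need at least 2 species")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    labels = labels or [f"sp{i + 1}" for i in range(s)]
    return _join_random_pairs(s, labels, lambda k: k * birth_rate, rng)


def simulate_coalescent_tree(
    n: int, theta: float, seed: int, labels: list[str] | None = None
) -> UltrametricTree:
    """Constant-size n-coalescent with pairwise coalescence rate 1/theta.

    E[TMRCA] = theta for n = 2 and 2 * theta * (1 - 1/n) in general.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    labels = labels or [f"t{i + 1}" for i in range(n)]
    return _join_random_pairs(
        n, labels, lambda k: k * (k - 1) / 2.0 / theta, rng
    )


def simulate_species_tree(
    s: int,
    birth_rate: float = 30.0,
    min_divergence: float = 0.01,
    seed: int = 0,
) -> UltrametricTree:
    """A Yule species tree conditioned on a minimum divergence.

    Redraws (up to 100 times) until the shallowest speciation node is at
    least ``min_divergence`` substitutions/site deep, so that a
    within-species coalescent gap is attainable downstream.
    """
    for attempt in range(100):
        tree = simulate_yule_tree(
            s, birth_rate, derive_seed(seed, "species-tree", counter=attempt)
        )
        if min(tree.node_heights()) >= min_divergence:
            return tree
    raise DelimError(
        f"no Yule draw with minimum divergence {min_divergence} in 100 attempts"
    )


@dataclass
class ScenarioTruth:
    """Ground truth attached to a simulated dataset."""

    species_tree_newick: str
    true_threshold: float
    tip_species: dict[str, str]
    hap_species: dict[str, str]
    species_profiles: dict[str, dict[str, float]]
    ploidy_map: dict[str, int]
    seed: int
    coal_mrca_heights: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_gmyc_tree(
    species_tree: UltrametricTree,
    n_per_species: dict[str, int],
    theta: float,
    min_gap_factor: float = 5.0,
    seed: int = 0,
) -> tuple[UltrametricTree, ScenarioTruth]:
    """Graft within-species coalescents below a species tree.

    Each species tip is replaced by an independent constant-size coalescent
    over its samples, redrawn (up to 100 times) until its depth is below
    (shallowest speciation height) / ``min_gap_factor``, so that every
    coalescent event is strictly younger than every speciation event.  The
    true threshold is the midpoint between the deepest coalescent MRCA and
    the shallowest speciation node.  Tip labels are ``<species>_<i>``.
    """
    spec_heights = species_tree.node_heights()
    min_spec = min(spec_heights)
    bound = min_spec / min_gap_factor
    deepest_coal = 0.0
    mrca_heights: dict[str, float] = {}
    tip_species: dict[str, str] = {}
    subtrees: dict[str, Node] = {}

    for si, sp in enumerate(sorted(species_tree.tips)):
        n_i = int(n_per_species.get(sp, 1))
        if n_i < 1:
            raise ValueError(f"sample size for {sp} must be >= 1")
        labels = [f"{sp}_{i + 1}" for i in range(n_i)]
        for lab in labels:
            tip_species[lab] = sp
        if n_i == 1:
            subtrees[sp] = Node(0.0, label=labels[0])
            mrca_heights[sp] = 0.0
            continue
        for attempt in range(100):
            sub = simulate_coalescent_tree(
                n_i, theta, derive_seed(seed, f"coal-{sp}", counter=attempt),
                labels=labels,
            )
            if sub.root_height < bound:
                break
        else:
            raise DelimError(
                f"could not draw a coalescent for {sp} shallower than "
                f"{bound:.3g} after 100 attempts; use a smaller theta"
            )
        subtrees[sp] = sub.root
        mrca_heights[sp] = sub.root_height
        deepest_coal = max(deepest_coal, sub.root_height)

    def graft(nd: Node) -> Node:
        if nd.is_tip:
            return subtrees[nd.label]
        return Node(nd.height, children=[graft(c) for c in nd.children])

    tree = UltrametricTree(graft(species_tree.root))
    truth = ScenarioTruth(
        species_tree_newick=species_tree.to_newick(),
        true_threshold=(deepest_coal + min_spec) / 2.0,
        tip_species=tip_species,
        hap_species={},
        species_profiles={},
        ploidy_map={},
        seed=seed,
        coal_mrca_heights=mrca_heights,
    )
    return tree, truth


# ---------------------------------------------------------------------------
# sequence evolution


def _k80_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """K80 substitution probabilities over branch length t (subs/site)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    same = 0.25 + 0.25 * e1 + 0.5 * e2
    ts = 0.25 + 0.25 * e1 - 0.5 * e2
    tv = 0.25 - 0.25 * e1
    # order A, C, G, T; transitions: A<->G, C<->T
    P = np.array(
        [
            [same, tv, ts, tv],
            [tv, same, tv, ts],
            [ts, tv, same, tv],
            [tv, ts, tv, same],
        ]
    )
    return P


def evolve_sequences(
    tree: UltrametricTree,
    length: int = 2000,
    kappa: float = 2.0,
    rate: float = 1.0,
    seed: int = 0,
) -> Alignment:
    """Simulate a K80 alignment along an ultrametric genealogy.

    Branch lengths are multiplied by ``rate`` to give expected substitutions
    per site; the root sequence is uniform over A, C, G, T.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if kappa <= 0 or rate < 0:
        raise ValueError("kappa must be > 0 and rate >= 0")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    ids: list[str] = []
    seqs: list[str] = []

    def descend(nd: Node, parent_height: float, parent_seq: np.ndarray) -> None:
        t = (parent_height - nd.height) * rate
        P = _k80_transition_matrix(t, kappa)
        cum = np.cumsum(P, axis=1)
        u = rng.random(len(parent_seq))
        seq = (u[:, None] > cum[parent_seq]).sum(axis=1)
        if nd.is_tip:
            ids.append(nd.label)
            seqs.append("".join(BASES[b] for b in seq))
        else:
            for ch in nd.children:
                descend(ch, nd.height, seq)

    for ch in tree.root.children:
        descend(ch, tree.root.height, root_seq)
    order = {lab: i for i, lab in enumerate(ids)}
    keep = sorted(ids, key=lambda lab: order[lab])
    return Alignment(keep, [seqs[order[lab]] for lab in keep])


# ---------------------------------------------------------------------------
# occurrences and the default scenario

#: default scenario layout (three species, five haplogroups, twelve
#: subprovinces on a cold-to-warm BIO11 gradient)
SPECIES = ("sp1", "sp2", "sp3")
N_PER_SPECIES = {"sp1": 6, "sp2": 10, "sp3": 14}
POPS_PER_SPECIES = {"sp1": 6, "sp2": 15, "sp3": 20}  # 41 populations
HAPLOGROUPS = {
    "sp1": ["hgA"],
    "sp2": ["hgB", "hgC"],
    "sp3": ["hgD", "hgE"],
}
PLOIDY = {"sp1": 2, "sp2": 2, "sp3": 4}
SUBPROVINCES = [f"SP{i:02d}" for i in range(1, 13)]
BIO11_MEANS = dict(zip(SUBPROVINCES, np.linspace(-2.0, 9.0, 12).round(2)))
SPECIES_PROFILES = {
    # narrow endemic diploid: a single warm subprovince
    "sp1": {"SP12": 1.0},
    # diploid over the warm south-western/eastern subprovinces
    "sp2": {"SP08": 0.15, "SP09": 0.25, "SP10": 0.3, "SP11": 0.3},
    # tetraploid over the colder subprovinces
    "sp3": {"SP01": 0.1, "SP02": 0.15, "SP03": 0.2, "SP04": 0.25,
            "SP05": 0.2, "SP06": 0.1},
}
BIRTH_RATE = 30.0
MIN_SPECIES_DIVERGENCE = 0.01
THETA = 5e-4
MIN_GAP_FACTOR = 5.0
SEQ_LENGTH = 2000
KAPPA = 2.0
DIRICHLET_CONC = 200.0
BIO11_SD = 0.5


def simulate_occurrences(
    truth: ScenarioTruth,
    pops_per_species: dict[str, int],
    bio11_by_subprovince: dict[str, float],
    dirichlet_conc: float = DIRICHLET_CONC,
    seed: int = 0,
    bio11_sd: float = BIO11_SD,
) -> pd.DataFrame:
    """Draw one occurrence row per population from the species profiles.

    Each species' occupancy profile is Dirichlet-perturbed once with
    concentration ``dirichlet_conc`` (larger = closer to the stated
    profile); each of its populations then draws a subprovince from the
    perturbed profile, a haplogroup uniformly from the species' haplogroup
    set, the species' ploidy, and bio11 as the subprovince mean plus
    Gaussian noise.
    """
    rng = np.random.default_rng(derive_seed(seed, "occurrences"))
    hap_of_species = {}
    for hg, sp in truth.hap_species.items():
        hap_of_species.setdefault(sp, []).append(hg)
    rows = []
    pop_counter = 0
    for sp in sorted(pops_per_species):
        profile = truth.species_profiles[sp]
        provs = sorted(profile)
        base = np.array([profile[p] for p in provs])
        pert = rng.dirichlet(np.maximum(base * dirichlet_conc, 1e-9))
        for _ in range(pops_per_species[sp]):
            pop_counter += 1
            prov = provs[rng.choice(len(provs), p=pert)]
            hg = rng.choice(sorted(hap_of_species[sp]))
            rows.append(
                {
                    "population_id": f"p{pop_counter:02d}",
                    "subprovince": prov,
                    "haplogroup": hg,
                    "ploidy": truth.ploidy_map[sp],
                    "bio11": round(
                        bio11_by_subprovince[prov] + rng.normal(0.0, bio11_sd), 3
                    ),
                    "species_label": sp,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Scenario:
    alignment: Alignment
    tree: UltrametricTree
    occurrences: pd.DataFrame
    truth: ScenarioTruth

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "alignment.fasta",
            "tree": out / "genealogy.nwk",
            "occurrences": out / "occurrences.csv",
            "truth": out / "truth.json",
        }
        self.alignment.write_fasta(paths["fasta"])
        self.tree.write(paths["tree"])
        self.occurrences.to_csv(paths["occurrences"], index=False)
        self.truth.to_json(paths["truth"])
        return paths


def make_scenario(seed: int = 42) -> Scenario:
    """The default three-species scenario with full ground truth.

    Species tree: Yule over three species, redrawn until the shallowest
    divergence exceeds 0.01 substitutions/site so the within/between gap is
    attainable at theta = 5e-4.  Gene tree: coalescents grafted per species
    (6 + 10 + 14 = 30 sampled individuals).  Alignment: 2000 sites of K80
    evolution (kappa = 2).  Occurrences: 41 populations over twelve
    subprovinces with the diploid-warm / tetraploid-cold layout.
    """
    for attempt in range(100):
        sp_tree = simulate_yule_tree(
            len(SPECIES), BIRTH_RATE,
            derive_seed(seed, "species-tree", counter=attempt),
            labels=list(SPECIES),
        )
        if min(sp_tree.node_heights()) >= MIN_SPECIES_DIVERGENCE:
            break
    else:  # pragma: no cover
        raise DelimError("could not draw a species tree with enough divergence")
    tree, truth = simulate_gmyc_tree(
        sp_tree, N_PER_SPECIES, THETA, MIN_GAP_FACTOR,
        seed=derive_seed(seed, "gene-tree"),
    )
    truth.hap_species = {
        hg: sp for sp, hgs in HAPLOGROUPS.items() for hg in hgs
    }
    truth.species_profiles = {sp: dict(SPECIES_PROFILES[sp]) for sp in SPECIES}
    truth.ploidy_map = dict(PLOIDY)
    truth.seed = seed
    aln = evolve_sequences(
        tree, length=SEQ_LENGTH, kappa=KAPPA, rate=1.0,
        seed=derive_seed(seed, "sequences"),
    )
    occ = simulate_occurrences(
        truth, POPS_PER_SPECIES, BIO11_MEANS, DIRICHLET_CONC, seed=seed
    )
    return Scenario(alignment=aln, tree=tree, occurrences=occ, truth=truth)
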