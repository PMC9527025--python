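"""Clock-simulated chronograms and alignments for end-to-end validation.

The generator produces the statistical structure the placement analysis
assumes: an ultrametric species tree from a Yule (pure-birth) process,
optionally rescaled to an exact crown age, and a one-locus alignment evolved
along it under a strict clock with Jukes–Cantor substitution.  Under JC the
expected uncorrected p-distance of a pair whose MRCA has age t is

    E[p] = 0.75 * (1 - exp(-8*mu*t/3)),

which gives every downstream stage an analytic oracle.  Conspecific
individuals are attached as a shallow star polytomy of fixed depth below
each species tip, enough to produce realistic within-species percent ranges
without coalescent machinery.

Held-out scenarios prune one non-basal species (the "newly discovered"
taxon) from the chronogram while keeping its sequences in the alignment, and
record its true divergence time T* so placement accuracy can be measured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .chronogram import Chronogram, parse_chronogram
from .msa import Alignment, SpeciesMap

__all__ = [
    "SimulationConfig",
    "SyntheticScenario",
    "simulate_yule_chronogram",
    "simulate_alignment_jc",
    "expected_p_jc",
    "simulate_focal_holdout",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic data set.

    Defaults emulate the empirical regime: a 16S-like locus on a dozen
    species with two sequenced individuals each, crown age a few tens of My,
    and a substitution rate slow enough that percent distances stay in the
    near-linear (unsaturated) range.
    """

    n_species: int = 12
    individuals_per_species: int = 2
    birth_rate: float = 0.2  # speciations per lineage per My
    crown_age: float | None = 30.0  # My; None keeps the raw Yule depth
    mu: float = 5e-4  # substitutions per site per My
    n_sites: int = 1600
    #: age (My) of the within-species polytomy; None = 0.05 * crown age
    intraspecific_depth: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        if self.individuals_per_species < 1:
            raise ValueError("need at least 1 individual per species")
        if self.birth_rate <= 0 or self.mu < 0 or self.n_sites < 1:
            raise ValueError("rates must be positive and n_sites >= 1")
        if self.crown_age is not None and self.crown_age <= 0:
            raise ValueError("crown_age must be positive")


def expected_p_jc(mu: float, pair_time: float) -> float:
    """Expected uncorrected p-distance under Jukes–Cantor for MRCA age t.

    Monotone increasing in ``mu * pair_time`` with asymptote 0.75 (the
    saturation limit where sequences are random with respect to each other).
    """
    if mu < 0 or pair_time < 0:
        raise ValueError("mu and pair_time must be non-negative")
    return 0.75 * (1.0 - np.exp(-8.0 * mu * pair_time / 3.0))


class _Lineage:
    __slots__ = ("t_birth", "t_end", "children", "label")

    def __init__(self, t_birth: float):
        self.t_birth = t_birth
        self.t_end: float | None = None
        self.children: list["_Lineage"] = []
        self.label: str | None = None


def simulate_yule_chronogram(
    n_species: int,
    birth_rate: float = 0.2,
    crown_age: float | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> Chronogram:
    """Sample a pure-birth species tree, ultrametric by construction.

    Forward simulation from the crown split: with k extant lineages the next
    speciation occurs after an Exp(birth_rate * k) wait and splits a
    uniformly chosen lineage; the tree is observed one further exponential
    wait after the n-th species appears.  With ``crown_age`` set, all branch
    lengths are rescaled so the root age equals it exactly.  Tips are
    labelled ``sp01``, ``sp02``, ... left to right.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    root = _Lineage(0.0)
    active = [_Lineage(0.0), _Lineage(0.0)]
    root.children = list(active)
    root.t_end = 0.0
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        parent = active[i]
        parent.t_end = t
        parent.children = [_Lineage(t), _Lineage(t)]
        active[i : i + 1] = parent.children
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    scale = 1.0 if crown_age is None else crown_age / t_end
    width = max(2, len(str(n_species)))

    counter = iter(range(1, n_species + 1))

    def newick(node: _Lineage) -> str:
        if not node.children:
            label = f"sp{next(counter):0{width}d}"
            bl = (t_end - node.t_birth) * scale
            return f"{label}:{bl!r}"
        inner = ",".join(newick(c) for c in node.children)
        if node is root:
            return f"({inner});"
        bl = (node.t_end - node.t_birth) * scale
        return f"({inner}):{bl!r}"

    return parse_chronogram(newick(root), epsilon=1e-9)


def _evolve(seq: np.ndarray, branch: float, mu: float,
            rng: np.random.Generator) -> np.ndarray:
    """One JC step: each site substitutes with total probability
    (3/4)(1 - exp(-4*mu*b/3)), uniformly to one of the other three bases."""
    child = seq.copy()
    if branch <= 0 or mu == 0:
        return child
    p_change = 0.75 * (1.0 - np.exp(-4.0 * mu * branch / 3.0))
    mask = rng.random(seq.size) < p_change
    k = int(mask.sum())
    if k:
        child[mask] = (child[mask] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
    return child


def simulate_alignment_jc(
    chron: Chronogram,
    mu: float,
    n_sites: int,
    individuals_per_species: int = 1,
    intraspecific_depth: float = 0.0,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[Alignment, SpeciesMap]:
    """Evolve a strict-clock JC alignment down a chronogram.

    The root sequence is uniform over {A, C, G, T}.  Each species tip yields
    ``individuals_per_species`` sequences; with more than one, the
    individuals radiate from a star ancestor at age ``intraspecific_depth``
    on the terminal branch (capped at 90% of that branch).  Tip identifiers
    are ``<species>_01``, ``<species>_02``, ...
    """
    if mu < 0 or n_sites < 1 or individuals_per_species < 1:
        raise ValueError("invalid simulation parameters")
    if intraspecific_depth < 0:
        raise ValueError("intraspecific_depth must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)

    tip_ids: list[str] = []
    rows: list[str] = []
    entries: dict[str, str] = {}
    root_seq = rng.integers(0, 4, size=n_sites, dtype=np.uint8)

    def decode(seq: np.ndarray) -> str:
        return _BASES[seq].tobytes().decode("ascii")

    def walk(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            child_seq_parent = seq
            b = child.edge.length or 0.0
            if child.is_leaf():
                species = child.taxon.label
                k = individuals_per_species
                d = min(intraspecific_depth, 0.9 * b) if k > 1 else 0.0
                anc = _evolve(child_seq_parent, b - d, mu, rng)
                for i in range(1, k + 1):
                    tid = f"{species}_{i:02d}"
                    tip_ids.append(tid)
                    rows.append(decode(_evolve(anc, d, mu, rng)))
                    entries[tid] = species
            else:
                walk(child, _evolve(child_seq_parent, b, mu, rng))

    walk(chron.tree.seed_node, root_seq)
    return Alignment(tuple(tip_ids), tuple(rows)), SpeciesMap(entries)


@dataclass(frozen=True)
class SyntheticScenario:
    """A held-out focal-taxon test case.

    The focal species is present in the alignment and species map but absent
    from ``chronogram`` (the tree handed to the pipeline); ``t_star`` is its
    true divergence time — the MRCA age of the focal tip with its sister
    clade on ``full_chronogram``.
    """

    chronogram: Chronogram
    full_chronogram: Chronogram
    alignment: Alignment
    species_map: SpeciesMap
    focal: str
    t_star: float
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.alignment.to_fasta(out / "alignment.fasta")
        self.species_map.to_tsv(out / "species_map.tsv")
        self.chronogram.write_newick(out / "chronogram.nwk")
        self.full_chronogram.write_newick(out / "full_chronogram.nwk")
        truth = {
            "focal_species": self.focal,
            "t_star_my": self.t_star,
            "config": dataclasses.asdict(self.config),
        }
        (out / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n"
        )


def simulate_focal_holdout(
    config: SimulationConfig, seed: int | None = None
) -> SyntheticScenario:
    """Simulate a full data set and hold one species out of the chronogram.

    The focal species is drawn uniformly among non-basal tips (tips whose
    parent is not the root), so pruning leaves a proper crown and T* is
    strictly inside the tree.  Requires at least 4 species.
    """
    if config.n_species < 4:
        raise ValueError("focal holdout needs at least 4 species")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    full = simulate_yule_chronogram(
        config.n_species, config.birth_rate, config.crown_age, rng=rng
    )
    depth = config.intraspecific_depth
    if depth is None:
        depth = 0.05 * full.height
    aln, sm = simulate_alignment_jc(
        full,
        config.mu,
        config.n_sites,
        individuals_per_species=config.individuals_per_species,
        intraspecific_depth=depth,
        rng=rng,
    )

    root = full.tree.seed_node
    candidates = sorted(
        lf.taxon.label
        for lf in full.tree.leaf_node_iter()
        if lf.parent_node is not root
    )
    if not candidates:
        raise ValueError("no non-basal tip available as focal")
    focal = candidates[int(rng.integers(len(candidates)))]
    focal_node = full._node(focal)
    t_star = full.age(focal_node.parent_node)

    pruned_tree = dendropy.Tree(full.tree)
    pruned_tree.prune_taxa_with_labels([focal])
    pruned = parse_chronogram(
        pruned_tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ),
        epsilon=1e-6,
    )
    return SyntheticScenario(
        chronogram=pruned,
        full_chronogram=full,
        alignment=aln,
        species_map=sm,
        focal=focal,
        t_star=float(t_star),
        config=config,
    )
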