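"""Two-locus sequence + morphology simulator with known truth.

The generator emulates the structure of a small integrative-taxonomy
study of encrusting sponges: eight species on one species tree split
into two deep parts, a fast mitochondrial-like locus and a slow
(10x slower) nuclear ribosomal-like locus evolved on that tree,
heavily unbalanced specimen sampling (one species with 27 specimens,
several singletons), and a four-character morphology table concordant
with species identity except for a controllable deviation rate.

Within-species variation is modelled as star-like terminal branch
extensions with exponentially distributed lengths of mean theta/2, so
the expected within-species pairwise diversity is theta (at locus rate
1); the pipeline consumes distances and split supports, not genealogy
shape, so no coalescent machinery is needed.  All randomness flows from
one seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import EsudelimError
from .morphology import CHARACTERS, VOCABULARY, MorphMatrix, StateTuple
from .partition import UnitPartition
from .seqmodels import Alignment, SubstitutionModel
from .trees import SupportTree

import pandas as pd


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class LocusSpec:
    name: str
    length: int
    rate: float                      # rate multiplier vs. the tree scale
    model: SubstitutionModel
    theta_scale: float = 1.0         # scales within-species theta per locus

    def __post_init__(self) -> None:
        if self.length < 1 or self.rate <= 0 or self.theta_scale < 0:
            raise EsudelimError("invalid locus specification")


@dataclass
class SimConfig:
    species_tree: str                # newick, lengths in subs/site at rate 1
    locus_specs: list[LocusSpec]
    n_specimens_per_species: dict[str, int]
    within_species_theta: float
    morphology_profiles: dict[str, StateTuple]
    morph_deviation_rate: float = 0.0
    incongruence: dict[str, str] | None = None  # locus -> alternative newick
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.morph_deviation_rate <= 1.0):
            raise EsudelimError("deviation rate must be in [0, 1]")
        if self.within_species_theta < 0:
            raise EsudelimError("theta must be >= 0")


@dataclass
class TruthTable:
    specimen_to_species: dict[str, str]
    species_to_part: dict[str, str]
    locus_trees: dict[str, str]      # specimen-level newick per locus
    models: dict[str, SubstitutionModel]

    def species_partition(self) -> UnitPartition:
        species = list(dict.fromkeys(self.specimen_to_species.values()))
        return UnitPartition(dict(self.specimen_to_species), species,
                             dict(self.species_to_part))


@dataclass
class StudyBundle:
    alignments: dict[str, Alignment]
    specimens: list            # list[formats_io.SpecimenRecord]
    morphology: MorphMatrix
    truth: TruthTable
    config: SimConfig


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree: SupportTree, model: SubstitutionModel,
                       length: int, rate: float = 1.0,
                       seed: int | np.random.Generator = 0) -> Alignment:
    """Evolve ``length`` sites along ``tree`` under ``model``.

    Root states are drawn from the stationary frequencies; a fraction
    p_inv of sites is held invariant across the whole tree and the
    remaining sites evolve through the transition probabilities of the
    normalised rate matrix, with branch lengths read as expected
    substitutions per site averaged over all sites (so the variable
    class evolves for t * rate / (1 - p_inv)).  Deterministic given the
    seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pi = np.asarray(model.pi, float)
    p_inv = model.p_inv
    scale = rate / (1.0 - p_inv)
    variable = rng.random(length) >= p_inv
    states = {id(tree.tree.seed_node): rng.choice(4, size=length, p=pi)}

    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        parent_states = states[id(node.parent_node)]
        t = (node.edge.length or 0.0) * scale
        child = parent_states.copy()
        if t > 0:
            p = model.transition_probabilities(t)
            p = p / p.sum(axis=1, keepdims=True)
            for x in range(4):
                sel = variable & (parent_states == x)
                k = int(sel.sum())
                if k:
                    child[sel] = rng.choice(4, size=k, p=p[x])
        states[id(node)] = child

    labels, seqs = [], []
    bases = np.array(list("ACGT"))
    for leaf in tree.tree.leaf_node_iter():
        labels.append(leaf.taxon.label)
        seqs.append("".join(bases[states[id(leaf)]]))
    return Alignment(labels, seqs)


def _specimen_tree(species_newick: str, counts: dict[str, int],
                   theta: float, rng: np.random.Generator) -> SupportTree:
    """Attach specimen tips (star-like, Exp(theta/2) branches) below each
    species leaf."""
    tree = dendropy.Tree.get(data=species_newick, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    ns = tree.taxon_namespace
    for leaf in list(tree.leaf_node_iter()):
        sp = leaf.taxon.label
        n = counts.get(sp, 1)
        names = [f"{sp}-{i + 1}" for i in range(n)]
        leaf.taxon = None
        for name in names:
            tax = ns.new_taxon(label=name)
            child = dendropy.Node(taxon=tax)
            child.edge.length = float(rng.exponential(theta / 2.0)) \
                if theta > 0 else 0.0
            leaf.add_child(child)
    return SupportTree(tree)


# ---------------------------------------------------------------------------
# full study simulation
# ---------------------------------------------------------------------------

_LOCALITY_POOL = ("ROC", "MIN", "SKA", "CAD", "POR", "BER", "ire")


def simulate_study(cfg: SimConfig) -> StudyBundle:
    """Generate the full dataset bundle: per-locus alignments, specimen
    records, a morphology table and the truth table."""
    from .formats_io import SpecimenRecord

    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("trees", "seqs", "morph", "meta"),
        np.random.SeedSequence(cfg.seed).spawn(4))}

    species_tree = SupportTree.from_newick(cfg.species_tree,
                                           parse_supports=False)
    species = species_tree.leaf_labels
    unknown = set(cfg.n_specimens_per_species) - set(species)
    if unknown:
        raise EsudelimError(f"sample sizes for unknown species: "
                            f"{sorted(unknown)}")

    spec_to_sp: dict[str, str] = {}
    for sp in species:
        for i in range(cfg.n_specimens_per_species.get(sp, 1)):
            spec_to_sp[f"{sp}-{i + 1}"] = sp

    # parts = clades under the root's children
    root_kids = species_tree.tree.seed_node.child_nodes()
    sp_to_part: dict[str, str] = {}
    for k, child in enumerate(root_kids):
        for lf in child.leaf_iter():
            sp_to_part[lf.taxon.label] = chr(ord("A") + k)

    alignments: dict[str, Alignment] = {}
    locus_trees: dict[str, str] = {}
    models: dict[str, SubstitutionModel] = {}
    for spec in cfg.locus_specs:
        newick = cfg.species_tree
        if cfg.incongruence and spec.name in cfg.incongruence:
            newick = cfg.incongruence[spec.name]
        tree = _specimen_tree(newick, cfg.n_specimens_per_species,
                              cfg.within_species_theta * spec.theta_scale,
                              streams["trees"])
        aln = simulate_alignment(tree, spec.model, spec.length,
                                 rate=spec.rate, seed=streams["seqs"])
        aln = Alignment(aln.labels, aln.sequences, locus=spec.name)
        # stable specimen order across loci
        order = list(spec_to_sp)
        alignments[spec.name] = aln.subset(order)
        locus_trees[spec.name] = tree.newick(with_supports=False)
        models[spec.name] = spec.model

    # morphology: species profile, per-specimen random single-character flip
    rows = []
    rng_m = streams["morph"]
    rng_meta = streams["meta"]
    localities = {s: _LOCALITY_POOL[int(rng_meta.integers(
        len(_LOCALITY_POOL)))] for s in spec_to_sp}
    for s, sp in spec_to_sp.items():
        states = list(cfg.morphology_profiles[sp])
        if cfg.morph_deviation_rate and \
                rng_m.random() < cfg.morph_deviation_rate:
            ci = int(rng_m.integers(len(CHARACTERS)))
            char = CHARACTERS[ci]
            others = [v for v in VOCABULARY[char] if v != states[ci]]
            states[ci] = others[int(rng_m.integers(len(others)))]
        rows.append({"specimen": s, "locality": localities[s],
                     **dict(zip(CHARACTERS, states))})
    mm = MorphMatrix(pd.DataFrame(rows).set_index("specimen"))

    specimens = [SpecimenRecord(s, localities[s],
                                frozenset(a for a in alignments))
                 for s in spec_to_sp]
    truth = TruthTable(spec_to_sp, sp_to_part, locus_trees, models)
    return StudyBundle(alignments, specimens, mm, truth, cfg)


def write_bundle(bundle: StudyBundle, outdir) -> None:
    """Emit the bundle in exactly the formats ``formats_io`` reads."""
    from pathlib import Path
    from .formats_io import (write_alignment, write_morph_matrix,
                             write_specimens)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, aln in bundle.alignments.items():
        write_alignment(aln, out / f"{name}.fasta")
    write_specimens(bundle.specimens, out / "specimens.csv")
    write_morph_matrix(bundle.morphology, out / "morphology.csv",
                       esu=bundle.truth.specimen_to_species)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: eight species in two deep parts; minimum between-species path 0.04,
#: between-part paths ~0.18 (fast-locus scale)
DEFAULT_SPECIES_TREE = (
    "((((H4:0.02,H5:0.02):0.015,H6:0.035):0.01,"
    "((H1:0.02,H2:0.02):0.01,H3:0.03):0.01):0.06,"
    "(H7:0.02,H8:0.02):0.06);"
)

DEFAULT_SAMPLING = {"H1": 1, "H2": 1, "H3": 1, "H4": 3,
                    "H5": 6, "H6": 5, "H7": 2, "H8": 27}

DEFAULT_PROFILES: dict[str, StateTuple] = {
    "H8": ("smooth", "fusiform", "truncate", "lt30"),
    "H7": ("smooth", "fusiform", "truncate", "lt30"),
    "H6": ("spined", "tylote", "simple_shape", "lt30"),
    "H5": ("spined", "mucronate", "simple_shape", "lt30"),
    "H4": ("spined", "mucronate", "simple_shape", "gt30"),
    "H3": ("spined", "tylote", "simple_shape", "gt30"),
    "H2": ("spined", "tylote", "simple_shape", "gt30"),
    "H1": ("spined", "tylote", "simple_shape", "gt30"),
}

FAST_MODEL = SubstitutionModel.gtr(
    rates=(2.0, 8.0, 1.5, 1.2, 8.0, 1.0),
    pi=(0.25, 0.15, 0.20, 0.40), p_inv=0.4)

SLOW_MODEL = SubstitutionModel.hky(
    kappa=2.5, pi=(0.20, 0.30, 0.30, 0.20), p_inv=0.6)


def plocamionida_like(seed: int = 0, length_fast: int = 2000,
                      length_slow: int = 2000,
                      theta: float = 0.002,
                      morph_deviation_rate: float = 0.02,
                      incongruent: bool = False) -> SimConfig:
    """Default preset: 8 species in two deep parts, a fast COI-like
    locus (GTR+I) and a 10x slower 28S-like locus (HKY+I, effectively
    invariant within species), unbalanced sampling with one
    27-specimen species and three singletons."""
    incong = None
    if incongruent:
        # move H5 next to H6: conflicting supported structure in the
        # slow locus
        incong = {"slow": (
            "((((H4:0.02,H6:0.02):0.015,H5:0.035):0.01,"
            "((H1:0.02,H2:0.02):0.01,H3:0.03):0.01):0.06,"
            "(H7:0.02,H8:0.02):0.06);")}
    return SimConfig(
        species_tree=DEFAULT_SPECIES_TREE,
        locus_specs=[
            LocusSpec("fast", length_fast, 1.0, FAST_MODEL, theta_scale=1.0),
            LocusSpec("slow", length_slow, 0.1, SLOW_MODEL, theta_scale=0.0),
        ],
        n_specimens_per_species=dict(DEFAULT_SAMPLING),
        within_species_theta=theta,
        morphology_profiles=dict(DEFAULT_PROFILES),
        morph_deviation_rate=morph_deviation_rate,
        incongruence=incong,
        seed=seed,
    )


def ild_sim_pair(seed: int, congruent: bool = True, n_sites: int = 300,
                 terminal: float = 0.5, internal: float = 0.05
                 ) -> tuple[Alignment, Alignment]:
    """Scaled-down two-locus simulation for ILD calibration: six taxa,
    JC, same topology for both loci when ``congruent`` else two
    conflicting topologies with the same branch-length profile.

    The long terminal branches make the data homoplasy-rich, which
    spreads the parsimony length-excess statistic over many values;
    with little homoplasy the excess is almost always zero and the
    permutation test becomes conservative (a known property of the
    Farris test, not a defect of the permutation machinery)."""
    t = terminal
    i = internal
    top1 = (f"((A:{t},B:{t}):{i},(C:{t},D:{t}):{i},(E:{t},F:{t}):{i});")
    top2 = (f"((A:{t},C:{t}):{i},(B:{t},D:{t}):{i},(E:{t},F:{t}):{i});")
    ss = np.random.SeedSequence(seed).spawn(2)
    jc = SubstitutionModel.jc()
    aln_a = simulate_alignment(SupportTree.from_newick(top1, False), jc,
                               n_sites, seed=np.random.default_rng(ss[0]))
    tree_b = top1 if congruent else top2
    aln_b = simulate_alignment(SupportTree.from_newick(tree_b, False), jc,
                               n_sites, seed=np.random.default_rng(ss[1]))
    aln_b = aln_b.subset(aln_a.labels)
    return (Alignment(aln_a.labels, aln_a.sequences, "locusA"),
            Alignment(aln_b.labels, aln_b.sequences, "locusB"))
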