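"""Synthetic proteomes, expression tables and kinetic datasets with planted
ground truth.

The generator emulates a comparative-genomics setting: a rooted guide tree
over 13 species (5 ingroup forming a monophyletic clade, emulating the
sampled Asteraceae, plus 8 outgroup species), gene families with controlled
within- and between-subfamily identity, clade-specific families gained on
the ingroup stem, random decoy proteins without the domain, an
FPKM-like expression matrix over 5 wild and 6 cultivated samples with
planted highly expressed pathway genes, and Michaelis-Menten rate data.

Sequence evolution is deliberately simple: uniform replacement over the
amino-acid alphabet with per-branch substitution counts
``round(rate * branch_length * length)`` and no indels, which keeps
identity arithmetic exact (identity = Hamming fraction). Identity targets
are enforced by bisection on the substitution rate (within subfamilies)
and on the subfamily-ancestor divergence count (between subfamilies), then
verified; generation fails loudly if a target cannot be realized.

All outputs are pure functions of (configuration, seed).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel

from .phylo import AMINO_ACIDS, Node, pairwise_identity

__all__ = [
    "ProteinRecord",
    "SpeciesDesign",
    "FamilySpec",
    "GeneTruth",
    "TruthTable",
    "ExpressionTable",
    "KineticDataset",
    "SyntheticBundle",
    "default_design",
    "default_family_specs",
    "simulate_gene_families",
    "simulate_expression",
    "simulate_kinetics",
    "simulate_bundle",
    "write_fixture",
    "read_fixture",
]

_N_AA = len(AMINO_ACIDS)
_AA_ARR = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class ProteinRecord:
    """A species-tagged amino-acid sequence; the atom of all mining stages."""

    gene: str
    species: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SpeciesDesign:
    """Species labels, the declared ingroup, and a rooted guide tree.

    The ingroup must be a non-empty strict subset of the species and form a
    monophyletic clade of the guide tree (branch lengths in
    substitutions/site).
    """

    species_ids: list[str]
    ingroup_ids: list[str]
    guide_tree: Node

    def __post_init__(self) -> None:
        sp, ing = set(self.species_ids), set(self.ingroup_ids)
        if not ing or not ing < sp:
            raise ValueError("ingroup must be a non-empty strict subset of species")
        if set(self.guide_tree.leaf_names()) != sp:
            raise ValueError("guide tree leaves do not match species_ids")
        if self.guide_tree.find_clade(ing) is None:
            raise ValueError("ingroup is not monophyletic in the guide tree")

    @property
    def outgroup_ids(self) -> list[str]:
        return [s for s in self.species_ids if s not in set(self.ingroup_ids)]


@dataclass
class FamilySpec:
    """Targets for one planted gene family.

    ``within_identity`` / ``between_identity`` are realized pairwise
    identity bounds inside / across subfamilies. Clade-specific families
    gain members only on the ingroup stem. ``domain_length`` defaults to
    400 residues so planted members pass the (350, 650) length filter.
    """

    family_id: str
    n_subfamilies: int = 1
    within_identity: float = 0.90
    between_identity: float = 0.30
    clade_specific: bool = False
    members_per_species: int = 1
    domain_length: int = 400

    def __post_init__(self) -> None:
        if not (0.0 < self.within_identity <= 1.0):
            raise ValueError("within_identity must be in (0, 1]")
        if not (0.0 <= self.between_identity < self.within_identity):
            raise ValueError("between_identity must be in [0, within_identity)")
        if self.n_subfamilies < 1 or self.members_per_species < 1:
            raise ValueError("counts must be >= 1")
        if self.domain_length < 10:
            raise ValueError("domain_length too short")


class GeneTruth(BaseModel):
    species: str
    family_id: str | None
    subfamily_id: str | None
    is_domain_bearing: bool


class TruthTable(BaseModel):
    """Planted ground truth: per-gene labels, per-subfamily specificity
    flags, and the list of planted high-expression pathway genes."""

    genes: dict[str, GeneTruth]
    subfamily_specific: dict[str, bool]
    pathway_genes: list[str]

    def domain_bearing(self) -> list[str]:
        return [g for g, t in self.genes.items() if t.is_domain_bearing]


@dataclass
class ExpressionTable:
    """Non-negative gene x sample expression matrix with a group label
    ('wild' or 'cultivated') for every sample."""

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad = set(self.groups.values()) - {"wild", "cultivated"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")


@dataclass
class KineticDataset:
    """Initial-rate measurements: substrate concentrations (µM) and
    observed rates (µM/s) at a fixed enzyme concentration (µM)."""

    substrate_concs: np.ndarray
    rates: np.ndarray
    enzyme_conc: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_concs, dtype=float)
        v = np.asarray(self.rates, dtype=float)
        if s.shape != v.shape:
            raise ValueError("concs and rates must have the same length")
        if (s <= 0).any():
            raise ValueError("substrate concentrations must be strictly positive")
        if len(np.unique(s)) != len(s):
            raise ValueError("substrate concentrations must be distinct")
        if (v < 0).any():
            raise ValueError("rates must be non-negative")
        self.substrate_concs, self.rates = s, v


@dataclass
class SyntheticBundle:
    """Everything one simulated study comprises."""

    proteomes: dict[str, list[ProteinRecord]]
    truth: TruthTable
    seed_alignments: dict[str, list[str]]  # family_id -> ungapped alignment
    expression: ExpressionTable | None = None
    kinetics: dict[str, KineticDataset] = field(default_factory=dict)

    def all_proteins(self) -> list[ProteinRecord]:
        return [p for sp in sorted(self.proteomes) for p in self.proteomes[sp]]


# ---------------------------------------------------------------------------
# Default study design
# ---------------------------------------------------------------------------


def _ladder(names: list[str], bl: float) -> Node:
    node = Node(name=names[0], length=bl)
    for nm in names[1:]:
        node = Node(children=[node, Node(name=nm, length=bl)], length=bl)
    return node


def default_design(n_ingroup: int = 5, n_outgroup: int = 8) -> SpeciesDesign:
    """5 ingroup + 8 outgroup species on a two-clade ladder guide tree."""
    ingroup = [f"ing{i + 1}" for i in range(n_ingroup)]
    outgroup = [f"out{i + 1}" for i in range(n_outgroup)]
    ing_clade = _ladder(ingroup, 0.05)
    out_clade = _ladder(outgroup, 0.05)
    ing_clade.length = 0.08  # ingroup stem
    out_clade.length = 0.08
    tree = Node(children=[ing_clade, out_clade])
    return SpeciesDesign(
        species_ids=ingroup + outgroup, ingroup_ids=ingroup, guide_tree=tree
    )


def default_family_specs() -> list[FamilySpec]:
    """One shared family (4 subfamilies across all species) and one
    clade-specific family (2 subfamilies, ingroup only)."""
    return [
        FamilySpec("famA", n_subfamilies=4, clade_specific=False),
        FamilySpec("famB", n_subfamilies=2, clade_specific=True),
    ]


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _mutate(seq: np.ndarray, n_mut: int, rng: np.random.Generator) -> np.ndarray:
    """Replace n_mut distinct positions with a uniformly chosen *different*
    residue (guarantees each touched position changes)."""
    out = seq.copy()
    n_mut = min(n_mut, len(seq))
    if n_mut <= 0:
        return out
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    shift = rng.integers(1, _N_AA, size=n_mut)
    out[pos] = (out[pos] + shift) % _N_AA
    return out


def _evolve(
    tree: Node, root_seq: np.ndarray, rate: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Evolve a sequence down the guide tree; returns leaf-name -> sequence."""
    leaves: dict[str, np.ndarray] = {}
    length = len(root_seq)

    def walk(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf():
            leaves[node.name] = seq
            return
        for child in node.children:
            n_mut = int(round(rate * child.length * length))
            walk(child, _mutate(seq, n_mut, rng))

    walk(tree, root_seq)
    return leaves


def _hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a == b))


def _min_within(leafsets: list[dict[str, np.ndarray]]) -> float:
    best = 1.0
    for leaves in leafsets:
        seqs = list(leaves.values())
        for a, b in itertools.combinations(seqs, 2):
            best = min(best, _hamming_identity(a, b))
    return best


def _max_between(leafsets: list[dict[str, np.ndarray]]) -> float:
    worst = 0.0
    for la, lb in itertools.combinations(leafsets, 2):
        for a in la.values():
            for b in lb.values():
                worst = max(worst, _hamming_identity(a, b))
    return worst


def _min_within_nw(leafsets) -> float:
    best = 1.0
    for leaves in leafsets:
        seqs = [_decode(s) for s in leaves.values()]
        for a, b in itertools.combinations(seqs, 2):
            best = min(best, pairwise_identity(a, b))
    return best


def _max_between_nw(leafsets) -> float:
    worst = 0.0
    for la, lb in itertools.combinations(leafsets, 2):
        sa = [_decode(s) for s in la.values()]
        sb = [_decode(s) for s in lb.values()]
        for a in sa:
            for b in sb:
                worst = max(worst, pairwise_identity(a, b))
    return worst


def simulate_gene_families(
    design: SpeciesDesign,
    specs: list[FamilySpec],
    decoy_count: int = 40,
    seed: int = 0,
) -> tuple[dict[str, list[ProteinRecord]], TruthTable]:
    """Plant gene families on the guide tree; see module docstring.

    Returns per-species proteomes and the ground-truth table. Use
    :func:`simulate_bundle` to also keep the families' seed alignments.
    """
    proteomes, truth, _ = _simulate_gene_families_full(design, specs, decoy_count, seed)
    return proteomes, truth


def _simulate_gene_families_full(
    design: SpeciesDesign,
    specs: list[FamilySpec],
    decoy_count: int,
    seed: int,
) -> tuple[dict[str, list[ProteinRecord]], TruthTable, dict[str, list[str]]]:
    """Plant gene families on the guide tree and return per-species
    proteomes plus the truth table.

    Each family descends from a random ancestral sequence; subfamily
    ancestors diverge from it by a bisected mutation count so realized
    between-subfamily identity stays at or below ``between_identity``,
    and leaves evolve along the guide tree at a bisected rate so realized
    within-subfamily identity stays at or above ``within_identity``.
    Clade-specific families are evolved over the ingroup clade only.
    Decoys are i.i.d. uniform-residue sequences with lengths in [200, 800],
    so some deliberately violate the (350, 650) length filter.

    Pathway genes (planted as highly expressed downstream) are the members
    of clade-specific subfamilies in the first ingroup species.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    ss = np.random.SeedSequence(seed)
    fam_seeds = ss.spawn(len(specs) + 1)

    genes: dict[str, GeneTruth] = {}
    sf_specific: dict[str, bool] = {}
    proteomes: dict[str, list[ProteinRecord]] = {sp: [] for sp in design.species_ids}
    seed_alignments: dict[str, list[str]] = {}
    counter = itertools.count(1)

    ing_clade = design.guide_tree.find_clade(set(design.ingroup_ids))
    focal = design.ingroup_ids[0]
    pathway: list[str] = []

    for spec, fam_ss in zip(specs, fam_seeds):
        tree = ing_clade if spec.clade_specific else design.guide_tree
        leafsets, ancestors = _generate_family(spec, tree, fam_ss)
        seed_alignments[spec.family_id] = [_decode(a) for a in ancestors]
        for k, leaves in enumerate(leafsets):
            sf_id = f"{spec.family_id}.{k + 1}"
            sf_specific[sf_id] = spec.clade_specific
            rng_copy = np.random.default_rng(fam_ss.spawn(1)[0])
            for sp in sorted(leaves):
                for copy in range(spec.members_per_species):
                    seq = leaves[sp]
                    if copy > 0:  # near-identical in-paralog
                        seq = _mutate(seq, max(1, len(seq) // 200), rng_copy)
                    gid = f"g{next(counter):05d}"
                    genes[gid] = GeneTruth(
                        species=sp,
                        family_id=spec.family_id,
                        subfamily_id=sf_id,
                        is_domain_bearing=True,
                    )
                    proteomes[sp].append(ProteinRecord(gid, sp, _decode(seq)))
                    if spec.clade_specific and sp == focal:
                        pathway.append(gid)

    rng_decoy = np.random.default_rng(fam_seeds[-1])
    for d in range(decoy_count):
        sp = design.species_ids[d % len(design.species_ids)]
        length = int(rng_decoy.integers(200, 801))
        seq = rng_decoy.integers(0, _N_AA, size=length).astype(np.int8)
        gid = f"g{next(counter):05d}"
        genes[gid] = GeneTruth(
            species=sp, family_id=None, subfamily_id=None, is_domain_bearing=False
        )
        proteomes[sp].append(ProteinRecord(gid, sp, _decode(seq)))

    truth = TruthTable(
        genes=genes, subfamily_specific=sf_specific, pathway_genes=pathway
    )
    _assert_clade_specific(truth, design)
    return proteomes, truth, seed_alignments


def _generate_family(
    spec: FamilySpec, tree: Node, fam_ss: np.random.SeedSequence
) -> tuple[list[dict[str, np.ndarray]], list[np.ndarray]]:
    length = spec.domain_length
    root_rng = np.random.default_rng(fam_ss)
    ancestor = root_rng.integers(0, _N_AA, size=length).astype(np.int8)

    # max leaf-to-leaf path length on the evolution tree
    dist, _ = _leaf_paths(tree)
    max_path = max(dist) if dist else 1.0

    gen_ss = np.random.SeedSequence(
        entropy=fam_ss.entropy, spawn_key=tuple(fam_ss.spawn_key) + (7,)
    )

    def gen(rate: float, k_between: int):
        # fresh generator from the same seed: every candidate evaluation
        # replays an identical stream, making the bisection well-behaved
        rng = np.random.default_rng(gen_ss)
        ancestors = [
            _mutate(ancestor, k_between, rng) for _ in range(spec.n_subfamilies)
        ]
        leafsets = [_evolve(tree, anc, rate, rng) for anc in ancestors]
        return leafsets, ancestors

    # --- within: largest rate keeping min within-identity >= target
    hi0 = 0.8 * (1.0 - spec.within_identity) / max(max_path, 1e-9)
    rate = 0.0
    if hi0 > 0:
        if _min_within(gen(hi0, 0)[0]) >= spec.within_identity:
            rate = hi0
        else:
            lo, hi = 0.0, hi0
            for _ in range(20):
                mid = 0.5 * (lo + hi)
                if _min_within(gen(mid, 0)[0]) >= spec.within_identity:
                    lo = mid
                else:
                    hi = mid
            rate = lo

    # --- between: smallest ancestor divergence count meeting the ceiling
    k = 0
    if spec.n_subfamilies > 1:
        if _max_between(gen(rate, length)[0]) > spec.between_identity:
            raise RuntimeError(
                f"family {spec.family_id}: between_identity target "
                f"{spec.between_identity} unreachable at full divergence"
            )
        lo, hi = 0, length
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if _max_between(gen(rate, mid)[0]) <= spec.between_identity:
                hi = mid
            else:
                lo = mid
        k = hi

    # Final generation + loud verification. The bisection uses the cheap
    # Hamming identity (exact for indel-free evolution); the verification
    # additionally uses the alignment-based identity that downstream
    # clustering measures, since a score-maximizing aligner can nudge
    # identity slightly above the positional value.
    for attempt in range(8):
        leafsets, ancestors = gen(rate, k)
        ok_within = (
            _min_within(leafsets) >= spec.within_identity
            and _min_within_nw(leafsets) >= spec.within_identity
        )
        ok_between = spec.n_subfamilies < 2 or (
            _max_between(leafsets) <= spec.between_identity
            and _max_between_nw(leafsets) <= spec.between_identity
        )
        if ok_within and ok_between:
            return leafsets, ancestors
        if not ok_within:
            rate *= 0.7
        if not ok_between:
            k = min(length, k + max(1, length // 50))
    raise RuntimeError(
        f"family {spec.family_id}: could not realize identity targets "
        f"(within >= {spec.within_identity}, between <= {spec.between_identity})"
    )


def _leaf_paths(tree: Node) -> tuple[list[float], int]:
    """Leaf-to-leaf path lengths (branch-length sums) and leaf count."""
    paths: list[float] = []

    def walk(node: Node) -> list[float]:
        if node.is_leaf():
            return [node.length]
        below = [walk(c) for c in node.children]
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a in below[i]:
                    for b in below[j]:
                        paths.append(a + b)
        return [d + node.length for sub in below for d in sub]

    walk(tree)
    return paths, len(tree.leaves())


def _decode(seq: np.ndarray) -> str:
    return _AA_ARR[np.asarray(seq, dtype=np.intp)].tobytes().decode()


def _assert_clade_specific(truth: TruthTable, design: SpeciesDesign) -> None:
    outgroup = set(design.outgroup_ids)
    for gid, t in truth.genes.items():
        if t.subfamily_id and truth.subfamily_specific[t.subfamily_id]:
            assert t.species not in outgroup, (
                f"clade-specific gene {gid} found in outgroup species {t.species}"
            )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

# log-scale parameters of the FPKM-like baseline; see docs/methods.md
_LOG_BASE_MEAN = np.log(8.0)
_LOG_BASE_SD = 1.2
_GROUP_EFFECT_SD = 0.25
_SAMPLE_NOISE_SD = 0.4
_PATHWAY_SHIFT = 3.0
_PATHWAY_SD = 0.5


def simulate_expression(
    truth: TruthTable,
    n_wild: int = 5,
    n_cultivated: int = 6,
    seed: int = 0,
) -> ExpressionTable:
    """FPKM-like expression for every gene of the truth table.

    A log-normal baseline per gene is shared across groups; per-group mean
    multipliers are mildly perturbed (so wild and cultivated means are
    correlated), pathway genes draw their baseline from a shifted (high)
    distribution, and per-sample noise is independent. Deterministic under
    a fixed seed.
    """
    if n_wild < 1 or n_cultivated < 1:
        raise ValueError("need at least one sample per group")
    if not truth.genes:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    genes = sorted(truth.genes)
    n = len(genes)
    base = np.exp(rng.normal(_LOG_BASE_MEAN, _LOG_BASE_SD, size=n))
    is_pathway = np.isin(genes, truth.pathway_genes)
    base[is_pathway] = np.exp(
        rng.normal(_LOG_BASE_MEAN + _PATHWAY_SHIFT, _PATHWAY_SD, size=is_pathway.sum())
    )
    wild_mean = base * np.exp(rng.normal(0.0, _GROUP_EFFECT_SD, size=n))
    cult_mean = base * np.exp(rng.normal(0.0, _GROUP_EFFECT_SD, size=n))

    cols, data, groups = [], [], {}
    for i in range(n_wild):
        name = f"wild_{i + 1}"
        cols.append(name)
        groups[name] = "wild"
        data.append(wild_mean * np.exp(rng.normal(0.0, _SAMPLE_NOISE_SD, size=n)))
    for i in range(n_cultivated):
        name = f"cult_{i + 1}"
        cols.append(name)
        groups[name] = "cultivated"
        data.append(cult_mean * np.exp(rng.normal(0.0, _SAMPLE_NOISE_SD, size=n)))
    frame = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    frame.index.name = "gene"
    return ExpressionTable(values=frame, groups=groups)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


def simulate_kinetics(
    km: float,
    kcat: float,
    enzyme_conc: float,
    concs,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticDataset:
    """Michaelis-Menten initial rates v = kcat*E0*S/(Km+S) with
    multiplicative Gaussian noise (1 + N(0, noise_sd)); noise_sd = 0 yields
    exact closed-form rates."""
    if km <= 0 or kcat <= 0 or enzyme_conc <= 0:
        raise ValueError("km, kcat and enzyme_conc must be positive")
    s = np.asarray(concs, dtype=float)
    if (s <= 0).any():
        raise ValueError("substrate concentrations must be strictly positive")
    v = kcat * enzyme_conc * s / (km + s)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
        v = v * (1.0 + rng.normal(0.0, noise_sd, size=s.shape))
        v = np.clip(v, 0.0, None)
    return KineticDataset(
        substrate_concs=s, rates=v, enzyme_conc=enzyme_conc, noise_sd=noise_sd
    )


# ---------------------------------------------------------------------------
# One-call bundle + fixture IO
# ---------------------------------------------------------------------------


def simulate_bundle(
    design: SpeciesDesign | None = None,
    specs: list[FamilySpec] | None = None,
    decoy_count: int = 40,
    n_wild: int = 5,
    n_cultivated: int = 6,
    seed: int = 0,
) -> SyntheticBundle:
    """Simulate proteomes, truth, seed alignments and expression in one go."""
    design = design or default_design()
    specs = specs or default_family_specs()
    proteomes, truth, seed_alignments = _simulate_gene_families_full(
        design, specs, decoy_count, seed
    )
    expression = simulate_expression(truth, n_wild, n_cultivated, seed=seed)
    return SyntheticBundle(
        proteomes=proteomes,
        truth=truth,
        seed_alignments=seed_alignments,
        expression=expression,
    )


def write_fixture(bundle: SyntheticBundle, directory) -> list[Path]:
    """Write a bundle to plain-text files.

    Layout: ``proteomes/<species>.fasta`` (headers ``species|gene``),
    ``seed_alignment_<family>.fasta``, ``expression.tsv``, ``truth.json``
    (truth table plus the sample group map), ``kinetics_<name>.csv``.
    Reading back with :func:`read_fixture` reproduces the bundle exactly.
    """
    directory = Path(directory)
    (directory / "proteomes").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for sp in sorted(bundle.proteomes):
        path = directory / "proteomes" / f"{sp}.fasta"
        records = [
            SeqRecord(Seq(p.sequence), id=f"{p.species}|{p.gene}", description="")
            for p in bundle.proteomes[sp]
        ]
        SeqIO.write(records, path, "fasta")
        written.append(path)
    for fam, aln in sorted(bundle.seed_alignments.items()):
        path = directory / f"seed_alignment_{fam}.fasta"
        SeqIO.write(
            [
                SeqRecord(Seq(s), id=f"{fam}|anc{i + 1}", description="")
                for i, s in enumerate(aln)
            ],
            path,
            "fasta",
        )
        written.append(path)
    payload = {
        "truth": bundle.truth.model_dump(),
        "groups": bundle.expression.groups if bundle.expression else {},
    }
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    written.append(truth_path)
    if bundle.expression is not None:
        expr_path = directory / "expression.tsv"
        bundle.expression.values.to_csv(expr_path, sep="\t", float_format="%.17g")
        written.append(expr_path)
    for name, kin in sorted(bundle.kinetics.items()):
        path = directory / f"kinetics_{name}.csv"
        frame = pd.DataFrame(
            {"S_uM": kin.substrate_concs, "rate_uM_per_s": kin.rates}
        )
        with open(path, "w") as fh:
            fh.write(f"# enzyme_conc_uM={kin.enzyme_conc!r} noise_sd={kin.noise_sd!r}\n")
            frame.to_csv(fh, index=False, float_format="%.17g")
        written.append(path)
    return written


def parse_fasta_header(header: str) -> tuple[str, str]:
    """Split a ``species|gene`` FASTA id."""
    species, _, gene = header.partition("|")
    if not gene:
        raise ValueError(f"FASTA header {header!r} is not 'species|gene'")
    return species, gene


def read_fixture(directory) -> SyntheticBundle:
    """Inverse of :func:`write_fixture`."""
    directory = Path(directory)
    proteomes: dict[str, list[ProteinRecord]] = {}
    for path in sorted((directory / "proteomes").glob("*.fasta")):
        records = []
        for rec in SeqIO.parse(path, "fasta"):
            species, gene = parse_fasta_header(rec.id)
            records.append(ProteinRecord(gene, species, str(rec.seq)))
        proteomes[path.stem] = records
    seed_alignments: dict[str, list[str]] = {}
    for path in sorted(directory.glob("seed_alignment_*.fasta")):
        fam = path.stem.removeprefix("seed_alignment_")
        seed_alignments[fam] = [str(r.seq) for r in SeqIO.parse(path, "fasta")]
    payload = json.loads((directory / "truth.json").read_text())
    truth = TruthTable.model_validate(payload["truth"])
    expression = None
    expr_path = directory / "expression.tsv"
    if expr_path.exists():
        frame = pd.read_csv(
            expr_path, sep="\t", index_col="gene", float_precision="round_trip"
        )
        expression = ExpressionTable(values=frame, groups=payload["groups"])
    kinetics: dict[str, KineticDataset] = {}
    for path in sorted(directory.glob("kinetics_*.csv")):
        name = path.stem.removeprefix("kinetics_")
        header = path.read_text().splitlines()[0]
        meta = dict(
            item.split("=") for item in header.lstrip("# ").split() if "=" in item
        )
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
        kinetics[name] = KineticDataset(
            substrate_concs=frame["S_uM"].to_numpy(),
            rates=frame["rate_uM_per_s"].to_numpy(),
            enzyme_conc=float(meta["enzyme_conc_uM"]),
            noise_sd=float(meta["noise_sd"]),
        )
    return SyntheticBundle(
        proteomes=proteomes,
        truth=truth,
        seed_alignments=seed_alignments,
        expression=expression,
        kinetics=kinetics,
    )
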