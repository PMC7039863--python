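"""Synthetic communities with known ground truth for end-to-end validation.

The generator emulates the structure the census pipeline assumes about real
metagenomes: a community of genomes with lognormal relative abundances;
exactly one single-copy marker per genome (recA in bacteria, β-actin in
eukaryotes); organosulfur gene families planted into a deterministic number
of carrier genomes at a chosen sequence divergence from their ratified
references; background genes drawn at background residue composition; and
per-sample read counts Poisson-distributed proportional to genome abundance
times gene length.

All randomness flows from one seed through named substreams (community
structure, sequence mutation, read counts), so every fixture is exactly
reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import AMINO_ACIDS, BACKGROUND
from .catalog import GeneRecord
from .census import BACTERIAL, EUKARYOTIC
from .errors import AbsentFamilyWarning, ParameterError
from .profiles import DEFAULT_SEED, TrainingSet
from .taxonomy import TaxNode, TaxonomyTree

BACKGROUND_LABEL = "background"

# substream tags hashed into the seed sequence
_STREAM_COMMUNITY = 0
_STREAM_MUTATION = 1
_STREAM_COUNTS = 2


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, *extra]))


def random_protein(length: int, rng: np.random.Generator) -> str:
    """I.i.d. background-composition protein sequence."""
    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=BACKGROUND))


def _substitution_kernel() -> np.ndarray:
    """P(replacement b | original a) ∝ bg(b)·exp(λ·BLOSUM62(a,b)), b ≠ a."""
    blosum = substitution_matrices.load("BLOSUM62")
    lam = math.log(2.0) / 2.0  # BLOSUM62 half-bit scale
    kernel = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i == j:
                continue
            kernel[i, j] = BACKGROUND[j] * math.exp(lam * blosum[a, b])
        kernel[i] /= kernel[i].sum()
    return kernel


_KERNEL: np.ndarray | None = None


def mutate_family_sequence(
    reference: str,
    divergence: float,
    seed: int | np.random.Generator = DEFAULT_SEED,
) -> str:
    """Substitute exactly ``round(divergence × length)`` positions.

    Replacements are drawn from a similarity-biased kernel (BLOSUM62-weighted
    background), emulating accepted point mutations. No indels.
    """
    if not (0.0 <= divergence <= 0.6):
        raise ParameterError(f"divergence {divergence} outside validated range [0, 0.6]")
    global _KERNEL
    if _KERNEL is None:
        _KERNEL = _substitution_kernel()
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _STREAM_MUTATION)
    n_sub = round(divergence * len(reference))
    if n_sub == 0:
        return reference
    positions = rng.choice(len(reference), size=n_sub, replace=False)
    out = list(reference)
    for pos in positions:
        a = AMINO_ACIDS.index(out[pos])
        out[pos] = AMINO_ACIDS[rng.choice(20, p=_KERNEL[a])]
    return "".join(out)


# --- bundled synthetic reference families ----------------------------------


@dataclass
class FamilyReference:
    """Synthetic stand-in for a ratified enzyme family (ancestor + training set)."""

    family_name: str
    ancestor: str
    training: TrainingSet


_BUNDLED_LENGTHS = {
    "DsyB": 200, "DddP": 230, "DmdA": 210, "MddA": 180, "DmoA": 240,
    "Alma1": 190, "DSYB": 200, "RecA": 210, "BetaActin": 220,
}


def bundled_reference_families(
    seed: int = DEFAULT_SEED,
    families: list[str] | None = None,
    n_positives: int = 5,
    n_negatives: int = 4,
    training_divergence: float = 0.15,
    lengths: dict[str, int] | None = None,
) -> dict[str, FamilyReference]:
    """Generate the package's bundled synthetic training families.

    Each family gets a random ancestor protein, ``n_positives`` aligned
    "ratified" positives at ``training_divergence`` from the ancestor, and
    negatives drawn from other families' ancestors plus random background
    proteins — different-function decoys for cutoff and verification tests.
    """
    names = families or list(_BUNDLED_LENGTHS)
    lengths = {**_BUNDLED_LENGTHS, **(lengths or {})}
    rng = _rng(seed, _STREAM_COMMUNITY, 17)
    ancestors = {name: random_protein(lengths.get(name, 200), rng) for name in names}
    out: dict[str, FamilyReference] = {}
    for name in names:
        mut_rng = _rng(seed, _STREAM_MUTATION, 17, names.index(name))
        positives = [
            mutate_family_sequence(ancestors[name], training_divergence, mut_rng)
            for _ in range(n_positives)
        ]
        others = [n for n in names if n != name]
        negatives = []
        for j in range(n_negatives):
            if j < len(others) and j % 2 == 0:
                negatives.append(
                    mutate_family_sequence(ancestors[others[j]], training_divergence, mut_rng)
                )
            else:
                negatives.append(random_protein(len(ancestors[name]), mut_rng))
        out[name] = FamilyReference(
            family_name=name,
            ancestor=ancestors[name],
            training=TrainingSet(name, positives, negatives),
        )
    return out


# --- taxonomy fixture ------------------------------------------------------


def synthetic_taxonomy(
    n_genera_bacteria: int = 12,
    n_genera_eukaryota: int = 4,
    genera_per_family: int = 2,
    families_per_order: int = 2,
) -> tuple[TaxonomyTree, dict[str, list[str]]]:
    """Deterministic rank-complete taxonomy with the requested genus counts.

    Returns the tree and a map domain -> genus node ids.
    """
    nodes: dict[str, TaxNode] = {"root": TaxNode(None, "root", "root")}
    genus_ids: dict[str, list[str]] = {}
    for domain, short, n_genera in (
        ("Bacteria", "B", n_genera_bacteria),
        ("Eukaryota", "E", n_genera_eukaryota),
    ):
        if n_genera == 0:
            genus_ids[BACTERIAL if short == "B" else EUKARYOTIC] = []
            continue
        nodes[short] = TaxNode("root", "domain", domain)
        genera = []
        n_families = math.ceil(n_genera / genera_per_family)
        n_orders = math.ceil(n_families / families_per_order)
        for o in range(n_orders):
            phylum = f"{short}_p{o}"
            nodes[phylum] = TaxNode(short, "phylum", f"{domain}Phylum{o}")
            clazz = f"{short}_c{o}"
            nodes[clazz] = TaxNode(phylum, "class", f"{domain}Class{o}")
            order = f"{short}_o{o}"
            nodes[order] = TaxNode(clazz, "order", f"{domain}Order{o}")
        for f in range(n_families):
            order = f"{short}_o{f // families_per_order}"
            family = f"{short}_f{f}"
            nodes[family] = TaxNode(order, "family", f"{domain}Family{f}")
        for g in range(n_genera):
            family = f"{short}_f{g // genera_per_family}"
            genus = f"{short}_g{g}"
            nodes[genus] = TaxNode(family, "genus", f"{domain}Genus{g}")
            genera.append(genus)
        genus_ids[BACTERIAL if short == "B" else EUKARYOTIC] = genera
    tree = TaxonomyTree(nodes=nodes, root="root")
    return tree, genus_ids


# --- community generation --------------------------------------------------


@dataclass
class FamilyCarriage:
    """Planting instructions for one gene family."""

    carriage_fraction: float
    copies_per_carrier: int = 1
    domain: str = BACTERIAL
    divergence: float = 0.30

    def __post_init__(self):
        if not (0.0 <= self.carriage_fraction <= 1.0):
            raise ParameterError(f"carriage fraction {self.carriage_fraction} outside [0, 1]")
        if self.copies_per_carrier < 1:
            raise ParameterError("copies_per_carrier must be >= 1")


CarriageSpec = dict[str, FamilyCarriage]


@dataclass
class SynGene:
    gene_id: str
    genome_id: str
    family: str  # family name, marker name, or "background"
    protein: str
    nt_length: int


@dataclass
class SynGenome:
    genome_id: str
    domain: str
    taxon_id: str
    relative_abundance: float
    genes: list[SynGene] = field(default_factory=list)


@dataclass
class GroundTruth:
    """What was actually planted, in both genome-count and cell-fraction terms."""

    carriage: dict[str, float]  # family -> fraction of domain genomes carrying it
    cell_fraction: dict[str, float]  # family -> abundance-weighted carrier fraction (%)
    carriers: dict[str, list[str]]  # family -> carrier genome ids
    genus_carrier_abundance: dict[str, dict[str, float]]  # family -> genus node -> abundance


@dataclass
class SyntheticCommunity:
    genomes: list[SynGenome]
    truth: GroundTruth
    seed: int

    def all_genes(self) -> list[SynGene]:
        return [g for genome in self.genomes for g in genome.genes]


@dataclass
class ReadSimConfig:
    """Read-count simulation settings.

    ``mean_depth`` is the expected read count of an average-length gene in a
    genome of relative abundance 1; for a community of N roughly equal
    genomes, ``mean_depth = N × r`` yields about ``r`` reads per gene.
    """

    mean_depth: float
    seed: int = DEFAULT_SEED
    background_length_mean: float = 200.0
    background_length_sd: float = 40.0

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ParameterError("mean_depth must be non-negative")


def _protein_nt_length(protein: str) -> int:
    return 3 * (len(protein) + 1)  # CDS includes the stop codon


def generate_community(
    n_genomes: int,
    spec: CarriageSpec,
    taxonomy: TaxonomyTree | None = None,
    abundance_sigma: float = 1.0,
    seed: int = DEFAULT_SEED,
    n_eukaryotes: int = 0,
    background_genes: int = 3,
    references: dict[str, FamilyReference] | None = None,
    marker_divergence: float = 0.15,
    length_model: tuple[float, float] = (200.0, 40.0),
) -> SyntheticCommunity:
    """Generate a community with deterministic family planting.

    Exactly ``round(fraction × n_domain)`` genomes per family carry that
    family (chosen by seeded shuffle); every bacterial genome carries one
    recA and every eukaryotic genome one β-actin, each mutated from the
    bundled marker reference. Relative abundances are lognormal(0, sigma),
    normalized to 1.
    """
    if n_genomes < 10:
        raise ParameterError("n_genomes must be >= 10")
    if n_eukaryotes > n_genomes:
        raise ParameterError("n_eukaryotes exceeds n_genomes")
    references = references or bundled_reference_families(seed)
    genus_ids: dict[str, list[str]] = {BACTERIAL: [], EUKARYOTIC: []}
    if taxonomy is None:
        taxonomy, genus_ids = synthetic_taxonomy()
    else:
        for nid, node in taxonomy.nodes.items():
            if node.rank == "genus":
                domain_node = taxonomy.ancestor_at_rank(nid, "domain")
                domain_name = taxonomy.name(domain_node) if domain_node else ""
                key = EUKARYOTIC if domain_name.lower().startswith("euk") else BACTERIAL
                genus_ids[key].append(nid)
        for key in genus_ids:
            genus_ids[key].sort()

    n_bacteria = n_genomes - n_eukaryotes
    rng_comm = _rng(seed, _STREAM_COMMUNITY)
    rng_mut = _rng(seed, _STREAM_MUTATION)

    if abundance_sigma < 0:
        raise ParameterError("abundance_sigma must be >= 0")
    raw = (
        np.ones(n_genomes)
        if abundance_sigma == 0
        else rng_comm.lognormal(0.0, abundance_sigma, size=n_genomes)
    )
    abundances = raw / raw.sum()

    genomes: list[SynGenome] = []
    length_mean, length_sd = length_model
    for i in range(n_genomes):
        domain = BACTERIAL if i < n_bacteria else EUKARYOTIC
        genome_id = f"G{i:04d}"
        genera = genus_ids[domain]
        taxon = genera[int(rng_comm.integers(len(genera)))] if genera else taxonomy.root
        genome = SynGenome(
            genome_id=genome_id,
            domain=domain,
            taxon_id=taxon,
            relative_abundance=float(abundances[i]),
        )
        marker = "RecA" if domain == BACTERIAL else "BetaActin"
        marker_seq = mutate_family_sequence(
            references[marker].ancestor, marker_divergence, rng_mut
        )
        genome.genes.append(
            SynGene(
                gene_id=f"{genome_id}_{marker}",
                genome_id=genome_id,
                family=marker,
                protein=marker_seq,
                nt_length=_protein_nt_length(marker_seq),
            )
        )
        for b in range(background_genes):
            length = max(60, int(round(rng_comm.normal(length_mean, length_sd))))
            prot = random_protein(length, rng_comm)
            genome.genes.append(
                SynGene(
                    gene_id=f"{genome_id}_bg{b}",
                    genome_id=genome_id,
                    family=BACKGROUND_LABEL,
                    protein=prot,
                    nt_length=_protein_nt_length(prot),
                )
            )
        genomes.append(genome)

    truth = GroundTruth(carriage={}, cell_fraction={}, carriers={}, genus_carrier_abundance={})
    for family, carriage in sorted(spec.items()):
        domain_genomes = [g for g in genomes if g.domain == carriage.domain]
        n_domain = len(domain_genomes)
        n_carriers = round(carriage.carriage_fraction * n_domain) if n_domain else 0
        if n_carriers == 0:
            if carriage.carriage_fraction > 0:
                warnings.warn(
                    f"family {family}: requested carriage "
                    f"{carriage.carriage_fraction:.3f} rounds to zero carriers",
                    AbsentFamilyWarning,
                )
            truth.carriage[family] = 0.0
            truth.cell_fraction[family] = 0.0
            truth.carriers[family] = []
            truth.genus_carrier_abundance[family] = {}
            continue
        order = rng_comm.permutation(n_domain)
        carriers = [domain_genomes[j] for j in order[:n_carriers]]
        ancestor = references[family].ancestor
        for genome in carriers:
            for c in range(carriage.copies_per_carrier):
                prot = mutate_family_sequence(ancestor, carriage.divergence, rng_mut)
                genome.genes.append(
                    SynGene(
                        gene_id=f"{genome.genome_id}_{family}_{c}",
                        genome_id=genome.genome_id,
                        family=family,
                        protein=prot,
                        nt_length=_protein_nt_length(prot),
                    )
                )
        domain_total = sum(g.relative_abundance for g in domain_genomes)
        carrier_total = sum(g.relative_abundance for g in carriers)
        truth.carriage[family] = n_carriers / n_domain
        truth.cell_fraction[family] = 100.0 * carrier_total / domain_total
        truth.carriers[family] = sorted(g.genome_id for g in carriers)
        genus_abundance: dict[str, float] = {}
        for genome in carriers:
            genus_abundance[genome.taxon_id] = (
                genus_abundance.get(genome.taxon_id, 0.0) + genome.relative_abundance
            )
        truth.genus_carrier_abundance[family] = genus_abundance

    return SyntheticCommunity(genomes=genomes, truth=truth, seed=seed)


def depth_for_mean_reads(community: SyntheticCommunity, reads_per_gene: float) -> float:
    """Depth setting giving an expected ``reads_per_gene`` for an average gene."""
    n = len(community.genomes)
    return reads_per_gene * n


def simulate_counts(
    community: SyntheticCommunity,
    config: ReadSimConfig,
    n_samples: int = 1,
    exact: bool = False,
) -> list[GeneRecord]:
    """Per-sample Poisson read counts proportional to abundance × gene length.

    Expected count of gene g in every sample is
    ``mean_depth × abundance(genome of g) × nt_length(g) / mean nt_length``;
    samples are independent with per-sample substream seeds. With
    ``exact=True`` the expectation itself is returned (no sampling), which
    isolates estimator behaviour from counting noise.
    """
    genes = community.all_genes()
    mean_length = float(np.mean([g.nt_length for g in genes]))
    abundance = {g.genome_id: g.relative_abundance for g in community.genomes}
    records = [
        GeneRecord(
            gene_id=g.gene_id,
            contig_id=f"C_{g.genome_id}",
            nt_length=g.nt_length,
            protein=g.protein,
            counts={},
        )
        for g in genes
    ]
    for s in range(n_samples):
        sample_id = f"S{s + 1}"
        rng = _rng(config.seed, _STREAM_COUNTS, s)
        for gene, record in zip(genes, records):
            expected = (
                config.mean_depth * abundance[gene.genome_id] * gene.nt_length / mean_length
            )
            count = expected if exact else float(rng.poisson(expected))
            record.counts[sample_id] = count
    return records
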