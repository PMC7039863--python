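"""Non-redundant gene catalog construction and length-normalized abundances.

The catalog step mirrors standard metagenomic gene-catalog practice:
contigs shorter than a minimum length are dropped, predicted genes are
clustered greedily at 95% identity / 90% coverage with the longest member
of each cluster as representative, and per-sample read counts are converted
to reads-per-base abundances, discarding (gene, sample) pairs with fewer
than two mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import identity_coverage
from .errors import DivisionGuardError, ParameterError


@dataclass
class Contig:
    contig_id: str
    length: int


@dataclass
class GeneRecord:
    """A predicted protein-coding gene with per-sample mapped-read counts."""

    gene_id: str
    contig_id: str
    nt_length: int
    protein: str
    counts: dict[str, float] = field(default_factory=dict)


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str]


class AbundanceTable:
    """Sparse (gene, sample) -> reads-per-base abundance map."""

    def __init__(self, entries: dict[tuple[str, str], float] | None = None):
        self.entries: dict[tuple[str, str], float] = dict(entries or {})

    def abundance(self, gene_id: str, sample_id: str, default: float = 0.0) -> float:
        return self.entries.get((gene_id, sample_id), default)

    def samples(self) -> list[str]:
        return sorted({s for (_, s) in self.entries})

    def genes(self) -> list[str]:
        return sorted({g for (g, _) in self.entries})

    def sample_total(self, sample_id: str) -> float:
        return sum(v for (g, s), v in self.entries.items() if s == sample_id)

    def scaled(self, sample_id: str, factor: float) -> "AbundanceTable":
        """Return a copy with one sample's abundances multiplied by ``factor``."""
        return AbundanceTable(
            {
                key: (v * factor if key[1] == sample_id else v)
                for key, v in self.entries.items()
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "sample_id": s, "abundance": v}
            for (g, s), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "sample_id", "abundance"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceTable":
        return cls(
            {
                (str(r.gene_id), str(r.sample_id)): float(r.abundance)
                for r in frame.itertuples()
            }
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, AbundanceTable) and self.entries == other.entries


def filter_contigs(contigs: list[Contig], min_length: int = 500) -> list[Contig]:
    """Keep contigs strictly longer than ``min_length`` (default 500 bp)."""
    return [c for c in contigs if c.length > min_length]


def cluster_genes(
    genes: list[GeneRecord],
    identity: float = 0.95,
    coverage: float = 0.90,
) -> list[Cluster]:
    """Greedy incremental clustering by identity over the aligned region.

    Genes are processed in decreasing nucleotide length (ties broken by
    gene id); each joins the first cluster whose representative it matches at
    >= ``identity`` over >= ``coverage`` of the shorter sequence, else founds
    a new cluster. The representative is the longest member, which under the
    greedy order is the founding gene.
    """
    for name, value in (("identity", identity), ("coverage", coverage)):
        if not (0.0 < value <= 1.0):
            raise ParameterError(f"{name}={value} outside (0, 1]")
    order = sorted(genes, key=lambda g: (-g.nt_length, g.gene_id))
    reps: list[GeneRecord] = []
    members: list[list[str]] = []
    for gene in order:
        for ci, rep in enumerate(reps):
            idc = identity_coverage(gene.protein, rep.protein)
            if idc.identity >= identity and idc.coverage >= coverage:
                members[ci].append(gene.gene_id)
                break
        else:
            reps.append(gene)
            members.append([gene.gene_id])
    return [
        Cluster(representative_id=rep.gene_id, member_ids=sorted(mem))
        for rep, mem in zip(reps, members)
    ]


def compute_abundance(genes: list[GeneRecord], min_reads: float = 2) -> AbundanceTable:
    """Reads-per-base abundance per (gene, sample), dropping entries below ``min_reads``."""
    entries: dict[tuple[str, str], float] = {}
    for gene in genes:
        if gene.nt_length <= 0:
            raise DivisionGuardError(f"gene {gene.gene_id} has non-positive length")
        for sample_id, count in gene.counts.items():
            if count >= min_reads:
                entries[(gene.gene_id, sample_id)] = count / gene.nt_length
    return AbundanceTable(entries)
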