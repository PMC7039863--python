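"""Community census: candidate verification, marker denominators, gene-family fractions.

The census expresses each gene family's abundance as the percentage of the
bacterial (or eukaryotic) community carrying it: the summed reads-per-base
abundance of verified family genes divided by the summed abundance of a
universal single-copy marker — RecA for bacteria, β-actin for eukaryotes —
in the same sample, times 100. Because both numerator and denominator are
length-normalized read densities, sequencing depth and gene length cancel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import align
from .alphabet import degap
from .catalog import AbundanceTable, GeneRecord
from .errors import (
    MissingNegativesWarning,
    MultiCopyFractionWarning,
    UndefinedDenominatorError,
)
from .profiles import SearchHit, TrainingSet

logger = logging.getLogger(__name__)

BACTERIAL = "bacterial"
EUKARYOTIC = "eukaryotic"

# Static domain assignment of the census families: DSYB and Alma1 are
# algal/eukaryotic enzymes; every other family is bacterial.
FAMILY_DOMAINS: dict[str, str] = {
    family: BACTERIAL
    for family in (
        "DddD", "DddK", "DddL", "DddP", "DddQ", "DddY", "DddW",
        "DsyB", "MmtN", "DmdA", "DmdB", "DmdC", "DmdD", "AcuH",
        "MddA", "DmoA", "DdhA", "Tmm", "MTO", "DMSOR",
    )
}
FAMILY_DOMAINS["DSYB"] = EUKARYOTIC
FAMILY_DOMAINS["Alma1"] = EUKARYOTIC


@dataclass(frozen=True)
class MarkerSpec:
    """A single-copy marker gene and its E-value inclusion cutoff."""

    marker_name: str
    e_value_cutoff: float

    def __post_init__(self):
        if self.e_value_cutoff <= 0:
            raise ValueError("marker E-value cutoff must be positive")


RECA = MarkerSpec("RecA", 1e-50)
BETA_ACTIN = MarkerSpec("BetaActin", 1e-60)

MARKER_BY_DOMAIN = {BACTERIAL: RECA, EUKARYOTIC: BETA_ACTIN}


@dataclass
class SampleCensus:
    """Per-sample census: family fractions plus the raw sums behind them."""

    sample_id: str
    fractions: dict[str, float] = field(default_factory=dict)
    marker_abundance: dict[str, float] = field(default_factory=dict)
    gene_abundance: dict[str, float] = field(default_factory=dict)


def verify_candidates(
    hits: list[SearchHit],
    catalog: list[GeneRecord],
    training: dict[str, TrainingSet],
) -> list[SearchHit]:
    """Keep candidates that align most closely to the ratified references.

    Each candidate is locally aligned against every positive and negative of
    its family; it verifies only if its best-scoring reference is a positive
    (ties fail, conservatively). A gene hitting several families keeps only
    its highest bit-score family. Families without negatives fall back to
    cutoff-only acceptance with a warning.
    """
    by_gene: dict[str, SearchHit] = {}
    for hit in hits:
        current = by_gene.get(hit.gene_id)
        if current is None or hit.bit_score > current.bit_score:
            by_gene[hit.gene_id] = hit
    proteins = {g.gene_id: g.protein for g in catalog}
    out = []
    for hit in sorted(by_gene.values(), key=lambda h: h.gene_id):
        ts = training[hit.family_name]
        seq = proteins[hit.gene_id]
        if not ts.negatives:
            warnings.warn(
                f"family {hit.family_name} has no negative references; "
                "verification falls back to the score cutoff only",
                MissingNegativesWarning,
            )
            hit.verified = True
            out.append(hit)
            continue
        best_pos = max(align.local_score(seq, degap(p)) for p in ts.positives)
        best_neg = max(align.local_score(seq, degap(n)) for n in ts.negatives)
        hit.verified = best_pos > best_neg
        out.append(hit)
    return out


def marker_abundance(
    table: AbundanceTable,
    hits: list[SearchHit],
    marker: MarkerSpec,
    sample: str,
) -> float:
    """Summed abundance of marker hits within the marker's E-value cutoff."""
    total = 0.0
    for hit in hits:
        if hit.family_name != marker.marker_name:
            continue
        if hit.e_value <= marker.e_value_cutoff:
            total += table.abundance(hit.gene_id, sample)
    if total == 0.0:
        logger.warning(
            "sample %s: no %s abundance within E <= %.3g; fractions for this "
            "domain are undefined",
            sample, marker.marker_name, marker.e_value_cutoff,
        )
    return total


def community_fraction(
    table: AbundanceTable,
    verified: list[SearchHit],
    family: str,
    marker: MarkerSpec,
    sample: str,
    marker_hits: list[SearchHit] | None = None,
) -> float:
    """Percent of the marker-defined community carrying ``family`` in ``sample``.

    The denominator is the marker abundance computed from ``marker_hits``
    (or from ``verified`` if the marker hits are mixed in). Values above
    100% are reported unclamped — multi-copy families can exceed one copy
    per genome — with a warning.
    """
    denominator = marker_abundance(table, marker_hits if marker_hits is not None else verified,
                                   marker, sample)
    if denominator <= 0.0:
        raise UndefinedDenominatorError(
            f"sample {sample}: {marker.marker_name} denominator is zero"
        )
    numerator = sum(
        table.abundance(h.gene_id, sample)
        for h in verified
        if h.family_name == family and h.verified
    )
    fraction = 100.0 * numerator / denominator
    if fraction > 100.0:
        warnings.warn(
            f"sample {sample}, family {family}: fraction {fraction:.1f}% exceeds "
            "100% (multi-copy family?)",
            MultiCopyFractionWarning,
        )
    return fraction


def census_table(
    samples: list[str],
    table: AbundanceTable,
    verified: list[SearchHit],
    marker_hits: list[SearchHit],
    families: list[str],
    family_domains: dict[str, str] | None = None,
    markers: dict[str, MarkerSpec] | None = None,
    groups: dict[str, list[str]] | None = None,
) -> tuple[list[SampleCensus], dict[str, dict[str, float]]]:
    """Assemble per-sample censuses and arithmetic-mean group summaries.

    Samples in a group whose denominator is undefined for a family are
    excluded from that family's group mean (with a log note). Returns
    (censuses, group means as group -> family -> mean %).
    """
    family_domains = family_domains or FAMILY_DOMAINS
    markers = markers or MARKER_BY_DOMAIN
    known = set(samples)
    censuses: list[SampleCensus] = []
    needed_domains = {family_domains[f] for f in families}
    for sample in samples:
        census = SampleCensus(sample_id=sample)
        for domain, marker in markers.items():
            if domain not in needed_domains:
                continue
            census.marker_abundance[marker.marker_name] = marker_abundance(
                table, marker_hits, marker, sample
            )
        for family in families:
            marker = markers[family_domains[family]]
            census.gene_abundance[family] = sum(
                table.abundance(h.gene_id, sample)
                for h in verified
                if h.family_name == family and h.verified
            )
            try:
                census.fractions[family] = community_fraction(
                    table, verified, family, marker, sample, marker_hits=marker_hits
                )
            except UndefinedDenominatorError:
                census.fractions[family] = float("nan")
        censuses.append(census)

    group_means: dict[str, dict[str, float]] = {}
    by_id = {c.sample_id: c for c in censuses}
    for group, members in (groups or {}).items():
        for member in members:
            if member not in known:
                raise KeyError(f"group {group!r}: unknown sample {member!r}")
        group_means[group] = {}
        for family in families:
            values = [
                by_id[m].fractions[family]
                for m in members
                if by_id[m].fractions[family] == by_id[m].fractions[family]  # not NaN
            ]
            if len(values) < len(members):
                logger.info(
                    "group %s, family %s: %d sample(s) excluded (undefined denominator)",
                    group, family, len(members) - len(values),
                )
            group_means[group][family] = (
                sum(values) / len(values) if values else float("nan")
            )
    return censuses, group_means


def census_frame(censuses: list[SampleCensus]) -> pd.DataFrame:
    """Family x sample matrix of community percentages."""
    families = sorted({f for c in censuses for f in c.fractions})
    data = {c.sample_id: [c.fractions.get(f, float("nan")) for f in families] for c in censuses}
    return pd.DataFrame(data, index=pd.Index(families, name="family"))
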