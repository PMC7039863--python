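"""End-to-end convenience flows tying profiles, catalog, census and taxonomy together.

These helpers wire the module surfaces into the two workflows users run most:
building calibrated family profiles from training sets, and running the full
census (search -> verify -> normalize) over a gene catalog. The synthetic
recovery harness used for validation lives here too, so the exact study
conditions (genome counts, depth, carriage truths) are stated in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import AbundanceTable, GeneRecord, compute_abundance
from .census import (
    FAMILY_DOMAINS,
    MARKER_BY_DOMAIN,
    SampleCensus,
    census_table,
    verify_candidates,
)
from .profiles import (
    DEFAULT_SEED,
    ProfileModel,
    SearchHit,
    TrainingSet,
    build_profile,
    calibrate_evalue,
    derive_family_cutoff,
    search_catalog,
)

MARKER_NAMES = ("RecA", "BetaActin")


def build_calibrated_profiles(
    training: dict[str, TrainingSet],
    pseudocount_weight: float = 1.0,
    decoy_count: int = 200,
    seed: int = DEFAULT_SEED,
) -> dict[str, ProfileModel]:
    """Build, cutoff-derive and EVD-calibrate one profile per training family."""
    profiles: dict[str, ProfileModel] = {}
    for i, (family, ts) in enumerate(sorted(training.items())):
        profile = build_profile(ts, pseudocount_weight)
        derive_family_cutoff(profile, ts)
        calibrate_evalue(profile, decoy_count=decoy_count, seed=seed + i)
        profiles[family] = profile
    return profiles


@dataclass
class CensusResult:
    """Everything the census run produced, for inspection and reporting."""

    censuses: list[SampleCensus]
    group_means: dict[str, dict[str, float]]
    table: AbundanceTable
    verified: list[SearchHit]
    marker_hits: list[SearchHit]


def run_census(
    catalog: list[GeneRecord],
    profiles: dict[str, ProfileModel],
    training: dict[str, TrainingSet],
    families: list[str] | None = None,
    samples: list[str] | None = None,
    min_reads: float = 2,
    family_domains: dict[str, str] | None = None,
    groups: dict[str, list[str]] | None = None,
    table: AbundanceTable | None = None,
) -> CensusResult:
    """Search a catalog with calibrated profiles and produce per-sample censuses.

    Marker hits (RecA / β-actin) are selected by their E-value cutoffs and
    form the denominators; all other families go through closest-reference
    verification before their abundances are summed.
    """
    family_domains = family_domains or FAMILY_DOMAINS
    if families is None:
        families = [f for f in profiles if f not in MARKER_NAMES]
    if table is None:
        table = compute_abundance(catalog, min_reads=min_reads)
    if samples is None:
        samples = table.samples()
    hits = search_catalog(list(profiles.values()), catalog)
    marker_hits = [h for h in hits if h.family_name in MARKER_NAMES]
    candidates = [h for h in hits if h.family_name in families]
    verified = verify_candidates(candidates, catalog, training)
    censuses, group_means = census_table(
        samples,
        table,
        verified,
        marker_hits,
        families,
        family_domains=family_domains,
        markers=MARKER_BY_DOMAIN,
        groups=groups,
    )
    return CensusResult(
        censuses=censuses,
        group_means=group_means,
        table=table,
        verified=verified,
        marker_hits=marker_hits,
    )


@dataclass
class RecoveryRun:
    """One synthetic-community recovery outcome."""

    family: str
    truth_planted: float  # planted genome-count carriage, %
    truth_cell_fraction: float  # abundance-weighted carrier fraction, %
    estimate: float  # census estimate, %


def carriage_recovery(
    truths: tuple[float, ...] = (0.01, 0.05, 0.10, 0.30, 0.50),
    n_genomes: int = 200,
    reads_per_gene: float = 20.0,
    n_seeds: int = 10,
    seed: int = DEFAULT_SEED,
    family: str = "DsyB",
    abundance_sigma: float = 1.0,
    references=None,
) -> list[RecoveryRun]:
    """Plant known carriage fractions and re-estimate them through the full pipeline.

    For each truth and replicate seed: generate a community, simulate Poisson
    counts, run profile search + verification + marker normalization, and
    record estimate vs truth. The truth compared against is the
    abundance-weighted carrier fraction — the quantity a read-based census
    actually measures.
    """
    from .census import BACTERIAL
    from .synthetic_data import (
        FamilyCarriage,
        ReadSimConfig,
        bundled_reference_families,
        depth_for_mean_reads,
        generate_community,
        simulate_counts,
    )

    if references is None:
        references = bundled_reference_families(seed)
    training = {name: references[name].training for name in (family, "RecA")}
    profiles = build_calibrated_profiles(training, seed=seed)
    runs: list[RecoveryRun] = []
    for truth in truths:
        spec = {family: FamilyCarriage(carriage_fraction=truth, domain=BACTERIAL)}
        for rep in range(n_seeds):
            rep_seed = (seed + 1009 * rep + int(truth * 100000)) % (2**31 - 1)
            community = generate_community(
                n_genomes,
                spec,
                abundance_sigma=abundance_sigma,
                seed=rep_seed,
                references=references,
            )
            config = ReadSimConfig(
                mean_depth=depth_for_mean_reads(community, reads_per_gene),
                seed=rep_seed,
            )
            catalog = simulate_counts(community, config, n_samples=1)
            result = run_census(
                catalog, profiles, training, families=[family], samples=["S1"]
            )
            estimate = result.censuses[0].fractions[family]
            runs.append(
                RecoveryRun(
                    family=family,
                    truth_planted=100.0 * community.truth.carriage[family],
                    truth_cell_fraction=community.truth.cell_fraction[family],
                    estimate=float(estimate),
                )
            )
    return runs


def recovery_errors(runs: list[RecoveryRun]) -> np.ndarray:
    """Signed estimate-minus-truth errors (percentage points) of recovery runs."""
    return np.array([r.estimate - r.truth_cell_fraction for r in runs])
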