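"""Candidate verification, marker denominators and community fractions."""

import math

import pytest

from sulfur_census.catalog import AbundanceTable, GeneRecord
from sulfur_census.census import (
    BETA_ACTIN,
    FAMILY_DOMAINS,
    RECA,
    MarkerSpec,
    census_table,
    community_fraction,
    marker_abundance,
    verify_candidates,
)
from sulfur_census.errors import (
    MissingNegativesWarning,
    MultiCopyFractionWarning,
    UndefinedDenominatorError,
)
from sulfur_census.profiles import SearchHit, TrainingSet
from sulfur_census.synthetic_data import mutate_family_sequence, random_protein


def hit(gene, family, score=100.0, e=1e-80, verified=False):
    return SearchHit(gene_id=gene, family_name=family, bit_score=score, e_value=e,
                     verified=verified)


def gene(gene_id, protein):
    return GeneRecord(gene_id=gene_id, contig_id="c", nt_length=3 * (len(protein) + 1),
                      protein=protein, counts={})


class TestVerifyCandidates:
    @pytest.fixture()
    def dsyb(self, references):
        return references["DsyB"]

    def test_candidate_identical_to_positive_verifies(self, dsyb):
        candidate = dsyb.training.positives[0]
        catalog = [gene("g1", candidate)]
        out = verify_candidates([hit("g1", "DsyB")], catalog, {"DsyB": dsyb.training})
        assert out[0].verified

    def test_candidate_closer_to_negative_is_removed(self, dsyb, rng):
        near_negative = mutate_family_sequence(dsyb.training.negatives[0], 0.05, rng)
        catalog = [gene("g1", near_negative)]
        out = verify_candidates([hit("g1", "DsyB")], catalog, {"DsyB": dsyb.training})
        assert not out[0].verified

    def test_exact_tie_is_removed(self, dsyb):
        shared = dsyb.training.positives[0]
        training = TrainingSet("DsyB", dsyb.training.positives, [shared])
        catalog = [gene("g1", shared)]
        out = verify_candidates([hit("g1", "DsyB")], catalog, {"DsyB": training})
        assert not out[0].verified

    def test_missing_negatives_falls_back_with_warning(self, dsyb):
        training = TrainingSet("DsyB", dsyb.training.positives, [])
        catalog = [gene("g1", dsyb.training.positives[0])]
        with pytest.warns(MissingNegativesWarning):
            out = verify_candidates([hit("g1", "DsyB")], catalog, {"DsyB": training})
        assert out[0].verified

    def test_multi_family_hit_keeps_highest_score(self, references):
        dsyb, dddp = references["DsyB"], references["DddP"]
        catalog = [gene("g1", dsyb.training.positives[0])]
        hits = [hit("g1", "DddP", score=80.0), hit("g1", "DsyB", score=200.0)]
        training = {"DsyB": dsyb.training, "DddP": dddp.training}
        out = verify_candidates(hits, catalog, training)
        assert len(out) == 1
        assert out[0].family_name == "DsyB"


class TestMarkerAbundance:
    def test_single_hit_within_cutoff(self):
        table = AbundanceTable({("r1", "S1"): 0.02})
        total = marker_abundance(table, [hit("r1", "RecA", e=1e-60)], RECA, "S1")
        assert total == pytest.approx(0.02)

    def test_weak_hit_excluded_by_evalue_cutoff(self):
        table = AbundanceTable({("r1", "S1"): 0.02})
        total = marker_abundance(table, [hit("r1", "RecA", e=1e-40)], RECA, "S1")
        assert total == 0.0

    def test_no_hits_gives_undefined_downstream(self):
        table = AbundanceTable({})
        assert marker_abundance(table, [], RECA, "S1") == 0.0
        with pytest.raises(UndefinedDenominatorError):
            community_fraction(table, [], "DsyB", RECA, "S1", marker_hits=[])


class TestCommunityFraction:
    def _equal_community(self, n=100, carriers=30):
        """n bacterial genomes, equal abundance, equal lengths, exact counts."""
        table_entries = {}
        marker_hits = []
        verified = []
        for i in range(n):
            table_entries[(f"recA{i}", "S1")] = 0.01
            marker_hits.append(hit(f"recA{i}", "RecA", e=1e-80))
        for i in range(carriers):
            table_entries[(f"dsyB{i}", "S1")] = 0.01
            verified.append(hit(f"dsyB{i}", "DsyB", verified=True))
        return AbundanceTable(table_entries), marker_hits, verified

    def test_noise_free_equal_community_is_exact(self):
        table, marker_hits, verified = self._equal_community()
        fraction = community_fraction(table, verified, "DsyB", RECA, "S1",
                                      marker_hits=marker_hits)
        assert fraction == pytest.approx(30.0, abs=1e-9)

    def test_zero_verified_hits_gives_zero_percent(self):
        table, marker_hits, _ = self._equal_community(carriers=0)
        fraction = community_fraction(table, [], "DsyB", RECA, "S1",
                                      marker_hits=marker_hits)
        assert fraction == 0.0

    def test_multicopy_fraction_exceeds_100_with_warning(self):
        table, marker_hits, verified = self._equal_community(carriers=30)
        # two extra copies per carrier: abundance tripled
        tripled = AbundanceTable(
            {k: (v * 3 if k[0].startswith("dsyB") else v) for k, v in table.entries.items()}
        )
        # 90% is fine; scale to exceed 100%
        boosted = AbundanceTable(
            {k: (v * 4 if k[0].startswith("dsyB") else v) for k, v in table.entries.items()}
        )
        with pytest.warns(MultiCopyFractionWarning):
            fraction = community_fraction(boosted, verified, "DsyB", RECA, "S1",
                                          marker_hits=marker_hits)
        assert fraction == pytest.approx(120.0)
        assert community_fraction(tripled, verified, "DsyB", RECA, "S1",
                                  marker_hits=marker_hits) == pytest.approx(90.0)

    def test_scale_invariance_of_fractions(self):
        table, marker_hits, verified = self._equal_community()
        base = community_fraction(table, verified, "DsyB", RECA, "S1",
                                  marker_hits=marker_hits)
        scaled = community_fraction(table.scaled("S1", 10.0), verified, "DsyB", RECA,
                                    "S1", marker_hits=marker_hits)
        assert scaled == pytest.approx(base, rel=1e-12)


class TestCensusTable:
    def _hits_for_sample(self, sample, fraction_pct):
        entries = {}
        marker_hits = []
        verified = []
        for i in range(10):
            entries[(f"recA_{sample}_{i}", sample)] = 0.01
            marker_hits.append(hit(f"recA_{sample}_{i}", "RecA", e=1e-80))
        carriers = round(fraction_pct / 10)
        for i in range(carriers):
            entries[(f"dsyB_{sample}_{i}", sample)] = 0.01
            verified.append(hit(f"dsyB_{sample}_{i}", "DsyB", verified=True))
        return entries, marker_hits, verified

    def test_single_sample_table(self):
        entries, marker_hits, verified = self._hits_for_sample("S1", 30.0)
        censuses, _ = census_table(["S1"], AbundanceTable(entries), verified,
                                   marker_hits, ["DsyB"])
        assert censuses[0].fractions["DsyB"] == pytest.approx(30.0)
        assert censuses[0].marker_abundance["RecA"] == pytest.approx(0.1)

    def test_group_average_is_arithmetic_mean(self):
        e1, m1, v1 = self._hits_for_sample("S1", 10.0)
        e2, m2, v2 = self._hits_for_sample("S2", 20.0)
        censuses, means = census_table(
            ["S1", "S2"], AbundanceTable({**e1, **e2}), v1 + v2, m1 + m2, ["DsyB"],
            groups={"sediment": ["S1", "S2"]},
        )
        assert means["sediment"]["DsyB"] == pytest.approx(15.0)

    def test_undefined_sample_excluded_from_group_mean(self):
        e1, m1, v1 = self._hits_for_sample("S1", 10.0)
        # S2 has no marker signal at all: fraction undefined (NaN)
        censuses, means = census_table(
            ["S1", "S2"], AbundanceTable(e1), v1, m1, ["DsyB"],
            groups={"sediment": ["S1", "S2"]},
        )
        s2 = next(c for c in censuses if c.sample_id == "S2")
        assert math.isnan(s2.fractions["DsyB"])
        assert means["sediment"]["DsyB"] == pytest.approx(10.0)

    def test_unknown_sample_in_group_raises(self):
        e1, m1, v1 = self._hits_for_sample("S1", 10.0)
        with pytest.raises(KeyError):
            census_table(["S1"], AbundanceTable(e1), v1, m1, ["DsyB"],
                         groups={"g": ["S1", "nope"]})


def test_family_domain_table_covers_census_families():
    assert FAMILY_DOMAINS["DSYB"] == "eukaryotic"
    assert FAMILY_DOMAINS["Alma1"] == "eukaryotic"
    assert FAMILY_DOMAINS["DsyB"] == "bacterial"
    assert FAMILY_DOMAINS["DddP"] == "bacterial"
    assert RECA.e_value_cutoff == 1e-50
    assert BETA_ACTIN.e_value_cutoff == 1e-60
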