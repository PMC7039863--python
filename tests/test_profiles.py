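"""Profile construction, scoring, calibration and catalog search."""

import numpy as np
import pytest
from scipy.stats import gumbel_r

from oracles import enumerate_local_score
from sulfur_census.alphabet import AMINO_ACIDS
from sulfur_census.errors import (
    AlignmentShapeError,
    AlphabetError,
    CalibrationMissingError,
    CalibrationUnderpoweredError,
    EmptyInputError,
    MissingTrainingError,
    NonSeparableTrainingWarning,
)
from sulfur_census.profiles import (
    ProfileModel,
    SearchHit,
    TrainingSet,
    build_profile,
    calibrate_evalue,
    derive_family_cutoff,
    evalue,
    fit_gumbel,
    read_profile,
    score_batch,
    score_sequence,
    search_catalog,
    write_profile,
)
from sulfur_census.synthetic_data import mutate_family_sequence, random_protein
from conftest import random_query, random_tiny_profile


class TestBuildProfile:
    def test_identical_ungapped_sequences_give_peaked_columns(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        profile = build_profile(TrainingSet("fam", [seq] * 3))
        assert profile.length == 40
        for k, residue in enumerate(seq):
            assert AMINO_ACIDS[np.argmax(profile.match_emissions[k])] == residue
        profile.validate()

    def test_majority_gapped_column_is_not_a_match_state(self):
        # middle column is 60% gapped -> dropped from the match columns
        rows = ["A-C", "A-C", "AGC", "A-C", "AGC"]
        profile = build_profile(TrainingSet("fam", rows))
        assert profile.length == 2

    def test_single_sequence_training(self):
        profile = build_profile(TrainingSet("fam", ["MKV"]))
        assert profile.length == 3
        # pseudocount-smoothed indicator: observed residue dominates
        for k, residue in enumerate("MKV"):
            assert AMINO_ACIDS[np.argmax(profile.match_emissions[k])] == residue
            assert profile.match_emissions[k].max() < 1.0

    def test_empty_positives_raises(self):
        with pytest.raises(MissingTrainingError):
            TrainingSet("fam", [])

    def test_ragged_alignment_raises(self):
        with pytest.raises(AlignmentShapeError):
            TrainingSet("fam", ["ACD", "AC"])

    def test_probability_bundles_normalized(self, references):
        for ref in references.values():
            profile = build_profile(ref.training)
            profile.validate()  # raises if any bundle is off by > 1e-9


class TestScoreSequence:
    def test_matches_exhaustive_path_enumeration(self, rng):
        """Viterbi equals brute-force enumeration on tiny models and queries."""
        checked = 0
        while checked < 120:
            profile = random_tiny_profile(rng)
            query = random_query(rng)
            fast = score_sequence(profile, query)
            slow = enumerate_local_score(profile, query)
            assert fast == pytest.approx(slow, abs=1e-9), (query, profile.length)
            checked += 1

    def test_self_sequence_beats_point_mutants(self, rng):
        seq = random_protein(60, rng)
        profile = build_profile(TrainingSet("fam", [seq]))
        self_score = score_sequence(profile, seq)
        for _ in range(20):
            pos = int(rng.integers(len(seq)))
            mutant = seq[:pos] + AMINO_ACIDS[rng.integers(20)] + seq[pos + 1 :]
            assert score_sequence(profile, mutant) <= self_score + 1e-9

    def test_shuffled_queries_score_below_self(self, rng):
        seq = random_protein(80, rng)
        profile = build_profile(TrainingSet("fam", [seq]))
        self_score = score_sequence(profile, seq)
        letters = list(seq)
        for _ in range(10):
            rng.shuffle(letters)
            assert score_sequence(profile, "".join(letters)) < self_score

    def test_empty_query_raises(self):
        profile = build_profile(TrainingSet("fam", ["MKV"]))
        with pytest.raises(EmptyInputError):
            score_sequence(profile, "")

    def test_bad_symbol_raises(self):
        profile = build_profile(TrainingSet("fam", ["MKV"]))
        with pytest.raises(AlphabetError):
            score_sequence(profile, "MK!")

    def test_ambiguity_scores_as_background(self, rng):
        # X contributes exactly 0 to every match emission: verified via oracle
        profile = random_tiny_profile(rng)
        for _ in range(10):
            query = random_query(rng, with_x=True)
            if "X" not in query:
                query = query[:-1] + "X"
            assert score_sequence(profile, query) == pytest.approx(
                enumerate_local_score(profile, query), abs=1e-9
            )


class TestCalibration:
    def test_seeded_determinism(self, references):
        profile_a = build_profile(references["DsyB"].training)
        profile_b = build_profile(references["DsyB"].training)
        calibrate_evalue(profile_a, decoy_count=150, seed=7)
        calibrate_evalue(profile_b, decoy_count=150, seed=7)
        assert profile_a.evd_lambda == profile_b.evd_lambda
        assert profile_a.evd_mu == profile_b.evd_mu

    def test_underpowered_raises(self, references):
        profile = build_profile(references["DsyB"].training)
        with pytest.raises(CalibrationUnderpoweredError):
            calibrate_evalue(profile, decoy_count=99)

    def test_gumbel_parameter_recovery(self):
        """Fitting samples drawn from a known Gumbel recovers it within 10%."""
        true_lambda, true_mu = 0.45, 12.0
        samples = gumbel_r.rvs(
            loc=true_mu, scale=1.0 / true_lambda, size=10_000,
            random_state=np.random.default_rng(3),
        )
        lam, mu = fit_gumbel(samples)
        assert lam == pytest.approx(true_lambda, rel=0.10)
        assert mu == pytest.approx(true_mu, rel=0.10)

    def test_evalue_strictly_decreases_with_score(self, references):
        profile = build_profile(references["DsyB"].training)
        calibrate_evalue(profile, decoy_count=150, seed=1)
        scores = np.linspace(0, 300, 31)
        evalues = [evalue(profile, s, 1000) for s in scores]
        assert all(a > b for a, b in zip(evalues, evalues[1:]))


class TestFamilyCutoff:
    def test_midpoint_between_positives_and_negatives(self, references):
        ref = references["DsyB"]
        profile = build_profile(ref.training)
        cutoff = derive_family_cutoff(profile, ref.training)
        # recompute the two sides independently
        loo = []
        for i in range(len(ref.training.positives)):
            rest = ref.training.positives[:i] + ref.training.positives[i + 1 :]
            loo_profile = build_profile(TrainingSet("DsyB", rest))
            loo.append(score_sequence(loo_profile, ref.training.positives[i]))
        neg = max(score_sequence(profile, n) for n in ref.training.negatives)
        assert cutoff == pytest.approx(0.5 * (min(loo) + neg), abs=1e-9)
        assert profile.score_cutoff == cutoff

    def test_margin_rule_without_negatives(self, references):
        ref = references["DsyB"]
        training = TrainingSet("DsyB", ref.training.positives, [])
        profile = build_profile(training)
        cutoff_margin = derive_family_cutoff(profile, training, margin=10.0)
        cutoff_zero = derive_family_cutoff(profile, training, margin=0.0)
        assert cutoff_margin == pytest.approx(cutoff_zero - 10.0)

    def test_overlapping_negatives_warn_and_fall_back(self, references):
        ref = references["DsyB"]
        # use the positives themselves as negatives: maximal overlap
        training = TrainingSet("DsyB", ref.training.positives, ref.training.positives)
        profile = build_profile(training)
        with pytest.warns(NonSeparableTrainingWarning):
            cutoff = derive_family_cutoff(profile, training)
        loo = []
        for i in range(len(training.positives)):
            rest = training.positives[:i] + training.positives[i + 1 :]
            loo.append(score_sequence(build_profile(TrainingSet("DsyB", rest)),
                                      training.positives[i]))
        assert cutoff == pytest.approx(min(loo), abs=1e-9)


class _Gene:
    def __init__(self, gene_id, protein):
        self.gene_id = gene_id
        self.protein = protein


class TestSearchCatalog:
    def test_empty_catalog(self, references):
        ref = references["DsyB"]
        profile = build_profile(ref.training)
        derive_family_cutoff(profile, ref.training)
        calibrate_evalue(profile, decoy_count=150, seed=2)
        assert search_catalog([profile], []) == []

    def test_uncalibrated_profile_raises(self, references):
        profile = build_profile(references["DsyB"].training)
        with pytest.raises(CalibrationMissingError):
            search_catalog([profile], [_Gene("g1", "MKV" * 20)])

    def test_training_positives_self_detect(self, references):
        ref = references["DsyB"]
        profile = build_profile(ref.training)
        derive_family_cutoff(profile, ref.training)
        calibrate_evalue(profile, decoy_count=150, seed=2)
        catalog = [_Gene(f"pos{i}", p) for i, p in enumerate(ref.training.positives)]
        hits = search_catalog([profile], catalog)
        assert {h.gene_id for h in hits} == {g.gene_id for g in catalog}

    def test_planted_homolog_found_among_decoys(self, references, rng):
        """One 30%-diverged DsyB homolog among 99 shuffled decoys: only it hits."""
        ref = references["DsyB"]
        profile = build_profile(ref.training)
        derive_family_cutoff(profile, ref.training)
        calibrate_evalue(profile, decoy_count=150, seed=2)
        planted = mutate_family_sequence(ref.ancestor, 0.30, rng)
        letters = list(planted)
        decoys = []
        for i in range(99):
            rng.shuffle(letters)
            decoys.append(_Gene(f"decoy{i}", "".join(letters)))
        catalog = [_Gene("planted", planted)] + decoys
        hits = search_catalog([profile], catalog)
        assert [h.gene_id for h in hits] == ["planted"]


class TestSerialization:
    def test_round_trip_is_lossless(self, references, tmp_path):
        ref = references["MddA"]
        profile = build_profile(ref.training)
        derive_family_cutoff(profile, ref.training)
        calibrate_evalue(profile, decoy_count=150, seed=4)
        path = tmp_path / "MddA.profile.tsv"
        write_profile(profile, path)
        loaded = read_profile(path)
        loaded.validate()
        assert loaded.family_name == profile.family_name
        np.testing.assert_allclose(loaded.match_emissions, profile.match_emissions, rtol=1e-11)
        np.testing.assert_allclose(loaded.transitions, profile.transitions, rtol=1e-11)
        assert loaded.score_cutoff == pytest.approx(profile.score_cutoff, rel=1e-11)
        assert loaded.evd_lambda == pytest.approx(profile.evd_lambda, rel=1e-11)
        # scores computed from the loaded model agree to full precision
        query = ref.training.positives[0]
        assert score_sequence(loaded, query) == pytest.approx(
            score_sequence(profile, query), rel=1e-9
        )
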