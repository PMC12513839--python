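import numpy as np
import pandas as pd
import pytest

from nucdep import analyses, depcore, synthetic
from nucdep.analyses import (
    DistanceSample,
    SpliceAnnotation,
    compartment,
    decoy_acceptor_dependencies,
    donor_acceptor_dependency,
    duplication_dependency_profile,
    duplication_pair_positions,
    fit_power_law,
    label_regions,
    matched_distance_background,
    residual_profile,
    simulate_power_law_sample,
    splice_outlier_score,
    tile_dependency_samples,
)
from nucdep.synthetic import PairwiseCouplingModel


def constant_map(n, c):
    e = np.full((n, n), float(c))
    np.fill_diagonal(e, np.nan)
    return e


def donor_acceptor_model(n, donor, acceptor, strength=2.5):
    """Couple both donor nucleotides to both acceptor nucleotides."""
    J = strength * np.eye(4)
    couplings = {}
    for p in (donor, donor + 1):
        for q in (acceptor, acceptor + 1):
            couplings[(p, q)] = J.copy()
    return PairwiseCouplingModel(np.zeros((n, 4)), couplings)


class TestDonorAcceptor:
    def test_constant_map_gives_constant(self):
        ann = SpliceAnnotation(donor_start=5, acceptor_start=20, intron=(5, 22))
        assert donor_acceptor_dependency(constant_map(30, 1.7), ann) == \
            pytest.approx(1.7)

    def test_single_orientation_mean(self):
        e = constant_map(30, 0.0)
        ann = SpliceAnnotation(donor_start=5, acceptor_start=20, intron=(5, 22))
        cells = {(5, 20): 1.0, (5, 21): 2.0, (6, 20): 3.0, (6, 21): 4.0}
        for (i, j), v in cells.items():
            e[i, j] = v
        assert donor_acceptor_dependency(e, ann, both_orientations=False) == \
            pytest.approx(2.5)

    def test_overlapping_sites_rejected(self):
        with pytest.raises(ValueError):
            ann = SpliceAnnotation(donor_start=5, acceptor_start=6,
                                   intron=(5, 8))
            donor_acceptor_dependency(constant_map(10, 1), ann)

    def test_coupled_model_beats_matched_background(self):
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 40
            donor, acceptor = 6, 30
            model = donor_acceptor_model(n, donor, acceptor)
            seq = synthetic.random_sequence(rng, n)
            m = depcore.dependency_map(model, seq)
            ann = SpliceAnnotation(donor_start=donor, acceptor_start=acceptor,
                                   intron=(donor, acceptor + 2))
            da = donor_acceptor_dependency(m, ann)
            bg = matched_distance_background(m, ann, n=4, rng=rng)
            if da > np.mean(bg):
                wins += 1
        assert wins >= 95


class TestDecoyAcceptors:
    def test_intron_without_ag_gives_empty_list(self):
        ann = SpliceAnnotation(donor_start=0, acceptor_start=10, intron=(0, 12))
        decoys = decoy_acceptor_dependencies(
            constant_map(15, 1.0), ann, "GTCCCCCCCCAG")
        assert decoys == []

    def test_constant_map_decoys_equal_constant(self):
        ann = SpliceAnnotation(donor_start=0, acceptor_start=10, intron=(0, 12))
        decoys = decoy_acceptor_dependencies(
            constant_map(15, 2.0), ann, "GTAGCCAGCCAG")
        assert len(decoys) == 2  # AG at offsets 2 and 6; offset 10 is the acceptor
        assert all(d == pytest.approx(2.0) for d in decoys)

    def test_true_acceptor_beats_decoys_on_coupled_model(self):
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            n = 40
            donor, acceptor = 4, 32
            model = donor_acceptor_model(n, donor, acceptor)
            # force decoy AG dinucleotides inside the intron
            seq = list(synthetic.random_sequence(rng, n))
            for off in (12, 20):
                seq[off], seq[off + 1] = "A", "G"
            seq = "".join(seq)
            m = depcore.dependency_map(model, seq)
            ann = SpliceAnnotation(donor_start=donor, acceptor_start=acceptor,
                                   intron=(donor, acceptor + 2))
            da = donor_acceptor_dependency(m, ann)
            decoys = decoy_acceptor_dependencies(
                m, ann, seq[donor:acceptor + 2])
            if decoys and da > max(decoys):
                wins += 1
        assert wins >= 95


class TestMatchedDistanceBackground:
    def test_constant_map_samples_constant(self):
        ann = SpliceAnnotation(donor_start=2, acceptor_start=12, intron=(2, 14))
        samples = matched_distance_background(constant_map(30, 0.9), ann,
                                              n=4, rng=0)
        assert all(s == pytest.approx(0.9) for s in samples)

    def test_seed_determinism(self):
        rng_map = np.random.default_rng(0)
        e = rng_map.random((30, 30))
        ann = SpliceAnnotation(donor_start=2, acceptor_start=12, intron=(2, 14))
        a = matched_distance_background(e, ann, n=4, rng=7)
        b = matched_distance_background(e, ann, n=4, rng=7)
        assert a == b

    def test_monte_carlo_mean_matches_distance_stratum(self):
        rng_map = np.random.default_rng(1)
        e = rng_map.random((40, 40))
        ann = SpliceAnnotation(donor_start=0, acceptor_start=10, intron=(0, 12))
        samples = matched_distance_background(e, ann, n=10_000, rng=3)
        d = ann.distance
        excluded = {0, 1, 10, 11}
        cells = [
            x for p in range(40 - d) if p not in excluded
            and p + d not in excluded
            for x in (e[p, p + d], e[p + d, p])
        ]
        se = np.std(cells) / np.sqrt(len(samples))
        assert abs(np.mean(samples) - np.mean(cells)) < 4 * se

    def test_no_eligible_pairs_rejected(self):
        ann = SpliceAnnotation(donor_start=0, acceptor_start=2, intron=(0, 4))
        with pytest.raises(ValueError):
            matched_distance_background(constant_map(4, 1.0), ann)


class TestSpliceOutlierScore:
    def test_constant_map_foreground_equals_background(self):
        fg, bg = splice_outlier_score(constant_map(40, 0.5), 5, 25)
        assert fg == pytest.approx(bg)

    def test_planted_intersection_beats_background(self):
        e = constant_map(40, 0.1)
        for q in (25, 26):
            e[5, q] = e[q, 5] = 3.0
        fg, bg = splice_outlier_score(e, 5, 25)
        assert fg > bg

    def test_variant_too_close_is_excluded(self):
        assert splice_outlier_score(constant_map(40, 0.5), 22, 25) is None
        assert splice_outlier_score(constant_map(40, 0.5), 20, 25) is not None


class TestDuplicationProfile:
    def test_forward_and_inverted_indexing_on_hand_built_map(self):
        # 10x10 map, copy1 at 1..3, copy2 at 6..8
        forward = duplication_pair_positions(1, 6, 3, "forward")
        assert forward == [(1, 6), (2, 7), (3, 8)]
        inverted = duplication_pair_positions(1, 6, 3, "inverted")
        assert inverted == [(1, 8), (2, 7), (3, 6)]
        e = constant_map(10, 0.0)
        for a, b in forward:
            e[a, b] = e[b, a] = 2.0
        placements = [{"seq_id": "s", "start1": 1, "start2": 6, "length": 3,
                       "orientation": "forward"}]
        profile = duplication_dependency_profile([e], placements)
        assert profile.loc[0, "mean_dependency"] == pytest.approx(2.0)

    def test_planted_diagonal_mean_is_exact(self):
        e = constant_map(12, 0.0)
        vals = [1.0, 2.0, 3.0]
        for t, v in enumerate(vals):
            e[2 + t, 9 - t] = v
            e[9 - t, 2 + t] = v
        placements = [{"seq_id": "s", "start1": 2, "start2": 7, "length": 3,
                       "orientation": "inverted"}]
        profile = duplication_dependency_profile([e], placements)
        assert profile.loc[0, "mean_dependency"] == pytest.approx(np.mean(vals))

    def test_placement_outside_map_rejected(self):
        placements = [{"seq_id": "s", "start1": 8, "start2": 9, "length": 3,
                       "orientation": "forward"}]
        with pytest.raises(ValueError):
            duplication_dependency_profile([constant_map(10, 1.0)], placements)

    def test_end_to_end_profile_on_generated_set(self):
        cfg = synthetic.DuplicationConfig(n_sequences=3, duplicate_length=6,
                                          orientation="inverted", seed=4,
                                          background_length=40)
        dup = synthetic.make_duplication_set(cfg)
        maps = [depcore.dependency_map(m, s)
                for m, s in zip(dup.models, dup.sequences)]
        profile = duplication_dependency_profile(maps, dup.placements)
        assert profile.loc[0, "orientation"] == "inverted"
        assert profile.loc[0, "mean_dependency"] > 1.0


class TestTiling:
    def test_sequence_equal_to_window_gives_one_tile(self):
        model = PairwiseCouplingModel(np.zeros((20, 4)))
        model.max_context = 20
        sample = tile_dependency_samples(
            model, "ACGT" * 5, window=20, stride=10, max_dist=10,
            n_sample=50, floor=-1.0, rng=0)
        # product model: all dependencies 0 > floor=-1, one tile of pairs
        assert (sample.records["dependency"] == 0).all()

    def test_overlap_averaging_matches_manual_tile_means(self):
        # a model whose predictions depend on global base composition gives
        # different values for the same genomic cell in different tiles;
        # the tiled sample must carry their average
        n, window, stride = 30, 20, 10

        class CompositionModel:
            style = "bidirectional"
            max_context = window
            supports_mask = False
            model_id = "composition"

            def predict(self, s):
                # position-weighted composition: the same genomic cell gets
                # a different value in each tile frame
                score = np.zeros(4)
                for t, b in enumerate(s):
                    score["ACGT".index(b)] += (t + 1) / len(s)
                row = np.exp(score - score.max())
                row /= row.sum()
                return np.tile(row, (len(s), 1))

        model = CompositionModel()
        seq = synthetic.random_sequence(np.random.default_rng(0), n)
        tile0 = depcore.dependency_map(model, seq[0:window]).e
        tile1 = depcore.dependency_map(model, seq[10:10 + window]).e
        # genomic cell (12, 17) lies in both tiles
        expected = np.mean([tile0[12, 17], tile1[2, 7]])
        assert tile0[12, 17] != tile1[2, 7]  # tiles genuinely disagree
        sample = tile_dependency_samples(
            model, seq, window=window, stride=stride,
            max_dist=window, n_sample=10_000, floor=-1.0, rng=0)
        assert np.any(np.isclose(sample.records["dependency"], expected,
                                 atol=1e-12))

    def test_sampler_determinism(self):
        model = PairwiseCouplingModel(
            np.zeros((25, 4)), {(3, 9): 1.0 * np.eye(4)})
        model.max_context = 25
        seq = synthetic.random_sequence(np.random.default_rng(2), 25)
        a = tile_dependency_samples(model, seq, window=25, stride=25,
                                    max_dist=25, n_sample=20, floor=-1.0,
                                    rng=42)
        b = tile_dependency_samples(model, seq, window=25, stride=25,
                                    max_dist=25, n_sample=20, floor=-1.0,
                                    rng=42)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_floor_and_distance_filters(self):
        model = PairwiseCouplingModel(
            np.zeros((25, 4)), {(3, 9): 1.0 * np.eye(4)})
        seq = synthetic.random_sequence(np.random.default_rng(2), 25)
        sample = tile_dependency_samples(model, seq, window=25, stride=25,
                                         max_dist=6, n_sample=1000,
                                         floor=0.001, rng=0)
        # only the coupled cells (distance 6) survive the floor
        assert len(sample.records) == 2
        assert (sample.records["distance"] == 6).all()
        assert (sample.records["dependency"] > 0.001).all()
        # tightening max_dist below the coupling distance leaves nothing
        tight = tile_dependency_samples(model, seq, window=25, stride=25,
                                        max_dist=4, n_sample=1000,
                                        floor=0.001, rng=0)
        assert tight.records.empty


class TestPowerLawFit:
    def _exact_sample(self, slope, intercept, n=200):
        rng = np.random.default_rng(0)
        d = rng.integers(1, 500, size=n).astype(float)
        y = 10.0 ** (intercept + slope * np.log10(d))
        return DistanceSample(records=pd.DataFrame(
            {"distance": d.astype(int), "dependency": y}))

    def test_inverse_distance_decays_ninety_percent(self):
        fit = fit_power_law(self._exact_sample(-1.0, -0.5))
        assert fit.decay_per_tenfold == pytest.approx(90.0, abs=1e-9)

    def test_constant_dependency_zero_decay(self):
        fit = fit_power_law(self._exact_sample(0.0, -0.7))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.decay_per_tenfold == pytest.approx(0.0, abs=1e-9)

    def test_exact_data_recovers_parameters_to_1e10(self):
        fit = fit_power_law(self._exact_sample(-0.65, -1.2))
        assert fit.slope == pytest.approx(-0.65, abs=1e-10)
        assert fit.intercept == pytest.approx(-1.2, abs=1e-10)
        assert fit.scaling_constant == pytest.approx(10**-1.2, rel=1e-9)

    def test_noisy_simulation_recovers_decay(self):
        errors = []
        for seed in range(50):
            sample = simulate_power_law_sample(
                n=10_000, decay_per_tenfold=78.0, noise_sd=0.3, rng=seed)
            fit = fit_power_law(sample)
            errors.append(abs(fit.decay_per_tenfold - 78.0))
        assert np.mean(np.array(errors) < 2.0) >= 0.95

    def test_too_few_points_rejected(self):
        sample = DistanceSample(records=pd.DataFrame(
            {"distance": [1, 2], "dependency": [0.5, 0.4]}))
        with pytest.raises(ValueError):
            fit_power_law(sample)


class TestResidualProfile:
    def test_exact_power_law_all_medians_zero(self):
        rng = np.random.default_rng(0)
        d = rng.integers(1, 100, size=500).astype(float)
        y = 10.0 ** (-1.0 - 0.6 * np.log10(d))
        sample = DistanceSample(records=pd.DataFrame(
            {"distance": d.astype(int), "dependency": y}))
        fit = fit_power_law(sample)
        prof = residual_profile(fit, sample)
        assert np.allclose(prof["median_residual"], 0.0, atol=1e-10)

    def test_planted_bump_detected_at_its_distance(self):
        rng = np.random.default_rng(1)
        d = rng.integers(1, 300, size=20_000).astype(float)
        log_y = -1.0 - 0.6 * np.log10(d) + 0.05 * rng.standard_normal(len(d))
        log_y[d == 164] += 0.5  # multiplicative bump at one distance
        sample = DistanceSample(records=pd.DataFrame(
            {"distance": d.astype(int), "dependency": 10.0 ** log_y}))
        fit = fit_power_law(sample)
        prof = residual_profile(fit, sample).set_index("distance")
        bump = prof.loc[164, "median_residual"]
        others = prof.drop(index=164)["median_residual"]
        assert bump > 0.4
        assert others.abs().median() < 0.05

    def test_mod3_enrichment_detected(self):
        rng = np.random.default_rng(2)
        d = rng.integers(1, 100, size=30_000).astype(float)
        log_y = -1.0 - 0.6 * np.log10(d) + 0.05 * rng.standard_normal(len(d))
        log_y[d % 3 == 0] += 0.3
        sample = DistanceSample(records=pd.DataFrame(
            {"distance": d.astype(int), "dependency": 10.0 ** log_y}))
        fit = fit_power_law(sample)
        prof = residual_profile(fit, sample)
        med = prof.groupby("mod3")["median_residual"].median()
        assert med[0] > med[1] and med[0] > med[2]


class TestRegionLabels:
    FEATURES = [
        {"seqid": "chrI", "type": "tRNA", "start": 100, "end": 180},
        {"seqid": "chrI", "type": "CDS", "start": 150, "end": 400},
        {"seqid": "chrI", "type": "pseudogene", "start": 600, "end": 700},
    ]

    def test_trna_is_structured_rna(self):
        assert label_regions([("chrI", 100, 120)], self.FEATURES) == \
            ["structured_RNA"]

    def test_cds_is_protein_coding(self):
        assert label_regions([("chrI", 300, 350)], self.FEATURES) == \
            ["protein_coding_gene"]

    def test_structured_rna_takes_precedence(self):
        assert label_regions([("chrI", 140, 200)], self.FEATURES) == \
            ["structured_RNA"]

    def test_no_annotation_is_intergenic(self):
        assert label_regions([("chrI", 450, 500)], self.FEATURES) == \
            ["intergenic"]
        assert label_regions([("chrI", 620, 650)], self.FEATURES) == \
            ["intergenic"]

    def test_compartment_from_seqid(self):
        assert compartment("chrM") == "mitochondrial"
        assert compartment("chrIV") == "nuclear"
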