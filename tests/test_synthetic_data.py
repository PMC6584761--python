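import numpy as np
import pytest
from scipy import stats

from lncprofile import synthetic_data as sim
from lncprofile.errors import ValidationError
from lncprofile.overlap_targets import classify_overlap


@pytest.fixture(scope="module")
def small_annotation():
    cfg = sim.SimulationConfig(seed=1, n_mrna=20, n_lnc=20)
    transcripts, truth = sim.make_annotation(cfg)
    return cfg, transcripts, truth


class TestConfigValidation:
    def test_short_length_override_refused(self):
        # transcripts <= 200 bp would all be removed by the length filter
        with pytest.raises(ValidationError, match="200"):
            sim.SimulationConfig(length_range=(50, 200))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nb_dispersion": 0.0},
            {"library_size_mean": 100},
            {"predictor_error_rate": 1.0},
            {"target_rho": 1.5},
            {"sigma_tech": -0.1},
            {"de_fraction": 0.01, "n_mrna": 10, "n_lnc": 10},
            {"chrom_sizes": {}},
        ],
    )
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            sim.SimulationConfig(**kwargs)


class TestAnnotation:
    def test_all_ten_overlap_classes_planted(self, small_annotation):
        _, transcripts, truth = small_annotation
        assert len(transcripts) == 40
        labels = set(truth.true_overlap_class.values())
        assert labels == set(sim.OVERLAP_LABELS)
        assert len(labels) == 10

    def test_classifier_agrees_with_planted_labels(self, small_annotation):
        _, transcripts, truth = small_annotation
        by_id = {t.transcript_id: t for t in transcripts}
        for (lnc, mrna), label in truth.true_overlap_class.items():
            assert classify_overlap(by_id[lnc], by_id[mrna]).value == label

    def test_unplanted_transcripts_do_not_overlap(self, small_annotation):
        _, transcripts, truth = small_annotation
        planted = {t for pair in truth.true_overlap_class for t in pair}
        free = [t for t in transcripts if t.transcript_id not in planted]
        for i, a in enumerate(free):
            for b in free[i + 1 :]:
                if a.chrom != b.chrom:
                    continue
                assert a.span[1] <= b.span[0] or b.span[1] <= a.span[0]

    def test_exons_sorted_disjoint_in_bounds(self, small_annotation):
        cfg, transcripts, _ = small_annotation
        for t in transcripts:
            assert t.span[1] <= cfg.chrom_sizes[t.chrom]
            # TranscriptModel construction enforces sorted/disjoint; length filter
            assert t.length > 200

    def test_determinism(self, small_annotation):
        cfg, transcripts, truth = small_annotation
        tx2, truth2 = sim.make_annotation(cfg)
        assert tx2 == transcripts
        assert truth2.true_de == truth.true_de
        assert truth2.true_target_pairs == truth.true_target_pairs

    def test_sizing_error_names_chromosome(self):
        cfg = sim.SimulationConfig(seed=1, chrom_sizes={"tiny": 1000})
        with pytest.raises(Exception, match="tiny"):
            sim.make_annotation(cfg)


class TestCounts:
    def test_planted_de_count_matches_config(self):
        cfg = sim.SimulationConfig(seed=2, n_mrna=100, n_lnc=100, de_fraction=0.1)
        _, truth = sim.make_annotation(cfg)
        n_de = sum(s != "null" for s in truth.true_de.values())
        assert n_de == round(0.1 * 200)

    def test_determinism(self, small_annotation):
        cfg, transcripts, truth = small_annotation
        a = sim.make_counts(cfg, transcripts, truth)
        b = sim.make_counts(cfg, transcripts, truth)
        assert np.array_equal(a.counts, b.counts)
        assert np.allclose(a.coverage, b.coverage)

    def test_column_sums_near_library_size(self, small_annotation):
        cfg, transcripts, truth = small_annotation
        cm = sim.make_counts(cfg, transcripts, truth)
        sums = cm.counts.sum(axis=0)
        # expected column sum is the configured library size; NB noise around it
        sd = sums.std()
        assert np.all(np.abs(sums - cfg.library_size_mean) < 3 * max(sd, 1) + 0.05 * cfg.library_size_mean)

    def test_comonotone_limit_gives_exact_spearman_one(self):
        cfg = sim.SimulationConfig(seed=5, n_mrna=15, n_lnc=15, target_rho=1.0, de_fraction=0.0)
        tx, truth = sim.make_annotation(cfg)
        cm = sim.make_counts(cfg, tx, truth)
        idx = {t: i for i, t in enumerate(cm.transcript_ids)}
        for lnc, mrna in truth.true_target_pairs:
            x, y = cm.counts[idx[lnc]], cm.counts[idx[mrna]]
            rho = stats.spearmanr(x, y).statistic
            assert rho == pytest.approx(1.0, abs=1e-12)
            # comonotone: no discordant sample pair
            assert np.all((x[:, None] - x[None, :]) * (y[:, None] - y[None, :]) >= 0)

    def test_copula_fidelity_at_rho_09(self):
        # median observed Spearman over 100 planted pairs, 24 samples
        cfg = sim.SimulationConfig(
            seed=3, n_mrna=110, n_lnc=110, target_rho=0.9, n_target_pairs=100, de_fraction=0.0
        )
        tx, truth = sim.make_annotation(cfg)
        assert len(truth.true_target_pairs) == 100
        cm = sim.make_counts(cfg, tx, truth)
        idx = {t: i for i, t in enumerate(cm.transcript_ids)}
        rhos = [
            stats.spearmanr(cm.counts[idx[l]], cm.counts[idx[m]]).statistic
            for l, m in truth.true_target_pairs
        ]
        assert 0.8 <= np.median(rhos) <= 0.97

    def test_nonpositive_dispersion_rejected(self, small_annotation):
        cfg, transcripts, truth = small_annotation
        with pytest.raises(ValidationError):
            sim.SimulationConfig(seed=1, nb_dispersion=-1.0)


class TestScores:
    def test_determinism_and_noiseless_recovery(self, small_annotation):
        cfg, _, truth = small_annotation
        from lncprofile.coding_consensus import classify_all

        cfg0 = sim.SimulationConfig(seed=1, n_mrna=20, n_lnc=20, predictor_error_rate=0.0)
        scores = sim.make_scores(cfg0, truth)
        assert scores == sim.make_scores(cfg0, truth)
        votes, _ = classify_all(scores)
        for v in votes:
            expect = "lncRNA" if truth.true_biotype[v.transcript_id] == "lncRNA" else "coding"
            assert v.call == expect

    def test_error_rate_half_matches_binomial_tail(self):
        # P(>=3 of 4 noncoding votes | per-predictor error 0.5) = 5/16
        cfg = sim.SimulationConfig(seed=4, predictor_error_rate=0.5, de_fraction=0.0)
        biotype = {f"LNC_{i:05d}": "lncRNA" for i in range(5000)}
        biotype.update({f"MRNA_{i:05d}": "mRNA" for i in range(5000)})
        truth = sim.GroundTruth(biotype, {}, {}, set())
        scores = sim.make_scores(cfg, truth)
        from lncprofile.coding_consensus import classify_all

        votes, _ = classify_all(scores)
        calls = {v.transcript_id: v.call for v in votes}
        lnc_ids = [t for t, b in truth.true_biotype.items() if b == "lncRNA"]
        frac = np.mean([calls[t] == "lncRNA" for t in lnc_ids])
        # binomial sd at n=5000 is ~0.0066; allow 4 sigma
        assert frac == pytest.approx(5 / 16, abs=0.027)


class TestCt:
    def test_null_effect_gives_unit_ratio(self):
        cfg = sim.SimulationConfig(seed=6, n_case=28, n_ctrl=28)
        ct = sim.make_ct(cfg, planted_log2fc=0.0)
        from lncprofile.qpcr_stats import compare_groups, ddct

        rel = ddct(ct, "TARGET", "GAPDH")
        cmp_res = compare_groups(rel)
        assert cmp_res.fold_change_of_means == pytest.approx(1.0, abs=0.25)

    def test_noiseless_effect_recovered_exactly(self):
        cfg = sim.SimulationConfig(seed=6, n_case=3, n_ctrl=3, sigma_ref=0.0, sigma_tech=0.0)
        ct = sim.make_ct(cfg, planted_log2fc=1.0)
        from lncprofile.qpcr_stats import ddct

        rel = ddct(ct, "TARGET", "GAPDH")
        case = rel[rel["group"] == "case"]["rel_expr"]
        assert np.allclose(case, 2.0)

    def test_truth_sidecar_round_trip(self, small_annotation, tmp_path):
        _, _, truth = small_annotation
        p = tmp_path / "truth.tsv"
        sim.write_truth(truth, p)
        back = sim.read_truth(p)
        assert back.true_biotype == truth.true_biotype
        assert back.true_de == truth.true_de
        assert back.true_overlap_class == truth.true_overlap_class
        assert back.true_target_pairs == truth.true_target_pairs
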