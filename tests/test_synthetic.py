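"""Generator: positions, onset field, trace shapes, cohort determinism."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from lenscalcium import GeneratorConfig, generate_capsule, generate_cohort
from lenscalcium.synthetic import (generate_onsets, generate_positions,
                                   pulse_peak_time, synthesize_traces)
from conftest import small_config


class TestPositions:
    def test_single_cell_inside_field(self):
        cfg = GeneratorConfig(n_cells=1, field_size=50, seed=0)
        pos = generate_positions(cfg)
        assert pos.shape == (1, 2)
        assert (pos >= 0).all() and (pos <= 50).all()

    def test_zero_jitter_gives_exact_hex_lattice(self):
        cfg = GeneratorConfig(n_cells=50, field_size=200, cell_spacing=20,
                              jitter_sd=0, seed=0)
        pos = generate_positions(cfg)
        d = pdist(pos)
        # nearest-neighbor distance of an ideal hexagonal lattice = pitch
        assert np.isclose(d.min(), 20.0, atol=1e-9)

    def test_jittered_nn_distance_stays_near_pitch(self):
        cfg = GeneratorConfig(n_cells=200, field_size=320, cell_spacing=20,
                              jitter_sd=2, seed=42)
        pos = generate_positions(cfg)
        from scipy.spatial.distance import squareform
        dm = squareform(pdist(pos))
        np.fill_diagonal(dm, np.inf)
        nn = dm.min(axis=1)
        assert 16 <= nn.mean() <= 24
        # hard guarantee from the truncated jitter
        assert nn.min() >= 20 - 4 * 2 - 1e-9

    def test_too_small_field_raises(self):
        with pytest.raises(ValueError, match="fits only"):
            generate_positions(GeneratorConfig(n_cells=500, field_size=60,
                                               cell_spacing=20, seed=0))


class TestOnsets:
    def test_zero_variance_field_gives_common_onset(self):
        cfg = small_config(onset_delay_sd=0.0, frac_nonresponder=0.1)
        pos = generate_positions(cfg)
        delays, resp = generate_onsets(pos, cfg)
        assert np.allclose(delays[resp], 0.0)
        assert np.isnan(delays[~resp]).all()

    def test_infinite_correlation_length_gives_flat_field(self):
        cfg = small_config(onset_corr_length=1e6, onset_delay_sd=3.0,
                           frac_nonresponder=0.0)
        pos = generate_positions(cfg)
        delays, _ = generate_onsets(pos, cfg)
        assert np.ptp(delays) < 0.05 * 3.0

    def test_delay_correlation_decays_with_distance(self):
        # brute-force pairwise delay similarity by distance bin, 20 seeds
        wins = 0
        for seed in range(20):
            cfg = small_config(n_cells=150, field_size=300,
                               onset_corr_length=50, onset_delay_sd=3,
                               frac_nonresponder=0.0, seed=seed)
            pos = generate_positions(cfg)
            delays, _ = generate_onsets(pos, cfg)
            d = pdist(pos)
            dd = pdist(delays[:, None], metric="cityblock")
            near = dd[d < 25].mean()
            far = dd[(d >= 100) & (d < 125)].mean()
            wins += near < far
        assert wins >= 18

    def test_nonresponder_fraction(self):
        cfg = small_config(frac_nonresponder=0.2)
        pos = generate_positions(cfg)
        _, resp = generate_onsets(pos, cfg)
        assert (~resp).sum() == round(0.2 * cfg.n_cells)

    def test_severity_widens_delay_dispersion(self):
        med = {}
        for sev in (0.0, 0.5, 1.0):
            sds = []
            for seed in range(10):
                cfg = small_config(severity=sev, frac_nonresponder=0.0,
                                   seed=seed)
                pos = generate_positions(cfg)
                delays, _ = generate_onsets(pos, cfg)
                sds.append(np.std(delays))
            med[sev] = np.median(sds)
        assert med[0.0] < med[0.5] < med[1.0]


class TestTraces:
    def test_noise_free_peak_at_analytic_time(self):
        cfg = small_config(noise_sd=0.0, frac_nonresponder=0.0,
                           spont_cluster_count=0, onset_delay_sd=0.0)
        rec = generate_capsule(cfg)
        t_peak_expected = cfg.t_stim + pulse_peak_time(cfg.rise_tau,
                                                       cfg.decay_tau)
        for i in range(5):
            t_peak = rec.times[np.argmax(rec.traces[i])]
            assert abs(t_peak - t_peak_expected) <= cfg.frame_dt

    def test_all_nonresponders_gives_flat_capsule(self):
        cfg = small_config(frac_nonresponder=1.0, spont_cluster_count=0)
        rec = generate_capsule(cfg)
        assert np.all(np.abs(rec.traces - cfg.baseline) < 6 * cfg.noise_sd)
        assert not rec.ground_truth.is_responder.any()

    def test_spontaneous_cells_lie_within_cluster_radius(self):
        cfg = small_config(spont_cluster_count=2, spont_cluster_radius=40,
                           seed=5)
        rec = generate_capsule(cfg)
        gt = rec.ground_truth
        centers = gt.cluster_centers
        for i in np.nonzero(gt.is_spontaneous)[0]:
            d = np.linalg.norm(rec.positions[i] - centers, axis=1)
            assert d.min() <= 40

    def test_traces_strictly_positive_and_finite(self, capsule):
        assert np.all(capsule.traces > 0)
        assert np.all(np.isfinite(capsule.traces))

    def test_responder_peak_detectable_above_noise(self, capsule):
        cfg_noise = 0.02
        gt = capsule.ground_truth
        base = capsule.traces[:, :30].mean(axis=1)
        for i in np.nonzero(gt.is_responder)[0][:20]:
            assert capsule.traces[i].max() - base[i] >= 3 * cfg_noise


class TestCohort:
    def test_empty_cohort(self):
        assert generate_cohort(0, {"a": 0.1}, small_config(), seed=0) == []

    def test_group_labels_balanced(self):
        caps = generate_cohort(4, {"mild": 0.1, "moderate": 0.7},
                               small_config(n_cells=30, field_size=150),
                               seed=0)
        labels = [c.cataract_type for c in caps]
        assert labels.count("mild") == labels.count("moderate") == 4

    def test_same_master_seed_is_bit_identical(self):
        base = small_config(n_cells=40, field_size=160)
        a = generate_cohort(2, {"g": 0.3}, base, seed=7)
        b = generate_cohort(2, {"g": 0.3}, base, seed=7)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.traces, cb.traces)
            np.testing.assert_array_equal(ca.positions, cb.positions)

    def test_empty_group_mapping_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(2, {}, small_config(), seed=0)


def test_generate_capsule_deterministic():
    cfg = small_config(seed=99)
    a, b = generate_capsule(cfg), generate_capsule(cfg)
    np.testing.assert_array_equal(a.traces, b.traces)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(n_cells=0)
    with pytest.raises(ValueError):
        GeneratorConfig(frame_dt=0)
    with pytest.raises(ValueError):
        GeneratorConfig(t_stim=700, t_total=600)
    with pytest.raises(ValueError):
        GeneratorConfig(frac_nonresponder=1.5)
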