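"""Synthetic-EEG generator: templates, Markov dynamics, epoch rendering,
and study assembly."""

import numpy as np
import pytest

import mstate
from mstate import (ConfigurationError, DimensionError, SimConfig,
                    generate_study, make_templates, sample_state_sequence,
                    synthesize_epoch, uniform_transition_matrix)
from mstate.containers import TemplateSet
from mstate.core import gfp, gfp_peaks
from mstate.hierarchy import backfit


class TestMakeTemplates:
    def test_orthonormal_zero_mean(self):
        t = make_templates(59, 4, seed=1)
        assert t.shape == (4, 59)
        assert np.abs(t.mean(axis=1)).max() < 1e-10
        gram = t @ t.T
        assert np.abs(gram - np.eye(4)).max() < 1e-10

    def test_too_many_states_for_zero_mean_subspace(self):
        # only n_channels - 1 orthogonal zero-mean vectors exist
        with pytest.raises(ConfigurationError):
            make_templates(4, 4, seed=7)

    def test_deterministic(self):
        a = make_templates(59, 4, seed=1)
        b = make_templates(59, 4, seed=1)
        np.testing.assert_array_equal(a, b)


class TestStateSequence:
    def test_degenerate_cycle(self):
        # chain forced A->B->C->D->A cycles deterministically
        tm = np.zeros((4, 4))
        for i in range(4):
            tm[i, (i + 1) % 4] = 1.0
        cfg = SimConfig(n_channels=8, sfreq=250.0, dwell_ms=100.0,
                        transition_matrix=tm, seed=3)
        seq = sample_state_sequence(cfg, 2.0)
        change = np.flatnonzero(np.diff(seq) != 0)
        states = np.concatenate(([seq[0]], seq[change + 1]))
        for a, b in zip(states[:-1], states[1:]):
            assert b == (a + 1) % 4
        assert np.all(np.diff(change := np.asarray(change)) > 0)

    def test_no_adjacent_repeat(self):
        cfg = SimConfig(n_channels=8, seed=5)
        seq = sample_state_sequence(cfg, 50.0)
        change = np.flatnonzero(np.diff(seq) != 0)
        assert np.all(seq[change] != seq[change + 1])

    def test_transition_frequencies_converge(self):
        # symmetric uniform chain: empirical frequencies near 1/3
        cfg = SimConfig(n_channels=8, seed=11)
        seq = sample_state_sequence(cfg, 10_000.0)
        change = np.flatnonzero(np.diff(seq) != 0)
        src, dst = seq[change], seq[change + 1]
        for i in range(4):
            sel = dst[src == i]
            for j in range(4):
                if i == j:
                    continue
                assert abs(np.mean(sel == j) - 1 / 3) < 0.02

    def test_mean_dwell_converges(self):
        cfg = SimConfig(n_channels=8, dwell_ms=125.0, seed=13)
        seq = sample_state_sequence(cfg, 10_000.0)
        change = np.flatnonzero(np.diff(seq) != 0)
        bounds = np.concatenate(([0], change + 1, [seq.size]))
        run_lengths = np.diff(bounds)[:-1]  # last run truncated by the horizon
        mean_ms = run_lengths.mean() * 1000.0 / cfg.sfreq
        assert abs(mean_ms - cfg.dwell_ms) / cfg.dwell_ms < 0.05


class TestSynthesizeEpoch:
    def test_noise_free_carrier_peaks_match_template(self):
        t = make_templates(16, 4, seed=2)
        cfg = SimConfig(n_channels=16, snr=np.inf, seed=2)
        seq = sample_state_sequence(cfg, 2.0)
        epoch, truth = synthesize_epoch(t, seq, cfg, seed=9)
        g = gfp(epoch)
        for p in gfp_peaks(g):
            v = epoch.data[:, p] - epoch.data[:, p].mean()
            c = abs(v @ t[seq[p]]) / np.linalg.norm(v)
            assert c == pytest.approx(1.0, abs=1e-9)

    def test_average_referenced(self):
        t = make_templates(16, 4, seed=2)
        cfg = SimConfig(n_channels=16, snr=4.0, seed=2)
        seq = sample_state_sequence(cfg, 1.0)
        epoch, _ = synthesize_epoch(t, seq, cfg, seed=1)
        assert np.abs(epoch.data.mean(axis=0)).max() < 1e-10

    def test_snr_scaling(self):
        t = make_templates(16, 4, seed=2)
        seq = sample_state_sequence(SimConfig(n_channels=16, seed=2), 2.0)
        cfg = SimConfig(n_channels=16, snr=4.0, seed=2)
        epoch, _ = synthesize_epoch(t, seq, cfg, seed=5)
        clean, _ = synthesize_epoch(t, seq, SimConfig(n_channels=16, snr=np.inf, seed=2), seed=5)
        noise = epoch.data - clean.data
        ratio = np.sqrt(np.mean(clean.data**2)) / np.sqrt(np.mean(noise**2))
        # average-referencing after mixing perturbs the ratio only slightly
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_channel_mismatch_raises(self):
        t = make_templates(16, 4, seed=2)
        cfg = SimConfig(n_channels=20, seed=2)
        with pytest.raises(DimensionError):
            synthesize_epoch(t, np.zeros(100, dtype=int), cfg)

    def test_backfit_recovers_peak_labels_at_snr4(self):
        # across 20 epochs, >= 95% of GFP-peak samples get the planted label
        t = make_templates(59, 4, seed=4)
        cfg = SimConfig(seed=4, snr=4.0)
        tset = TemplateSet(maps=t)
        hits = total = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            seq = sample_state_sequence(cfg, 2.0, rng=rng)
            epoch, _ = synthesize_epoch(t, seq, cfg, seed=200 + rep)
            labels = backfit(epoch, tset).labels
            peaks = gfp_peaks(gfp(epoch))
            hits += int(np.sum(labels[peaks] == seq[peaks]))
            total += peaks.size
        assert hits / total >= 0.95


class TestGenerateStudy:
    def test_bookkeeping(self):
        cfg = SimConfig(n_channels=12, n_subjects=10,
                        n_trials_per_condition=5, seed=6)
        study = generate_study(cfg)
        assert len(study.epochs) == 150
        assert len(study.truths) == 150
        for ep, truth in zip(study.epochs, study.truths):
            assert ep.subject_id and ep.trial_id and ep.condition
            assert truth.state_sequence.size == ep.n_samples

    def test_valence_matches_condition(self):
        from mstate import categorize_valence

        cfg = SimConfig(n_channels=12, n_subjects=3,
                        n_trials_per_condition=2, seed=6)
        study = generate_study(cfg)
        for ep in study.epochs:
            assert categorize_valence(ep.valence) == ep.condition

    def test_condition_dwell_overrides(self):
        cfg = SimConfig(n_channels=12, seed=6)
        for cond, dwell in (("negative", 140.0), ("neutral", 125.0),
                            ("positive", 110.0)):
            d, _ = cfg.for_condition(cond)
            assert d == dwell

    def test_deterministic(self):
        cfg = SimConfig(n_channels=12, n_subjects=2,
                        n_trials_per_condition=2, seed=9)
        a = generate_study(cfg)
        b = generate_study(cfg)
        for ea, eb in zip(a.epochs, b.epochs):
            np.testing.assert_array_equal(ea.data, eb.data)
            assert ea.valence == eb.valence

    def test_subject_rotation_small_but_nonzero(self):
        cfg = SimConfig(n_channels=20, n_subjects=3,
                        n_trials_per_condition=1, subject_rotation_deg=5.0,
                        seed=8)
        study = generate_study(cfg)
        for templ in study.subject_templates.values():
            c = np.abs(np.sum(templ * study.base_templates, axis=1))
            assert np.all(c > 0.95)        # close to the base maps
            assert np.all(c < 1.0 - 1e-6)  # but genuinely rotated


class TestConfigValidation:
    def test_row_stochastic_enforced(self):
        tm = uniform_transition_matrix(4)
        tm[0, 1] += 1e-6
        with pytest.raises(ConfigurationError):
            SimConfig(n_channels=8, transition_matrix=tm)

    def test_nonzero_diagonal_rejected(self):
        tm = np.full((4, 4), 0.25)
        with pytest.raises(ConfigurationError):
            SimConfig(n_channels=8, transition_matrix=tm)

    @pytest.mark.parametrize("kw", [{"dwell_ms": 0.0}, {"snr": 0.0},
                                    {"n_subjects": 0}])
    def test_positive_parameters_enforced(self, kw):
        with pytest.raises(ConfigurationError):
            SimConfig(n_channels=8, **kw)
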