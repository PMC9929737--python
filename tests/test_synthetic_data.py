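"""Generators: planted interfaces, detachment schedules, swing-out dimer,
Langevin sampler correctness."""

import numpy as np
import pytest
from scipy.special import logsumexp

from clampdyn.collective_variables import com_distance, contact_set
from clampdyn.contact_scoring import binding_scores, contact_frequency
from clampdyn.conformational_dynamics import mode_overlap, pca_modes
from clampdyn.free_energy import KB, detect_detachment
from clampdyn.synthetic_data import (
    AnalyticPotential, gen_detachment_traj, gen_dimer_breathing,
    gen_toy_complex, linear_separation, simulate_langevin_metad,
)


class TestToyComplex:
    def test_contact_set_equals_planted_reference(self, toy_complex):
        observed = contact_set(toy_complex.structure,
                               toy_complex.structure.positions,
                               toy_complex.cv_spec)
        assert observed.pairs == toy_complex.reference_contacts.pairs
        assert len(observed) == 6

    def test_control_residue_is_isolated(self, toy_complex):
        s = toy_complex.structure
        ctrl = s.positions[s.atom_indices(toy_complex.control_residue)][0]
        b_pos = s.positions[s.domain_label == "B"]
        assert np.linalg.norm(b_pos - ctrl, axis=1).min() >= 10.0

    def test_same_seed_reproduces_structure(self):
        a = gen_toy_complex(seed=3)
        b = gen_toy_complex(seed=3)
        np.testing.assert_array_equal(a.structure.positions,
                                      b.structure.positions)
        assert a.reference_contacts.pairs == b.reference_contacts.pairs

    def test_oversized_interface_rejected(self):
        with pytest.raises(ValueError, match="n_interface"):
            gen_toy_complex(n_res_a=4, n_res_b=4, n_interface=5)


class TestDetachment:
    def test_com_distance_tracks_driving_cv(self, detachment):
        truth = detachment.complex_truth
        for t in range(0, detachment.trajectory.n_frames, 10):
            d = com_distance(truth.structure, detachment.trajectory.frames[t],
                             truth.cv_spec)
            assert abs(d - detachment.d_series[t]) < 0.1

    def test_fcc_non_increasing_along_monotone_path(self, detachment):
        truth = detachment.complex_truth
        ref = truth.reference_contacts
        prev = 1.0
        for t in range(detachment.trajectory.n_frames):
            cs = contact_set(truth.structure, detachment.trajectory.frames[t],
                             truth.cv_spec, frame_index=t)
            fcc = len(cs.pairs & ref.pairs) / len(ref.pairs)
            assert fcc <= prev + 1e-12
            prev = fcc

    def test_detection_matches_schedule_bookkeeping(self, detachment):
        truth = detachment.complex_truth
        counts = []
        for t in range(detachment.trajectory.n_frames):
            cs = contact_set(truth.structure, detachment.trajectory.frames[t],
                             truth.cv_spec, frame_index=t)
            counts.append(len(cs.pairs & truth.reference_contacts.pairs))
        dt = detachment.trajectory.dt
        t_star = detect_detachment(np.arange(len(counts)) * dt,
                                   np.array(counts, float),
                                   window_ps=200.0, eps=0.5)
        assert t_star is not None
        frame = int(round(t_star / dt))
        assert abs(frame - detachment.last_break_frame) <= 1

    def test_control_residue_score_is_zero_interface_positive(self, detachment):
        truth = detachment.complex_truth
        series = [contact_set(truth.structure, f, truth.cv_spec)
                  for f in detachment.trajectory.frames]
        omega = contact_frequency(series)
        scores = binding_scores(
            omega, residues=truth.structure.residue_index.tolist())
        assert scores.scores[truth.control_residue] == 0.0
        for (i, j) in truth.reference_contacts.pairs:
            assert scores.scores[i] > 0 and scores.scores[j] > 0

    def test_infeasible_driving_distance_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="offset"):
            gen_detachment_traj(toy_complex, np.array([0.5, 0.6]))


class TestDimer:
    def test_noiseless_oscillation_is_rank_one(self):
        lobe_a = gen_toy_complex(20, 16, seed=0)
        lobe_b = gen_toy_complex(20, 16, seed=1)
        traj, truth = gen_dimer_breathing(lobe_a, lobe_b, noise_sd=0.0,
                                          n_frames=80, seed=0)
        modes = pca_modes(traj)
        assert modes.variance_fraction[0] > 0.99
        assert mode_overlap(modes.mode(0), truth.planted_mode) > 0.999

    def test_noise_splits_variance_as_planted_fraction(self):
        lobe_a = gen_toy_complex(20, 16, seed=0)
        lobe_b = gen_toy_complex(20, 16, seed=1)
        amplitude = 2.0
        traj, truth = gen_dimer_breathing(lobe_a, lobe_b, amplitude=amplitude,
                                          noise_sd=0.2, n_frames=400, seed=2)
        modes = pca_modes(traj)
        # planted motion variance vs isotropic noise variance accounting
        scale = amplitude / np.abs(truth.planted_mode).max()
        planted_var = 0.5 * scale**2  # mean of sin² times unit-norm mode
        noise_var = 0.2**2 * truth.planted_mode.size
        expected = planted_var / (planted_var + noise_var)
        got = modes.variance_fraction[0]
        assert got == pytest.approx(expected, rel=0.15)

    def test_determinism(self):
        lobe_a = gen_toy_complex(20, 16, seed=0)
        lobe_b = gen_toy_complex(20, 16, seed=1)
        t1, _ = gen_dimer_breathing(lobe_a, lobe_b, seed=5, n_frames=10)
        t2, _ = gen_dimer_breathing(lobe_a, lobe_b, seed=5, n_frames=10)
        np.testing.assert_array_equal(t1.frames, t2.frames)


class TestAnalyticPotential:
    def test_planted_delta_g_matches_well_depth(self):
        pot = AnalyticPotential.double_well(delta_u=3.0)
        assert pot.planted_delta_g() == pytest.approx(3.0, abs=0.02)

    def test_symmetric_potential_has_zero_delta_g(self):
        pot = AnalyticPotential.symmetric()
        assert pot.planted_delta_g() == pytest.approx(0.0, abs=0.02)

    def test_constant_tether_adds_only_constant_to_marginal(self):
        pot = AnalyticPotential.double_well()
        prof = pot.marginal_profile(d_width=0.02)
        w = pot.w(prof.d_centers)
        np.testing.assert_allclose(prof.G, w - w.min(), atol=5e-3)


class TestLangevinSampler:
    def test_unbiased_histogram_matches_boltzmann(self):
        # h0 = 0: plain Langevin must sample exp(-U/RT); compare the
        # d-marginal histogram against the quadrature density
        pot = AnalyticPotential(wells=((1.0, 8.0, 1.5),), barriers=(),
                                d_range=(4.0, 14.0))
        from clampdyn.synthetic_data import MetadParams
        cv, hills = simulate_langevin_metad(
            pot, params=MetadParams(h0=0.0), steps=400_000, seed=11,
            record_stride=4)
        assert len(hills) == 0
        edges = np.linspace(4.0, 14.0, 21)
        hist, _ = np.histogram(cv.d_com, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rt = KB * 300.0
        logp = -pot.w(centers) / rt
        p = np.exp(logp - logsumexp(logp)) / (edges[1] - edges[0])
        n_eff = len(cv) / 50  # correlated samples: conservative ESS
        se = np.sqrt(p * (1 - p * (edges[1] - edges[0])) /
                     (n_eff * (edges[1] - edges[0])))
        assert np.max(np.abs(hist - p) / np.maximum(se, 1e-3)) < 3.0

    def test_seeded_reproducibility(self):
        pot = AnalyticPotential.double_well()
        cv1, h1 = simulate_langevin_metad(pot, steps=50_000, seed=4)
        cv2, h2 = simulate_langevin_metad(pot, steps=50_000, seed=4)
        np.testing.assert_array_equal(cv1.d_com, cv2.d_com)
        np.testing.assert_array_equal(h1.height, h2.height)

    def test_well_tempered_heights_decay_in_expectation(self):
        pot = AnalyticPotential.double_well()
        _, hills = simulate_langevin_metad(pot, steps=500_000, seed=2)
        k = len(hills) // 4
        assert hills.height[-k:].mean() < hills.height[:k].mean()
        assert np.all(hills.height <= 0.3 + 1e-12)
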