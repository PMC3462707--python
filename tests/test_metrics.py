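"""Structural metrics against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tbmcore import synth
from tbmcore.metrics import (
    chi_accuracy, gdt_ts, kabsch, paired_t_test, tm_d0, tm_score,
)

from conftest import ca_structure, rigid_transform


def brute_force_rmsd(mobile, fixed, grid=10):
    """Oracle: minimum RMSD over rotations by Euler-angle grid + refinement."""
    p = mobile - mobile.mean(axis=0)
    q = fixed - fixed.mean(axis=0)

    def f(angles):
        r = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((p @ r.T - q) ** 2, axis=1)))

    ticks = np.linspace(0, 2 * math.pi, grid, endpoint=False)
    best = min((np.array([a, b, c]) for a in ticks for b in ticks for c in ticks),
               key=f)
    res = minimize(f, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return res.fun


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        sup = kabsch(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-8)
        assert abs(np.linalg.det(sup.rotation) - 1.0) < 1e-8

    def test_pure_translation_recovered(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        sup = kabsch(pts, pts + [5.0, 0.0, 0.0])
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.translation, [5.0, 0.0, 0.0], atol=1e-8)

    def test_matches_brute_force_oracle(self):
        # 4 points rotated 90 deg about z, one perturbed by 1 A
        mobile = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1.0]])
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        fixed = mobile @ rot90.T
        fixed[3] += [0.0, 0.0, 1.0]
        assert kabsch(mobile, fixed).rmsd == pytest.approx(
            brute_force_rmsd(mobile, fixed), abs=1e-6)

    def test_closed_form_pure_rotation_family(self):
        # two points at +-r on the x axis, target rotated by theta about z:
        # optimal fit is exact, rmsd 0, and for a *fixed* identity rotation
        # the residual is 2 r sin(theta/2) per point; the optimizer must hit 0
        r, theta = 3.0, np.radians(40.0)
        mobile = np.array([[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, 0, r]])
        rot = Rotation.from_euler("z", theta).as_matrix()
        sup = kabsch(mobile, mobile @ rot.T)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, rot, atol=1e-8)

    def test_reflection_not_used(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        mirrored = pts * [1, 1, -1]
        sup = kabsch(pts, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)
        assert sup.rmsd > 0.1  # a proper rotation cannot absorb the mirror

    def test_degenerate_and_small_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch(line, line)
        with pytest.raises(ValueError, match="at least 3"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_subset_restriction(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3))
        moved = pts.copy()
        moved[5:] += rng.normal(0, 4.0, (5, 3))
        sup = kabsch(pts, moved, subset=range(5))
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)


class TestTmScore:
    def test_d0_formula(self):
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8, abs=1e-9)
        assert tm_d0(100) == pytest.approx(3.6518, abs=1e-3)
        assert tm_d0(15) == 0.5
        assert tm_d0(19) == 0.5  # formula would be negative; floored

    def test_self_comparison_is_one(self, helix40):
        pairs = [(i, i) for i in range(1, 41)]
        assert tm_score(helix40, helix40, pairs, l_ref=40) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_invariance(self, helix40):
        pairs = [(i, i) for i in range(1, 41)]
        moved = rigid_transform(helix40, seed=5)
        assert tm_score(moved, helix40, pairs, l_ref=40) == pytest.approx(1.0, abs=1e-6)

    def test_reference_length_normalization(self, helix40):
        # scoring the same 40 perfect pairs against a longer reference halves it
        pairs = [(i, i) for i in range(1, 41)]
        assert tm_score(helix40, helix40, pairs, l_ref=80) == pytest.approx(0.5, abs=1e-9)

    def test_errors(self, helix40):
        with pytest.raises(ValueError):
            tm_score(helix40, helix40, [], l_ref=40)
        with pytest.raises(ValueError):
            tm_score(helix40, helix40, [(1, 1)], l_ref=0)

    def test_monotone_under_growing_noise(self):
        # expectation over seeds: more coordinate noise, lower TM-score
        sigmas = (0.5, 1.5, 3.0)
        pairs = [(i, i) for i in range(1, 41)]
        means = []
        for sigma in sigmas:
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                native = synth.ideal_backbone(synth._sequence(40))
                noisy = native.copy()
                for res in noisy.residues:
                    for nm in res.atoms:
                        res.atoms[nm] = res.atoms[nm] + rng.normal(0, sigma, 3)
                vals.append(tm_score(noisy, native, pairs, l_ref=40))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestGdtTs:
    def test_self_comparison_is_100(self, helix40):
        pairs = [(i, i) for i in range(1, 41)]
        assert gdt_ts(helix40, helix40, pairs) == 100.0

    def test_rigid_invariance(self, helix40):
        pairs = [(i, i) for i in range(1, 41)]
        moved = rigid_transform(helix40, seed=7)
        assert gdt_ts(moved, helix40, pairs) == pytest.approx(100.0, abs=1e-6)

    def test_matches_exhaustive_subset_oracle_on_toy_instance(self):
        # 10 residues: 5 rigid core, 5 displaced 10 A orthogonally
        rng = np.random.default_rng(42)
        base = rng.normal(size=(10, 3)) * 3.0
        model = base.copy()
        model[5:] += [0.0, 0.0, 10.0]
        ref = ca_structure(base)
        mod = ca_structure(model)
        pairs = [(i, i) for i in range(1, 11)]

        def exhaustive_count(thr):
            best = 0
            for mask in range(1 << 10):
                idx = [i for i in range(10) if mask >> i & 1]
                if len(idx) < 4:
                    continue
                try:
                    sup = kabsch(model, base, subset=idx)
                except ValueError:
                    continue
                d = np.linalg.norm(sup.apply(model) - base, axis=1)
                best = max(best, int(np.sum(d <= thr)))
            return best

        expected = np.mean([100.0 * exhaustive_count(t) / 10
                            for t in (1.0, 2.0, 4.0, 8.0)])
        assert gdt_ts(mod, ref, pairs) == pytest.approx(expected, abs=1e-6)

    def test_heuristic_at_least_full_kabsch(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(12, 3)) * 4.0
        model = base + rng.normal(0, 2.0, (12, 3))
        sup = kabsch(model, base)
        d = np.linalg.norm(sup.apply(model) - base, axis=1)
        naive = np.mean([100.0 * np.sum(d <= t) / 12 for t in (1, 2, 4, 8)])
        score = gdt_ts(ca_structure(model), ca_structure(base),
                       [(i, i) for i in range(1, 13)])
        assert score >= naive - 1e-9

    def test_too_few_pairs(self, helix40):
        with pytest.raises(ValueError, match="4"):
            gdt_ts(helix40, helix40, [(1, 1), (2, 2), (3, 3)])


class TestChiAccuracy:
    def test_self_comparison(self, helix40):
        assert chi_accuracy(helix40, helix40, "chi1") == 100.0
        assert chi_accuracy(helix40, helix40, "chi1_chi2") == 100.0

    def test_one_rotated_valine_among_ten(self):
        seq = "AV" * 10  # exactly 10 chi1-bearing residues (the valines)
        native = synth.ideal_backbone(seq, chi1=-60.0)
        model = synth.set_chi(native, seq_pos=2, chi1=-60.0 + 45.0)
        assert chi_accuracy(model, native, "chi1") == pytest.approx(90.0)
        # a 25-degree rotation stays within the 30-degree window
        model_ok = synth.set_chi(native, seq_pos=2, chi1=-60.0 + 25.0)
        assert chi_accuracy(model_ok, native, "chi1") == pytest.approx(100.0)

    def test_symmetric_terminal_group_mod_180(self):
        seq = "ADADAD"  # aspartates: chi2 has a 180-degree-symmetric carboxylate
        native = synth.ideal_backbone(seq, chi1=-60.0, chi2=30.0)
        flipped = synth.ideal_backbone(seq, chi1=-60.0, chi2=30.0 + 180.0)
        assert chi_accuracy(flipped, native, "chi1_chi2") == pytest.approx(100.0)

    def test_no_eligible_residues(self):
        ala = synth.ideal_backbone("AGAGAG")
        with pytest.raises(ValueError, match="no residues"):
            chi_accuracy(ala, ala, "chi1")

    def test_sequence_mismatch(self):
        a = synth.ideal_backbone("AVAV")
        b = synth.ideal_backbone("AVAL")
        with pytest.raises(ValueError, match="differ"):
            chi_accuracy(a, b)


class TestPairedTTest:
    def test_hand_computed_example(self):
        # differences (1,2,3): t = 2 / (1/sqrt(3)), df = 2
        t, p = paired_t_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2.0 * math.sqrt(3), abs=1e-9)
        assert p == pytest.approx(2 * sps.t.sf(2 * math.sqrt(3), df=2), abs=1e-12)
        assert p == pytest.approx(0.0742, abs=5e-4)

    def test_constant_shift_sign(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        t_pos, _ = paired_t_test(y + 2.0 + rng.normal(0, 0.1, 12), y)
        t_neg, _ = paired_t_test(y - 2.0 + rng.normal(0, 0.1, 12), y)
        assert t_pos > 0 > t_neg

    def test_antisymmetry(self):
        x = [1.0, 2.5, 3.0, 0.5]
        y = [0.5, 2.0, 3.5, 0.0]
        t1, p1 = paired_t_test(x, y)
        t2, p2 = paired_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
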