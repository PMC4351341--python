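"""Force mixing, momentum correction and method-variant semantics."""

import numpy as np
import pytest

from adbfsim.core import ForceResult
from adbfsim.forcefields import make_model_pair
from adbfsim.mixing import (MixedForces, MomentumCorrectionSpec, correct_momentum,
                            mix_forces, run_variant_step, validate_variant_spec)
from adbfsim.regions import BUFFER, CORE, DYN_QM, MM, RegionLabels, RegionSpec


def labels_from_codes(codes):
    return RegionLabels(np.asarray(codes, dtype=np.int8))


class TestMixForces:
    def test_identity_when_inputs_equal(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(6, 3))
        lab = labels_from_codes([CORE, DYN_QM, BUFFER, MM, MM, DYN_QM])
        out = mix_forces(ForceResult(f), ForceResult(f.copy()), lab)
        assert np.array_equal(out.forces, f)

    def test_all_mm_takes_reduced(self):
        rng = np.random.default_rng(1)
        fe, fr = rng.normal(size=(2, 5, 3))
        out = mix_forces(ForceResult(fe), ForceResult(fr), labels_from_codes([MM] * 5))
        assert np.array_equal(out.forces, fr)

    def test_elementwise_selection_oracle(self):
        rng = np.random.default_rng(2)
        fe, fr = rng.normal(size=(2, 30, 3))
        codes = rng.integers(0, 4, 30)
        out = mix_forces(ForceResult(fe), ForceResult(fr), labels_from_codes(codes))
        for i in range(30):
            expect = fe[i] if codes[i] in (CORE, DYN_QM) else fr[i]
            assert np.array_equal(out.forces[i], expect)
            assert out.source[i] == (0 if codes[i] in (CORE, DYN_QM) else 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mix_forces(ForceResult(np.zeros((3, 3))), ForceResult(np.zeros((4, 3))),
                       labels_from_codes([MM, MM, MM]))


class TestMomentumCorrection:
    def test_zero_net_force_is_fixed_point(self):
        f = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        mixed = MixedForces(f.copy(), np.zeros(2, np.int8), f.sum(0))
        out = correct_momentum(mixed, np.ones(2), MomentumCorrectionSpec("uniform", "all"))
        assert np.allclose(out.forces, f)

    def test_uniform_symmetric_two_atoms(self):
        f = np.array([[2.0, 0, 0], [0.0, 0, 0]])
        mixed = MixedForces(f, np.zeros(2, np.int8), f.sum(0))
        out = correct_momentum(mixed, np.ones(2), MomentumCorrectionSpec("uniform", "all"))
        assert np.allclose(out.forces, [[1.0, 0, 0], [-1.0, 0, 0]])

    def test_mass_weighted_matches_formula(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=(12, 3))
        m = rng.uniform(1, 20, 12)
        mixed = MixedForces(f.copy(), np.zeros(12, np.int8), f.sum(0))
        out = correct_momentum(mixed, m, MomentumCorrectionSpec("mass_weighted", "all"))
        assert np.max(np.abs(out.forces.sum(axis=0))) < 1e-10
        delta = f - out.forces
        expect = (m / m.sum())[:, None] * f.sum(axis=0)
        assert np.allclose(delta, expect)

    def test_region_restricted_leaves_outside_atoms(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=(6, 3))
        lab = labels_from_codes([CORE, DYN_QM, BUFFER, MM, MM, MM])
        mixed = MixedForces(f.copy(), np.zeros(6, np.int8), f.sum(0))
        out = correct_momentum(mixed, np.ones(6),
                               MomentumCorrectionSpec("uniform", "extended_qm"), lab)
        assert np.allclose(out.forces[3:], f[3:])
        assert np.max(np.abs(out.forces.sum(axis=0))) < 1e-10

    def test_empty_region_rejected(self):
        f = np.ones((2, 3))
        lab = labels_from_codes([MM, MM])
        mixed = MixedForces(f, np.zeros(2, np.int8), f.sum(0))
        with pytest.raises(ValueError):
            correct_momentum(mixed, np.ones(2),
                             MomentumCorrectionSpec("uniform", "dynamical_qm"), lab)


class TestVariants:
    def test_invalid_variant_specs_rejected(self):
        spec = RegionSpec(fixed_core=(0,), r_buffer=(3.0, 3.5))
        for variant in ("Conv", "AdConv", "AdUF"):
            with pytest.raises(ValueError, match="buffer"):
                validate_variant_spec(variant, spec)
        with pytest.raises(ValueError):
            validate_variant_spec("Magic", RegionSpec())

    def test_evaluation_counts_and_degeneracies(self, medium_box):
        """AdBF with a zero buffer equals AdUF; AdUF with DYN_QM = CORE gives
        AdConv forces on the QM atoms; Conv/AdConv do one evaluation."""
        A, B = make_model_pair(0.35)
        core = tuple(np.flatnonzero(medium_box.molecule_id == 0).tolist())
        prev = RegionLabels.initial(medium_box.n_atoms)
        spec_uf = RegionSpec(fixed_core=core, r_core=(0, 0), r_qm=(3.0, 3.5))
        f_uf, lab_uf, n_uf = run_variant_step(medium_box, spec_uf, "AdUF", A, B, prev)
        f_bf0, _, n_bf = run_variant_step(medium_box, spec_uf, "AdBF", A, B, prev)
        assert n_uf == 2 and n_bf == 2
        assert np.array_equal(f_uf.forces, f_bf0.forces)

        spec_conv = RegionSpec(fixed_core=core)
        f_conv, _, n_conv = run_variant_step(medium_box, spec_conv, "Conv", A, B, prev)
        assert n_conv == 1

        spec_adconv = RegionSpec(fixed_core=core, r_core=(3.0, 3.5))
        f_ac, lab_ac, n_ac = run_variant_step(medium_box, spec_adconv, "AdConv", A, B, prev)
        assert n_ac == 1
        spec_uf2 = RegionSpec(fixed_core=tuple(lab_ac.core.tolist()))
        f_uf2, lab2, _ = run_variant_step(medium_box, spec_uf2, "AdUF", A, B, prev)
        qm = lab2.dyn_qm
        assert np.allclose(f_uf2.forces[qm], f_ac.forces[qm])

    def test_empty_core_reduced_is_pure_mm(self, medium_box):
        """With an empty core the reduced evaluation is a plain model-B call."""
        A, B = make_model_pair(0.35)
        spec = RegionSpec(fixed_qm=tuple(np.flatnonzero(medium_box.molecule_id == 0)),
                          r_buffer=(0.0, 0.0))
        prev = RegionLabels.initial(medium_box.n_atoms, spec)
        mixed, lab, _ = run_variant_step(medium_box, spec, "AdUF", A, B, prev)
        fB = B.evaluate(medium_box).forces
        mm = lab.atoms(3)
        assert np.array_equal(mixed.forces[mm], fB[mm])
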