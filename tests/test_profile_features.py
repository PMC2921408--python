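"""Gaussian window coefficients and the integrative profile encoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiface.profile_features import (
    AMINO_ACIDS,
    KYTE_DOOLITTLE,
    ChainProfile,
    ResidueProfile,
    encode_chain,
    encode_residue,
    gaussian_coefficients,
    integrative_sd,
    profile_sd,
)
from ppiface.synthetic import worked_example_chain


def brute_force_sd(values):
    """Independent two-pass unbiased standard deviation oracle."""
    mean = sum(values) / len(values)
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))


class TestGaussianCoefficients:
    def test_center_is_window_midpoint(self):
        assert gaussian_coefficients(19).mu == 10

    def test_variance_and_center_density_for_l5(self):
        c = gaussian_coefficients(5)
        assert c.sigma2 == pytest.approx(2.5)
        assert c.p[2] == pytest.approx(1 / math.sqrt(2 * math.pi * 2.5))
        assert c.p[2] == pytest.approx(0.25231, abs=1e-5)

    @pytest.mark.parametrize("L", range(1, 43, 2))
    def test_symmetric_positive_unimodal(self, L):
        p = gaussian_coefficients(L).p
        assert np.all(p > 0)
        assert np.allclose(p, p[::-1], atol=1e-12)
        center = (L - 1) // 2
        assert np.all(np.diff(p[: center + 1]) > 0) or L == 1
        assert np.argmax(p) == center

    def test_population_divisor_option(self):
        c = gaussian_coefficients(5, variance_divisor="population")
        assert c.sigma2 == pytest.approx(2.0)

    @pytest.mark.parametrize("L", [0, 2, 4, -3])
    def test_rejects_even_or_nonpositive_lengths(self, L):
        with pytest.raises(ValueError):
            gaussian_coefficients(L)


class TestIntegrativeSD:
    def test_constant_product_vector_has_zero_sd(self):
        assert integrative_sd(np.ones(20), np.ones(20) * 2.0) == 0.0

    def test_single_mass_profile(self):
        sp = np.zeros(20)
        sp[0] = 1.0  # all profile mass on alanine-position 'A'
        kd = KYTE_DOOLITTLE.vector()
        expected = kd[0] * math.sqrt(0.05)
        assert integrative_sd(sp, kd) == pytest.approx(abs(expected), rel=1e-12)
        assert integrative_sd(sp, kd) == pytest.approx(1.8 * 0.2236068, abs=1e-6)

    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_positive_homogeneity(self, seed, alpha):
        r = np.random.default_rng(seed)
        sp, kd = r.random(20), r.normal(size=20)
        assert integrative_sd(alpha * sp, kd) == pytest.approx(
            alpha * integrative_sd(sp, kd), rel=1e-9, abs=1e-12
        )

    def test_invariant_under_joint_axis_permutation(self, rng):
        sp, kd = rng.random(20), rng.normal(size=20)
        perm = rng.permutation(20)
        assert integrative_sd(sp[perm], kd[perm]) == pytest.approx(
            integrative_sd(sp, kd), rel=1e-12
        )

    def test_matches_two_pass_oracle(self, rng):
        sp, kd = rng.random(20) * 3, rng.normal(size=20)
        assert integrative_sd(sp, kd) == pytest.approx(
            brute_force_sd(list(sp * kd)), rel=1e-12
        )

    @pytest.mark.parametrize("bad", [np.ones(19), np.ones(21), np.r_[np.ones(19), np.nan]])
    def test_rejects_malformed_vectors(self, bad):
        with pytest.raises(ValueError):
            integrative_sd(bad, KYTE_DOOLITTLE.vector())


def _uniform_chain(chain_id, sequence, value=0.05):
    sp = np.full((len(sequence), 20), value)
    return ChainProfile.from_arrays(chain_id, sequence, sp)


class TestEncoding:
    def test_single_residue_chain_zero_pads_all_but_center(self):
        chain = _uniform_chain("one", "A")
        coeffs = gaussian_coefficients(19)
        fv = encode_residue(chain, 1, coeffs)
        nonzero = np.flatnonzero(fv.v)
        assert list(nonzero) == [9]  # slot mu = 10, 0-based index 9

    def test_constant_chain_interior_equals_sd_times_p(self):
        chain = _uniform_chain("const", "ACDEFGHIKL")
        coeffs = gaussian_coefficients(3)
        kd = KYTE_DOOLITTLE.vector()
        sd = integrative_sd(chain.residues[0].sp, kd)
        for pos in range(2, 10):  # interior: full window in-chain
            fv = encode_residue(chain, pos, coeffs)
            assert np.allclose(fv.v, sd * coeffs.p, rtol=1e-12)

    def test_three_residue_chain_matches_slot_oracle(self, rng):
        sp = rng.random((3, 20))
        chain = ChainProfile.from_arrays("tri", "ARN", sp)
        coeffs = gaussian_coefficients(3)
        kd = KYTE_DOOLITTLE.vector()
        sds = [integrative_sd(row, kd) for row in sp]
        for pos in (1, 2, 3):
            fv = encode_residue(chain, pos, coeffs)
            for j in range(3):  # window slot j covers chain index pos-2+j
                src = pos - 2 + j
                expected = sds[src] * coeffs.p[j] if 0 <= src < 3 else 0.0
                assert fv.v[j] == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_translation_invariance_at_interior_positions(self, rng):
        sp = rng.random((8, 20))
        chain = ChainProfile.from_arrays("orig", "ARNDCQEG", sp)
        shifted = ChainProfile.from_arrays("shift", "WARNDCQEGW",
                                           np.vstack([rng.random(20), sp, rng.random(20)]))
        coeffs = gaussian_coefficients(3)
        for pos in range(2, 8):
            a = encode_residue(chain, pos, coeffs)
            b = encode_residue(shifted, pos + 1, coeffs)
            assert np.allclose(a.v, b.v, rtol=1e-12)

    def test_position_out_of_range(self):
        chain = _uniform_chain("x", "ARN")
        with pytest.raises(ValueError):
            encode_residue(chain, 4, gaussian_coefficients(3))

    def test_unknown_mode_rejected(self):
        chain = _uniform_chain("x", "ARN")
        with pytest.raises(ValueError):
            encode_chain(chain, gaussian_coefficients(3), mode="both")

    def test_integrative_mode_equals_per_residue_encoding(self, rng):
        chain = ChainProfile.from_arrays("c", "ARNDC", rng.random((5, 20)))
        coeffs = gaussian_coefficients(5)
        fvs = encode_chain(chain, coeffs, mode="integrative")
        for pos in range(1, 6):
            assert np.allclose(fvs[pos - 1].v, encode_residue(chain, pos, coeffs).v)

    def test_hydropathy_mode_ignores_profiles(self, rng):
        seq = "ARNDCQEG"
        a = ChainProfile.from_arrays("a", seq, rng.random((8, 20)))
        b = ChainProfile.from_arrays("b", seq, rng.random((8, 20)))
        coeffs = gaussian_coefficients(3)
        va = np.vstack([f.v for f in encode_chain(a, coeffs, mode="hydropathy_only")])
        vb = np.vstack([f.v for f in encode_chain(b, coeffs, mode="hydropathy_only")])
        assert np.array_equal(va, vb)

    def test_three_modes_differ_on_signal_chain(self, small_dataset):
        chain = small_dataset.chains[0]
        coeffs = gaussian_coefficients(5)
        mats = {
            mode: np.vstack([f.v for f in encode_chain(chain, coeffs, mode=mode)])
            for mode in ("integrative", "profile_only", "hydropathy_only")
        }
        assert not np.allclose(mats["integrative"], mats["profile_only"])
        assert not np.allclose(mats["integrative"], mats["hydropathy_only"])
        assert not np.allclose(mats["profile_only"], mats["hydropathy_only"])

    def test_nonstandard_residue_hydropathy_warns_and_is_zero(self):
        chain = ChainProfile.from_arrays("x", "AXA", np.full((3, 20), 0.05))
        with pytest.warns(UserWarning):
            fvs = encode_chain(chain, gaussian_coefficients(1), mode="hydropathy_only")
        assert fvs[1].v[0] == 0.0


class TestWorkedExample:
    """The documented 5-residue 'GRAVY' chain with frozen oracle values."""

    FROZEN_SD = [0.1493485855, 0.6251899585, 0.3286994948, 0.4171708094, 0.1361687807]

    def test_chain_is_constant(self):
        a, b = worked_example_chain(), worked_example_chain()
        assert a.sequence == b.sequence == "GRAVY"
        assert np.array_equal(a.sp_matrix(), b.sp_matrix())

    def test_sd_values_match_frozen_oracle(self):
        chain = worked_example_chain()
        kd = KYTE_DOOLITTLE.vector()
        for res, frozen in zip(chain.residues, self.FROZEN_SD):
            assert integrative_sd(res.sp, kd) == pytest.approx(frozen, abs=1e-9)
            assert integrative_sd(res.sp, kd) == pytest.approx(
                brute_force_sd(list(res.sp * kd)), rel=1e-12
            )

    def test_feature_vectors_match_recomputation(self):
        chain = worked_example_chain()
        coeffs = gaussian_coefficients(3)
        fvs = encode_chain(chain, coeffs)
        sds = [0.0] + self.FROZEN_SD + [0.0]  # zero-padded chain values
        for pos in range(1, 6):
            expected = [sds[pos - 1 + j] * coeffs.p[j] for j in range(3)]
            assert np.allclose(fvs[pos - 1].v, expected, atol=1e-9)


class TestChainProfileValidation:
    def test_position_gap_rejected(self):
        with pytest.raises(ValueError):
            ChainProfile("x", [
                ResidueProfile("A", 1, np.full(20, 0.05)),
                ResidueProfile("R", 3, np.full(20, 0.05)),
            ])

    def test_sequence_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ChainProfile.from_arrays("x", "AR", np.full((3, 20), 0.05))

    def test_negative_profile_rejected(self):
        sp = np.full((2, 20), 0.05)
        sp[0, 0] = -0.1
        with pytest.raises(ValueError):
            ChainProfile.from_arrays("x", "AR", sp)

    def test_profile_sd_matches_oracle(self, rng):
        sp = rng.random(20)
        assert profile_sd(sp) == pytest.approx(brute_force_sd(list(sp)), rel=1e-12)
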