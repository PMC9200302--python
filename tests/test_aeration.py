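"""Aeration bands, compartment bookkeeping and the densitometric equations.

The brute-force oracle used here tallies compartments, MLA and FRC voxel by
voxel in pure Python, independently of the vectorised implementation.
"""

import math

import numpy as np
import pytest

from lungquant import (
    AIR_HU,
    AerationLabel,
    ClassificationBands,
    ImageVolume,
    LungMask,
    MaskProvenance,
    Unit,
    air_tissue_ratio,
    classify_aeration,
    compartment_volumes,
    frc,
    mean_lung_attenuation,
    summarize,
    tissue_volume,
)
from lungquant.errors import EmptyMaskError, UndefinedRatioError
from tests.conftest import full_mask, make_hu_volume


def brute_force_profile(hu, mask, spacing, bands=ClassificationBands()):
    """Per-voxel python tally: the independent oracle."""
    vox = spacing[0] * spacing[1] * spacing[2]
    counts = dict.fromkeys(
        ["hyper", "normo", "hypo", "non", "dense_out"], 0)
    total, s = 0, 0.0
    for z in range(hu.shape[0]):
        for y in range(hu.shape[1]):
            for x in range(hu.shape[2]):
                if not mask[z, y, x]:
                    continue
                v = hu[z, y, x]
                total += 1
                s += v
                if v < bands.normo[0]:
                    counts["hyper"] += 1
                elif v < bands.normo[1]:
                    counts["normo"] += 1
                elif v < bands.hypo[1]:
                    counts["hypo"] += 1
                elif v <= bands.non[1]:
                    counts["non"] += 1
                else:
                    counts["dense_out"] += 1
    mla = s / total
    v_exp = total * vox
    return {
        "v_exp": v_exp,
        "volumes": {k: c * vox for k, c in counts.items()},
        "mla": mla,
        "frc": v_exp * mla / AIR_HU,
    }


class TestClassify:
    @pytest.mark.parametrize(
        "hu,expected",
        [
            (-600.0, AerationLabel.NORMO),
            (0.0, AerationLabel.NON),
            (-900.0, AerationLabel.HYPER),
            (-860.0, AerationLabel.NORMO),   # band edges: low side inclusive
            (-435.0, AerationLabel.HYPO),    # shared edge -> denser band
            (-121.0, AerationLabel.NON),
            (121.0, AerationLabel.NON),      # non band closed on top
            (121.5, AerationLabel.DENSE_OUT),
        ],
    )
    def test_band_membership(self, hu, expected):
        vol = make_hu_volume([[[hu]]])
        labels = classify_aeration(vol, full_mask(vol))
        assert labels[0, 0, 0] == expected

    def test_out_of_mask_is_background(self):
        vol = make_hu_volume(np.full((2, 2, 2), -600.0))
        mask = LungMask(np.zeros((2, 2, 2), bool), MaskProvenance.MANUAL,
                        vol.spacing)
        mask.mask[0, 0, 0] = True
        labels = classify_aeration(vol, mask)
        assert labels[0, 0, 0] == AerationLabel.NORMO
        assert (labels[labels != AerationLabel.NORMO]
                == AerationLabel.BACKGROUND).all()

    def test_shape_mismatch_rejected(self):
        vol = make_hu_volume(np.zeros((3, 3, 3)))
        mask = LungMask(np.ones((2, 2, 2), bool), MaskProvenance.MANUAL,
                        vol.spacing)
        with pytest.raises(EmptyMaskError):
            classify_aeration(vol, mask)

    def test_non_contiguous_bands_rejected(self):
        with pytest.raises(ValueError):
            ClassificationBands(normo=(-860, -400), hypo=(-435, -121))


class TestCompartments:
    def test_equal_three_way_partition(self):
        vol = make_hu_volume([[[-600.0, -300.0, 0.0]]])
        prof = compartment_volumes(
            classify_aeration(vol, full_mask(vol)), vol.spacing)
        assert prof.v_normo == prof.v_hypo == prof.v_non == 1.0
        for f in (prof.f_normo, prof.f_hypo, prof.f_non):
            assert f == pytest.approx(100.0 / 3.0)

    def test_all_normo(self):
        vol = make_hu_volume(np.full((3, 3, 3), -500.0))
        prof = compartment_volumes(
            classify_aeration(vol, full_mask(vol)), vol.spacing)
        assert prof.f_normo == 100.0
        assert prof.f_hypo == prof.f_non == 0.0

    def test_empty_mask_rejected(self):
        labels = np.zeros((2, 2, 2), dtype=np.int8)
        with pytest.raises(EmptyMaskError):
            compartment_volumes(labels, (1, 1, 1))

    def test_matches_brute_force_oracle_and_conserves_volume(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            hu = rng.uniform(-1200, 300, size=(8, 8, 8))
            mask = rng.random((8, 8, 8)) < 0.6
            if not mask.any():
                continue
            spacing = tuple(rng.uniform(0.02, 0.1, 3))
            vol = ImageVolume(hu, spacing, Unit.HU)
            lm = LungMask(mask, MaskProvenance.MANUAL, spacing)
            prof = compartment_volumes(classify_aeration(vol, lm), spacing)
            oracle = brute_force_profile(hu, mask, spacing)
            assert prof.v_exp == pytest.approx(oracle["v_exp"], rel=1e-9)
            for key, val in (
                ("hyper", prof.v_hyper), ("normo", prof.v_normo),
                ("hypo", prof.v_hypo), ("non", prof.v_non),
                ("dense_out", prof.v_dense_out),
            ):
                assert val == pytest.approx(oracle["volumes"][key], rel=1e-9)
            # exact conservation: compartments partition the mask
            total = (prof.v_hyper + prof.v_normo + prof.v_hypo
                     + prof.v_non + prof.v_dense_out)
            assert total == pytest.approx(prof.v_exp, rel=1e-12)
            assert mean_lung_attenuation(vol, lm) == pytest.approx(
                oracle["mla"], rel=1e-9)


class TestEquations:
    def test_mla_of_two_voxels(self):
        vol = make_hu_volume([[[-1000.0, 0.0]]])
        assert mean_lung_attenuation(vol, full_mask(vol)) == -500.0

    def test_mla_empty_mask(self):
        vol = make_hu_volume(np.zeros((2, 2, 2)))
        empty = LungMask(np.zeros((2, 2, 2), bool), MaskProvenance.MANUAL,
                         vol.spacing)
        with pytest.raises(EmptyMaskError):
            mean_lung_attenuation(vol, empty)

    @pytest.mark.parametrize("mla,expected", [(-1000.0, 1000.0), (0.0, 0.0),
                                              (-600.0, 600.0)])
    def test_frc_limits_and_midpoint(self, mla, expected):
        value, clamped = frc(1000.0, mla)
        assert value == pytest.approx(expected)
        assert not clamped

    def test_frc_clamps_noisy_mla(self):
        value, clamped = frc(1000.0, -1050.0)
        assert value == 1000.0 and clamped
        value, clamped = frc(1000.0, 25.0)
        assert value == 0.0 and clamped

    def test_frc_rejects_nonpositive_volume(self):
        with pytest.raises(EmptyMaskError):
            frc(0.0, -500.0)

    def test_tissue_volume(self):
        assert tissue_volume(1000.0, 600.0) == 400.0
        assert tissue_volume(1000.0, 1000.0) == 0.0
        assert tissue_volume(1000.0, 0.0) == 1000.0
        with pytest.raises(EmptyMaskError):
            tissue_volume(1000.0, 1001.0)

    def test_air_tissue_ratio(self):
        assert air_tissue_ratio(600.0, 400.0) == pytest.approx(1.5)
        assert air_tissue_ratio(0.0, 400.0) == 0.0
        with pytest.raises(UndefinedRatioError):
            air_tissue_ratio(600.0, 0.0)


class TestSummarize:
    def test_profile_identities_on_random_volume(self):
        rng = np.random.default_rng(7)
        hu = rng.uniform(-1100, 200, size=(10, 10, 10))
        vol = make_hu_volume(hu, spacing=(0.05, 0.05, 0.05))
        prof = summarize(vol, full_mask(vol))
        assert prof.frc + prof.tissue == pytest.approx(prof.v_exp, rel=1e-12)
        assert prof.at_ratio == pytest.approx(
            prof.frc_over_vexp / (1 - prof.frc_over_vexp), rel=1e-9)

    def test_pure_air_limit(self):
        vol = make_hu_volume(np.full((4, 4, 4), -1000.0))
        prof = summarize(vol, full_mask(vol))
        assert prof.f_normo == 0.0          # all voxels HYPER, below normo
        assert prof.v_hyper == prof.v_exp
        assert prof.frc_over_vexp == 1.0
        assert math.isnan(prof.at_ratio)    # A/T undefined at zero tissue

    def test_raising_one_voxel_monotonicity(self):
        """Raising one in-mask voxel's HU never increases FRC, never
        decreases tissue, and never moves the voxel to a lighter band."""
        rng = np.random.default_rng(3)
        hu = rng.uniform(-1000, 100, size=(6, 6, 6))
        vol = make_hu_volume(hu)
        base = summarize(vol, full_mask(vol))
        base_label = classify_aeration(vol, full_mask(vol))[2, 3, 4]
        hu2 = hu.copy()
        hu2[2, 3, 4] += 400.0
        vol2 = make_hu_volume(hu2)
        bumped = summarize(vol2, full_mask(vol2))
        assert bumped.frc <= base.frc
        assert bumped.tissue >= base.tissue
        assert classify_aeration(vol2, full_mask(vol2))[2, 3, 4] >= base_label
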