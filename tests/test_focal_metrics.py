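import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focalsf.focal_metrics import (
    FocalRecord,
    MissingFocalValue,
    RNFLProfile,
    assemble_records,
    focal_cd,
    focal_rnflt,
    global_metrics,
    read_rnfl_csv,
    records_to_frame,
    write_rnfl_csv,
)
from focalsf.octa_preproc import BinaryPerfusionMap
from focalsf.trajectory import WedgeROI
from focalsf.vf_data import VFLocation

MMPP = 4.11 / 960


def make_roi(mask, arc=(0.0, 30.0), index=1):
    return WedgeROI(
        location_index=index,
        phi0_center=float(np.mean(arc)),
        phi0_lo=float(arc[0]),
        phi0_hi=float(arc[1]),
        pixel_mask=mask,
        ring_arc=arc,
    )


def make_map(perfused, vessels=None):
    vessels = vessels if vessels is not None else np.zeros_like(perfused)
    return BinaryPerfusionMap(perfused, vessels, MMPP)


class TestFocalCD:
    def test_exact_counting(self):
        perfused = np.zeros((10, 10), bool)
        perfused.ravel()[:37] = True
        roi = make_roi(np.ones((10, 10), bool))
        assert focal_cd(make_map(perfused), roi) == pytest.approx(0.37, abs=0)

    def test_all_perfused_is_one(self):
        roi = make_roi(np.ones((5, 5), bool))
        assert focal_cd(make_map(np.ones((5, 5), bool)), roi) == 1.0

    def test_roi_inside_vessel_mask_flags_missing(self):
        mask = np.ones((5, 5), bool)
        with pytest.raises(MissingFocalValue):
            focal_cd(make_map(np.ones((5, 5), bool), vessels=mask), make_roi(mask))

    def test_vessel_pixels_excluded_from_denominator(self):
        perfused = np.zeros((10, 10), bool)
        perfused.ravel()[:30] = True
        vessels = np.zeros((10, 10), bool)
        vessels.ravel()[:10] = True  # 10 perfused pixels under vessels
        roi = make_roi(np.ones((10, 10), bool))
        assert focal_cd(make_map(perfused, vessels), roi) == pytest.approx(20 / 90)

    def test_invariant_to_pixels_outside_roi(self, rng):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        inner = rng.random((20, 20)) < 0.4
        a = make_map(inner.copy())
        outer_changed = inner.copy()
        outer_changed[~mask] = ~outer_changed[~mask]
        b = make_map(outer_changed)
        roi = make_roi(mask)
        assert focal_cd(a, roi) == focal_cd(b, roi)

    @given(extra=st.integers(0, 24))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_added_perfusion(self, extra):
        mask = np.zeros((10, 10), bool)
        mask[2:7, 2:7] = True
        base = np.zeros((10, 10), bool)
        base[2:4, 2:7] = True
        before = focal_cd(make_map(base.copy()), make_roi(mask))
        flat = np.flatnonzero(mask & ~base)
        add = base.copy()
        add.ravel()[flat[:extra]] = True
        after = focal_cd(make_map(add), make_roi(mask))
        assert after >= before

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            focal_cd(make_map(np.ones((4, 4), bool)), make_roi(np.ones((5, 5), bool)))


class TestFocalRNFLT:
    def profile(self, n=768, fn=None):
        angles = np.linspace(0, 360, n, endpoint=False)
        t = np.full(n, 100.0) if fn is None else fn(angles)
        return RNFLProfile(angles, t)

    def test_constant_profile(self):
        assert focal_rnflt(self.profile(), (12.0, 77.0)) == 100.0

    def test_equal_halves(self):
        prof = self.profile(fn=lambda a: np.where(a < 180.0, 50.0, 150.0))
        assert focal_rnflt(prof, (90.0, 270.0)) == pytest.approx(100.0)

    def test_wraparound_matches_brute_force(self):
        prof = self.profile(fn=lambda a: 40.0 + 0.1 * a)
        arc = (350.0, 370.0)  # wraps through 0
        got = focal_rnflt(prof, arc)
        angles = np.asarray(prof.angles_deg)
        sel = (angles >= 350.0) | (angles < 10.0)
        assert got == pytest.approx(float(prof.thickness_um[sel].mean()))

    def test_full_circle_equals_global_mean(self, rng):
        prof = self.profile(fn=lambda a: rng.uniform(20, 140, a.size))
        full = focal_rnflt(prof, (123.0, 123.0 + 360.0))
        assert full == pytest.approx(float(np.mean(prof.thickness_um)))

    def test_arc_narrower_than_sampling_step(self):
        prof = RNFLProfile(np.arange(0.0, 360.0, 45.0), np.full(8, 90.0))
        with pytest.raises(MissingFocalValue, match="narrower"):
            focal_rnflt(prof, (10.0, 12.0))

    def test_half_open_membership(self):
        prof = RNFLProfile(np.array([0.0, 90.0, 180.0, 270.0]),
                           np.array([10.0, 20.0, 30.0, 40.0]))
        # [0, 90) contains only the sample at 0
        assert focal_rnflt(prof, (0.0, 90.0)) == 10.0

    def test_validation(self):
        with pytest.raises(ValueError, match="duplicate"):
            RNFLProfile(np.array([0.0, 360.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="negative"):
            RNFLProfile(np.array([0.0, 10.0]), np.array([1.0, -2.0]))


class TestGlobalMetrics:
    def test_checkerboard(self):
        n = 64
        board = (np.indices((n, n)).sum(axis=0) % 2).astype(bool)
        prof = RNFLProfile(np.arange(0, 360, 10.0), np.full(36, 62.0))
        gcd, grnflt = global_metrics(make_map(board), prof)
        assert gcd == 0.5
        assert grnflt == 62.0

    def test_disc_mask_excluded(self):
        perfused = np.zeros((10, 10), bool)
        perfused[:, :5] = True
        disc = np.zeros((10, 10), bool)
        disc[:, :5] = True  # exclude exactly the perfused half
        prof = RNFLProfile(np.arange(0, 360, 90.0), np.full(4, 80.0))
        gcd, _ = global_metrics(make_map(perfused), prof, disc_mask=disc)
        assert gcd == 0.0


class TestAssembleRecords:
    def _inputs(self, n_subjects=2, locations=None):
        from focalsf.vf_data import VFExam

        locations = locations or [VFLocation(i, 3.0, 3.0) for i in (1, 2, 3)]
        exams, pmaps, profiles, rois = {}, {}, {}, {}
        for s in range(n_subjects):
            sid = f"S{s}"
            exams[sid] = VFExam(sid, "right",
                                {l.index: -5.0 for l in locations}, -5.0, 0.1, 0.1, 0.1)
            perfused = np.zeros((10, 10), bool)
            perfused[:5] = True
            pmaps[sid] = make_map(perfused)
            profiles[sid] = RNFLProfile(np.arange(0, 360, 10.0), np.full(36, 90.0))
            rois[sid] = {
                l.index: make_roi(np.ones((10, 10), bool), arc=(0.0, 40.0), index=l.index)
                for l in locations
            }
        return exams, pmaps, profiles, rois, locations

    def test_full_product(self):
        exams, pmaps, profiles, rois, locs = self._inputs()
        records = assemble_records(exams, pmaps, profiles, rois, locs)
        assert len(records) == 2 * 3
        assert all(isinstance(r, FocalRecord) for r in records)

    def test_flagged_missing_row_dropped(self, caplog):
        exams, pmaps, profiles, rois, locs = self._inputs()
        vessels = np.ones((10, 10), bool)
        pmaps["S0"] = make_map(np.ones((10, 10), bool), vessels=vessels)
        records = assemble_records(exams, pmaps, profiles, rois, locs)
        assert len(records) == 3  # S0 rows all dropped (empty denominators)

    def test_subject_mismatch_raises(self):
        exams, pmaps, profiles, rois, locs = self._inputs()
        del pmaps["S1"]
        with pytest.raises(ValueError, match="S1"):
            assemble_records(exams, pmaps, profiles, rois, locs)

    def test_empty_inputs(self):
        assert assemble_records({}, {}, {}, {}, []) == []

    def test_frame_columns(self):
        exams, pmaps, profiles, rois, locs = self._inputs()
        df = records_to_frame(assemble_records(exams, pmaps, profiles, rois, locs))
        assert list(df.columns) == ["subject_id", "loc_index", "fVFD_db", "fCD", "fRNFLT_um"]


class TestProfileIO:
    def test_roundtrip(self, tmp_path, rng):
        prof = RNFLProfile(
            np.linspace(0, 360, 96, endpoint=False),
            rng.uniform(30, 140, 96),
        )
        write_rnfl_csv(prof, tmp_path / "p.csv")
        back = read_rnfl_csv(tmp_path / "p.csv")
        assert np.allclose(back.angles_deg, prof.angles_deg, atol=1e-4)
        assert np.allclose(back.thickness_um, prof.thickness_um, atol=1e-3)
        assert back.n_samples == 96
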