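"""Synthetic longitudinal phantom generator: geometry, determinism, labels."""

import json

import numpy as np
import pytest

from metseg import metrics, phantom, rano
from metseg.phantom import PhantomSpec


def simple_spec(**kw):
    base = dict(
        grid_shape=(64, 64, 64),
        n_lesions=1,
        lesion_diameters_mm=(10.0,),
        trajectory=((1.0, 0.6),),
        seed=3,
    )
    base.update(kw)
    return PhantomSpec(**base)


class TestSpecValidation:
    def test_diameter_bounds(self):
        with pytest.raises(ValueError):
            simple_spec(lesion_diameters_mm=(1.0,))
        with pytest.raises(ValueError):
            simple_spec(lesion_diameters_mm=(60.0,))

    def test_baseline_factor_must_be_one(self):
        with pytest.raises(ValueError):
            simple_spec(trajectory=((0.9, 0.6),))

    def test_contrast_must_enhance(self):
        with pytest.raises(ValueError):
            simple_spec(contrast=0.9)


class TestGenerateSession:
    def test_sphere_diameter_brute_force(self):
        """10 mm sphere at 1 mm spacing: max voxel-center pairwise distance in 9-10 mm."""
        spec = simple_spec(trajectory=((1.0, 1.0),))
        _, _, truth = phantom.generate_session(spec, 0)
        idx = np.argwhere(truth.data == 1).astype(float)
        diff = idx[:, None, :] - idx[None, :, :]
        maxdist = np.sqrt((diff**2).sum(-1)).max()
        assert 9.0 <= maxdist <= 10.0 + 1e-9

    def test_zero_factor_gives_empty_mask(self):
        spec = simple_spec(trajectory=((1.0, 0.5, 0.0),))
        _, _, truth = phantom.generate_session(spec, 2)
        assert not (truth.data == 1).any()

    def test_bit_identical_determinism(self):
        spec = simple_spec()
        a = phantom.generate_session(spec, 1)
        b = phantom.generate_session(spec, 1)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.data, vb.data)

    def test_out_of_range_session(self):
        with pytest.raises(ValueError):
            phantom.generate_session(simple_spec(), 5)

    def test_placement_failure_raises(self):
        # ten large lesions cannot fit disjointly in a small grid
        with pytest.raises(phantom.PlacementError):
            spec = PhantomSpec(
                grid_shape=(48, 48, 48),
                n_lesions=6,
                lesion_diameters_mm=(25.0,) * 6,
                trajectory=((1.0, 1.0),) * 6,
                seed=1,
            )
            phantom.generate_session(spec, 0)

    def test_channels_are_skull_stripped(self):
        t1c, flair, _ = phantom.generate_session(simple_spec(), 0)
        assert t1c.data[0, 0, 0] == 0.0 and flair.data[0, 0, 0] == 0.0
        assert (t1c.data != 0).any()


class TestInvariants:
    @pytest.mark.parametrize("trial", range(12))
    def test_ld_agreement_disjointness_determinism(self, trial):
        """Prescribed vs measured LD within max(1 voxel, 5%); masks disjoint."""
        rng = np.random.default_rng(1000 + trial)
        spec = phantom.random_spec(rng, grid_shape=(64, 64, 64), n_sessions=3)
        for s in range(spec.n_sessions):
            _, _, truth = phantom.generate_session(spec, s)
            labels = truth.data
            for k in range(spec.n_lesions):
                prescribed = spec.lesion_diameters_mm[k] * spec.trajectory[k][s]
                measured = metrics.longest_diameter(labels == k + 1, spec.spacing_mm)
                tol = max(max(spec.spacing_mm), 0.05 * prescribed)
                assert abs(measured - prescribed) <= tol + 1e-9, (
                    f"lesion {k} session {s}: prescribed {prescribed}, measured {measured}"
                )
        # labels partition: each voxel belongs to at most one lesion by construction
        assert labels.max() <= spec.n_lesions


class TestGenerateSeries:
    def test_labels_self_consistent(self, small_series):
        for k, tl in enumerate(small_series.timelines):
            redo = rano.assess_timeline(small_series.gt_ld_mm[k], lesion_id=k + 1)
            assert redo.status_series == tl.status_series
            assert redo.outcome == tl.outcome

    def test_shrink_trajectory_labels(self):
        spec = simple_spec(trajectory=((1.0, 0.6, 0.4),), lesion_diameters_mm=(12.0,))
        series = phantom.generate_series(spec)
        tl = series.timelines[0]
        assert tl.status_series == [rano.SHRINKAGE, rano.SHRINKAGE]
        assert tl.outcome == rano.LC

    def test_regrowth_trajectory_is_lf(self):
        spec = simple_spec(trajectory=((1.0, 0.6, 1.0, 1.3),), lesion_diameters_mm=(12.0,))
        series = phantom.generate_series(spec)
        tl = series.timelines[0]
        assert tl.status_series[1] == rano.ENLARGEMENT
        assert tl.outcome == rano.LF

    def test_steady_trajectory(self):
        spec = simple_spec(trajectory=((1.0, 1.0),))
        series = phantom.generate_series(spec)
        assert series.timelines[0].status_series == [rano.STEADY]

    def test_single_session_rejected(self):
        with pytest.raises(ValueError):
            phantom.generate_series(simple_spec(trajectory=((1.0,),)))

    def test_prescribed_label_agreement_rate(self):
        """Labels from prescribed vs rendered LD series agree >= 95% over random series."""
        rng = np.random.default_rng(42)
        agree = total = 0
        n_series = 0
        while n_series < 60:
            spec = phantom.random_spec(rng, grid_shape=(48, 48, 48), n_sessions=4,
                                       diameter_range=(8.0, 18.0), max_lesions=2)
            try:
                series = phantom.generate_series(spec)
            except phantom.PlacementError:
                continue
            n_series += 1
            for k, tl in enumerate(series.timelines):
                total += 1
                ref = rano.assess_timeline(series.prescribed_ld_mm[k])
                if ref.outcome == tl.outcome and ref.are_flag == tl.are_flag:
                    agree += 1
        assert agree / total >= 0.95, f"{agree}/{total}"


class TestWriteSeries(object):
    def test_files_and_manifest(self, tmp_path):
        spec = PhantomSpec(
            grid_shape=(48, 48, 48),
            n_lesions=2,
            lesion_diameters_mm=(10.0, 8.0),
            trajectory=((1.0, 0.6, 0.4), (1.0, 1.0, 1.0)),
            seed=5,
        )
        manifest_path = phantom.write_series(spec, tmp_path)
        manifest = json.loads(manifest_path.read_text())
        assert len(manifest["sessions"]) == 3
        nii = list(tmp_path.rglob("*.nii.gz"))
        assert len(nii) == 9  # 3 sessions x (t1c, flair, truth)
        assert len(manifest["lesions"]) == 2
        assert manifest["lesions"][0]["outcome"] in ("LC", "LF", "indeterminate")
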