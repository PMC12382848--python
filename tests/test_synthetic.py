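"""Generator contracts: determinism, manifest fidelity, forward-model
invertibility and noise monotonicity."""

import numpy as np
import pytest

from mitoquant import SimConfig
from mitoquant.pipeline import quantify_mpt, quantify_swelling
from mitoquant.segmentation import adjacent_blank, auto_threshold, detect_particles, extract_trace, occupied_mask
from mitoquant.synthetic import (
    CalceinEvent,
    SwellSpec,
    expected_calcein_amplitude,
    gen_calcein_timelapse,
    gen_plate_readouts,
    gen_transmittance_zstacks,
    gen_uptake_field,
)


@pytest.fixture
def calcein_cfg():
    return SimConfig(seed=7, particle_diameter_um=(0.8, 2.0))


@pytest.fixture
def zstack_cfg():
    return SimConfig(
        seed=11, pixel_size_um=0.1625, particle_diameter_um=(1.5, 3.0),
        field_shape=(320, 320),
    )


class TestCalceinGenerator:
    def test_empty_field_is_noise_only_with_empty_manifest(self, calcein_cfg):
        bundle, manifest = gen_calcein_timelapse(calcein_cfg, 0)
        assert len(manifest) == 0
        assert np.allclose(bundle.frames, calcein_cfg.background)
        assert bundle.frames.shape[0] == calcein_cfg.n_frames

    def test_same_seed_same_config_is_bit_identical(self, calcein_cfg):
        b1, _ = gen_calcein_timelapse(
            calcein_cfg.replace(noise_sd=2.0), 10, event_fraction=0.5
        )
        b2, _ = gen_calcein_timelapse(
            calcein_cfg.replace(noise_sd=2.0), 10, event_fraction=0.5
        )
        assert np.array_equal(b1.frames, b2.frames)

    def test_requested_event_fraction_is_exact_in_manifest(self, calcein_cfg):
        _, manifest = gen_calcein_timelapse(calcein_cfg, 50, event_fraction=0.8)
        assert manifest.event_fraction() == pytest.approx(0.8)
        assert len(manifest.mitochondria) == 50

    def test_zero_noise_mpt_roundtrip_flags_exactly_the_event_objects(self, calcein_cfg):
        # 40 of 50 objects get a 60% step drop: the full trace-extraction +
        # calling pipeline must recover exactly 80%
        rng = np.random.default_rng(3)
        events = [
            CalceinEvent(int(rng.integers(3, 11)), 0.6) if i < 40 else None
            for i in range(50)
        ]
        bundle, manifest = gen_calcein_timelapse(calcein_cfg, 50, events=events)
        calls = quantify_mpt(bundle)
        assert len(calls) == 50
        assert sum(c.underwent_mpt for c in calls) == 40

    def test_overlapping_explicit_centers_rejected(self, calcein_cfg):
        with pytest.raises(ValueError, match="overlap"):
            gen_calcein_timelapse(
                calcein_cfg,
                2,
                events=[None, None],
                centers=[(50.0, 50.0), (51.0, 50.0)],
                diameters_um=[1.5, 1.5],
            )

    def test_event_frame_out_of_range_rejected(self, calcein_cfg):
        with pytest.raises(ValueError, match="frame"):
            gen_calcein_timelapse(calcein_cfg, 1, events=[CalceinEvent(99, 0.5)])

    def test_ramp_event_declines_linearly_to_total_drop(self, calcein_cfg):
        _, manifest = gen_calcein_timelapse(
            calcein_cfg, 1, events=[CalceinEvent(2, 0.5, mode="ramp")]
        )
        obj = manifest.mitochondria[0]
        amps = [expected_calcein_amplitude(obj, t, 11) for t in range(11)]
        assert amps[0] == amps[2] == obj.amplitude
        assert amps[10] == pytest.approx(0.5 * obj.amplitude)
        diffs = np.diff(amps[2:])
        assert np.allclose(diffs, diffs[0])


class TestTransmittanceGenerator:
    def test_blank_field_reads_unit_ratio(self, zstack_cfg):
        stacks, manifest = gen_transmittance_zstacks(zstack_cfg, 0)
        assert len(manifest) == 0
        frames = stacks[0].frames
        assert np.allclose(frames, frames.flat[0])

    def test_forward_model_inverts_exactly_at_zero_noise(self, zstack_cfg):
        specs = [SwellSpec(0.60, 0.60), SwellSpec(0.60, 0.80, onset_min=5.0)]
        stacks, manifest = gen_transmittance_zstacks(zstack_cfg, 2, swell=specs)
        series = quantify_swelling(stacks)
        measured = sorted(tuple(np.round(s.transmittance, 10)) for s in series)
        assert measured == [(0.60, 0.60), (0.60, 0.80)]

    def test_swelling_above_threshold_is_called(self, zstack_cfg):
        stacks, _ = gen_transmittance_zstacks(
            zstack_cfg, 1, swell=[SwellSpec(0.60, 0.80, onset_min=5.0)]
        )
        (series,) = quantify_swelling(stacks)
        assert series.change == pytest.approx(0.20, abs=1e-9)
        assert series.swollen

    def test_transmittance_above_one_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SwellSpec(0.6, 1.2, onset_min=5.0)

    def test_swollen_fraction_exact_in_manifest(self, zstack_cfg):
        _, manifest = gen_transmittance_zstacks(zstack_cfg, 20, swollen_fraction=0.6)
        assert manifest.swollen_fraction() == pytest.approx(0.6)


class TestUptakeGenerator:
    def test_cells_without_puncta_measure_zero(self):
        cfg = SimConfig(seed=2, field_shape=(256, 256))
        channels, manifest = gen_uptake_field(cfg, 1, [0], 0)
        from mitoquant.segmentation import measure_cell_fluorescence, roi_from_disk, roi_from_polygon

        cell = manifest.cells[0]
        roi = roi_from_polygon(cell.polygon, (256, 256))
        bg = roi_from_disk(cell.background_disk[:2], cell.background_disk[2], (256, 256))
        rec = measure_cell_fluorescence(channels["GFP"].frames[0], roi, bg)
        assert rec.integrated == pytest.approx(0.0, abs=1e-6)

    def test_free_particle_count_and_polarized_split_exact(self):
        cfg = SimConfig(seed=8, field_shape=(384, 384))
        _, manifest = gen_uptake_field(
            cfg, 0, [], 25, free_polarized_fraction=0.6
        )
        mitos = manifest.mitochondria
        assert len(mitos) == 25
        assert sum(m.polarized for m in mitos) == 15

    def test_out_of_gate_diameters_excluded_by_detection(self):
        # particles rendered at 0.3 and 5 um must fall outside the
        # 0.5-3 um single-mitochondrion gate; in-gate companions remain
        cfg = SimConfig(seed=4, field_shape=(384, 384), pixel_size_um=0.1625)
        channels, manifest = gen_uptake_field(
            cfg, 0, [], 4, free_diameters_um=[0.3, 5.0, 1.5, 1.5], amplitude=3000.0
        )
        gfp = channels["GFP"].frames[0]
        rois = detect_particles(
            gfp, cfg.pixel_size_um, d_range=(0.5, 3.0), threshold=14.0
        )
        assert len(rois) == 2
        for roi in rois:
            assert 0.5 <= roi.equivalent_diameter_um <= 3.0

    def test_field_too_small_raises(self):
        cfg = SimConfig(seed=1, field_shape=(64, 64))
        with pytest.raises(ValueError, match="too small"):
            gen_uptake_field(cfg, 9, [5] * 9, 0)


class TestPlateGenerator:
    def test_zero_noise_values_equal_truth(self):
        design = {"ctrl": {"DH": (0.5, 0.0)}, "tx": {"DH": (0.3, 0.0)}}
        table, manifest = gen_plate_readouts(design, n_wells=4)
        assert set(table["condition"]) == {"ctrl", "tx"}
        assert (table.loc[table["condition"] == "ctrl", "value"] == 0.5).all()
        assert manifest.well_truth.shape[0] == 2

    def test_same_seed_reproduces_table(self):
        design = {"a": {"ATP": (100.0, 10.0)}}
        t1, _ = gen_plate_readouts(design, seed=5)
        t2, _ = gen_plate_readouts(design, seed=5)
        assert t1.equals(t2)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            gen_plate_readouts({})


def test_trace_recovery_error_monotone_in_noise():
    """Mean absolute trace-recovery error must not decrease as pixel
    noise grows."""
    errors = []
    for noise in (0.0, 2.0, 8.0):
        errs = []
        for rep in range(3):
            cfg = SimConfig(
                seed=100 + rep, noise_sd=noise, particle_diameter_um=(1.0, 1.6)
            )
            bundle, manifest = gen_calcein_timelapse(
                cfg, 12, event_fraction=0.5
            )
            first = bundle.frames[0]
            rois = detect_particles(
                first, cfg.pixel_size_um, threshold=auto_threshold(first)
            )
            occ = occupied_mask(rois, cfg.field_shape, dilate_px=3)
            by_center = {
                (round(o.center[0]), round(o.center[1])): o
                for o in manifest.mitochondria
            }
            for roi in rois:
                key = min(
                    by_center,
                    key=lambda k: (k[0] - roi.centroid[0]) ** 2
                    + (k[1] - roi.centroid[1]) ** 2,
                )
                obj = by_center[key]
                trace = extract_trace(bundle, roi, adjacent_blank(roi, occ))
                truth = np.array(
                    [
                        expected_calcein_amplitude(obj, t, cfg.n_frames)
                        for t in range(cfg.n_frames)
                    ]
                )
                # trace captures a sub-unit fraction of the kernel; compare shapes
                scale = trace.values[0] / truth[0]
                errs.append(np.mean(np.abs(trace.values - scale * truth)))
        errors.append(np.mean(errs))
    assert errors[0] <= errors[1] + 1e-9 <= errors[2] + 1e-9
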