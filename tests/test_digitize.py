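"""Column scanning, square-wave calibration, voltage conversion, leads."""

import numpy as np
import pytest

from ecgpaperkit import (
    DistortionConfig,
    RenderConfig,
    digitize_image,
    generate_signal,
    render_paper,
)
from ecgpaperkit.binarize import binarize
from ecgpaperkit.digitize import (
    CalibrationError,
    CalibrationInfo,
    EmptyLeadError,
    LayoutMismatchError,
    LeadSignal,
    LowQualityTraceWarning,
    TraceArray,
    calibrate_trace,
    detect_square_wave,
    estimate_pixel_rate,
    scan_columns,
    split_leads,
)
from ecgpaperkit.layout import LeadLayout, LeadSpan, RowBand


class TestScanColumns:
    def test_horizontal_line(self):
        sk = np.zeros((80, 100), dtype=bool)
        sk[40, :] = True
        tr = scan_columns(sk, band=(0, 80))
        assert tr.x.size == 100
        assert (tr.y == 40).all()
        assert not tr.gap.any()

    def test_text_label_above_curve_is_ignored(self):
        sk = np.zeros((80, 100), dtype=bool)
        sk[40, :] = True
        sk[10, 30] = True  # a label stroke above the curve
        tr = scan_columns(sk, band=(0, 80))
        assert tr.y[30] == 40

    def test_gap_linear_interpolation(self):
        sk = np.zeros((80, 10), dtype=bool)
        sk[40, 0:3] = True  # columns 0-2 at y=40
        sk[44, 6:10] = True  # columns 6-9 at y=44
        tr = scan_columns(sk, band=(0, 80))
        assert list(tr.y[3:6]) == [41, 42, 43]
        assert tr.gap[3:6].all()

    def test_edge_gaps_extend_nearest(self):
        sk = np.zeros((80, 10), dtype=bool)
        sk[40, 3:7] = True
        tr = scan_columns(sk, band=(0, 80))
        assert (tr.y == 40).all()

    def test_empty_band_raises(self):
        with pytest.raises(EmptyLeadError):
            scan_columns(np.zeros((80, 10), dtype=bool), band=(0, 80))

    def test_mostly_empty_band_warns(self):
        sk = np.zeros((80, 100), dtype=bool)
        sk[40, 0:50] = True  # 50% gaps
        with pytest.warns(LowQualityTraceWarning):
            scan_columns(sk, band=(0, 80))

    def test_band_outside_image_raises(self):
        with pytest.raises(LayoutMismatchError):
            scan_columns(np.zeros((80, 10), dtype=bool), band=(0, 200))


class TestPixelRate:
    @pytest.mark.parametrize(
        "n_cols,seconds,expected", [(2500, 5.0, 500.0), (1000, 10.0, 100.0), (3640, 10.0, 364.0)]
    )
    def test_columns_per_second(self, n_cols, seconds, expected):
        tr = TraceArray(
            x=np.arange(n_cols), y=np.zeros(n_cols),
            gap=np.zeros(n_cols, bool), band=(0, 10),
        )
        assert estimate_pixel_rate(tr, seconds) == pytest.approx(expected)

    def test_zero_span_raises(self):
        tr = TraceArray(x=np.arange(10), y=np.zeros(10), gap=np.zeros(10, bool), band=(0, 1))
        with pytest.raises(ValueError):
            estimate_pixel_rate(tr, 0.0)


def _pulse_trace(fs_px=200.0, delta=80.0, baseline=300.0, n_signal=1600):
    """Trace with rise at column 40, fall at 80, signal from 120 on."""
    rng = np.random.default_rng(0)
    y = np.concatenate([
        np.full(40, baseline),
        np.full(40, baseline - delta),
        np.full(40, baseline),
        baseline + 12 * np.sin(np.arange(n_signal) * 2 * np.pi * 1.2 / fs_px),
    ])
    x = np.arange(y.size)
    return TraceArray(x=x, y=y, gap=np.zeros(y.size, bool), band=(0, 600))


class TestSquareWave:
    def test_transitions_and_anchors_on_ideal_pulse(self):
        tr = _pulse_trace()
        cal = detect_square_wave(tr, fs_px=200.0)
        assert abs(cal.rise - 40) <= 2
        assert abs(cal.fall - 80) <= 2
        assert abs(cal.x_begin - 120) <= 4
        assert abs(cal.delta - 80) <= 1
        assert cal.y_low == pytest.approx(300, abs=1)

    def test_flat_trace_has_no_calibration(self):
        tr = TraceArray(
            x=np.arange(800), y=np.full(800, 250.0),
            gap=np.zeros(800, bool), band=(0, 600),
        )
        with pytest.raises(CalibrationError):
            detect_square_wave(tr, fs_px=200.0)

    def test_threshold_rescales_with_resolution(self):
        # the same pulse at half resolution is still found because the
        # peak gate is proportional to the nominal pulse height
        rng = np.random.default_rng(0)
        y = np.concatenate([
            np.full(20, 150.0), np.full(20, 110.0), np.full(20, 150.0),
            150 + 6 * np.sin(np.arange(800) * 2 * np.pi * 1.2 / 100.0),
        ])
        lo = TraceArray(x=np.arange(y.size), y=y, gap=np.zeros(y.size, bool), band=(0, 300))
        cal_hi = detect_square_wave(_pulse_trace(fs_px=200.0, delta=80.0), fs_px=200.0)
        cal_lo = detect_square_wave(lo, fs_px=100.0)
        assert abs(cal_lo.delta - 40.0) <= 1
        assert abs(cal_lo.x_begin - 60.0) <= 4
        assert abs(cal_hi.delta - 2 * cal_lo.delta) <= 2

    def test_calibration_identities(self):
        tr = _pulse_trace()
        cal = detect_square_wave(tr, fs_px=200.0)
        assert cal.theta * cal.delta == pytest.approx(1.0, rel=1e-12)
        assert cal.beta * cal.delta == pytest.approx(0.4, rel=1e-12)
        assert cal.delta > 0


class TestCalibrateTrace:
    def _cal(self, delta=100.0, y_low=400.0, x_begin=300.0):
        return CalibrationInfo(
            y_high=y_low - delta, y_low=y_low, delta=delta, x_begin=x_begin,
            theta=1.0 / delta, beta=0.4 / delta,
        )

    def test_conversion_ratios(self):
        cal = self._cal(delta=100.0)
        assert cal.theta == pytest.approx(0.01)
        assert cal.beta == pytest.approx(0.004)

    def test_low_level_maps_to_zero_high_to_one(self):
        cal = self._cal(delta=100.0, y_low=400.0)
        tr = TraceArray(
            x=np.arange(300, 310),
            y=np.array([400.0] * 5 + [300.0] * 5),
            gap=np.zeros(10, bool), band=(0, 600),
        )
        sig = calibrate_trace(tr, cal)
        assert sig.v[:5] == pytest.approx(0.0)
        assert sig.v[5:] == pytest.approx(1.0)  # upward deflection positive
        assert sig.t[0] == pytest.approx(0.0)
        assert (np.diff(sig.t) > 0).all()

    def test_pulse_columns_excluded(self):
        cal = self._cal(x_begin=300.0)
        tr = TraceArray(
            x=np.arange(0, 400), y=np.full(400, 400.0),
            gap=np.zeros(400, bool), band=(0, 600),
        )
        sig = calibrate_trace(tr, cal)
        assert sig.t.size == 100


class TestSplitLeads:
    def _row(self, leads, seconds=10.0):
        return RowBand(band=(0.1, 0.9), span=(0.0, 1.0), seconds=seconds, leads=leads)

    def test_boundary_discard_between_half_planes(self):
        row = self._row([LeadSpan("I", 0.0, 5.0), LeadSpan("V1", 5.0, 10.0)])
        layout = LeadLayout(rows=[row])
        t = np.arange(0.0, 10.0, 0.01)
        sig = LeadSignal(t=t, v=np.sin(t))
        rec = split_leads([(row, sig)], layout)
        assert rec.leads["I"].t[-1] == pytest.approx(4.9, abs=0.02)
        assert rec.leads["V1"].t[0] == 0.0
        assert rec.leads["V1"].t[-1] == pytest.approx(4.9, abs=0.02)
        # 4.9-5.1 s of the row recording was discarded
        assert rec.leads["I"].t.size + rec.leads["V1"].t.size < t.size

    def test_single_lead_keeps_everything(self):
        row = self._row([LeadSpan("II", 0.0, 10.0)])
        layout = LeadLayout(rows=[row])
        t = np.arange(0.0, 10.0, 0.01)
        sig = LeadSignal(t=t, v=np.cos(t))
        rec = split_leads([(row, sig)], layout)
        assert rec.leads["II"].t.size == t.size


class TestEndToEnd:
    def test_clean_render_reconstructs_faithfully(self, short_render):
        from ecgpaperkit.evaluate import score_reconstruction

        sig, page, gt = short_render
        rec = digitize_image(page, gt.layout, skip_rectify=True)
        lead = next(iter(rec.leads.values()))
        r, lag, err, _ = score_reconstruction(sig, 500.0, lead)
        assert r >= 0.99
        assert (np.diff(lead.t) > 0).all()

    def test_detected_anchors_match_render_truth(self, short_render):
        _, page, gt = short_render
        rec = digitize_image(page, gt.layout, skip_rectify=True)
        cal = rec.calibrations[0]
        assert abs(cal.rise - gt.rise[0]) <= 2
        assert abs(cal.fall - gt.fall[0]) <= 2
        assert abs(cal.x_begin - gt.x_begin[0]) <= 4
        # detected high-level width matches the 0.2 s generator width
        width_true = gt.fall[0] - gt.rise[0]
        assert abs((cal.fall - cal.rise) - width_true) <= 2

    def test_resolution_equivariance_under_2x_upscale(self):
        sig = generate_signal(4.0, 500.0, seed=3)
        page, gt = render_paper(sig, RenderConfig(px_per_mm=8), fs=500.0)
        up = np.kron(page, np.ones((2, 2, 1), dtype=np.uint8))
        r1 = digitize_image(page, gt.layout, skip_rectify=True)
        r2 = digitize_image(up, gt.layout, skip_rectify=True)
        c1, c2 = r1.calibrations[0], r2.calibrations[0]
        assert c2.theta == pytest.approx(c1.theta / 2, rel=0.01)
        assert c2.beta == pytest.approx(c1.beta / 2, rel=0.01)
        from ecgpaperkit.evaluate import pearson_tlcc

        l1, l2 = r1.leads["II"], r2.leads["II"]
        tg = np.arange(0.0, min(l1.t[-1], l2.t[-1]), 0.002)
        v1 = np.interp(tg, l1.t, l1.v)
        v2 = np.interp(tg, l2.t, l2.v)
        _, lag = pearson_tlcc(v1, v2, 50)
        if lag >= 0:
            d = np.abs(v1[: v1.size - lag] - v2[lag:])
        else:
            d = np.abs(v1[-lag:] - v2[: v2.size + lag])
        # mean agreement after lag alignment; the max is dominated by
        # sub-column sampling phase on the steep QRS slopes
        assert d.mean() <= 0.02

    def test_corrupt_file_names_the_input(self, tmp_path):
        from ecgpaperkit.rectify import InputError

        bad = tmp_path / "not_an_image.png"
        bad.write_text("this is not a PNG")
        gt_layout = LeadLayout(
            rows=[RowBand(band=(0.1, 0.9), span=(0.0, 1.0), seconds=1.0,
                          leads=[LeadSpan("II", 0.0, 1.0)])]
        )
        with pytest.raises(InputError, match="not_an_image"):
            digitize_image(str(bad), gt_layout, skip_rectify=True)

    def test_stage_name_attached_on_failure(self):
        layout = LeadLayout(
            rows=[RowBand(band=(0.1, 0.9), span=(0.0, 1.0), seconds=1.0,
                          leads=[LeadSpan("II", 0.0, 1.0)])]
        )
        blank = np.full((100, 200, 3), 255, dtype=np.uint8)
        with pytest.raises(Exception) as exc_info:
            digitize_image(blank, layout, skip_rectify=True)
        notes = getattr(exc_info.value, "__notes__", [])
        assert any("binarize" in n for n in notes)

    def test_standard_12_lead_sheet(self):
        from ecgpaperkit.layout import standard_12_lead_layout

        layout = standard_12_lead_layout(seconds_per_lead=5.0)
        sigs = [
            generate_signal(10.0, 250.0, heart_rate_bpm=60 + 3 * i, seed=20 + i) * 0.9
            for i in range(7)
        ]
        page, gt = render_paper(
            sigs, RenderConfig(px_per_mm=4, band_height_mm=30), layout=layout, fs=250.0
        )
        rec = digitize_image(page, gt.layout, skip_rectify=True)
        assert set(rec.leads) == {
            "I", "II", "III", "aVR", "aVL", "aVF",
            "V1", "V2", "V3", "V4", "V5", "V6", "II-rhythm",
        }
        from ecgpaperkit.evaluate import score_reconstruction

        r, _, _, _ = score_reconstruction(sigs[6], 250.0, rec.leads["II-rhythm"])
        assert r >= 0.95
        for lead in rec.leads.values():
            assert (np.diff(lead.t) > 0).all()
            assert np.isfinite(lead.v).all()

    def test_uniform_resampling(self, short_render):
        sig, page, gt = short_render
        rec = digitize_image(page, gt.layout, skip_rectify=True, resample_hz=500.0)
        lead = next(iter(rec.leads.values()))
        assert np.allclose(np.diff(lead.t), 0.002)
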