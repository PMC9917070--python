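"""XIC extraction and peak detection/integration."""

import base64

import numpy as np
import pandas as pd
import pytest

from bileprof.signal import Trace, detect_peaks, extract_xic


def gaussian_trace(amplitudes, centers, sigma=0.05, rt_range=(20.0, 24.0), step=0.005,
                   baseline=0.0, target_mz=471.2422):
    rt = np.arange(*rt_range, step)
    y = np.full_like(rt, baseline)
    for a, mu in zip(amplitudes, centers):
        y += a * np.exp(-((rt - mu) ** 2) / (2 * sigma**2))
    return Trace(rt=rt, intensity=y, target_mz=target_mz, ppm_window=10.0)


class TestTrace:
    def test_rejects_unsorted_grid(self):
        with pytest.raises(ValueError):
            Trace(np.array([1.0, 0.5]), np.array([0.0, 0.0]), 400.0, 10.0)

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            Trace(np.array([0.5, 1.0]), np.array([1.0, -1.0]), 400.0, 10.0)


class TestExtractXic:
    def test_summed_within_window_on_grid(self):
        run = pd.DataFrame(
            {
                "rt_min": [1.0, 1.0, 2.0, 3.0],
                "mz": [471.2422, 471.2500, 471.2423, 400.0],
                "intensity": [100.0, 50.0, 200.0, 10.0],
            }
        )
        t = extract_xic(run, 471.2422, 10.0)
        assert t.rt.tolist() == [1.0, 2.0, 3.0]
        # 471.25 is ~16 ppm away and must be excluded; absent scans are zero
        assert t.intensity.tolist() == [100.0, 200.0, 0.0]

    def test_no_matching_points_gives_all_zero(self):
        run = pd.DataFrame({"rt_min": [1.0, 2.0], "mz": [300.0, 301.0], "intensity": [5.0, 6.0]})
        t = extract_xic(run, 471.2422, 10.0)
        assert np.all(t.intensity == 0.0)

    def test_rejects_zero_window_and_empty_run(self):
        run = pd.DataFrame({"rt_min": [1.0], "mz": [400.0], "intensity": [1.0]})
        with pytest.raises(ValueError):
            extract_xic(run, 400.0, 0.0)
        with pytest.raises(ValueError):
            extract_xic(run.iloc[:0], 400.0, 10.0)

    def test_planted_gaussian_apex_recovered(self):
        rng = np.random.default_rng(11)
        rt = np.round(np.arange(20.0, 23.0, 0.01), 5)
        rows = []
        for r in rt:
            inten = 5000 * np.exp(-((r - 21.6) ** 2) / (2 * 0.05**2))
            if inten > 1:
                rows.append((r, 471.2422 * (1 + rng.normal(0, 2e-6)), inten))
            rows.append((r, 450.0, 100.0))  # unrelated channel keeps the grid full
        run = pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])
        t = extract_xic(run, 471.2422, 10.0)
        assert t.rt[np.argmax(t.intensity)] == pytest.approx(21.6, abs=0.011)

    def test_minimal_mzml_file(self, tmp_path):
        def encode(arr):
            return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()

        def scan(idx, rt, mzs, intens):
            arrays = f"""
              <binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
              <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
              <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
              <binary>{encode(mzs)}</binary></binaryDataArray>
              <binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
              <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
              <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
              <binary>{encode(intens)}</binary></binaryDataArray>"""
            return f"""<spectrum index="{idx}" id="scan={idx}" defaultArrayLength="{len(mzs)}">
              <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
              <scanList count="1"><scan>
                <cvParam cvRef="MS" accession="MS:1000016" name="scan start time"
                         value="{rt}" unitName="minute"/></scan></scanList>
              <binaryDataArrayList count="2">{arrays}</binaryDataArrayList></spectrum>"""

        doc = (
            '<?xml version="1.0" encoding="utf-8"?>'
            '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0"><run id="r">'
            f'<spectrumList count="2">{scan(0, 1.0, [471.2420, 400.0], [100.0, 5.0])}'
            f'{scan(1, 1.1, [471.2425], [200.0])}</spectrumList></run></mzML>'
        )
        path = tmp_path / "mini.mzML"
        path.write_text(doc)
        t = extract_xic(path, 471.2422, 10.0)
        assert t.rt.tolist() == [1.0, 1.1]
        assert t.intensity.tolist() == [100.0, 200.0]


class TestDetectPeaks:
    def test_all_zero_trace_has_no_peaks(self):
        t = Trace(np.arange(0, 5, 0.01), np.zeros(500), 400.0, 10.0)
        assert detect_peaks(t) == []

    def test_gaussian_area_matches_closed_form(self):
        amp, sigma = 1000.0, 0.05
        t = gaussian_trace([amp], [21.6], sigma=sigma)
        peaks = detect_peaks(t)
        assert len(peaks) == 1
        expected = amp * sigma * np.sqrt(2 * np.pi)
        assert peaks[0].area == pytest.approx(expected, rel=0.02)
        assert peaks[0].apex_rt == pytest.approx(21.6, abs=0.006)

    def test_two_well_separated_gaussians(self):
        t = gaussian_trace([1000.0, 800.0], [21.0, 22.5], sigma=0.05)
        peaks = detect_peaks(t)
        assert len(peaks) == 2
        assert peaks[0].apex_rt < peaks[1].apex_rt

    def test_area_additivity_under_concatenation(self):
        a = gaussian_trace([1000.0], [21.0], rt_range=(20.0, 22.0))
        b = gaussian_trace([500.0], [23.0], rt_range=(22.5, 24.5))
        joint = Trace(
            rt=np.concatenate([a.rt, b.rt]),
            intensity=np.concatenate([a.intensity, b.intensity]),
            target_mz=a.target_mz,
            ppm_window=a.ppm_window,
        )
        separate = detect_peaks(a) + detect_peaks(b)
        together = detect_peaks(joint)
        assert len(together) == len(separate) == 2
        for p, q in zip(together, separate):
            assert p.area == pytest.approx(q.area, rel=1e-6)

    def test_planted_peaks_recovered_in_noise(self):
        # SNR >= 10: recall must be 1.0 with zero false peaks
        rng = np.random.default_rng(3)
        rt = np.arange(18.0, 26.0, 0.005)
        noise = np.abs(rng.normal(0, 20, rt.size)) + 50
        y = noise.copy()
        planted = [20.0, 22.4, 24.8]
        for mu in planted:
            y += 2500 * np.exp(-((rt - mu) ** 2) / (2 * 0.05**2))
        peaks = detect_peaks(Trace(rt, y, 471.2422, 10.0), min_snr=3.0)
        assert len(peaks) == len(planted)
        for p, mu in zip(peaks, planted):
            assert p.apex_rt == pytest.approx(mu, abs=0.02)
            assert p.snr >= 10
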