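import numpy as np
import pytest

from pedinirs.core_io import DTOFHistogram, InstrumentResponse, OpticalProperties
from pedinirs.fitting import (
    FitConfig,
    dpf_from_mean_time,
    estimate_subject,
    fit_optical_properties,
    measured_mean_time,
    select_fit_window,
)
from pedinirs.forward_model import MediumGeometry, convolve_irf, mean_time, simulate_dtof, tr_reflectance
from pedinirs.synthetic_data import RepositioningModel, generate_cohort, simulate_protocol


def _triangle(peak_channel=50, n=200, peak=1000):
    up = np.linspace(0, peak, peak_channel + 1)
    down = np.linspace(peak, 0, n - peak_channel)[1:]
    return DTOFHistogram(
        counts=np.concatenate([up, down]).astype(int), channel_width=9.7
    )


class TestFitWindow:
    def test_brackets_the_peak(self):
        h = _triangle()
        cfg = FitConfig(background_channels=0)
        lo, hi = select_fit_window(h, cfg)
        assert lo <= 50 < hi

    def test_degenerate_fractions_select_the_peak_only(self):
        h = _triangle()
        cfg = FitConfig(
            window_rise_fraction=1.0, window_tail_fraction=1.0, background_channels=0
        )
        lo, hi = select_fit_window(h, cfg)
        assert lo == hi == 50

    def test_all_zero_histogram_rejected(self):
        h = DTOFHistogram(counts=np.zeros(64, dtype=int), channel_width=9.7)
        with pytest.raises(ValueError, match="all-zero"):
            select_fit_window(h, FitConfig())

    def test_window_captures_most_counts_of_a_physiological_dtof(
        self, instrument, geom, irf60
    ):
        subject = generate_cohort(seed=4)[0]
        proto = simulate_protocol(subject, instrument, irf=irf60, seed=9)
        h = proto[0].dtof
        lo, hi = select_fit_window(h, FitConfig())
        # the 80%-of-peak rising cut deliberately discards early photons, so
        # the window holds the bulk but not all of the counts
        assert h.counts[lo : hi + 1].sum() / h.total_counts >= 0.80


class TestFit:
    def test_noiseless_fit_recovers_truth(self, instrument, geom, irf60, t_grid):
        truth = OpticalProperties(mua=0.22, musp=12.0)
        conv = convolve_irf(tr_reflectance(truth, geom, t_grid), irf60)
        n = instrument.n_channels
        values = np.zeros(n)
        start = round(float(conv.times[0]) / instrument.channel_width)
        values[start:] = conv.values[: n - start]
        h = DTOFHistogram(
            counts=np.round(values * (1e9 / values.sum())).astype(np.int64),
            channel_width=instrument.channel_width,
        )
        report = fit_optical_properties(h, irf60, geom, FitConfig(weighting="uniform"))
        assert report.converged
        assert report.estimate.mua == pytest.approx(truth.mua, rel=1e-3)
        assert report.estimate.musp == pytest.approx(truth.musp, rel=1e-3)

    def test_channel_width_mismatch_rejected(self, geom):
        h = DTOFHistogram(counts=np.ones(64, dtype=int), channel_width=9.7)
        irf = InstrumentResponse(counts=np.ones(64, dtype=int), channel_width=10.0)
        with pytest.raises(ValueError, match="channel-width mismatch"):
            fit_optical_properties(h, irf, geom)

    def test_recovery_degrades_monotonically_with_fewer_counts(
        self, instrument, geom, irf60, t_grid
    ):
        truth = OpticalProperties(mua=0.22, musp=12.0)
        conv = convolve_irf(tr_reflectance(truth, geom, t_grid), irf60)
        n = instrument.n_channels
        values = np.zeros(n)
        start = round(float(conv.times[0]) / instrument.channel_width)
        values[start:] = conv.values[: n - start]
        from pedinirs.forward_model import ModelCurve

        curve = ModelCurve(times=t_grid, values=values)
        rng = np.random.default_rng(17)
        sds = []
        for total in (1e6, 1e5, 1e4):
            estimates = []
            for _ in range(8):
                h = simulate_dtof(curve, total, rng)
                report = fit_optical_properties(h, irf60, geom)
                estimates.append(report.estimate.mua)
            sds.append(np.std(estimates, ddof=1) / truth.mua)
        assert sds[0] < sds[1] < sds[2]


class TestDPF:
    def test_zero_mean_time_gives_zero_dpf(self, geom):
        assert dpf_from_mean_time(0.0, geom).dpf == 0.0

    def test_hand_example(self):
        geom = MediumGeometry(rho=2.5, refractive_index_tissue=1.4)
        res = dpf_from_mean_time(500.0, geom)
        # (c/1.4) * 500 ps / 2.5 cm = 4.283
        assert res.dpf == pytest.approx(4.283, abs=0.005)

    def test_inverse_proportional_to_rho(self):
        near = dpf_from_mean_time(500.0, MediumGeometry(rho=2.5))
        far = dpf_from_mean_time(500.0, MediumGeometry(rho=5.0))
        assert near.dpf == pytest.approx(2 * far.dpf)

    def test_measured_moment_matches_model_moment(self, instrument, geom, irf60, t_grid):
        """Instrument-corrected measured mean time reproduces the model
        curve's first moment once the IRF barycenter is removed."""
        truth = OpticalProperties(mua=0.22, musp=12.0)
        curve = tr_reflectance(truth, geom, t_grid)
        conv = convolve_irf(curve, irf60)
        n = instrument.n_channels
        values = np.zeros(n)
        start = round(float(conv.times[0]) / instrument.channel_width)
        values[start:] = conv.values[: n - start]
        h = DTOFHistogram(
            counts=np.round(values * (1e9 / values.sum())).astype(np.int64),
            channel_width=instrument.channel_width,
        )
        mt = measured_mean_time(h, irf60)
        assert mt == pytest.approx(mean_time(curve), rel=0.01)


class TestSubjectAggregation:
    def test_identical_dtofs_collapse_to_single_estimate(self, instrument, geom, irf60):
        subject = generate_cohort(seed=4)[10]
        quiet = RepositioningModel(mua_rel_sd=0, musp_rel_sd=0, amplitude_rel_sd=0)
        proto = simulate_protocol(subject, instrument, quiet, irf60, seed=5)
        one = [p for p in proto if p.wavelength == 686.0][0]
        measurements = [(rep, acq, one.dtof) for rep in range(1, 6) for acq in range(1, 6)]
        est = estimate_subject(measurements, irf60, geom)
        assert len(est.per_dtof) == 25
        single = est.per_dtof.iloc[0]
        assert est.subject_mean["mua"].iloc[0] == pytest.approx(single["mua"])
        rep_means = est.per_repositioning["mua"].to_numpy()
        assert np.std(rep_means) == pytest.approx(0.0, abs=1e-12)

    def test_protocol_yields_25_estimates_per_wavelength(self, instrument, geom, irf60):
        subject = generate_cohort(seed=4)[20]
        proto = simulate_protocol(subject, instrument, irf=irf60, seed=6)
        measurements = [
            (p.repositioning_index, p.acquisition_index, p.dtof)
            for p in proto
            if p.wavelength == 830.0
        ]
        est = estimate_subject(measurements, irf60, geom)
        assert len(est.per_dtof) == 25
        assert len(est.per_repositioning) == 5
        # subject mean is the arithmetic mean of the 25 per-DTOF estimates
        assert est.subject_mean["musp"].iloc[0] == pytest.approx(
            est.per_dtof["musp"].mean()
        )

    def test_empty_input_rejected(self, geom, irf60):
        with pytest.raises(ValueError, match="no measurements"):
            estimate_subject([], irf60, geom)
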