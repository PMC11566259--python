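import numpy as np
import pytest

from pedinirs.core_io import cohort_frame, write_cohort
from pedinirs.synthetic_data import (
    CLUSTER_LABELS,
    DRAWN_VARIABLES,
    REFERENCE_CELLS,
    REFERENCE_COUNTS,
    CohortSpec,
    RepositioningModel,
    filter_compliant,
    generate_cohort,
    generate_enrollment_fixture,
    generate_irf,
    simulate_protocol,
)


class TestCohortGeneration:
    def test_default_spec_reproduces_reference_counts(self):
        records = generate_cohort(seed=0)
        df = cohort_frame(records)
        assert (df["gender"] == "F").sum() == 157
        assert (df["gender"] == "M").sum() == 148
        assert len(records) == 305

    def test_fixed_seed_gives_byte_identical_cohort_files(self, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(generate_cohort(seed=11), a)
        write_cohort(generate_cohort(seed=11), b)
        assert a.read_bytes() == b.read_bytes()

    def test_zero_sd_spec_pins_every_subject_to_the_cell_mean(self):
        cells = {
            var: {key: (mean, 0.0) for key, (mean, _) in REFERENCE_CELLS[var].items()}
            for var in DRAWN_VARIABLES
        }
        spec = CohortSpec(cells=cells)
        df = cohort_frame(generate_cohort(spec, seed=1))
        sub = df[(df["gender"] == "F") & (df["age_years"] < 4)]
        assert np.allclose(sub["musp_686"], REFERENCE_CELLS["musp_686"][("2 to 4", "F")][0])
        assert np.allclose(sub["thb_um"], REFERENCE_CELLS["thb_um"][("2 to 4", "F")][0])

    def test_negative_sd_rejected(self):
        cells = {
            var: dict(REFERENCE_CELLS[var]) for var in DRAWN_VARIABLES
        }
        cells["bmi"][("2 to 4", "F")] = (15.0, -1.0)
        with pytest.raises(ValueError, match="negative SD"):
            CohortSpec(cells=cells)

    def test_hemodynamic_and_optical_truth_are_beer_consistent(self):
        from pedinirs.hemodynamics import invert_beer

        r = generate_cohort(seed=2)[0]
        state = invert_beer(r.mua_686, r.mua_830)
        assert state.hbo2 == pytest.approx(r.hbo2_um, rel=1e-9)
        assert state.hhb == pytest.approx(r.hhb_um, rel=1e-9)
        assert r.thb_um == pytest.approx(r.hbo2_um + r.hhb_um)

    def test_spo2_respects_its_physiological_ceiling(self):
        df = cohort_frame(generate_cohort(seed=3))
        assert (df["spo2_pct"] <= 100.0).all()

    def test_ages_stay_inside_their_cluster(self):
        df = cohort_frame(generate_cohort(seed=5))
        assert df["age_years"].between(2, 18).all()


class TestEnrollment:
    @pytest.mark.parametrize(
        "enrolled,flagged,compliant", [(307, 2, 305), (10, 0, 10), (5, 5, 0)]
    )
    def test_exclusion_filter(self, enrolled, flagged, compliant):
        records = generate_enrollment_fixture(enrolled, flagged, seed=1)
        assert len(records) == enrolled
        assert sum(not r.compliant for r in records) == flagged
        assert len(filter_compliant(records)) == compliant

    def test_over_flagging_rejected(self):
        with pytest.raises(ValueError):
            generate_enrollment_fixture(3, 4)


class TestIRFGeneration:
    def _fwhm(self, irf):
        c = irf.counts.astype(float)
        half = c.max() / 2.0
        above = np.nonzero(c >= half)[0]
        return (above[-1] - above[0]) * irf.channel_width

    def test_requested_fwhm_within_one_channel(self, instrument):
        irf = generate_irf(60.0, instrument, seed=2)
        assert self._fwhm(irf) == pytest.approx(60.0, abs=instrument.channel_width)

    def test_exp_modified_shape_has_a_slower_tail(self, instrument):
        gauss = generate_irf(60.0, instrument, shape="gaussian", seed=2)
        emg = generate_irf(60.0, instrument, shape="exp-modified", seed=2)
        assert emg.barycenter > gauss.barycenter

    def test_determinism_and_empty_rejection(self, instrument):
        assert generate_irf(60.0, instrument, seed=3) == generate_irf(
            60.0, instrument, seed=3
        )
        with pytest.raises(ValueError, match="nonempty"):
            generate_irf(60.0, instrument, total_counts=0)

    def test_sub_channel_fwhm_warns(self, instrument):
        with pytest.warns(UserWarning, match="quantization"):
            generate_irf(5.0, instrument, seed=1)


class TestProtocolSimulation:
    def test_25_dtofs_per_wavelength_with_grouping_metadata(self, instrument, irf60):
        subject = generate_cohort(seed=4)[0]
        proto = simulate_protocol(subject, instrument, irf=irf60, seed=8)
        for wl in (686.0, 830.0):
            sub = [p for p in proto if p.wavelength == wl]
            assert len(sub) == 25
            keys = {(p.repositioning_index, p.acquisition_index) for p in sub}
            assert keys == {(r, a) for r in range(1, 6) for a in range(1, 6)}

    def test_quiet_model_gives_statistically_identical_repositionings(
        self, instrument, irf60
    ):
        subject = generate_cohort(seed=4)[0]
        quiet = RepositioningModel(mua_rel_sd=0, musp_rel_sd=0, amplitude_rel_sd=0)
        proto = simulate_protocol(subject, instrument, quiet, irf60, seed=8)
        totals = [p.dtof.total_counts for p in proto if p.wavelength == 686.0]
        # all 25 draws share one expected curve: totals scatter like Poisson
        assert np.std(totals) < 5 * np.sqrt(np.mean(totals))

    def test_fixed_seed_reproduces_the_protocol(self, instrument, irf60):
        subject = generate_cohort(seed=4)[1]
        a = simulate_protocol(subject, instrument, irf=irf60, seed=13)
        b = simulate_protocol(subject, instrument, irf=irf60, seed=13)
        assert all(x.dtof == y.dtof for x, y in zip(a, b))

    def test_subject_without_truth_rejected(self, instrument, irf60):
        subject = generate_cohort(seed=4)[2]
        subject.mua_686 = None
        with pytest.raises(ValueError, match="true optical properties"):
            simulate_protocol(subject, instrument, irf=irf60, seed=1)
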