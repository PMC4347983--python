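import numpy as np
import pytest

from kinteam.mechanics import MechanicalParams
from kinteam.rebinding import (
    AttachmentProfile,
    PositionPdf,
    RebindingStep,
    binding_probabilities,
    calibrate_CA,
    cargo_pdf,
    load_free_unbound_pdf,
    mean_site_rates,
    relative_pdf,
    sample_rebinding,
    site_rate_profile,
    time_avg_rate,
    total_mean_rate,
    unbound_pdf,
)


class TestCargoPdf:
    def test_normalized(self, mech):
        assert cargo_pdf([0.0], 0.0, mech).integral() == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_about_anchor_without_load(self, mech):
        pdf = cargo_pdf([16.0], 0.0, mech)
        assert pdf.mean() == pytest.approx(16.0, abs=1e-3)

    def test_plateau_over_slack_window(self, mech):
        pdf = cargo_pdf([0.0], 0.0, mech)
        inside = pdf.density[np.abs(pdf.x) < mech.L_c - 1.0]
        assert inside.max() - inside.min() < 1e-9 * inside.max()

    def test_hindering_load_shifts_minus_ward(self, mech):
        pdf = cargo_pdf([0.0], 4.0, mech)
        assert pdf.mean() < 0.0

    def test_no_bound_motor_rejected(self, mech):
        with pytest.raises(ValueError):
            cargo_pdf([], 0.0, mech)


class TestRelativePdf:
    def test_zero_mean(self, mech):
        assert relative_pdf(mech).mean() == pytest.approx(0.0, abs=1e-6)

    def test_equals_load_free_cargo_pdf_at_origin(self, mech):
        rel = relative_pdf(mech)
        ref = cargo_pdf([0.0], 0.0, mech)
        common = np.linspace(-30, 30, 601)
        assert np.allclose(
            np.interp(common, rel.x, rel.density),
            np.interp(common, ref.x, ref.density),
            rtol=1e-6, atol=1e-9,
        )

    def test_plateau_half_width_is_slack_length(self, mech):
        rel = relative_pdf(mech)
        peak = rel.density.max()
        inside = np.interp(mech.L_c - 0.5, rel.x, rel.density)
        outside = np.interp(mech.L_c + 5.0, rel.x, rel.density)
        assert inside == pytest.approx(peak, rel=1e-6)
        assert outside < peak


class TestConvolution:
    def test_delta_kernel_identity(self, mech):
        cargo = cargo_pdf([0.0], 0.0, mech)
        dx = cargo.dx
        x = np.arange(-3 * dx, 3 * dx + dx / 2, dx)
        delta = PositionPdf(x, np.where(np.abs(x) < dx / 2, 1.0 / dx, 0.0))
        out = unbound_pdf(cargo, delta)
        assert out.mean() == pytest.approx(cargo.mean(), abs=1e-3)
        assert out.var() == pytest.approx(cargo.var(), rel=1e-3)

    def test_variance_additivity(self, mech):
        cargo = cargo_pdf([0.0], 3.0, mech)
        rel = relative_pdf(mech)
        out = unbound_pdf(cargo, rel)
        assert out.var() == pytest.approx(cargo.var() + rel.var(), rel=1e-3)

    def test_variance_against_double_integral_oracle(self):
        """Brute-force E[(x+y)^2] over the product density on coarse grids."""
        x = np.linspace(-5, 5, 401)
        f = np.exp(-0.5 * x**2)
        g = np.exp(-np.abs(x))
        pf = PositionPdf(x, f).normalize()
        pg = PositionPdf(x.copy(), g).normalize()
        out = unbound_pdf(pf, pg)
        X, Y = np.meshgrid(x, x, indexing="ij")
        w = np.outer(pf.density, pg.density)
        m2 = np.trapezoid(np.trapezoid((X + Y) ** 2 * w, x, axis=1), x)
        assert out.var() == pytest.approx(m2, rel=2e-3)

    def test_normalization_preserved(self, mech):
        out = load_free_unbound_pdf(mech)
        assert out.integral() == pytest.approx(1.0, abs=1e-6)

    def test_grid_mismatch_resampled(self, mech):
        cargo = cargo_pdf([0.0], 0.0, mech)
        x = np.arange(-40.0, 40.0, 0.25)
        rel = PositionPdf(x, np.exp(-0.01 * x**2)).normalize()
        out = unbound_pdf(cargo, rel)
        assert out.dx == pytest.approx(cargo.dx)
        assert out.integral() == pytest.approx(1.0, abs=1e-5)


class TestAttachmentProfile:
    def test_peak_at_site(self, profile):
        assert site_rate_profile(8.0, 8.0, profile) == profile.C_A

    def test_zero_beyond_half_width(self, profile):
        assert site_rate_profile(8.0 + profile.half_width, 8.0, profile) == 0.0
        assert site_rate_profile(8.0 - 6.0, 8.0, profile) == 0.0

    def test_three_quarters_at_half_distance(self, profile):
        v = site_rate_profile(8.0 + profile.half_width / 2, 8.0, profile)
        assert v == pytest.approx(0.75 * profile.C_A)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            AttachmentProfile(half_width=0.0)


class TestTimeAverage:
    def test_near_delta_pdf_gives_peak_rate(self, profile):
        dx = 0.01
        x = np.arange(-0.05, 0.05 + dx / 2, dx)
        delta = PositionPdf(x, np.where(np.abs(x) < dx / 2, 1 / dx, 0.0)).normalize()
        assert time_avg_rate(delta, 0.0, profile) == pytest.approx(profile.C_A, rel=1e-4)

    def test_uniform_over_support_gives_two_thirds(self, profile):
        w = profile.half_width
        x = np.linspace(-w, w, 1601)
        uni = PositionPdf(x, np.full_like(x, 1 / (2 * w)))
        assert time_avg_rate(uni, 0.0, profile) == pytest.approx(2 / 3 * profile.C_A, rel=1e-5)

    def test_disjoint_support_gives_zero(self, profile):
        x = np.linspace(100.0, 120.0, 201)
        far = PositionPdf(x, np.full_like(x, 1 / 20.0))
        assert time_avg_rate(far, 0.0, profile) == 0.0


class TestBindingProbabilities:
    def _flat_pdf(self):
        x = np.linspace(-24, 24, 961)
        return PositionPdf(x, np.full_like(x, 1 / 48.0))

    def test_linear_in_T_and_PK(self, profile):
        pdf = self._flat_pdf()
        s1 = binding_probabilities(pdf, profile, P_K=1.0, T=1e-3)
        s2 = binding_probabilities(pdf, profile, P_K=1.0, T=2e-3)
        s3 = binding_probabilities(pdf, profile, P_K=0.5, T=2e-3)
        assert np.allclose(s2.P_A, 2 * s1.P_A)
        assert np.allclose(s3.P_A, s1.P_A)

    def test_already_bound_gives_zero(self, profile):
        s = binding_probabilities(self._flat_pdf(), profile, P_K=0.0, T=1e-3)
        assert s.total == 0.0

    def test_single_site_arithmetic(self):
        step = RebindingStep(sites=[0], mean_rates=[5.0], P_K=1.0, T=1e-3)
        assert step.P_A[0] == pytest.approx(0.005)

    def test_oversized_interval_rejected(self, profile):
        with pytest.raises(ValueError):
            binding_probabilities(self._flat_pdf(), profile, P_K=1.0, T=1.0)

    def test_occupied_sites_excluded(self, profile):
        s = binding_probabilities(self._flat_pdf(), profile, P_K=1.0, T=1e-3, excluded_sites=[0])
        assert 0 not in s.sites


class TestCalibration:
    def test_calibrated_peak_rate(self, mech):
        # calibrating to the ~5 1/s bead-assay rate recovers C_A ~ 7.68 1/s
        C_A = calibrate_CA(5.0, mech)
        assert C_A == pytest.approx(7.68, rel=0.10)

    def test_peak_768_gives_mean_rate_5p1(self, mech):
        pdf = load_free_unbound_pdf(mech)
        total = total_mean_rate(pdf, AttachmentProfile(C_A=7.68))
        assert total == pytest.approx(5.1, rel=0.10)

    def test_linearity_in_target(self, mech):
        assert calibrate_CA(10.0, mech) == pytest.approx(2 * calibrate_CA(5.0, mech))

    def test_nonpositive_target_rejected(self, mech):
        with pytest.raises(ValueError):
            calibrate_CA(0.0, mech)


class TestSampleRebinding:
    def test_zero_total_never_binds(self):
        step = RebindingStep(sites=[0, 1], mean_rates=[0.0, 0.0], P_K=1.0, T=1e-3)
        assert sample_rebinding(step, 0.001, 0.5) is None

    def test_plus_end_site_chosen_by_late_draw(self):
        step = RebindingStep(sites=[3, 4], mean_rates=[10.0, 10.0], P_K=1.0, T=1e-3)
        assert sample_rebinding(step, 1e-6, 0.75) == 4
        assert sample_rebinding(step, 1e-6, 0.25) == 3

    def test_site_choice_frequencies(self, rng):
        step = RebindingStep(sites=[0, 1, 2], mean_rates=[1.0, 3.0, 6.0], P_K=1.0, T=1e-3)
        picks = []
        for _ in range(100_000):
            s = sample_rebinding(step, 1e-9, rng.uniform(1e-9, 1 - 1e-9))
            picks.append(s)
        freqs = np.array([picks.count(j) for j in (0, 1, 2)]) / len(picks)
        expect = np.array([0.1, 0.3, 0.6])
        se = np.sqrt(expect * (1 - expect) / len(picks))
        assert np.all(np.abs(freqs - expect) < 4 * se)

    def test_invalid_draws_rejected(self):
        step = RebindingStep(sites=[0], mean_rates=[1.0], P_K=1.0, T=1e-3)
        with pytest.raises(ValueError):
            sample_rebinding(step, 0.0, 0.5)


@pytest.fixture(scope="module")
def totals_and_means():
    mech = MechanicalParams()
    profile = AttachmentProfile()
    rel = relative_pdf(mech)
    out = {}
    for F_L in (-5.0, 0.0, 2.0, 5.0, 10.0):
        pdf_u = unbound_pdf(cargo_pdf([0.0], F_L, mech), rel)
        sites, rates = mean_site_rates(pdf_u, profile)
        tot = rates.sum()
        out[F_L] = (tot, (sites * rates).sum() / tot)
    return out


class TestLoadDependence:
    def test_total_rate_load_invariant(self, totals_and_means):
        totals = [v[0] for v in totals_and_means.values()]
        assert (max(totals) - min(totals)) / min(totals) < 0.10

    def test_hindering_load_shifts_sites_minus_ward(self, totals_and_means):
        assert totals_and_means[2.0][1] < totals_and_means[0.0][1]
        assert totals_and_means[10.0][1] < totals_and_means[2.0][1]

    def test_assisting_load_shifts_sites_ahead(self, totals_and_means):
        # mean rebinding position lands in front of the bound motor
        assert totals_and_means[-5.0][1] > 0.0
        assert totals_and_means[5.0][1] < 0.0
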