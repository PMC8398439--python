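import dataclasses

import numpy as np
import pytest

import twdiss as tw
from twdiss.geometry import CapacityError
from twdiss.metrics import f1_f2
from twdiss.simulate import (
    DEFAULT_DIFFUSION_CM2_PER_H,
    DrugProperties,
    hayduk_laudie_D,
    solution_closed_form,
)


class TestHaydukLaudie:
    def test_unit_arguments(self):
        # η = 1 cP, V_M = 1 cm³/mol → 13.26e-5 cm²/s before unit conversion
        assert hayduk_laudie_D(1.0, 1.0) == pytest.approx(13.26e-5 * 3600, rel=1e-12)

    def test_molecular_volume_power_law(self):
        ratio = hayduk_laudie_D(0.69, 600.0) / hayduk_laudie_D(0.69, 300.0)
        assert ratio == pytest.approx(2 ** -0.589, rel=1e-12)

    def test_default_constant_is_physically_consistent(self):
        # the fluticasone default should be in the range Hayduk–Laudie
        # gives for water at 37 °C and a steroid-sized molecule
        d = hayduk_laudie_D(0.69, 380.0)
        assert d == pytest.approx(DEFAULT_DIFFUSION_CM2_PER_H, rel=0.10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            hayduk_laudie_D(0.0, 300.0)

    def test_drug_properties_resolve_d_from_eta_and_vm(self):
        drug = DrugProperties(
            diffusion_coefficient=None, water_viscosity=0.69, molecular_volume=380.0
        )
        assert drug.resolved_diffusion_coefficient == pytest.approx(
            hayduk_laudie_D(0.69, 380.0)
        )

    def test_drug_properties_need_d_or_eta_vm(self):
        with pytest.raises(ValueError):
            DrugProperties(diffusion_coefficient=None, water_viscosity=0.69)


class TestSolutionClosedForm:
    def test_equilibrium_receptor_fraction(self, solution_config):
        """Without sampling, the receptor ends with V_r/(V_d+V_r) of the drug."""
        cfg = dataclasses.replace(
            solution_config,
            schedule=tw.SamplingSchedule(times_min=(6000.0,), sample_volume=0.0),
        )
        res = solution_closed_form(cfg)
        assert res.observed_percent[-1] / 100 == pytest.approx(
            1.5 / (0.58 + 1.5), rel=1e-9
        )

    def test_rate_constant(self, solution_config):
        """Bench parameters give k = P·SM·(1/V_d + 1/V_r) = 3.124 h⁻¹."""
        k = 0.289 * 4.52 * (1 / 0.58 + 1 / 1.5)
        cfg = dataclasses.replace(
            solution_config,
            schedule=tw.SamplingSchedule(times_min=(30.0,), sample_volume=0.0),
        )
        res = solution_closed_form(cfg)
        frac_r = 1.5 / (0.58 + 1.5)
        t_h = res.time_min / 60.0
        expected = 100 * frac_r * (1 - np.exp(-k * t_h))
        assert res.cumulative_transferred_percent == pytest.approx(expected, abs=1e-9)
        assert k == pytest.approx(3.124, rel=1e-3)

    def test_initial_condition(self, solution_config):
        res = solution_closed_form(solution_config)
        assert res.time_min[0] == 0.0
        assert res.donor_dissolved[0] == solution_config.initial_amount
        assert res.receptor_amount[0] == 0.0

    def test_rejects_particle_config(self, particle_config):
        with pytest.raises(ValueError):
            solution_closed_form(particle_config)


class TestSimulateSolution:
    def test_matches_closed_form(self, solution_config, solution_result):
        """Adaptive integration agrees with the analytic two-compartment solution."""
        exact = solution_closed_form(solution_config)
        x0 = solution_config.initial_amount
        assert solution_result.time_min == pytest.approx(exact.time_min)
        assert solution_result.donor_dissolved == pytest.approx(
            exact.donor_dissolved, abs=1e-6 * x0
        )
        assert solution_result.receptor_amount == pytest.approx(
            exact.receptor_amount, abs=1e-6 * x0
        )
        assert solution_result.observed_percent == pytest.approx(
            exact.observed_percent, abs=1e-4
        )

    def test_impermeable_membrane(self, solution_config):
        cfg = dataclasses.replace(
            solution_config, drug=dataclasses.replace(solution_config.drug, permeability=0.0)
        )
        res = tw.simulate(cfg)
        assert np.all(res.receptor_amount == 0.0)
        assert np.all(res.removed_cumulative == 0.0)

    def test_sixty_percent_transfer_around_thirty_minutes(self, solution_result):
        t60 = tw.time_to_fraction(solution_result, 0.6)
        assert t60 == pytest.approx(30.0, rel=0.2)


class TestSimulateParticles:
    def test_mass_conservation(self, particle_result, solution_result):
        assert particle_result.mass_balance_error() < 1e-9
        assert solution_result.mass_balance_error() < 1e-9

    def test_euler_oracle_agreement(self, particle_config):
        """Adaptive and fixed-step Euler integration agree on the observed profile."""
        adaptive = tw.simulate(particle_config)
        euler = tw.simulate(particle_config, method="euler")
        assert euler.mass_balance_error() < 1e-9
        assert np.max(np.abs(adaptive.observed_percent - euler.observed_percent)) < 0.5

    def test_observed_profile_monotone_and_bounded(self, particle_result):
        obs = particle_result.observed_percent
        assert np.all(np.diff(obs) >= 0)
        assert obs[-1] <= 100.0 + 1e-9

    def test_donor_concentration_capped_by_solubility(self, particle_result):
        cs = particle_result.config.medium.solubility
        assert particle_result.donor_concentration.max() <= cs * (1 + 1e-6)

    def test_higher_solubility_is_never_slower(self, particle_config):
        lo = tw.simulate(
            dataclasses.replace(particle_config, medium=tw.MediumProperties(5.3))
        )
        hi = tw.simulate(
            dataclasses.replace(particle_config, medium=tw.MediumProperties(19.12))
        )
        assert np.all(hi.observed_percent >= lo.observed_percent - 1e-9)

    def test_instantaneous_dissolution_limit(self, formulation_c_psd):
        """Effectively infinite solubility with fine particles reproduces a solution run."""
        fine = tw.synthetic_psd(mmad=0.3, gsd=1.3)
        cfg = tw.ExperimentConfig(psd=fine, medium=tw.MediumProperties(1e6))
        sol = tw.ExperimentConfig(psd=None, medium=tw.MediumProperties(1e6))
        res = f1_f2(
            tw.simulate(sol).observed_profile(), tw.simulate(cfg).observed_profile()
        )
        assert res.f1 < 1.0

    def test_sampling_jump_bookkeeping(self, particle_result):
        """Each sample moves Y·V_s/V_r from the receptor into the removed pool."""
        t = particle_result.time_min
        vs = particle_result.config.schedule.sample_volume
        vr = particle_result.config.receptor_volume
        for t_k in particle_result.observed_times_min[:-1]:
            idx = np.nonzero(t == t_k)[0]
            assert idx.size == 2  # pre- and post-sample rows
            pre, post = idx
            y_pre = particle_result.receptor_amount[pre]
            removed = (
                particle_result.removed_cumulative[post]
                - particle_result.removed_cumulative[pre]
            )
            assert removed == pytest.approx(y_pre * vs / vr, rel=1e-9)


class TestConfigValidation:
    def test_volumes_must_fit_apparatus(self, formulation_c_psd):
        cfg = tw.ExperimentConfig(psd=formulation_c_psd, donor_volume=5.0)
        with pytest.raises(CapacityError):
            tw.simulate(cfg)

    def test_sample_volume_cannot_exceed_receptor(self):
        cfg = tw.ExperimentConfig(
            schedule=tw.SamplingSchedule(times_min=(10.0,), sample_volume=2.0),
            receptor_volume=1.5,
        )
        with pytest.raises(ValueError):
            tw.simulate(cfg)

    def test_schedule_times_must_increase(self):
        with pytest.raises(ValueError):
            tw.SamplingSchedule(times_min=(10.0, 10.0))
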