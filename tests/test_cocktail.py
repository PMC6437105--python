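"""Killing-dynamics model: analytic limits, conservation, scenario library."""

from dataclasses import replace

import numpy as np
import pytest

from phagechar import (
    Bacterium,
    CocktailScenario,
    PHAGE_PRESETS,
    control_of,
    killing_summary,
    scenario_library,
    simulate,
)
from phagechar.errors import InvalidParameterError, ScenarioError
from phagechar.synthetic import PhagePreset


@pytest.fixture(scope="module")
def library():
    return scenario_library("normalized")


@pytest.fixture(scope="module")
def control_traj(library):
    return simulate(library["control"])


class TestAnalyticLimits:
    def test_no_phage_matches_logistic_closed_form(self, library, control_traj):
        sc = library["control"]
        S0 = sum(b.s0 for b in sc.bacteria)
        r, K = sc.bacteria[0].r, sc.carrying_capacity
        t = control_traj.times_min
        closed = K * S0 * np.exp(r * t) / (K + S0 * (np.exp(r * t) - 1.0))
        total = control_traj.susceptible.sum(axis=1)
        assert np.max(np.abs(total - closed) / closed) < 1e-3

    def test_zero_dose_phage_equivalent_to_no_infection(self, library, control_traj):
        sc = replace(library["EKL4"], doses=[0.0, 0.0, 0.0], name="zero_dose")
        traj = simulate(sc)
        total = traj.susceptible.sum(axis=1)
        ctrl = control_traj.susceptible.sum(axis=1)
        n = min(total.size, ctrl.size)
        assert np.allclose(total[:n], ctrl[:n], rtol=1e-6)

    def test_no_replication_populations_nonincreasing(self):
        # burst 1 (minimum) and r = 0: bacteria fall, phage never amplify
        phage = PhagePreset("min_burst", 2.8e-9, 11.0, 1.0)
        sc = CocktailScenario(
            name="no_growth",
            phages=[phage],
            doses=[1e6],
            bacteria=[Bacterium("b", 1e6, r=0.0)],
            infectivity=np.ones((1, 1)),
        )
        traj = simulate(sc, t_end_min=360.0)
        assert np.all(np.diff(traj.susceptible[:, 0]) <= 1e-6 * traj.susceptible[0, 0])
        assert np.all(traj.phage <= 1e6 * (1 + 1e-6))


class TestConservationAndShape:
    def test_adsorbed_phage_equal_infected_cells_created(self, library):
        traj = simulate(library["KL2"], t_end_min=90.0)
        c_in = traj.audit["cumulative_infections"]
        c_out = traj.audit["cumulative_lyses"]
        e_tot = traj.infected
        resid = np.abs(e_tot - (c_in - c_out)).max()
        assert resid <= 1e-6 * max(c_in.max(), 1.0)

    def test_phage_mass_balance(self, library):
        traj = simulate(library["mono_E"], t_end_min=90.0)
        sc = traj.scenario
        b = sc.phages[0].burst
        expected = sc.doses[0] + (
            b * traj.audit["cumulative_lyses"][:, 0, 0]
            - traj.audit["cumulative_infections"][:, 0, 0]
        )
        assert np.allclose(traj.phage[:, 0], expected, rtol=1e-6, atol=1e-3)

    def test_nonnegative_compartments(self, library):
        for name in ("EK1", "EL3", "EKL4"):
            traj = simulate(library[name])
            assert traj.susceptible.min() >= 0
            assert traj.infected.min() >= 0
            assert traj.phage.min() >= 0

    def test_extinct_species_stay_zero(self, library):
        traj = simulate(library["EKL4"])
        viable = traj.viable
        for i in range(viable.shape[1]):
            crossed = np.flatnonzero(viable[:, i] == 0.0)
            if crossed.size:
                assert np.all(viable[crossed[0] :, i] == 0.0)

    def test_erlang_chain_first_lysis_converges_to_latent(self, library):
        mono = library["mono_E"]
        latent = mono.phages[0].latent_min
        t_first = []
        for n in (10, 20, 40):
            traj = simulate(replace(mono, n_stages=n), t_end_min=120.0, dt_out=0.25)
            lysed = traj.audit["cumulative_lyses"].sum(axis=(1, 2))
            infected = traj.audit["cumulative_infections"].sum(axis=(1, 2))
            thr = 0.01 * infected[np.searchsorted(traj.times_min, latent)]
            t_first.append(traj.times_min[np.argmax(lysed > thr)])
        gaps = [latent - t for t in t_first]
        assert all(g > 0 for g in gaps)
        assert gaps[0] > gaps[1] > gaps[2]  # spread shrinks monotonically with n

    def test_doubling_burst_never_increases_viable_count(self):
        base = PHAGE_PRESETS["escherichia_myPSH2311"]
        finals = []
        for mult in (1.0, 2.0, 4.0):
            phage = PhagePreset("sweep", base.k_ads, base.latent_min, base.burst * mult)
            sc = CocktailScenario(
                name=f"sweep_{mult}",
                phages=[phage],
                doses=[1e4],
                bacteria=[Bacterium("b", 1e6)],
                infectivity=np.ones((1, 1)),
                sample_times_h=(0.0, 1.0),
            )
            traj = simulate(sc, t_end_min=60.0)
            finals.append(traj.viable[-1, 0])
        assert finals[0] >= finals[1] >= finals[2]


class TestEndpoints:
    def test_kl2_reaches_1e3_within_2h(self, library):
        at = simulate(library["KL2"]).at_hours()
        assert at.loc[at.time_h == 2.0, "viable_total"].iloc[0] <= 1e3

    def test_ekl4_extinct_at_24h(self, library):
        at = simulate(library["EKL4"]).at_hours()
        assert at.loc[at.time_h == 24.0, "viable_total"].iloc[0] == 0.0

    def test_killing_summary_arithmetic(self, library, control_traj):
        ks = killing_summary(simulate(library["KL2"]), control_traj)
        row0 = ks[ks.time_h == 0.0].iloc[0]
        assert row0["log10_reduction_vs_control"] == pytest.approx(0.0, abs=1e-6)
        row24 = ks[ks.time_h == 24.0].iloc[0]
        assert row24["extinct"]
        assert row24["log10_reduction_vs_baseline"] == pytest.approx(6.0, abs=0.01)

    def test_identical_trajectories_zero_reduction(self, control_traj):
        ks = killing_summary(control_traj, control_traj)
        assert np.allclose(ks["log10_reduction_vs_control"], 0.0)

    def test_mismatched_sample_times_rejected(self, library, control_traj):
        other = simulate(replace(library["KL2"], sample_times_h=(0.0, 2.0)))
        with pytest.raises(InvalidParameterError):
            killing_summary(other, control_traj)


class TestScenarioLibrary:
    def test_ekl4_composition(self, library):
        sc = library["EKL4"]
        assert len(sc.phages) == 3 and len(sc.bacteria) == 3
        assert np.array_equal(sc.infectivity, np.eye(3))

    def test_control_has_no_phage(self, library):
        assert library["control"].phages == []

    def test_ek1_excludes_enterobacter(self, library):
        sc = library["EK1"]
        ids = [b.bacterium_id for b in sc.bacteria] + [p.phage_id for p in sc.phages]
        assert not any("cloacae" in x or "enterobacter" in x for x in ids)

    def test_variants_set_inoculum_totals(self):
        for variant, total in (("normalized", 1e6), ("assay", 6e6)):
            lib = scenario_library(variant)
            for sc in lib.values():
                assert sum(b.s0 for b in sc.bacteria) == pytest.approx(total)

    def test_unknown_variant_and_override_errors(self, library):
        with pytest.raises(ScenarioError):
            scenario_library("bogus")

    def test_control_of_strips_phages(self, library):
        ctrl = control_of(library["KL2"])
        assert ctrl.phages == [] and len(ctrl.bacteria) == 2

    def test_determinism(self, library):
        a = simulate(library["KL2"])
        b = simulate(library["KL2"])
        assert np.array_equal(a.susceptible, b.susceptible)
        assert np.array_equal(a.phage, b.phage)
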