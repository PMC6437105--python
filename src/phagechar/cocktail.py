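"""Deterministic multi-phage / multi-host killing-dynamics model.

The model couples logistic bacterial growth to mass-action phage infection
with a distributed lysis delay.  For bacterium i (susceptible density S_i,
CFU/mL) and phage j (free density P_j, PFU/mL), with binary infectivity
I_ij, adsorption constant k_j (mL/min), latent period L_j (min) and burst
size b_j:

    dS_i/dt = r_i S_i (1 - N/K) - S_i * sum_j I_ij k_j P_j
    dE_ij1/dt = I_ij k_j P_j S_i - (n/L_j) E_ij1
    dE_ijm/dt = (n/L_j) (E_ij,m-1 - E_ijm)        m = 2..n
    dP_j/dt  = b_j (n/L_j) sum_i E_ijn - sum_i I_ij k_j P_j S_i

where the infected cells pass through an n-stage Erlang chain (n = 10 by
default), giving a lysis delay with mean L_j and coefficient of variation
1/sqrt(n) — a stiff-solver-friendly stand-in for a fixed delay.  N is the
total bacterial density (susceptible + infected) sharing one carrying
capacity K.  Free phage adsorb only to susceptible cells.

A bacterial species whose viable density (susceptible + infected by
default) falls below the extinction threshold (1 CFU/mL) is clamped to zero
for the rest of the run — the deterministic reading of "no viable cells".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import (
    IntegrationError,
    InvalidParameterError,
    ScenarioError,
)
from .synthetic import PHAGE_PRESETS, PhagePreset

__all__ = [
    "Bacterium",
    "CocktailScenario",
    "Trajectory",
    "simulate",
    "killing_summary",
    "scenario_library",
    "control_of",
    "SAMPLE_TIMES_H",
]

#: Hour marks at which killing assays are titered.
SAMPLE_TIMES_H = (0.0, 2.0, 4.0, 6.0, 24.0)

#: Default calibration shared by all three species: growth rate 0.023/min
#: (~30 min doubling time) and carrying capacity 1e9 CFU/mL.
DEFAULT_GROWTH_RATE = 0.023
DEFAULT_CARRYING_CAPACITY = 1e9
DEFAULT_EXTINCTION_THRESHOLD = 1.0  # CFU/mL
DEFAULT_N_STAGES = 10


@dataclass(frozen=True)
class Bacterium:
    """One bacterial species in a killing assay."""

    bacterium_id: str
    s0: float  # initial density, CFU/mL
    r: float = DEFAULT_GROWTH_RATE  # per min

    def __post_init__(self):
        if self.s0 < 0:
            raise InvalidParameterError("initial density must be >= 0")


@dataclass
class CocktailScenario:
    """Composition and parameters of one killing-assay simulation."""

    name: str
    phages: list[PhagePreset]
    doses: list[float]  # initial free phage, PFU/mL, aligned with phages
    bacteria: list[Bacterium]
    infectivity: np.ndarray  # (n_bacteria, n_phages) binary
    carrying_capacity: float = DEFAULT_CARRYING_CAPACITY
    sample_times_h: tuple = SAMPLE_TIMES_H
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD
    n_stages: int = DEFAULT_N_STAGES
    viable_includes_infected: bool = False
    nominal_moi: float | None = None  # as stated in the assay write-up

    def __post_init__(self):
        self.infectivity = np.atleast_2d(np.asarray(self.infectivity, dtype=float))
        nb, nph = len(self.bacteria), len(self.phages)
        if nph == 0:
            self.infectivity = np.zeros((nb, 0))
        if self.infectivity.shape != (nb, nph):
            raise ScenarioError(
                f"{self.name}: infectivity shape {self.infectivity.shape} != ({nb}, {nph})"
            )
        if len(self.doses) != nph:
            raise ScenarioError(f"{self.name}: {len(self.doses)} doses for {nph} phages")
        if any(d < 0 for d in self.doses):
            raise InvalidParameterError("phage doses must be >= 0")
        total = sum(b.s0 for b in self.bacteria)
        if self.carrying_capacity < total:
            raise InvalidParameterError("carrying capacity below total initial density")


@dataclass
class Trajectory:
    """Simulated state over time, in minutes, plus hour-mark snapshots."""

    scenario: CocktailScenario
    times_min: np.ndarray
    susceptible: np.ndarray  # (nt, n_bacteria) CFU/mL
    infected: np.ndarray  # (nt, n_bacteria, n_phages) summed over stages
    phage: np.ndarray  # (nt, n_phages) PFU/mL
    audit: dict = field(default_factory=dict)

    @property
    def viable(self) -> np.ndarray:
        """Viable CFU/mL per bacterium, floored to 0 below the extinction threshold.

        By default only susceptible cells count as colony-forming: infected
        cells are committed to lysis and do not plate.  Set the scenario flag
        ``viable_includes_infected`` to count them until lysis instead.
        """
        v = self.susceptible.copy()
        if self.scenario.viable_includes_infected:
            v = v + self.infected.sum(axis=2)
        v[v < self.scenario.extinction_threshold] = 0.0
        return v

    def at_hours(self, hours=None) -> pd.DataFrame:
        """Viable counts and free phage at the assay hour marks."""
        hours = np.asarray(self.scenario.sample_times_h if hours is None else hours, float)
        rows = []
        for h in hours:
            idx = int(np.argmin(np.abs(self.times_min - 60.0 * h)))
            row = {"time_h": h}
            for b, bac in enumerate(self.scenario.bacteria):
                row[f"viable_{bac.bacterium_id}"] = self.viable[idx, b]
            row["viable_total"] = float(self.viable[idx].sum())
            for j, ph in enumerate(self.scenario.phages):
                row[f"phage_{ph.phage_id}"] = self.phage[idx, j]
            rows.append(row)
        return pd.DataFrame(rows)


def _pack_rhs(scenario: CocktailScenario):
    nb = len(scenario.bacteria)
    nph = len(scenario.phages)
    n = scenario.n_stages
    r = np.array([b.r for b in scenario.bacteria])
    k = np.array([p.k_ads for p in scenario.phages])
    burst = np.array([p.burst for p in scenario.phages])
    rate = np.array([n / p.latent_min for p in scenario.phages])  # stage rate per phage
    I = scenario.infectivity
    K = scenario.carrying_capacity

    ne = nb * nph * n

    def rhs(t, y, alive):
        S = np.clip(y[:nb], 0.0, None) * alive
        E = np.clip(y[nb : nb + ne].reshape(nb, nph, n), 0.0, None) * alive[:, None, None]
        P = np.clip(y[nb + ne : nb + ne + nph], 0.0, None)

        infection = I * (k * P)[None, :] * S[:, None]  # (nb, nph) cells/min
        N = S.sum() + E.sum()
        dS = r * S * (1.0 - N / K) - infection.sum(axis=1)
        dE = np.empty_like(E)
        dE[:, :, 0] = infection - rate[None, :] * E[:, :, 0]
        if n > 1:
            dE[:, :, 1:] = rate[None, :, None] * (E[:, :, :-1] - E[:, :, 1:])
        lysis = rate[None, :] * E[:, :, -1]  # cells lysing per min, (nb, nph)
        dP = burst * lysis.sum(axis=0) - infection.sum(axis=0)
        dC_in = infection.ravel()
        dC_out = lysis.ravel()
        return np.concatenate([dS, dE.ravel(), dP, dC_in, dC_out])

    return rhs, nb, nph, n, ne


def simulate(
    scenario: CocktailScenario,
    t_end_min: float | None = None,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-4,
) -> Trajectory:
    """Integrate the killing-dynamics model for one scenario.

    Uses the stiff LSODA integrator with per-species terminal extinction
    events: when a species' viable density crosses the extinction threshold
    from above, its susceptible and infected compartments are zeroed and the
    integration restarted, so extinct species stay exactly at zero.
    """
    rhs, nb, nph, n, ne = _pack_rhs(scenario)
    if t_end_min is None:
        t_end_min = 60.0 * max(scenario.sample_times_h)
    sample_min = 60.0 * np.asarray(scenario.sample_times_h, float)
    t_grid = np.unique(np.concatenate([np.arange(0.0, t_end_min + dt_out / 2, dt_out), sample_min]))
    t_grid = t_grid[t_grid <= t_end_min + 1e-9]

    y = np.concatenate(
        [
            [b.s0 for b in scenario.bacteria],
            np.zeros(ne),
            scenario.doses,
            np.zeros(2 * nb * nph),
        ]
    )
    alive = np.ones(nb)

    # Extinction events track the species' total bacterial material
    # (susceptible + infected): a species is removed only once nothing of it
    # remains, so lysis-committed cells keep producing phage until the end.
    def make_event(i):
        def event(t, yy, alive_mask):
            S_i = yy[i]
            E_i = yy[nb : nb + ne].reshape(nb, nph, n)[i].sum() if ne else 0.0
            return S_i + E_i - scenario.extinction_threshold

        event.terminal = True
        event.direction = -1.0
        return event

    events = [make_event(i) for i in range(nb)]

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    t0 = 0.0
    while t0 < t_end_min - 1e-9:
        seg_eval = t_grid[(t_grid >= t0 - 1e-9) & (t_grid <= t_end_min + 1e-9)]
        active_events = [events[i] for i in range(nb) if alive[i] > 0 and y[i] > 0]
        sol = solve_ivp(
            rhs,
            (t0, t_end_min),
            y,
            method="LSODA",
            t_eval=seg_eval if seg_eval.size else None,
            events=active_events or None,
            args=(alive,),
            rtol=rtol,
            atol=atol,
        )
        if sol.status == -1:
            raise IntegrationError(
                f"integrator failed in scenario {scenario.name!r} near t={sol.t[-1] if sol.t.size else t0:.2f} min: {sol.message}"
            )
        if sol.t.size:
            times_out.append(sol.t)
            states_out.append(sol.y.T)
        if sol.status == 1:  # extinction event fired
            t_event = max(te[-1] for te in sol.t_events if te.size)
            y_event = None
            for ev_idx, te in enumerate(sol.t_events):
                if te.size:
                    y_event = sol.y_events[ev_idx][-1]
            y = np.array(y_event)
            # zero every species at/below threshold at the event time
            E_view = y[nb : nb + ne].reshape(nb, nph, n) if ne else np.zeros((nb, nph, n))
            for i in range(nb):
                total_i = y[i] + E_view[i].sum()
                if alive[i] > 0 and total_i <= scenario.extinction_threshold * (1 + 1e-9):
                    alive = alive.copy()
                    alive[i] = 0.0
                    y[i] = 0.0
                    E_view[i, :, :] = 0.0
            t0 = t_event
        else:
            break

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    # de-duplicate segment joins, keep the later (post-clamp) state
    keep = np.append(np.diff(times) > 1e-12, True)
    times, states = times[keep], states[keep]

    nt = states.shape[0]
    S = np.clip(states[:, :nb], 0.0, None)
    E = np.clip(states[:, nb : nb + ne].reshape(nt, nb, nph, max(n, 1)), 0.0, None)
    P = np.clip(states[:, nb + ne : nb + ne + nph], 0.0, None)
    C_in = states[:, nb + ne + nph : nb + ne + nph + nb * nph].reshape(nt, nb, nph)
    C_out = states[:, nb + ne + nph + nb * nph :].reshape(nt, nb, nph)
    return Trajectory(
        scenario=scenario,
        times_min=times,
        susceptible=S,
        infected=E.sum(axis=3),
        phage=P,
        audit={"cumulative_infections": C_in, "cumulative_lyses": C_out},
    )


def killing_summary(traj: Trajectory, control: Trajectory) -> pd.DataFrame:
    """Log10 reduction of viable counts versus control and versus baseline.

    Treated counts are floored at the extinction threshold inside the log so
    an extinct culture reports a finite reduction.  Both log10 and plain
    fold-change columns are emitted, since verbal "n-fold decrease" claims
    are ambiguous between the two.
    """
    t_hours = traj.scenario.sample_times_h
    if tuple(control.scenario.sample_times_h) != tuple(t_hours):
        raise InvalidParameterError("treated and control trajectories use different sample times")
    treated = traj.at_hours()
    ctrl = control.at_hours()
    floor = traj.scenario.extinction_threshold
    baseline = max(treated["viable_total"].iloc[0], floor)

    out = pd.DataFrame({"time_h": treated["time_h"]})
    out["viable_total"] = treated["viable_total"]
    out["control_total"] = ctrl["viable_total"].values
    t_floored = np.maximum(treated["viable_total"].values, floor)
    c_floored = np.maximum(ctrl["viable_total"].values, floor)
    out["log10_viable"] = np.log10(t_floored)
    out["log10_reduction_vs_control"] = np.log10(c_floored) - np.log10(t_floored)
    out["log10_reduction_vs_baseline"] = np.log10(baseline) - np.log10(t_floored)
    out["fold_reduction_vs_control"] = c_floored / t_floored
    out["extinct"] = treated["viable_total"].values < floor
    return out


# ---------------------------------------------------------------------------
# Scenario library: the published single-phage and cocktail assay designs
# ---------------------------------------------------------------------------

_BACT_IDS = {
    "E": "E_coli_ec311",
    "K": "K_pneumoniae_kp235",
    "L": "E_cloacae_el140",
}
_PHAGE_KEYS = {
    "E": "escherichia_myPSH2311",
    "K": "klebsiella_myPSH1235",
    "L": "enterobacter_myPSH1140",
}
_COMPOSITIONS = {
    "mono_E": "E",
    "mono_K": "K",
    "mono_L": "L",
    "EK1": "EK",
    "KL2": "KL",
    "EL3": "EL",
    "EKL4": "EKL",
}

#: Bacterial inocula: the assay as run used 6e6 CFU/mL total; the
#: normalized variant rescales to 1e6 CFU/mL total (the density the
#: killing-curve endpoints are quoted from).
_TOTALS = {"assay": 6e6, "normalized": 1e6}
PHAGE_DOSE = 1e6  # PFU/mL per phage in every cocktail


def _build_scenario(name: str, letters: str, variant: str, with_phages: bool) -> CocktailScenario:
    total = _TOTALS[variant]
    per = total / len(letters)
    bacteria = [Bacterium(_BACT_IDS[c], per) for c in letters]
    if with_phages:
        phages = [PHAGE_PRESETS[_PHAGE_KEYS[c]] for c in letters]
        doses = [PHAGE_DOSE] * len(letters)
        infectivity = np.eye(len(letters))  # each phage infects only its genus
    else:
        phages, doses = [], []
        infectivity = np.zeros((len(letters), 0))
    return CocktailScenario(
        name=name,
        phages=phages,
        doses=doses,
        bacteria=bacteria,
        infectivity=infectivity,
        nominal_moi=1.0 if with_phages else None,
    )


def scenario_library(variant: str = "normalized") -> dict[str, CocktailScenario]:
    """Named presets of the published assay designs.

    ``mono_E/K/L``: each phage alone against its host.  ``EK1``, ``KL2``,
    ``EL3``: two-phage cocktails against the matching two-species mixture.
    ``EKL4``: all three phages against all three species.  ``control``: the
    three-species mixture with no phage.  Each phage at 1e6 PFU/mL
    (nominal MOI 1.0 as quoted in the assay description); infectivity is
    diagonal.  ``variant`` selects the bacterial inoculum: ``assay``
    (6e6 CFU/mL total) or ``normalized`` (1e6 CFU/mL total).
    """
    if variant not in _TOTALS:
        raise ScenarioError(f"unknown variant {variant!r}; expected one of {tuple(_TOTALS)}")
    lib = {
        name: _build_scenario(name, letters, variant, with_phages=True)
        for name, letters in _COMPOSITIONS.items()
    }
    lib["control"] = _build_scenario("control", "EKL", variant, with_phages=False)
    return lib


def control_of(scenario: CocktailScenario) -> CocktailScenario:
    """Phage-free control matched to a scenario's bacterial composition."""
    nb = len(scenario.bacteria)
    return replace(
        scenario,
        name=f"{scenario.name}_control",
        phages=[],
        doses=[],
        infectivity=np.zeros((nb, 0)),
        nominal_moi=None,
    )
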