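"""Velocity-Verlet molecular dynamics with NVE/NVT ensembles and restraints.

The integrator takes any calculator honouring the reference-calculator
contract (``energy_forces``/``bind``), so the classical surrogate and a
trained linear MLP are interchangeable.  NVT uses the stochastic
velocity-rescaling (CSVR) thermostat: a deterministic relaxation of the
kinetic energy toward its canonical mean over a coupling time tau, plus the
noise terms that make the stationary kinetic-energy distribution canonical.

Restraints follow the biasing-library convention U = k * delta^2 (no 1/2);
the WHAM unbiasing in :mod:`solvshell.sampling` uses the same convention,
which is the consistency that actually matters.

Defaults mirror the production protocol this package emulates: 0.5 fs
timestep and a 100 fs thermostat coupling time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import Configuration
from .units import KB, KE_CONV


@dataclass
class MDState:
    """Positions + velocities + masses + clock of one MD run."""

    config: Configuration
    velocities: np.ndarray
    masses: np.ndarray
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def __post_init__(self):
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.velocities.shape != self.config.positions.shape:
            raise ValueError("velocities shape must match positions")
        self.masses = np.asarray(self.masses, dtype=float)

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * KE_CONV * float(np.sum(self.masses * (self.velocities**2).sum(axis=1)))

    @property
    def n_dof(self) -> int:
        # centre-of-mass momentum is zeroed at initialization and conserved by
        # both the integrator and the (uniform-scaling) thermostat; a single
        # particle keeps its 3 degrees of freedom
        n = self.config.n_atoms
        return 3 * n - 3 if n > 1 else 3

    def temperature(self) -> float:
        return 2.0 * self.kinetic_energy / (self.n_dof * KB)


def initialize_state(config: Configuration, temperature: float, seed: int = 0) -> MDState:
    """Maxwell-Boltzmann velocities at the target temperature, zero net momentum."""
    rng = np.random.default_rng(seed)
    masses = config.masses()
    n = config.n_atoms
    # sigma_v = sqrt(kB T / m) in Å/fs
    sigma = np.sqrt(KB * temperature / (masses * KE_CONV))
    v = rng.standard_normal((n, 3)) * sigma[:, None]
    # remove net momentum
    p = (masses[:, None] * v).sum(axis=0) / masses.sum()
    v -= p[None, :]
    state = MDState(config=config.copy(), velocities=v, masses=masses, rng=rng)
    # rescale to the exact target temperature
    t_now = state.temperature()
    if t_now > 0:
        state.velocities *= math.sqrt(temperature / t_now)
    return state


@dataclass
class ThermostatSpec:
    kind: str = "csvr"          # csvr | none
    temperature: float = 300.0  # K
    tau: float = 100.0          # fs

    def __post_init__(self):
        if self.kind not in ("csvr", "none"):
            raise ValueError(f"unknown thermostat kind {self.kind!r}")
        if self.kind != "none" and self.tau <= 0:
            raise ValueError("coupling time must be positive")


@dataclass
class RestraintSpec:
    """Flat-bottom spherical restraint specification.

    ``center`` is an atom index (int) or a fixed point (3-vector); atoms in
    ``applies_to`` (indices; None = all atoms except the center atom) feel
    U = k (r - r_fb)^2 beyond the onset radius r_fb.
    """

    center: object = 0
    r_fb: float = 8.0
    k: float = 500.0
    applies_to: np.ndarray | None = None

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("force constant must be non-negative")
        if self.r_fb <= 0:
            raise ValueError("onset radius must be positive")


class FlatBottomRestraint:
    """U = k (r - r_fb)^2 outside a sphere; zero (and once-differentiable) inside."""

    def __init__(self, spec: RestraintSpec, n_atoms: int):
        self.spec = spec
        if isinstance(spec.center, (int, np.integer)):
            self.center_atom = int(spec.center)
            self.center_point = None
        else:
            self.center_atom = None
            self.center_point = np.asarray(spec.center, dtype=float)
        if spec.applies_to is None:
            sel = np.arange(n_atoms)
            if self.center_atom is not None:
                sel = sel[sel != self.center_atom]
        else:
            sel = np.asarray(spec.applies_to, dtype=np.int64)
        self.sel = sel

    def energy_force(self, positions: np.ndarray):
        spec = self.spec
        c = (positions[self.center_atom] if self.center_atom is not None
             else self.center_point)
        d = positions[self.sel] - c[None, :]
        r = np.linalg.norm(d, axis=1)
        out = np.maximum(r - spec.r_fb, 0.0)
        energy = float(spec.k * np.sum(out**2))
        forces = np.zeros_like(positions)
        mask = out > 0
        if np.any(mask):
            # F = -dU/dr * rhat on the restrained atom; reaction on the center atom
            fmag = -2.0 * spec.k * out[mask]
            fv = fmag[:, None] * (d[mask] / r[mask][:, None])
            np.add.at(forces, self.sel[mask], fv)
            if self.center_atom is not None:
                forces[self.center_atom] -= fv.sum(axis=0)
        return energy, forces


def flat_bottom_energy_force(positions: np.ndarray, spec: RestraintSpec):
    """Flat-bottom spherical restraint energy and forces (functional form)."""
    return FlatBottomRestraint(spec, positions.shape[0]).energy_force(positions)


class HarmonicCVRestraint:
    """U = k (cv(x) - center)^2 on any collective variable with a gradient."""

    def __init__(self, cv, center: float, k: float):
        self.cv = cv
        self.center = center
        self.k = k

    def energy_force(self, positions: np.ndarray):
        val, grad = self.cv.value_and_gradient(positions)
        delta = val - self.center
        energy = self.k * delta * delta
        forces = -2.0 * self.k * delta * grad
        return float(energy), forces


def csvr_scale(kinetic: float, n_dof: int, temperature: float, tau: float,
               dt: float, rng: np.random.Generator) -> float:
    """Stochastic velocity-rescaling factor (canonical sampling through
    velocity rescaling).

    Relaxes the kinetic energy toward K_bar = n_dof * kB * T / 2 on the
    timescale tau, with Gaussian/chi-squared noise such that the stationary
    distribution of K is the canonical Gamma(n_dof/2) distribution.
    tau -> infinity gives factor -> 1; tau -> 0 resamples K outright.
    """
    if tau <= 0:
        raise ValueError("coupling time must be positive")
    if kinetic <= 0:
        return 1.0
    k_bar = 0.5 * n_dof * KB * temperature
    c = math.exp(-dt / tau)
    r1 = rng.standard_normal()
    s = rng.chisquare(n_dof - 1) if n_dof > 1 else 0.0
    ratio = k_bar / (n_dof * kinetic)
    alpha2 = (
        c
        + (1.0 - c) * ratio * (r1 * r1 + s)
        + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ratio)
    )
    return math.sqrt(max(alpha2, 0.0))


def _total_ef(ef, restraints, positions):
    e, f = ef(positions)
    for r in restraints:
        er, fr = r.energy_force(positions)
        e += er
        f = f + fr
    return e, f


def velocity_verlet_step(state: MDState, calculator, dt: float,
                         restraints=(), _bound=None, _forces=None):
    """One velocity-Verlet step; returns (state, energy, forces) with the
    state mutated in place.  ``_bound``/``_forces`` let run_md avoid
    recomputing forces; casual callers can ignore them."""
    if dt <= 0:
        raise ValueError("timestep must be positive")
    ef = _bound if _bound is not None else calculator.bind(state.config)
    pos = state.config.positions
    if _forces is None:
        _, _forces = _total_ef(ef, restraints, pos)
    if not np.all(np.isfinite(_forces)):
        raise FloatingPointError("non-finite forces")
    # F in kcal/mol/Å; a = F / (m * KE_CONV) in Å/fs^2
    acc = _forces / (state.masses[:, None]) / KE_CONV
    state.velocities += 0.5 * dt * acc
    pos += dt * state.velocities
    e_new, f_new = _total_ef(ef, restraints, pos)
    acc_new = f_new / (state.masses[:, None]) / KE_CONV
    state.velocities += 0.5 * dt * acc_new
    state.time += dt
    return state, e_new, f_new


@dataclass
class MDResult:
    trajectory: list
    log: pd.DataFrame
    stable: bool = True
    final_state: MDState | None = None


def run_md(
    state: MDState,
    calculator,
    thermostat: ThermostatSpec | None = None,
    restraints=(),
    n_steps: int = 1000,
    dt: float = 0.5,
    sample_every: int = 10,
) -> MDResult:
    """Propagate dynamics; returns sampled trajectory plus an energy log.

    The log holds (t, E_pot, E_kin, E_tot, T) at every sampled step (restraint
    energy counts as potential energy, so E_tot is conserved in NVE).
    Non-finite energies truncate the run and flag the result unstable — the
    active-learning driver uses that signal.  Deterministic per state.rng.
    """
    thermostat = thermostat or ThermostatSpec(kind="none")
    built = []
    for r in restraints:
        if isinstance(r, RestraintSpec):
            built.append(FlatBottomRestraint(r, state.config.n_atoms))
        else:
            built.append(r)
    restraints = built

    ef = calculator.bind(state.config)
    pos = state.config.positions
    trajectory: list[Configuration] = []
    rows = []
    stable = True

    e_pot, forces = _total_ef(ef, restraints, pos)

    def _log_row():
        ke = state.kinetic_energy
        rows.append((state.time, e_pot, ke, e_pot + ke, state.temperature()))

    _log_row()
    for step in range(1, n_steps + 1):
        try:
            state, e_pot, forces = velocity_verlet_step(
                state, calculator, dt, restraints, _bound=ef, _forces=forces
            )
        except FloatingPointError:
            stable = False
            break
        if not math.isfinite(e_pot):
            stable = False
            break
        if thermostat.kind == "csvr":
            ke = state.kinetic_energy
            factor = csvr_scale(ke, state.n_dof, thermostat.temperature,
                                thermostat.tau, dt, state.rng)
            state.velocities *= factor
        if step % sample_every == 0:
            snap = state.config.copy()
            snap.energy = e_pot
            snap.forces = forces.copy()
            trajectory.append(snap)
            _log_row()

    log = pd.DataFrame(rows, columns=["t", "E_pot", "E_kin", "E_tot", "T"])
    return MDResult(trajectory=trajectory, log=log, stable=stable, final_state=state)
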