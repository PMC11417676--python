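"""Free-energy machinery: steered MD, umbrella sampling, WHAM, corrections.

Umbrella windows restrain a collective variable xi harmonically with
U_i(xi) = k_i (xi - c_i)^2 (the same no-1/2 convention as the MD restraints).
The window histograms are unbiased with the standard self-consistent WHAM
equations; distance-coordinate profiles can be corrected by the configurational
volume (Jacobian/entropy) term 2 kB T ln(r / r_ref); barriers and their
uncertainties come from repeats with different velocity seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .md import HarmonicCVRestraint, ThermostatSpec, initialize_state, run_md
from .structures import Configuration
from .units import KB

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """One umbrella window: CV target, restraint strength and sampling plan."""

    cv: object
    center: float
    k_umb: float                      # kcal/mol per CV-unit^2 (U = k delta^2)
    n_steps: int = 4000
    n_equil: int = 1000
    seed: int = 0
    temperature: float = 300.0
    dt: float = 0.5
    sample_every: int = 10
    start: Configuration | None = None
    restraints: tuple = ()            # extra (e.g. flat-bottom cluster) restraints

    def __post_init__(self):
        if self.k_umb <= 0:
            raise ValueError("umbrella force constant must be positive")


@dataclass
class PmfProfile:
    """Free-energy profile over a collective variable, gauge-fixed to min = 0."""

    grid: np.ndarray
    free_energy: np.ndarray
    uncertainty: np.ndarray | None = None
    cv_kind: str = "interatomic-distance"
    wham_iterations: int = 0
    wham_residual: float = 0.0
    jacobian_corrected: bool = False
    barrier: float | None = None
    barrier_location: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if np.any(self.uncertainty < 0):
                raise ValueError("uncertainties must be non-negative")

    def to_frame(self):
        import pandas as pd

        d = {"cv": self.grid, "A": self.free_energy}
        if self.uncertainty is not None:
            d["sigma_A"] = self.uncertainty
        return pd.DataFrame(d)


def steered_md(
    state,
    calculator,
    cv,
    start_value: float,
    end_value: float,
    k_pull: float,
    n_steps: int,
    dt: float = 0.5,
    thermostat: ThermostatSpec | None = None,
    extra_restraints=(),
    sample_every: int = 10,
):
    """Steered MD: harmonic CV restraint whose center moves linearly.

    Returns (trajectory, cv_values); a large lag between the CV and the moving
    center (> 3 sigma of the restraint at temperature) is logged as a warning
    but does not stop the run.
    """
    thermostat = thermostat or ThermostatSpec(kind="csvr", temperature=300.0, tau=100.0)
    centers = np.linspace(start_value, end_value, n_steps)
    restraint = HarmonicCVRestraint(cv, start_value, k_pull)
    trajectory = []
    cv_values = []
    ef = calculator.bind(state.config)
    from .md import velocity_verlet_step, _total_ef, csvr_scale

    all_restraints = [restraint, *extra_restraints]
    _, forces = _total_ef(ef, all_restraints, state.config.positions)
    sigma_tol = np.sqrt(KB * thermostat.temperature / max(k_pull, 1e-12)) if k_pull > 0 else np.inf
    warned = False
    for step in range(n_steps):
        restraint.center = centers[step]
        state, e_pot, forces = velocity_verlet_step(
            state, calculator, dt, all_restraints, _bound=ef, _forces=None
        )
        if thermostat.kind == "csvr":
            factor = csvr_scale(state.kinetic_energy, state.n_dof, thermostat.temperature,
                                thermostat.tau, dt, state.rng)
            state.velocities *= factor
        if step % sample_every == 0:
            val = cv.value(state.config.positions)
            cv_values.append(val)
            snap = state.config.copy()
            snap.energy = e_pot
            trajectory.append(snap)
            if k_pull > 0 and abs(val - restraint.center) > 3 * sigma_tol and not warned:
                logger.warning(
                    "steered MD lags its moving center (cv=%.3f, center=%.3f)",
                    val, restraint.center,
                )
                warned = True
    return trajectory, np.array(cv_values)


def pick_window_starts(trajectory, cv_values, centers) -> list:
    """Frames whose CV is nearest each requested window center."""
    cv_values = np.asarray(cv_values)
    return [trajectory[int(np.argmin(np.abs(cv_values - c)))] for c in centers]


def run_umbrella(windows: list, calculator):
    """Independent restrained NVT runs, one per window.

    Returns (series, histogram overlap report): ``series`` is a list of CV
    sample arrays with the equilibration portion removed; windows with fewer
    than 50 effective samples raise.
    """
    if any(w1.center > w2.center for w1, w2 in zip(windows, windows[1:])):
        raise ValueError("windows must be ordered by center")
    series = []
    for i, w in enumerate(windows):
        if w.start is None:
            raise ValueError(f"window {i} has no start configuration")
        state = initialize_state(w.start, w.temperature, seed=w.seed)
        restraint = HarmonicCVRestraint(w.cv, w.center, w.k_umb)
        res = run_md(
            state, calculator,
            thermostat=ThermostatSpec("csvr", w.temperature, 100.0),
            restraints=[restraint, *w.restraints],
            n_steps=w.n_steps, dt=w.dt, sample_every=w.sample_every,
        )
        n_equil_frames = w.n_equil // w.sample_every
        vals = np.array([w.cv.value(c.positions) for c in res.trajectory[n_equil_frames:]])
        if vals.size < 50:
            raise ValueError(f"window {i} (center {w.center}) has only {vals.size} samples")
        series.append(vals)
    return series


def histogram_overlap(series, n_bins: int = 50):
    """Fraction of shared histogram mass between neighbouring windows."""
    lo = min(s.min() for s in series)
    hi = max(s.max() for s in series)
    edges = np.linspace(lo, hi, n_bins + 1)
    hists = [np.histogram(s, bins=edges, density=False)[0] / len(s) for s in series]
    return np.array(
        [float(np.minimum(h1, h2).sum()) for h1, h2 in zip(hists, hists[1:])]
    )


def wham(
    series: list,
    windows: list,
    temperature: float,
    n_bins: int = 200,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> PmfProfile:
    """Self-consistent WHAM reconstruction of the unbiased profile.

    Iterates the window free-energy constants f_i to a residual below ``tol``
    and returns A(xi) on the bin-centre grid, gauge-fixed to min(A) = 0.
    Raises if adjacent windows share no histogram mass (no path to stitch).
    """
    if len(series) != len(windows):
        raise ValueError("need one CV series per window")
    if len(series) < 1:
        raise ValueError("no windows")
    beta = 1.0 / (KB * temperature)
    lo = min(s.min() for s in series)
    hi = max(s.max() for s in series)
    pad = 1e-9 * max(1.0, abs(hi))
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    centers_grid = 0.5 * (edges[:-1] + edges[1:])

    if len(series) > 1:
        ov = histogram_overlap(series)
        for i, o in enumerate(ov):
            if o <= 0:
                raise ValueError(
                    f"windows {i} and {i + 1} (centers {windows[i].center}, "
                    f"{windows[i + 1].center}) have non-overlapping histograms"
                )

    H = np.array([np.histogram(s, bins=edges)[0] for s in series], dtype=float)
    N = np.array([len(s) for s in series], dtype=float)
    H_tot = H.sum(axis=0)
    # bias matrix: U_i(x_bin), same k*delta^2 convention as the MD restraints
    bias = np.array([w.k_umb * (centers_grid - w.center) ** 2 for w in windows])
    expb = np.exp(-beta * bias)

    f = np.zeros(len(windows))
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        denom = (N[:, None] * np.exp(beta * f)[:, None] * expb).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, H_tot / denom, 0.0)
        zi = (expb * p[None, :]).sum(axis=1)
        f_new = -np.log(zi) / beta
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break

    denom = (N[:, None] * np.exp(beta * f)[:, None] * expb).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, H_tot / denom, 0.0)
    mask = p > 0
    A = np.full_like(p, np.nan)
    A[mask] = -np.log(p[mask]) / beta
    A -= np.nanmin(A)
    cv_kind = getattr(windows[0].cv, "kind", "interatomic-distance")
    return PmfProfile(
        grid=centers_grid,
        free_energy=A,
        cv_kind=cv_kind,
        wham_iterations=it,
        wham_residual=residual,
        meta={"temperature": temperature, "n_bins": n_bins},
    )


def boltzmann_inversion(samples: np.ndarray, temperature: float, n_bins: int = 200) -> PmfProfile:
    """Unbiased single-window limit of WHAM: A = -kBT ln h(xi) + const."""
    h, edges = np.histogram(samples, bins=n_bins)
    centers_grid = 0.5 * (edges[:-1] + edges[1:])
    A = np.full(n_bins, np.nan)
    mask = h > 0
    A[mask] = -KB * temperature * np.log(h[mask])
    A -= np.nanmin(A)
    return PmfProfile(grid=centers_grid, free_energy=A)


def jacobian_correction(pmf: PmfProfile, temperature: float, r_ref: float) -> PmfProfile:
    """Radial configuration-volume correction A(r) + 2 kB T ln(r / r_ref).

    Only meaningful for a distance coordinate; the sampled volume at distance
    r grows as r^2, and this entropy term removes that growth.  The corrected
    profile is re-gauged to min = 0.
    """
    if pmf.cv_kind != "interatomic-distance":
        raise ValueError("the radial Jacobian correction applies to distance CVs only")
    if pmf.jacobian_corrected:
        raise ValueError("profile is already Jacobian-corrected")
    corr = 2.0 * KB * temperature * np.log(pmf.grid / r_ref)
    A = pmf.free_energy + corr
    A = A - np.nanmin(A)
    return PmfProfile(
        grid=pmf.grid.copy(),
        free_energy=A,
        uncertainty=None if pmf.uncertainty is None else pmf.uncertainty.copy(),
        cv_kind=pmf.cv_kind,
        wham_iterations=pmf.wham_iterations,
        wham_residual=pmf.wham_residual,
        jacobian_corrected=True,
        meta=dict(pmf.meta, r_ref=r_ref),
    )


def barrier_and_uncertainty(profiles: list, ts_location: float | None = None):
    """Mean barrier over repeats and its standard deviation.

    The reactant state is the global minimum of the mean profile; the
    transition state is the profile maximum beyond it (distance CV) or a
    supplied CV value (coordination CV).  A single repeat reports std 0 with
    a warning.  Returns (mean profile, barrier, std, location).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if p.grid.shape != grid.shape or not np.allclose(p.grid, grid):
            raise ValueError("repeats are on different grids")
    A = np.nanmean([p.free_energy for p in profiles], axis=0)
    A = A - np.nanmin(A)
    std_all = (
        np.nanstd([p.free_energy for p in profiles], axis=0)
        if len(profiles) > 1 else np.zeros_like(A)
    )
    if len(profiles) == 1:
        logger.warning("single umbrella repeat: uncertainty reported as 0")

    i_min = int(np.nanargmin(A))
    if ts_location is not None:
        i_ts = int(np.argmin(np.abs(grid - ts_location)))
    else:
        seg = A[i_min:]
        i_ts = i_min + int(np.nanargmax(seg))
    barrier = float(A[i_ts] - A[i_min])
    std = float(std_all[i_ts])
    mean_profile = PmfProfile(
        grid=grid.copy(),
        free_energy=A,
        uncertainty=std_all,
        cv_kind=profiles[0].cv_kind,
        jacobian_corrected=profiles[0].jacobian_corrected,
        barrier=barrier,
        barrier_location=float(grid[i_ts]),
    )
    return mean_profile, barrier, std, float(grid[i_ts])
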