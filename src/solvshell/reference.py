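"""Pluggable "ground truth" calculators and the built-in classical surrogate.

In the workflow this package implements, training labels normally come from an
expensive electronic-structure code.  Here that role is filled by an analytic
classical force field — flexible 3-site water-like solvent (SPC/Fw-style),
a linear united-atom nitrile-like solvent, and bare divalent cations — so that
every stage of the active-learning pipeline has a cheap, exactly
differentiable reference whose energies and forces can be verified by finite
differences.

Any object with ``energy_forces(config) -> (E, F)``, a ``cutoff`` and an
``elements`` attribute satisfies the reference-calculator contract and is
interchangeable in the MD engine and the active-learning driver (the trained
:class:`~solvshell.model.LinearMLP` honours the same contract).

Electrostatics use damped shifted-force (DSF) Coulomb and shifted-force
Lennard-Jones: both are continuous in energy AND force at the cutoff, which
is what makes microcanonical dynamics conserve energy with a plain cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _kernels
from .structures import Configuration, LabeledDataset
from .units import COULOMB

logger = logging.getLogger(__name__)

# degrees -> rad shortcut for parameter tables
_D2R = math.pi / 180.0


@dataclass
class ClassicalFFParams:
    """Parameters of the analytic classical surrogate force field.

    ``charges``/``lj_sigma``/``lj_epsilon`` are per-element; ``bonds`` and
    ``angles`` are harmonic terms (1/2 k conventions) keyed by in-molecule
    element tuples; ``topologies`` maps an ordered molecule element tuple to
    its bond/angle index lists.
    """

    charges: dict = field(default_factory=dict)          # e
    lj_sigma: dict = field(default_factory=dict)         # Å
    lj_epsilon: dict = field(default_factory=dict)       # kcal/mol
    bonds: dict = field(default_factory=dict)            # (el_i, el_j) -> (k, r0)
    angles: dict = field(default_factory=dict)           # (el_i, el_j, el_k) -> (k, th0)
    topologies: dict = field(default_factory=dict)       # element tuple -> {"bonds": [...], "angles": [...]}
    alpha: float = 0.2                                   # DSF damping, 1/Å
    base_cutoff: float = 9.0                             # Å; reduced to L/2 under PBC

    def __post_init__(self):
        for el, s in self.lj_sigma.items():
            if s < 0:
                raise ValueError(f"negative LJ sigma for {el}")
        for el, e in self.lj_epsilon.items():
            if e < 0:
                raise ValueError(f"negative LJ epsilon for {el}")
        if self.base_cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def elements(self) -> list[str]:
        return sorted(self.charges)

    def to_yaml(self, path) -> None:
        doc = {
            "charges": dict(self.charges),
            "lj_sigma": dict(self.lj_sigma),
            "lj_epsilon": dict(self.lj_epsilon),
            "bonds": {"-".join(k): list(v) for k, v in self.bonds.items()},
            "angles": {"-".join(k): list(v) for k, v in self.angles.items()},
            "topologies": {
                "-".join(k): {kk: [list(t) for t in vv] for kk, vv in v.items()}
                for k, v in self.topologies.items()
            },
            "alpha": self.alpha,
            "base_cutoff": self.base_cutoff,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "ClassicalFFParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            charges=doc["charges"],
            lj_sigma=doc["lj_sigma"],
            lj_epsilon=doc["lj_epsilon"],
            bonds={tuple(k.split("-")): tuple(v) for k, v in doc["bonds"].items()},
            angles={tuple(k.split("-")): tuple(v) for k, v in doc["angles"].items()},
            topologies={
                tuple(k.split("-")): {kk: [tuple(t) for t in vv] for kk, vv in v.items()}
                for k, v in doc["topologies"].items()
            },
            alpha=doc["alpha"],
            base_cutoff=doc["base_cutoff"],
        )


def water_ion_params() -> ClassicalFFParams:
    """Flexible water-like solvent plus a bare +2 magnesium-like cation.

    Solvent: SPC/Fw-style 3-site model (qO = -0.82, qH = +0.41, flexible OH
    bonds and HOH angle).  Ion: +2 point charge with 12-6 LJ chosen so that
    the first solvation shell is octahedral (coordination number 6), verified
    by direct MD during development and locked in the test suite.
    """
    return ClassicalFFParams(
        charges={"O": -0.82, "H": 0.41, "Mg": 2.0},
        lj_sigma={"O": 3.1655, "H": 0.0, "Mg": 1.644},
        lj_epsilon={"O": 0.1554, "H": 0.0, "Mg": 0.875},
        bonds={("O", "H"): (1059.162, 1.012)},
        angles={("H", "O", "H"): (75.90, 113.24 * _D2R)},
        topologies={
            ("O", "H", "H"): {"bonds": [(0, 1), (0, 2)], "angles": [(1, 0, 2)]},
            ("Mg",): {"bonds": [], "angles": []},
        },
    )


def nitrile_ion_params() -> ClassicalFFParams:
    """Linear united-atom Me-C-N solvent plus a bare +2 palladium-like cation.

    The nitrile-like molecule is a rigid-ish linear rotor: two stiff bonds and
    a stiff harmonic angle at 180 deg; charges put the negative end on N so
    the nitrogen is the coordinating (anchor) atom, as in acetonitrile.
    """
    return ClassicalFFParams(
        charges={"Me": 0.269, "C": 0.129, "N": -0.398, "Pd": 2.0},
        lj_sigma={"Me": 3.60, "C": 3.40, "N": 3.25, "Pd": 1.75},
        lj_epsilon={"Me": 0.160, "C": 0.100, "N": 0.170, "Pd": 0.60},
        bonds={("Me", "C"): (600.0, 1.458), ("C", "N"): (1200.0, 1.157)},
        angles={("Me", "C", "N"): (120.0, math.pi)},
        topologies={
            # fixture templates list the anchor (N) first
            ("N", "C", "Me"): {"bonds": [(0, 1), (1, 2)], "angles": [(0, 1, 2)]},
            ("Pd",): {"bonds": [], "angles": []},
        },
    )


class ClassicalCalculator:
    """Analytic classical force field satisfying the reference-calculator contract."""

    def __init__(self, params: ClassicalFFParams | None = None):
        self.params = params if params is not None else water_ion_params()

    @property
    def elements(self) -> list[str]:
        return self.params.elements

    @property
    def cutoff(self) -> float:
        return self.params.base_cutoff

    def name(self) -> str:
        return "classical-surrogate"

    # -- system preparation -------------------------------------------------

    def _prepare(self, config: Configuration):
        p = self.params
        for el in set(config.elements):
            if el not in p.charges:
                raise ValueError(f"element {el!r} not supported by the classical surrogate")
        n = config.n_atoms
        q = np.array([p.charges[e] for e in config.elements])
        sig = np.array([p.lj_sigma[e] for e in config.elements])
        eps = np.array([p.lj_epsilon[e] for e in config.elements])
        mol = np.asarray(config.molecule_ids, dtype=np.int64)

        bonds, bond_params, angles, angle_params = [], [], [], []
        for m in np.unique(mol):
            idx = np.flatnonzero(mol == m)
            key = tuple(config.elements[i] for i in idx)
            if len(idx) == 1:
                continue
            if key not in p.topologies:
                raise ValueError(f"no intramolecular topology registered for molecule {key}")
            topo = p.topologies[key]
            for (a, b) in topo["bonds"]:
                ea, eb = key[a], key[b]
                term = p.bonds.get((ea, eb)) or p.bonds.get((eb, ea))
                if term is None:
                    raise ValueError(f"no bond parameters for {ea}-{eb}")
                bonds.append((idx[a], idx[b]))
                bond_params.append(term)
            for (a, b, c) in topo["angles"]:
                ea, eb, ec = key[a], key[b], key[c]
                term = p.angles.get((ea, eb, ec)) or p.angles.get((ec, eb, ea))
                if term is None:
                    raise ValueError(f"no angle parameters for {ea}-{eb}-{ec}")
                angles.append((idx[a], idx[b], idx[c]))
                angle_params.append(term)

        bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
        bond_params = np.array(bond_params, dtype=float).reshape(-1, 2)
        angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
        angle_params = np.array(angle_params, dtype=float).reshape(-1, 2)

        periodic = any(config.pbc)
        if periodic:
            cell = config.cell
            if not np.allclose(cell, np.diag(np.diagonal(cell))):
                raise ValueError("only orthorhombic periodic cells are supported")
            box = np.diagonal(cell).copy()
            cutoff = min(p.base_cutoff, 0.5 * float(box.min()))
        else:
            box = np.array([-1.0, -1.0, -1.0])
            cutoff = p.base_cutoff
        return q, sig, eps, mol, bonds, bond_params, angles, angle_params, box, periodic, cutoff

    def bind(self, config: Configuration):
        """Return a fast positions -> (energy, forces) callable for this system."""
        (q, sig, eps, mol, bonds, bond_params, angles, angle_params,
         box, periodic, cutoff) = self._prepare(config)
        alpha = self.params.alpha

        def _ef(pos: np.ndarray):
            e_nb, f_nb = _kernels.nonbonded_ef(pos, mol, q, sig, eps, box, periodic,
                                               cutoff, alpha, COULOMB)
            e_b, f_b = _kernels.bonded_ef(pos, bonds, bond_params, angles, angle_params,
                                          box, periodic)
            return e_nb + e_b, f_nb + f_b

        return _ef

    def energy_forces(self, config: Configuration):
        """Total energy (kcal/mol) and per-atom forces (kcal/mol/Å)."""
        return self.bind(config)(np.ascontiguousarray(config.positions))


def classical_energy_forces(config: Configuration, params: ClassicalFFParams):
    """Functional entry point: energy and forces of the classical surrogate."""
    return ClassicalCalculator(params).energy_forces(config)


def label_dataset(configs, calculator) -> LabeledDataset:
    """Label configurations with a reference calculator.

    Configurations the calculator cannot handle are skipped and logged with
    their index; the relative order of the remaining configs is preserved.
    """
    out = LabeledDataset([])
    name = calculator.name() if hasattr(calculator, "name") else type(calculator).__name__
    for i, cfg in enumerate(configs):
        try:
            e, f = calculator.energy_forces(cfg)
        except Exception as err:  # noqa: BLE001 - any calculator failure is a skip
            logger.warning("labelling failed for config %d: %s", i, err)
            continue
        labelled = cfg.copy()
        labelled.energy = float(e)
        labelled.forces = np.asarray(f)
        labelled.tags["labelled_by"] = name
        labelled.tags.setdefault("provenance", name)
        out.append(labelled)
    return out


def finite_difference_forces(calculator, config: Configuration, h: float = 1e-4) -> np.ndarray:
    """Central-difference force oracle, for consistency tests against analytic forces."""
    ef = calculator.bind(config) if hasattr(calculator, "bind") else (
        lambda pos: calculator.energy_forces(
            Configuration(list(config.elements), pos, cell=config.cell, pbc=config.pbc,
                          molecule_ids=config.molecule_ids)
        )
    )
    pos = config.positions.copy()
    F = np.zeros_like(pos)
    for a in range(pos.shape[0]):
        for alpha in range(3):
            pos[a, alpha] += h
            ep, _ = ef(pos)
            pos[a, alpha] -= 2 * h
            em, _ = ef(pos)
            pos[a, alpha] += h
            F[a, alpha] = -(ep - em) / (2 * h)
    return F
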