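"""The trainable potential: linear ridge regression on invariant atomic features.

The energy is a sum of per-atom contributions, each a linear function of
rotation/translation/permutation-invariant features of the atom's
neighbourhood inside ``r_cut``:

  * a constant (per-element reference energy),
  * 2-body: per neighbour species, Gaussian radial functions times a smooth
    cosine cutoff, summed over neighbours,
  * 3-body: per unordered neighbour-species pair, products of coarse radial
    Gaussians and integer powers of cos(theta), summed over neighbour pairs.

Forces are the exact analytic negative gradient of this energy, so the model
satisfies the same calculator contract as the classical surrogate and can
drive the MD engine directly.  Fitting is a deterministic joint
energy + force ridge regression (stacked least squares), the standard
low-data regime approach for linear body-ordered potentials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .structures import Configuration, LabeledDataset


@dataclass
class FeatureSpec:
    """Invariant feature hyperparameters; dimensionality is a pure function of these."""

    species: tuple = ("H", "O", "Mg")
    r_cut: float = 6.0
    n_radial: int = 32          # 2-body Gaussian count
    n_radial_3b: int = 4        # coarse radial Gaussians for 3-body
    n_cos: int = 6              # cos(theta) powers 0..n_cos-1
    r_min: float = 0.6          # first radial center (Å)

    def __post_init__(self):
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        self.species = tuple(self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_pairs(self) -> int:
        return self.n_species * (self.n_species + 1) // 2

    @property
    def dim(self) -> int:
        return 1 + self.n_species * self.n_radial + self.n_pairs * self.n_radial_3b * self.n_cos

    def centers2(self) -> np.ndarray:
        return np.linspace(self.r_min, self.r_cut, self.n_radial)

    def width2(self) -> float:
        return (self.r_cut - self.r_min) / max(self.n_radial - 1, 1)

    def centers3(self) -> np.ndarray:
        return np.linspace(self.r_min, self.r_cut, self.n_radial_3b)

    def width3(self) -> float:
        return (self.r_cut - self.r_min) / max(self.n_radial_3b - 1, 1)


def _z_indices(config: Configuration, spec: FeatureSpec) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(spec.species)}
    try:
        return np.array([lookup[e] for e in config.elements], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"element {e.args[0]!r} not supported by this model") from None


def _box_of(config: Configuration):
    if any(config.pbc):
        cell = config.cell
        if not np.allclose(cell, np.diag(np.diagonal(cell))):
            raise ValueError("only orthorhombic periodic cells are supported")
        return np.diagonal(cell).copy(), True
    return np.array([-1.0, -1.0, -1.0]), False


def featurize(config: Configuration, spec: FeatureSpec):
    """Per-element summed features X (n_species, D) and Jacobian dX/dr.

    The Jacobian has shape (n_atoms, 3, n_species, D); the energy of a linear
    model with weights w is (X * w).sum() and its forces are
    -einsum('xasd,sd->xa', J, w).
    """
    z = _z_indices(config, spec)
    box, periodic = _box_of(config)
    X, J = _kernels.mlp_features(
        np.ascontiguousarray(config.positions), z, spec.r_cut,
        spec.centers2(), spec.width2(), spec.centers3(), spec.width3(),
        spec.n_cos, spec.n_species, box, periodic,
    )
    return X, J


@dataclass
class LinearMLP:
    """Linear potential over invariant features; honours the calculator contract.

    ``core_rc`` is an optional per-species-pair onset matrix for a fixed
    short-range repulsive wall (amplitude ``core_amp``, cubic ramp).  ``fit``
    sets it to 0.8x the shortest distance of each pair observed in the
    training data, so the wall is exactly zero everywhere the model was
    fitted and only acts in the unsampled collapse region — the standard
    core-repulsion guard used with linear body-ordered potentials.
    """

    spec: FeatureSpec
    weights: np.ndarray                       # (n_species, D)
    core_rc: np.ndarray | None = None         # (n_species, n_species), Å
    core_amp: float = 5000.0                  # kcal/mol at r -> 0
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.spec.n_species, self.spec.dim):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match spec "
                f"({self.spec.n_species}, {self.spec.dim})"
            )
        if self.core_rc is not None:
            self.core_rc = np.asarray(self.core_rc, dtype=float)
            if self.core_rc.shape != (self.spec.n_species,) * 2:
                raise ValueError("core_rc must be a species-pair matrix")

    # calculator contract ---------------------------------------------------

    @property
    def elements(self) -> list[str]:
        return list(self.spec.species)

    @property
    def cutoff(self) -> float:
        return self.spec.r_cut

    def name(self) -> str:
        return "linear-mlp"

    def bind(self, config: Configuration):
        z = _z_indices(config, spec := self.spec)
        box, periodic = _box_of(config)
        w = self.weights
        c2, w2 = spec.centers2(), spec.width2()
        c3, w3 = spec.centers3(), spec.width3()

        core_rc = self.core_rc
        core_amp = self.core_amp

        def _ef(pos: np.ndarray):
            e, f = _kernels.mlp_energy_forces(
                pos, z, w, spec.r_cut, c2, w2, c3, w3,
                spec.n_cos, spec.n_species, box, periodic,
            )
            if core_rc is not None:
                ec, fc = _kernels.core_repulsion(pos, z, core_rc, core_amp, box, periodic)
                e += ec
                f = f + fc
            return e, f

        return _ef

    def energy_forces(self, config: Configuration):
        return self.bind(config)(np.ascontiguousarray(config.positions))

    def predict(self, config: Configuration):
        return self.energy_forces(config)

    # persistence -----------------------------------------------------------

    def save(self, path) -> None:
        doc = {
            "format": "solvshell-linear-mlp",
            "version": 1,
            "spec": {
                "species": list(self.spec.species),
                "r_cut": self.spec.r_cut,
                "n_radial": self.spec.n_radial,
                "n_radial_3b": self.spec.n_radial_3b,
                "n_cos": self.spec.n_cos,
                "r_min": self.spec.r_min,
            },
            "weights": self.weights.tolist(),
            "core_rc": None if self.core_rc is None else self.core_rc.tolist(),
            "core_amp": self.core_amp,
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "LinearMLP":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "solvshell-linear-mlp":
            raise ValueError("not a solvshell linear-MLP file")
        spec = FeatureSpec(**doc["spec"])
        core_rc = doc.get("core_rc")
        return cls(
            spec=spec,
            weights=np.array(doc["weights"]),
            core_rc=None if core_rc is None else np.array(core_rc),
            core_amp=doc.get("core_amp", 5000.0),
            training_meta=doc["training_meta"],
        )


class NormalEquations:
    """Accumulated normal equations of the joint energy + force regression.

    The active-learning loop appends configurations one at a time and refits
    after every cycle; accumulating A^T A / A^T b incrementally makes each
    refit O(D^3) instead of O(dataset * D^2).  The solution is identical to a
    from-scratch fit (pure summation, no state beyond the sums).
    """

    def __init__(self, spec: FeatureSpec, force_weight: float = 0.1):
        self.spec = spec
        self.force_weight = force_weight
        n_sp, D = len(spec.species), spec.dim
        self._P = n_sp * D
        self.AtA = np.zeros((self._P, self._P))
        self.Atb = np.zeros(self._P)
        self.n_configs = 0
        self.min_pair = np.full((n_sp, n_sp), np.inf)

    def add(self, cfg: Configuration) -> None:
        if not cfg.is_labelled:
            raise ValueError("cannot accumulate an unlabelled configuration")
        spec = self.spec
        n_sp = len(spec.species)
        box, periodic = _box_of(cfg)
        mp = _kernels.min_pair_distances(
            np.ascontiguousarray(cfg.positions), _z_indices(cfg, spec),
            n_sp, box, periodic,
        )
        self.min_pair = np.minimum(self.min_pair, mp)
        X, J = featurize(cfg, spec)
        we = 1.0 / np.sqrt(cfg.n_atoms)
        row = X.ravel() * we
        self.AtA += np.outer(row, row)
        self.Atb += row * (cfg.energy * we)
        if self.force_weight > 0:
            rows = -J.reshape(cfg.n_atoms * 3, self._P) * np.sqrt(self.force_weight)
            self.AtA += rows.T @ rows
            self.Atb += rows.T @ (cfg.forces.ravel() * np.sqrt(self.force_weight))
        self.n_configs += 1

    def solve(self, ridge: float = 1e-4, ridge_3body: float | None = 0.1) -> LinearMLP:
        """Solve with structured (block) Tikhonov regularization.

        ``ridge`` applies to the constant and 2-body weights; ``ridge_3body``
        (None = same as ridge) applies to the 3-body block.  The 3-body basis
        is strongly collinear on fixed-composition training sets, and a
        stronger penalty there keeps its weights — and hence the model's
        off-manifold extrapolation — bounded without hurting the fit.
        """
        if self.n_configs == 0:
            raise ValueError("cannot fit on an empty dataset")
        n_sp, D = len(self.spec.species), self.spec.dim
        A = self.AtA.copy()
        if ridge_3body is None:
            ridge_3body = ridge
        mask3 = np.zeros(D, dtype=bool)
        mask3[1 + n_sp * self.spec.n_radial:] = True
        A[np.diag_indices_from(A)] += np.where(np.tile(mask3, n_sp), ridge_3body, ridge)
        try:
            w = np.linalg.solve(A, self.Atb)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "normal equations are singular; use ridge > 0"
            ) from None
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError("normal equations are singular; use ridge > 0")
        core_rc = np.where(np.isfinite(self.min_pair), 0.8 * self.min_pair, 0.0)
        return LinearMLP(
            spec=self.spec,
            weights=w.reshape(n_sp, D),
            core_rc=core_rc,
            training_meta={"n_configs": self.n_configs, "ridge": ridge,
                           "ridge_3body": ridge_3body,
                           "force_weight": self.force_weight},
        )


def fit(
    dataset: LabeledDataset,
    spec: FeatureSpec,
    ridge: float = 1e-4,
    force_weight: float = 0.1,
    ridge_3body: float | None = 0.1,
) -> LinearMLP:
    """Joint energy + force ridge regression (deterministic direct solve).

    Minimizes
      sum_c (E_pred - E_ref)^2 / N_atoms_c
      + force_weight * sum_components (F_pred - F_ref)^2
      + ridge * ||w||^2.
    Raises if the normal equations are singular at ridge = 0.
    """
    acc = NormalEquations(spec, force_weight=force_weight)
    for cfg in dataset:
        acc.add(cfg)
    return acc.solve(ridge, ridge_3body)
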