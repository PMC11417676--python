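"""Deterministic synthetic-system generators.

These replace the external structure-preparation tools a production workflow
would use (solvent packers, cluster-growth codes, conformer generators):
jittered-lattice solvent boxes at a target density, random-displacement
ensembles of a gas-phase complex, ideal polyhedral metal complexes, and
spherical solvation of a complex.  Everything is deterministic per seed and
emits :class:`~solvshell.structures.Configuration` objects with molecule ids
assigned, so downstream cluster cutting never has to guess bonding.
"""

from __future__ import annotations

import math

import numpy as np

from .structures import Configuration
from .units import MOLAR_MASS_NITRILE_LIKE, MOLAR_MASS_WATER_LIKE, N_AVOGADRO

_D2R = math.pi / 180.0

# internal geometry templates: positions with the anchor (coordinating) atom first,
# molecule oriented along -z (anchor points toward whatever it coordinates)
_WATER_R = 1.012
_WATER_TH = 113.24 * _D2R


def water_template() -> tuple[list[str], np.ndarray]:
    """Flexible 3-site water-like molecule; O is the anchor atom."""
    h = _WATER_TH / 2
    pos = np.array(
        [
            [0.0, 0.0, 0.0],
            [_WATER_R * math.sin(h), 0.0, _WATER_R * math.cos(h)],
            [-_WATER_R * math.sin(h), 0.0, _WATER_R * math.cos(h)],
        ]
    )
    return ["O", "H", "H"], pos


def nitrile_template() -> tuple[list[str], np.ndarray]:
    """Linear united-atom Me-C-N molecule; N is the anchor atom (listed last,
    anchored by convention: templates are returned anchor-first)."""
    # anchor-first ordering: N, C, Me stacked along +z away from the anchor
    pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.157], [0.0, 0.0, 1.157 + 1.458]])
    return ["N", "C", "Me"], pos


_TEMPLATES = {"water": water_template, "nitrile": nitrile_template}
_MOLAR_MASS = {"water": MOLAR_MASS_WATER_LIKE, "nitrile": MOLAR_MASS_NITRILE_LIKE}
# anchor / heavy atoms per solvent kind
_HEAVY = {"water": {"O"}, "nitrile": {"N", "C", "Me"}}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def box_edge(n_molecules: int, density: float, kind: str = "water") -> float:
    """Cubic box edge (Å) for n molecules at the given density (g/cm^3)."""
    m = _MOLAR_MASS[kind]
    vol_cm3 = n_molecules * m / (density * N_AVOGADRO)
    return (vol_cm3 * 1e24) ** (1.0 / 3.0)


def pack_solvent_box(
    n_molecules: int,
    density: float = 0.997,
    kind: str = "water",
    seed: int = 0,
    min_contact: float = 2.2,
    ion: str | None = None,
) -> Configuration:
    """Pack a periodic cubic solvent box on a jittered lattice.

    Molecules are placed on a cubic sublattice with random orientations and
    small positional jitter; a placement is rejected while any intermolecular
    heavy-atom contact is below ``min_contact`` Å.  If ``ion`` is given, one
    bare cation replaces the most central lattice site.
    """
    if n_molecules <= 0:
        raise ValueError("need at least one molecule")
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    L = box_edge(n_molecules, density, kind)
    elements_t, pos_t = _TEMPLATES[kind]()
    pos_t = pos_t - pos_t.mean(axis=0)   # centroid at the lattice site
    heavy = _HEAVY[kind]

    n_sites = n_molecules + (1 if ion else 0)
    m_grid = math.ceil(n_sites ** (1.0 / 3.0))
    spacing = L / m_grid
    if spacing < min_contact:
        raise ValueError(
            f"density {density} g/cm^3 infeasible with a {min_contact} Å contact rule"
        )
    # positional jitter must not eat the contact margin at tight packings
    jitter_amp = min(0.12 * spacing, 0.45 * (spacing - min_contact))
    sites = np.array(
        [[(i + 0.5), (j + 0.5), (k + 0.5)]
         for i in range(m_grid) for j in range(m_grid) for k in range(m_grid)]
    ) * spacing
    # deterministic subset: sites closest to the box centre first
    order = np.argsort(np.linalg.norm(sites - L / 2, axis=1), kind="stable")
    sites = sites[order[:n_sites]]

    elements: list[str] = []
    positions: list[np.ndarray] = []
    mol_ids: list[int] = []
    heavy_placed: list[np.ndarray] = []

    def _ok(cand_heavy):
        if not heavy_placed:
            return True
        placed = np.vstack(heavy_placed)
        for p in cand_heavy:
            d = placed - p
            d -= L * np.round(d / L)
            if np.min(np.einsum("ij,ij->i", d, d)) < min_contact**2:
                return False
        return True

    mol_counter = 0
    site_iter = iter(range(n_sites))
    if ion:
        elements.append(ion)
        positions.append(sites[next(site_iter)].reshape(1, 3))
        mol_ids.append(mol_counter)
        heavy_placed.append(positions[-1])
        mol_counter += 1
    for s in site_iter:
        placed = False
        for _ in range(500):
            R = _random_rotation(rng)
            jitter = rng.uniform(-jitter_amp, jitter_amp, 3)
            cand = pos_t @ R.T + sites[s] + jitter
            cand_heavy = cand[[i for i, e in enumerate(elements_t) if e in heavy]]
            if _ok(cand_heavy):
                placed = True
                break
        if not placed:
            raise ValueError("could not place molecule without close contacts")
        elements.extend(elements_t)
        positions.append(cand)
        mol_ids.extend([mol_counter] * len(elements_t))
        heavy_placed.append(cand_heavy)
        mol_counter += 1

    return Configuration(
        elements=elements,
        positions=np.vstack(positions),
        cell=np.eye(3) * L,
        pbc=(True, True, True),
        molecule_ids=np.array(mol_ids),
        tags={"provenance": "pack_solvent_box", "density": density},
    )


def random_displace(
    config: Configuration, sigma: float, n_copies: int, seed: int = 0,
    min_dist: float = 0.5,
) -> list[Configuration]:
    """Gaussian random-displacement ensemble of a structure.

    Each copy displaces every Cartesian coordinate by N(0, sigma^2); copies
    that create an interatomic distance below ``min_dist`` Å are resampled
    (at most 100 attempts each).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_copies):
        for attempt in range(100):
            cand = config.copy()
            cand.positions = config.positions + rng.normal(0.0, sigma, config.positions.shape)
            d = cand.positions[:, None, :] - cand.positions[None, :, :]
            r = np.sqrt((d**2).sum(-1))
            np.fill_diagonal(r, np.inf)
            if r.min() >= min_dist:
                break
        else:
            raise ValueError("could not generate a displacement without clashes")
        cand.energy = None
        cand.forces = None
        cand.tags = dict(config.tags)
        cand.tags["provenance"] = "random_displace"
        out.append(cand)
    return out


_GEOMETRIES = {
    "octahedral": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
    ),
    "square-planar": np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float),
    "square-pyramidal": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]], dtype=float
    ),
    "trigonal-bipyramidal": np.array(
        [
            [1, 0, 0],
            [-0.5, math.sqrt(3) / 2, 0],
            [-0.5, -math.sqrt(3) / 2, 0],
            [0, 0, 1],
            [0, 0, -1],
        ]
    ),
}


def build_complex(
    geometry: str,
    metal: str = "Mg",
    ligand: str = "water",
    bond_length: float | tuple = 2.10,
) -> Configuration:
    """Ideal polyhedral metal complex with template ligands on the anchors.

    ``bond_length`` may be a single value, or a (equatorial, axial) pair for
    geometries with distinguished axial sites (square-pyramidal axial apex,
    trigonal-bipyramidal axial pair) — useful for transition-state-like
    templates with two elongated bonds.
    """
    if geometry not in _GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; options: {sorted(_GEOMETRIES)}")
    dirs = _GEOMETRIES[geometry]
    n_lig = len(dirs)
    if isinstance(bond_length, (tuple, list)):
        r_eq, r_ax = bond_length
        lengths = np.full(n_lig, float(r_eq))
        # axial sites are those with a z component
        lengths[np.abs(dirs[:, 2]) > 0.5] = float(r_ax)
    else:
        lengths = np.full(n_lig, float(bond_length))

    elements_t, pos_t = _TEMPLATES[ligand]()
    elements = [metal]
    positions = [np.zeros((1, 3))]
    mol_ids = [0]
    for i, (d, rl) in enumerate(zip(dirs, lengths)):
        d = d / np.linalg.norm(d)
        # rotate template's -z (anchor->metal direction) onto -d
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, d)
        c = float(np.dot(z, d))
        if np.linalg.norm(v) < 1e-12:
            R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            R = np.eye(3) + vx + vx @ vx / (1 + c)
        lig = pos_t @ R.T + d * rl
        elements.extend(elements_t)
        positions.append(lig)
        mol_ids.extend([i + 1] * len(elements_t))
    return Configuration(
        elements=elements,
        positions=np.vstack(positions),
        molecule_ids=np.array(mol_ids),
        tags={"provenance": f"build_complex:{geometry}"},
    )


def solvate_complex(
    complex_config: Configuration,
    n_solvent: int,
    radius: float,
    kind: str = "water",
    seed: int = 0,
    min_contact: float = 2.2,
) -> Configuration:
    """Pack solvent molecules into a sphere around a complex.

    Anchors are placed uniformly in the sphere of the given radius about the
    complex centroid, subject to the intermolecular heavy-atom contact rule.
    Intended for cluster MD under a flat-bottom spherical restraint at the
    same radius.
    """
    if n_solvent == 0:
        return complex_config.copy()
    rng = np.random.default_rng(seed)
    elements_t, pos_t = _TEMPLATES[kind]()
    heavy = _HEAVY[kind]
    center = complex_config.positions.mean(axis=0)

    elements = list(complex_config.elements)
    positions = [complex_config.positions.copy()]
    mol_ids = list(complex_config.molecule_ids)
    next_mol = int(np.max(complex_config.molecule_ids)) + 1
    heavy_placed = [complex_config.positions.copy()]  # whole complex is an obstacle

    for _ in range(n_solvent):
        placed = False
        for _attempt in range(4000):
            u = rng.random() ** (1.0 / 3.0)
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            anchor = center + d * u * radius
            R = _random_rotation(rng)
            cand = pos_t @ R.T + anchor
            cand_heavy = cand[[i for i, e in enumerate(elements_t) if e in heavy]]
            placed_arr = np.vstack(heavy_placed)
            dmin = np.min(
                np.linalg.norm(placed_arr[:, None, :] - cand_heavy[None, :, :], axis=-1)
            )
            if dmin >= min_contact:
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not pack {n_solvent} solvent molecules in a {radius} Å sphere"
            )
        elements.extend(elements_t)
        positions.append(cand)
        mol_ids.extend([next_mol] * len(elements_t))
        next_mol += 1
        heavy_placed.append(cand_heavy)

    return Configuration(
        elements=elements,
        positions=np.vstack(positions),
        molecule_ids=np.array(mol_ids),
        tags={"provenance": "solvate_complex"},
    )


def minimize(config: Configuration, calculator, n_steps: int = 200,
             max_step: float = 0.05) -> Configuration:
    """Damped steepest-descent relaxation (displacement-capped).

    Only used to relax freshly packed fixtures before dynamics; not a
    production optimizer.
    """
    ef = calculator.bind(config)
    pos = config.positions.copy()
    for _ in range(n_steps):
        e, f = ef(pos)
        fmax = np.abs(f).max()
        if fmax < 1.0:
            break
        step = f * (max_step / max(fmax, 1e-12))
        pos = pos + step
    out = config.copy()
    out.positions = pos
    return out
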