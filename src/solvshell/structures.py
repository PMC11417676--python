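"""Molecular configurations, labelled datasets, extended-XYZ IO and validation metrics.

A :class:`Configuration` is one molecular snapshot: chemical symbols, Cartesian
positions in Å, an optional periodic cell, and optional energy (kcal/mol) and
force (kcal/mol/Å) labels.  ``molecule_ids`` partition the atoms into whole
molecules; they are assigned at construction time by the fixture generators
rather than inferred from geometry, so that cluster cutting is deterministic.

The on-disk format is multi-frame extended XYZ with a ``key=value`` comment
line (``Lattice``, ``Properties``, ``energy``, ``pbc``) and forces as a
per-atom column — the de-facto dialect consumed by atomistic toolchains.
"""

from __future__ import annotations

import re
import shlex
from dataclasses import dataclass, field

import numpy as np

from .units import EV_TO_KCAL, KCAL_TO_MEV, mass_of


class ParseError(ValueError):
    """Malformed extended-XYZ input."""


@dataclass
class Configuration:
    """One molecular snapshot in internal units (Å, kcal/mol)."""

    elements: list[str]
    positions: np.ndarray
    cell: np.ndarray | None = None
    pbc: tuple[bool, bool, bool] = (False, False, False)
    energy: float | None = None
    forces: np.ndarray | None = None
    molecule_ids: np.ndarray | None = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.elements), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if self.forces is not None:
            self.forces = np.ascontiguousarray(self.forces, dtype=float)
            if self.forces.shape != self.positions.shape:
                raise ValueError("forces shape does not match positions")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        if any(self.pbc):
            if self.cell is None:
                raise ValueError("periodic configuration requires a cell")
            if abs(np.linalg.det(self.cell)) < 1e-10:
                raise ValueError("periodic cell is singular")
        if self.molecule_ids is None:
            self.molecule_ids = np.arange(len(self.elements), dtype=np.int64)
        else:
            self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
            if self.molecule_ids.shape != (len(self.elements),):
                raise ValueError("molecule_ids must have one entry per atom")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.elements])

    def copy(self) -> "Configuration":
        return Configuration(
            elements=list(self.elements),
            positions=self.positions.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            pbc=tuple(self.pbc),
            energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
            molecule_ids=self.molecule_ids.copy(),
            tags=dict(self.tags),
        )

    @property
    def is_labelled(self) -> bool:
        return self.energy is not None and self.forces is not None


@dataclass
class LabeledDataset:
    """Ordered collection of labelled configurations — the AL training set."""

    configs: list[Configuration] = field(default_factory=list)

    def __post_init__(self):
        for i, c in enumerate(self.configs):
            if not c.is_labelled:
                raise ValueError(f"config {i} is missing energy/forces labels")

    def __len__(self) -> int:
        return len(self.configs)

    def __iter__(self):
        return iter(self.configs)

    def __getitem__(self, i):
        return self.configs[i]

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for c in self.configs:
            for e in c.elements:
                if e not in seen:
                    seen.append(e)
        return sorted(seen)

    def append(self, config: Configuration) -> None:
        if not config.is_labelled:
            raise ValueError("cannot append an unlabelled configuration")
        self.configs.append(config)

    def extend(self, configs) -> None:
        for c in configs:
            self.append(c)

    def provenance_counts(self) -> dict:
        out: dict = {}
        for c in self.configs:
            key = c.tags.get("provenance", "unknown")
            out[key] = out.get(key, 0) + 1
        return out


@dataclass
class ValidationReport:
    """Point-to-point validation metrics in MLP-benchmark units."""

    mad_energy: float    # meV per atom
    mad_forces: float    # meV per Å
    n_configs: int

    def __post_init__(self):
        if self.mad_energy < 0 or self.mad_forces < 0:
            raise ValueError("MADs must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mad_energy_meV_per_atom": [self.mad_energy],
                "mad_forces_meV_per_A": [self.mad_forces],
                "n_configs": [self.n_configs],
            }
        )


def mad_metrics(predicted: list[Configuration], reference: list[Configuration]) -> ValidationReport:
    """Mean absolute deviations of energies (meV/atom) and forces (meV/Å).

    ``mad_energy`` averages |ΔE|/N_atoms over configurations; ``mad_forces``
    averages |ΔF| over every Cartesian force component of every atom.
    """
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference have different lengths")
    if not predicted:
        raise ValueError("empty comparison")
    de = []
    df_all = []
    for i, (p, r) in enumerate(zip(predicted, reference)):
        if p.n_atoms != r.n_atoms:
            raise ValueError(f"config {i}: atom count mismatch ({p.n_atoms} vs {r.n_atoms})")
        if p.energy is None or r.energy is None:
            raise ValueError(f"config {i}: missing energy label")
        de.append(abs(p.energy - r.energy) / p.n_atoms)
        if p.forces is None or r.forces is None:
            raise ValueError(f"config {i}: missing force labels")
        if p.forces.shape != r.forces.shape:
            raise ValueError(f"config {i}: force shape mismatch")
        df_all.append(np.abs(p.forces - r.forces).ravel())
    mad_e = float(np.mean(de)) * KCAL_TO_MEV
    mad_f = float(np.mean(np.concatenate(df_all))) * KCAL_TO_MEV
    return ValidationReport(mad_energy=mad_e, mad_forces=mad_f, n_configs=len(predicted))


# ---------------------------------------------------------------------------
# extended-XYZ IO
# ---------------------------------------------------------------------------

_PROP_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*):([SRIL]):(\d+)$")


def _parse_comment(line: str) -> dict:
    """Parse the key=value comment line, honouring double quotes."""
    out = {}
    try:
        tokens = shlex.split(line)
    except ValueError as e:
        raise ParseError(f"unparseable comment line: {e}") from None
    for tok in tokens:
        if "=" not in tok:
            out[tok] = True
            continue
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def _parse_properties(prop_str: str):
    cols = []
    parts = prop_str.split(":")
    if len(parts) % 3:
        raise ParseError(f"bad Properties string {prop_str!r}")
    for i in range(0, len(parts), 3):
        name, kind, n = parts[i], parts[i + 1], int(parts[i + 2])
        if kind not in "SRIL":
            raise ParseError(f"bad Properties string {prop_str!r}")
        cols.append((name, kind, n))
    return cols


def read_extxyz(path) -> list[Configuration]:
    """Read a (multi-frame) extended-XYZ file.

    Energies/forces are converted to internal kcal/mol units when the frame
    declares ``units=eV``; otherwise kcal/mol is assumed.
    """
    configs = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"frame {frame}: bad atom-count line {lines[i]!r}")
        if i + 1 >= len(lines):
            raise ParseError(f"frame {frame}: missing comment line")
        info = _parse_comment(lines[i + 1])
        body = lines[i + 2 : i + 2 + n]
        if len(body) != n:
            raise ParseError(f"frame {frame}: expected {n} atom lines, found {len(body)}")
        prop_str = info.pop("Properties", "species:S:1:pos:R:3")
        cols = _parse_properties(prop_str)
        rows = [ln.split() for ln in body]
        width = sum(nc for _, _, nc in cols)
        for j, r in enumerate(rows):
            if len(r) != width:
                raise ParseError(
                    f"frame {frame}, atom {j}: expected {width} columns, found {len(r)}"
                )
        data = {}
        off = 0
        arr = rows
        for name, kind, nc in cols:
            block = [r[off : off + nc] for r in arr]
            if kind == "S":
                data[name] = [b[0] for b in block] if nc == 1 else block
            elif kind == "R":
                data[name] = np.array(block, dtype=float)
                if nc == 1:
                    data[name] = data[name][:, 0]
            elif kind == "I":
                data[name] = np.array(block, dtype=np.int64)
                if nc == 1:
                    data[name] = data[name][:, 0]
            else:  # L
                data[name] = np.array([[b.lower() in ("t", "true", "1") for b in bb] for bb in block])
            off += nc

        elements = data.get("species")
        pos = data.get("pos")
        if elements is None or pos is None:
            raise ParseError(f"frame {frame}: Properties must include species and pos")
        pos = np.atleast_2d(np.asarray(pos, dtype=float))

        cell = None
        pbc = (False, False, False)
        if "Lattice" in info:
            cell = np.array(info["Lattice"].split(), dtype=float).reshape(3, 3)
        if "pbc" in info:
            flags = info["pbc"].replace('"', "").split()
            pbc = tuple(f.lower() in ("t", "true", "1") for f in flags)
        elif cell is not None:
            pbc = (True, True, True)

        scale = 1.0
        if str(info.get("units", "")).lower() == "ev":
            scale = EV_TO_KCAL
        energy = float(info["energy"]) * scale if "energy" in info else None
        forces = data.get("forces")
        if forces is not None:
            forces = np.asarray(forces, dtype=float) * scale
        mol_ids = data.get("mol_id")

        tags = {}
        for k, v in info.items():
            if k in ("Lattice", "pbc", "energy", "units"):
                continue
            tags[k] = v
        configs.append(
            Configuration(
                elements=list(elements),
                positions=pos,
                cell=cell,
                pbc=pbc,
                energy=energy,
                forces=forces,
                molecule_ids=mol_ids,
                tags=tags,
            )
        )
        i += 2 + n
        frame += 1
    return configs


def write_extxyz(configs, path) -> None:
    """Write configurations as multi-frame extended XYZ (kcal/mol, Å)."""
    if isinstance(configs, Configuration):
        configs = [configs]
    configs = list(configs)
    if not configs:
        raise ValueError("no configurations to write")
    # validate everything before touching the file
    for i, c in enumerate(configs):
        if not isinstance(c, Configuration):
            raise TypeError(f"item {i} is not a Configuration")
        if c.forces is not None and c.forces.shape != c.positions.shape:
            raise ValueError(f"config {i}: forces shape mismatch")
        if any(c.pbc) and c.cell is None:
            raise ValueError(f"config {i}: pbc set but no cell")

    with open(path, "w") as fh:
        for c in configs:
            keys = []
            if c.cell is not None:
                lat = " ".join(f"{x:.10g}" for x in c.cell.ravel())
                keys.append(f'Lattice="{lat}"')
            props = "species:S:1:pos:R:3"
            if c.forces is not None:
                props += ":forces:R:3"
            props += ":mol_id:I:1"
            keys.append(f"Properties={props}")
            if c.energy is not None:
                keys.append(f"energy={c.energy:.12g}")
            keys.append('pbc="%s %s %s"' % tuple("T" if f else "F" for f in c.pbc))
            for k, v in c.tags.items():
                sv = str(v)
                keys.append(f'{k}="{sv}"' if " " in sv else f"{k}={sv}")
            fh.write(f"{c.n_atoms}\n")
            fh.write(" ".join(keys) + "\n")
            for j in range(c.n_atoms):
                parts = [f"{c.elements[j]:<2s}"]
                parts += [f"{x:.12g}" for x in c.positions[j]]
                if c.forces is not None:
                    parts += [f"{x:.12g}" for x in c.forces[j]]
                parts.append(str(int(c.molecule_ids[j])))
                fh.write(" ".join(parts) + "\n")
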