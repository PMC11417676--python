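"""Structural post-processing: RDFs, coordination numbers, cluster cutting,
and axial-coordination classification of square-planar complexes.

The radial distribution function g(r) between a centre selection and a
partner selection is normalized by ideal-gas shell counts at the partner
number density; its running integral N(r) = 4 pi rho int g(s) s^2 ds is the
coordination number, and the first minimum of g delimits the first solvation
shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Configuration


@dataclass
class RdfResult:
    r: np.ndarray
    g: np.ndarray
    n_running: np.ndarray
    center_sel: object
    partner_sel: object
    n_frames: int
    density: float
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r": self.r, "g": self.g, "N": self.n_running})


def _resolve_selection(config: Configuration, sel) -> np.ndarray:
    if isinstance(sel, str):
        return np.array([i for i, e in enumerate(config.elements) if e == sel], dtype=np.int64)
    return np.asarray(sel, dtype=np.int64)


def rdf(
    trajectory,
    center_sel,
    partner_sel,
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> RdfResult:
    """Radial distribution function and running coordination number.

    Selections are an element symbol or explicit atom indices.  For periodic
    frames, r_max must not exceed half the smallest box edge, and distances
    use the minimum image.  For clusters the partner density is taken as the
    mean partner count inside the r_max sphere, which leaves N(r) exact and
    fixes only the (arbitrary) vertical scale of g.
    """
    trajectory = list(trajectory)
    if not trajectory:
        raise ValueError("empty trajectory")
    first = trajectory[0]
    periodic = any(first.pbc)
    if periodic:
        box = np.diagonal(first.cell)
        half = 0.5 * float(box.min())
        if r_max is None:
            r_max = half
        if r_max > half + 1e-9:
            raise ValueError(f"r_max {r_max} exceeds half the minimum box edge {half:.3f}")
    elif r_max is None:
        raise ValueError("r_max is required for non-periodic trajectories")

    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    n_centers_total = 0
    n_partners = None
    for frame in trajectory:
        centers = _resolve_selection(frame, center_sel)
        partners = _resolve_selection(frame, partner_sel)
        if centers.size == 0 or partners.size == 0:
            raise ValueError("empty selection")
        n_partners = partners.size
        pos = frame.positions
        d = pos[partners][None, :, :] - pos[centers][:, None, :]
        if periodic:
            d = d - box * np.round(d / box)
        rr = np.linalg.norm(d, axis=-1)
        # drop self pairs
        overlap = np.isin(partners, centers)
        if overlap.any():
            for ci, c in enumerate(centers):
                rr[ci, np.flatnonzero(partners == c)] = np.inf
        h, _ = np.histogram(rr.ravel(), bins=edges)
        counts += h
        n_centers_total += centers.size

    mean_counts = counts / n_centers_total           # partners per center per bin
    n_running = np.cumsum(mean_counts)
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    if periodic:
        volume = float(np.prod(box))
        rho = n_partners / volume
    else:
        rho = n_running[-1] / (4.0 / 3.0 * np.pi * r_max**3)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = mean_counts / (shell_vol * rho)
    return RdfResult(
        r=r_mid, g=g, n_running=n_running,
        center_sel=center_sel, partner_sel=partner_sel,
        n_frames=len(trajectory), density=float(rho),
    )


def first_shell(result: RdfResult, smooth: int = 5):
    """First-peak position, first-minimum position, and the coordination
    number N at the first minimum (raw and rounded).

    Peak finding runs on a moving-average-smoothed g; the integral N comes
    from the raw histogram, so smoothing cannot bias the coordination number.
    Raises if g has no interior maximum (no shell structure).
    """
    g = result.g
    if smooth > 1:
        kern = np.ones(smooth) / smooth
        padded = np.pad(g, (smooth // 2, smooth - 1 - smooth // 2), mode="edge")
        gs = np.convolve(padded, kern, mode="valid")
    else:
        gs = g
    # first interior maximum with non-trivial height
    i_peak = None
    for i in range(1, len(gs) - 1):
        if gs[i] > gs[i - 1] and gs[i] >= gs[i + 1] and gs[i] > 1e-3:
            i_peak = i
            break
    if i_peak is None:
        raise ValueError("g(r) is monotone: no shell structure to locate")
    i_min = None
    floor = 1e-3 * gs[i_peak]
    for i in range(i_peak + 1, len(gs) - 1):
        if gs[i] <= gs[i - 1] and gs[i] < gs[i + 1]:
            i_min = i
            break
        if gs[i] <= floor:
            # g fell to (numerically) zero: an isolated shell with no
            # neighbouring structure — the depletion zone is the minimum
            i_min = i
            break
    if i_min is None:
        raise ValueError("no first minimum found after the first peak")
    cn = float(result.n_running[i_min])
    return {
        "peak_r": float(result.r[i_peak]),
        "min_r": float(result.r[i_min]),
        "cn": cn,
        "cn_rounded": int(round(cn)),
    }


_DEFAULT_ANCHORS = {"O", "N"}


def cut_cluster(
    config: Configuration,
    center: int,
    radius: float,
    anchor_elements=frozenset(_DEFAULT_ANCHORS),
) -> Configuration:
    """Extract a spherical cluster of whole molecules from a periodic box.

    A molecule is kept when its anchor atom (the coordinating heavy atom:
    O for water-like, N for nitrile-like; single-atom molecules anchor on
    themselves) lies within ``radius`` of the center atom under the minimum
    image.  Kept molecules are unwrapped to be contiguous, the cluster is
    re-centered on the center atom, and the cell is removed.
    """
    if not any(config.pbc):
        raise ValueError("cut_cluster expects a periodic configuration")
    box = np.diagonal(config.cell)
    pos = config.positions
    c0 = pos[center]
    elements: list[str] = []
    out_pos: list[np.ndarray] = []
    mol_ids: list[int] = []
    new_mol = 0
    center_mol = int(config.molecule_ids[center])
    for m in np.unique(config.molecule_ids):
        idx = np.flatnonzero(config.molecule_ids == m)
        mol_elements = [config.elements[i] for i in idx]
        if len(idx) == 1:
            anchor_local = 0
        else:
            anchors = [i for i, e in enumerate(mol_elements) if e in anchor_elements]
            if not anchors:
                raise ValueError(
                    f"molecule {m} ({mol_elements}) has no anchor atom among {sorted(anchor_elements)}"
                )
            anchor_local = anchors[0]
        anchor = pos[idx[anchor_local]]
        d_anchor = anchor - c0
        d_anchor = d_anchor - box * np.round(d_anchor / box)
        if m != center_mol and np.linalg.norm(d_anchor) > radius:
            continue
        # rebuild molecule contiguously around its (min-imaged) anchor
        rel = pos[idx] - anchor
        rel = rel - box * np.round(rel / box)
        mol_pos = d_anchor[None, :] + rel
        elements.extend(mol_elements)
        out_pos.append(mol_pos)
        mol_ids.extend([new_mol] * len(idx))
        new_mol += 1
    return Configuration(
        elements=elements,
        positions=np.vstack(out_pos),
        molecule_ids=np.array(mol_ids),
        tags=dict(config.tags, provenance="cut_cluster", cut_radius=radius),
    )


@dataclass
class ComplexSpec:
    """Geometry definition for axial-coordination classification."""

    metal: int
    equatorial: np.ndarray               # 4 bound ligand anchor indices
    solvent_anchors: object = "N"        # element symbol or indices
    r_min: float = 2.4                   # axial distance window (Å)
    r_max: float = 3.6
    cone_half_angle: float = 35.0        # deg about the plane normal

    def __post_init__(self):
        self.equatorial = np.asarray(self.equatorial, dtype=np.int64)
        if self.equatorial.size != 4:
            raise ValueError("need exactly 4 equatorial anchors")


_STATES = {0: "square-planar", 1: "square-pyramidal", 2: "octahedral"}


def axial_state_classifier(trajectory, spec: ComplexSpec):
    """Classify each frame by axial occupancy of a square-planar complex.

    The equatorial plane is fit through the 4 bound anchors (SVD); solvent
    anchors within the axial distance window of the metal and inside the
    angular cone about the plane normal count as axial occupants.  0/1/2
    occupants map to square-planar / square-pyramidal / octahedral.  Returns
    (per-frame state list, fractions dict).
    """
    states = []
    cos_cone = np.cos(np.deg2rad(spec.cone_half_angle))
    for frame in trajectory:
        pos = frame.positions
        metal = pos[spec.metal]
        eq = pos[spec.equatorial] - metal
        # plane normal via SVD of centered anchor coordinates
        _, _, vt = np.linalg.svd(eq - eq.mean(axis=0))
        normal = vt[-1]
        solvent = _resolve_selection(frame, spec.solvent_anchors)
        solvent = solvent[~np.isin(solvent, spec.equatorial)]
        d = pos[solvent] - metal
        r = np.linalg.norm(d, axis=1)
        in_window = (r >= spec.r_min) & (r <= spec.r_max)
        cosang = np.abs(d[in_window] @ normal) / r[in_window]
        n_axial = int(np.sum(cosang >= cos_cone))
        states.append(_STATES.get(min(n_axial, 2)))
    fractions = {s: states.count(s) / len(states) for s in _STATES.values()}
    return states, fractions
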