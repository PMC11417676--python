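"""SOAP descriptors, the normalized similarity kernel, and the AL selector.

Each atom's neighbour density (Gaussians of width ``sigma_atom`` on every
neighbour inside ``r_cut``, including the atom itself, weighted by a smooth
cosine cutoff) is expanded per neighbour species in an orthonormalized
Gaussian radial basis times real spherical harmonics.  The rotationally
invariant power spectrum

    p_{n n' l}^{(s, s')} = sum_m  c_{n l m}^{(s)} c_{n' l m}^{(s')}

is the per-atom descriptor; the global structure descriptor is the average
over atoms, L2-normalized.  Structure similarity is the normalized
dot-product kernel raised to an integer power zeta,

    k(p, p') = |p . p'|^zeta  in [0, 1],

and a candidate enters the training set when the maximum of its similarity
vector K against all training structures is below the threshold k_T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import fractional_matrix_power

from .structures import Configuration


def _spherical_in_scaled(l_max: int, x: np.ndarray) -> np.ndarray:
    """Exponentially scaled modified spherical Bessel i_l(x) * exp(-x), l = 0..l_max.

    Power series for small x (upward recurrence cancels catastrophically
    there), stable closed forms + upward recurrence for large x.  Vectorized;
    returns shape (l_max + 1,) + x.shape.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty((l_max + 1,) + x.shape)
    small = x < 8.0
    if np.any(small):
        xs = x[small]
        scale = np.exp(-xs)
        for l in range(l_max + 1):
            # i_l(x) = sum_k x^(2k+l) / (2^k k! (2l+2k+1)!!)
            dfact = np.prod(np.arange(2 * l + 1, 0, -2), dtype=float)
            term = xs**l / dfact
            acc = term.copy()
            for k in range(1, 30):
                term = term * xs * xs / (2.0 * k * (2 * l + 2 * k + 1))
                acc += term
            out[l][small] = acc * scale
    big = ~small
    if np.any(big):
        xb = x[big]
        e2 = np.exp(-2.0 * xb)
        i_prev = (1.0 - e2) / (2.0 * xb)                               # l = 0
        out[0][big] = i_prev
        if l_max >= 1:
            i_cur = ((xb - 1.0) + (xb + 1.0) * e2) / (2.0 * xb * xb)   # l = 1
            out[1][big] = i_cur
            for l in range(2, l_max + 1):
                i_next = i_prev - (2.0 * l - 1.0) / xb * i_cur
                out[l][big] = i_next
                i_prev, i_cur = i_cur, i_next
    return out


@dataclass
class SoapSpec:
    """SOAP hyperparameters.

    The production workflow this mirrors states only the 5 Å cutoff; the
    remaining values are common SOAP-GAP defaults, all exposed here.
    """

    r_cut: float = 5.0
    n_max: int = 6
    l_max: int = 4
    sigma_atom: float = 0.5
    zeta: int = 4
    species: tuple = ("H", "O", "Mg")
    switch_width: float = 1.0   # cosine switch from r_cut - width to r_cut
    n_quad: int = 80            # radial quadrature points

    def __post_init__(self):
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.n_max < 1 or self.l_max < 1:
            raise ValueError("n_max and l_max must be >= 1")
        if int(self.zeta) != self.zeta or self.zeta < 1:
            raise ValueError("zeta must be a positive integer")
        self.species = tuple(self.species)


@dataclass
class SimilarityRecord:
    """Outcome of screening one candidate against a training set."""

    descriptor: np.ndarray
    similarities: np.ndarray
    k_T: float
    selected: bool

    @property
    def max_similarity(self) -> float:
        return float(np.max(self.similarities)) if self.similarities.size else 0.0


# ---------------------------------------------------------------------------
# real spherical harmonics (orthonormal), evaluated from unit vectors
# ---------------------------------------------------------------------------


def _real_sph_harm(l_max: int, unit: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonics Y_lm for unit vectors.

    Returns array of shape (n_points, (l_max+1)^2), ordered (l, m) with
    m = -l..l.  Built from scipy's complex spherical harmonics.
    """
    from scipy.special import sph_harm_y

    x, y, z = unit[:, 0], unit[:, 1], unit[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    ls = np.concatenate([[l] * (2 * l + 1) for l in range(l_max + 1)])
    ms = np.concatenate([np.arange(-l, l + 1) for l in range(l_max + 1)])
    cplx = sph_harm_y(ls[None, :], np.abs(ms)[None, :], theta[:, None], phi[:, None])
    out = np.real(cplx).copy()
    pos_m = ms > 0
    neg_m = ms < 0
    sign = (-1.0) ** np.abs(ms)
    out[:, pos_m] = math.sqrt(2) * sign[pos_m] * np.real(cplx[:, pos_m])
    out[:, neg_m] = math.sqrt(2) * sign[neg_m] * np.imag(cplx[:, neg_m])
    return out


class _RadialBasis:
    """Orthonormalized Gaussians on an equispaced grid in [0, r_cut]."""

    def __init__(self, spec: SoapSpec):
        self.spec = spec
        n, rc = spec.n_max, spec.r_cut
        self.centers = np.linspace(0.0, rc, n)
        self.width = rc / (n - 1) if n > 1 else rc
        # Gauss-Legendre quadrature on [0, r_cut]
        x, w = np.polynomial.legendre.leggauss(spec.n_quad)
        self.r = 0.5 * rc * (x + 1.0)
        self.w = 0.5 * rc * w
        raw = np.exp(-(((self.r[None, :] - self.centers[:, None]) / self.width) ** 2))
        S = (raw * self.w * self.r**2) @ raw.T
        self._S_inv_half = np.real(fractional_matrix_power(S, -0.5))
        self.G = self._S_inv_half @ raw    # orthonormal basis on the quad grid

    def evaluate(self, r: np.ndarray) -> np.ndarray:
        """Orthonormalized radial functions g_n on an arbitrary grid, (n, len(r))."""
        raw = np.exp(-(((np.asarray(r)[None, :] - self.centers[:, None]) / self.width) ** 2))
        return self._S_inv_half @ raw

    def coeff_integrals(self, r_neighbors: np.ndarray) -> np.ndarray:
        """I[n, l, j] = int g_n(r) r^2 exp(-(r^2+R_j^2)/2s^2) i_l(r R_j / s^2) dr."""
        s2 = self.spec.sigma_atom**2
        l_max = self.spec.l_max
        r = self.r                                     # (Q,)
        R = np.asarray(r_neighbors)                    # (J,)
        x = np.outer(r, R) / s2                        # (Q, J)
        # scaled Bessel: exp(-(r^2+R^2)/2s^2) i_l(rR/s^2) = exp(-(r-R)^2/2s^2) i_l_scaled
        expo = np.exp(-((r[:, None] - R[None, :]) ** 2) / (2 * s2))
        il = _spherical_in_scaled(l_max, x)            # (l+1, Q, J)
        kern = il * (expo * (self.w * r**2)[:, None])[None, :, :]
        out = np.einsum("nq,lqj->nlj", self.G, kern)
        return out


def _smooth_cutoff(r: np.ndarray, r_cut: float, width: float) -> np.ndarray:
    """Cosine switching function: 1 below r_cut - width, 0 at r_cut."""
    r0 = r_cut - width
    out = np.ones_like(r)
    mask = r > r0
    out[mask] = 0.5 * (1.0 + np.cos(np.pi * (r[mask] - r0) / width))
    out[r >= r_cut] = 0.0
    return out


def soap_power_spectrum(config: Configuration, spec: SoapSpec) -> np.ndarray:
    """Per-atom SOAP power-spectrum descriptors, shape (n_atoms, D).

    The central atom contributes its own density (an l = 0 self term), so an
    isolated atom has a well-defined, element-dependent descriptor.  The
    expansion is vectorized over all neighbour pairs at once.
    """
    for e in set(config.elements):
        if e not in spec.species:
            raise ValueError(f"element {e!r} not in SOAP species list {spec.species}")
    basis = _radial_basis_for(spec)
    n_sp = len(spec.species)
    sp_index = {s: i for i, s in enumerate(spec.species)}
    n, lm = spec.n_max, spec.l_max
    n_lm = (lm + 1) ** 2
    pos = config.positions
    N = config.n_atoms
    z = np.array([sp_index[e] for e in config.elements])

    periodic = any(config.pbc)
    box = np.diagonal(config.cell) if periodic else None

    # l-block index map for power spectrum contraction
    l_of = np.concatenate([[l] * (2 * l + 1) for l in range(lm + 1)])

    # expansion coefficients c[atom, species, n, lm]
    c = np.zeros((N, n_sp, n, n_lm))
    # self term: l = 0 only (limit R -> 0 of the Gaussian expansion)
    self_I = basis.coeff_integrals(np.array([1e-12]))[:, 0, 0]
    c[np.arange(N), z, :, 0] += 4.0 * math.pi / math.sqrt(4.0 * math.pi) * self_I

    d = pos[None, :, :] - pos[:, None, :]
    if periodic:
        d = d - box * np.round(d / box)
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    ii, jj = np.nonzero(r < spec.r_cut)
    if ii.size:
        rj = r[ii, jj]
        unit = d[ii, jj] / rj[:, None]
        fc = _smooth_cutoff(rj, spec.r_cut, spec.switch_width)
        Y = _real_sph_harm(lm, unit)                  # (P, n_lm)
        I = basis.coeff_integrals(rj)                 # (n, l+1, P)
        contrib = (fc[:, None] * Y)[None, :, :] * I[:, l_of, :].transpose(0, 2, 1)
        # scatter into (atom, neighbour-species) channels
        flat = c.reshape(N * n_sp, n, n_lm)
        np.add.at(flat, ii * n_sp + z[jj], 4.0 * math.pi * contrib.transpose(1, 0, 2))
        c = flat.reshape(N, n_sp, n, n_lm)

    # power spectrum: per species pair, sum over m within each l block
    triu_n = np.triu_indices(n)
    blocks = []
    for s1 in range(n_sp):
        for s2 in range(s1, n_sp):
            for l in range(lm + 1):
                sl = slice(l * l, (l + 1) * (l + 1))
                P = np.einsum("anm,abm->anb", c[:, s1, :, sl], c[:, s2, :, sl])
                if s1 == s2:
                    blocks.append(P[:, triu_n[0], triu_n[1]])
                else:
                    blocks.append(P.reshape(N, -1))
    return np.concatenate(blocks, axis=1)


_BASIS_CACHE: dict = {}


def _radial_basis_for(spec: SoapSpec) -> _RadialBasis:
    key = (spec.r_cut, spec.n_max, spec.sigma_atom, spec.n_quad)
    if key not in _BASIS_CACHE:
        _BASIS_CACHE[key] = _RadialBasis(spec)
    return _BASIS_CACHE[key]


def global_descriptor(config: Configuration, spec: SoapSpec) -> np.ndarray:
    """Average of per-atom descriptors, L2-normalized (||p|| = 1)."""
    if config.n_atoms == 0:
        raise ValueError("empty configuration has no descriptor")
    p = soap_power_spectrum(config, spec).mean(axis=0)
    norm = np.linalg.norm(p)
    if norm == 0:
        raise ValueError("zero descriptor")
    return p / norm


def kernel(p: np.ndarray, p_prime: np.ndarray, zeta: int) -> float:
    """Normalized dot-product kernel |p . p'|^zeta; 1 for identical inputs."""
    for v in (p, p_prime):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("kernel inputs must be L2-normalized")
    return float(np.abs(np.dot(p, p_prime)) ** zeta)


def similarity_select(
    candidate: Configuration,
    training,
    spec: SoapSpec,
    k_T: float,
    training_descriptors: np.ndarray | None = None,
) -> SimilarityRecord:
    """Screen a candidate: selected iff max similarity to the training set < k_T.

    An empty training set always selects (bootstrap convention).  Passing
    ``training_descriptors`` (rows = global descriptors of the training
    configs) avoids recomputing them — the active-learning driver does this.
    """
    if not (0.0 < k_T <= 1.0):
        raise ValueError("k_T must be in (0, 1]")
    p0 = global_descriptor(candidate, spec)
    if training_descriptors is None:
        configs = training.configs if hasattr(training, "configs") else list(training)
        training_descriptors = (
            np.array([global_descriptor(c, spec) for c in configs])
            if configs else np.empty((0, p0.size))
        )
    if training_descriptors.shape[0] == 0:
        return SimilarityRecord(descriptor=p0, similarities=np.empty(0), k_T=k_T, selected=True)
    K = np.abs(training_descriptors @ p0) ** spec.zeta
    # descriptors are unit vectors: |p.p'| <= 1 up to rounding; snap an exact
    # self-match to 1 so it can never pass a k_T <= 1 threshold
    K = np.minimum(K, 1.0)
    K[K > 1.0 - 1e-12] = 1.0
    return SimilarityRecord(
        descriptor=p0, similarities=K, k_T=k_T, selected=bool(np.max(K) < k_T)
    )
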