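"""SOAP descriptors: invariances, the kernel contract, the similarity
selector, and a brute-force grid-quadrature oracle for the power spectrum."""

import math

import numpy as np
import pytest

from solvshell.soap import (
    SimilarityRecord,
    SoapSpec,
    _radial_basis_for,
    _real_sph_harm,
    _smooth_cutoff,
    global_descriptor,
    kernel,
    similarity_select,
    soap_power_spectrum,
)
from solvshell.structures import Configuration, LabeledDataset
from solvshell.fixtures import build_complex, random_displace


@pytest.fixture(scope="module")
def spec():
    return SoapSpec(species=("H", "O", "Mg"))


def _rot(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [[1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
         [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
         [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]]
    )


class TestDescriptorInvariances:
    def test_isolated_atom_self_contribution(self, spec):
        a = Configuration(["O"], np.zeros((1, 3)))
        b = Configuration(["O"], np.full((1, 3), 7.0))
        da = soap_power_spectrum(a, spec)
        db = soap_power_spectrum(b, spec)
        assert np.linalg.norm(da) > 0
        np.testing.assert_allclose(da, db, atol=1e-12)

    def test_rotation_invariance(self, spec, rng):
        comp = build_complex("octahedral", bond_length=2.1)
        d0 = soap_power_spectrum(comp, spec)
        for _ in range(3):
            rot = comp.copy()
            rot.positions = comp.positions @ _rot(rng).T
            np.testing.assert_allclose(soap_power_spectrum(rot, spec), d0, atol=1e-8)

    def test_translation_invariance(self, spec, rng):
        comp = build_complex("octahedral", bond_length=2.1)
        d0 = soap_power_spectrum(comp, spec)
        t = comp.copy()
        t.positions = comp.positions + rng.uniform(-9, 9, 3)
        np.testing.assert_allclose(soap_power_spectrum(t, spec), d0, atol=1e-8)

    def test_permutation_invariance_global(self, spec, rng):
        comp = build_complex("octahedral", bond_length=2.1)
        p0 = global_descriptor(comp, spec)
        perm = rng.permutation(comp.n_atoms)
        shuffled = Configuration(
            [comp.elements[i] for i in perm], comp.positions[perm],
            molecule_ids=comp.molecule_ids[perm],
        )
        np.testing.assert_allclose(global_descriptor(shuffled, spec), p0, atol=1e-8)

    def test_descriptor_continuity_at_cutoff(self, spec):
        """Displacing an atom across r_cut changes the descriptor smoothly."""
        deltas = [0.1, 0.01, 0.001]
        base = Configuration(["O", "O"], np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        p0 = global_descriptor(base, spec)
        changes = []
        for d in deltas:
            c = base.copy()
            c.positions[1, 0] += d
            changes.append(np.linalg.norm(global_descriptor(c, spec) - p0))
        assert changes[0] > changes[1] > changes[2]
        assert changes[2] < 1e-3

    def test_distinct_structures_distinct_descriptors(self, spec):
        d1 = Configuration(["O", "O"], np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        d2 = Configuration(["O", "O"], np.array([[0.0, 0, 0], [2.5, 0, 0]]))
        k = kernel(global_descriptor(d1, spec), global_descriptor(d2, spec), spec.zeta)
        assert k < 1.0 - 1e-6


class TestGridOracle:
    def test_power_spectrum_matches_numeric_integration(self):
        """Brute-force quadrature of the smeared-density expansion coefficients
        reproduces the basis-expansion power spectrum for a heteronuclear dimer."""
        spec = SoapSpec(species=("O", "Mg"), n_max=4, l_max=3)
        cfg = Configuration(["O", "Mg"], np.array([[0.0, 0, 0], [2.0, 0.5, -0.3]]))
        fast = soap_power_spectrum(cfg, spec)

        basis = _radial_basis_for(spec)
        n_sp, n, lm = 2, spec.n_max, spec.l_max
        n_lm = (lm + 1) ** 2
        l_of = np.concatenate([[l] * (2 * l + 1) for l in range(lm + 1)])
        # spherical product grid: Gauss-Legendre in r and cos(theta), trapezoid in phi
        xr, wr = np.polynomial.legendre.leggauss(90)
        r = 0.5 * spec.r_cut * (xr + 1)
        wr = 0.5 * spec.r_cut * wr
        xc, wc = np.polynomial.legendre.leggauss(60)
        phi = np.linspace(0, 2 * np.pi, 91)[:-1]
        wphi = 2 * np.pi / 90
        theta = np.arccos(xc)
        # grid points
        st = np.sin(theta)
        dirs = np.stack(
            [np.outer(st, np.cos(phi)), np.outer(st, np.sin(phi)),
             np.outer(np.cos(theta), np.ones_like(phi))], axis=-1
        )  # (nc, nphi, 3)
        Y = _real_sph_harm(lm, dirs.reshape(-1, 3)).reshape(len(theta), len(phi), n_lm)

        s2 = spec.sigma_atom**2
        sp_index = {"O": 0, "Mg": 1}
        per_atom_oracle = []
        for i in range(2):
            c = np.zeros((n_sp, n, n_lm))
            for j in range(2):
                R = cfg.positions[j] - cfg.positions[i]
                Rn = np.linalg.norm(R)
                if Rn >= spec.r_cut:
                    continue
                fc = 1.0 if Rn < 1e-9 else float(
                    _smooth_cutoff(np.array([Rn]), spec.r_cut, spec.switch_width)[0]
                )
                # density of neighbour j on the grid
                pts = r[:, None, None, None] * dirs[None, :, :, :]  # (nr, nc, nphi, 3)
                rho = fc * np.exp(-np.sum((pts - R) ** 2, axis=-1) / (2 * s2))
                # c_nlm = int g_n(r) Y_lm rho r^2 dr dOmega
                ang = np.einsum("rcp,cpq,c->rq", rho, Y, wc) * wphi
                G = basis.evaluate(r)
                c[sp_index[cfg.elements[j]]] += np.einsum(
                    "nr,rq->nq", G * (wr * r**2)[None, :], ang
                )
            blocks = []
            triu = np.triu_indices(n)
            for s1 in range(n_sp):
                for s2i in range(s1, n_sp):
                    for l in range(lm + 1):
                        sl = slice(l * l, (l + 1) * (l + 1))
                        P = c[s1][:, sl] @ c[s2i][:, sl].T
                        blocks.append(P[triu] if s1 == s2i else P.ravel())
            per_atom_oracle.append(np.concatenate(blocks))
        oracle = np.array(per_atom_oracle)
        scale = np.abs(fast).max()
        assert np.abs(fast - oracle).max() / scale < 1e-4


class TestKernel:
    def test_self_similarity_is_one(self, spec, rng):
        p = rng.standard_normal(20)
        p /= np.linalg.norm(p)
        assert kernel(p, p, 4) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_is_zero(self):
        p = np.zeros(4)
        p[0] = 1.0
        q = np.zeros(4)
        q[1] = 1.0
        assert kernel(p, q, 2) == 0.0

    def test_zeta_power(self):
        p = np.array([1.0, 0.0])
        q = np.array([0.9, math.sqrt(1 - 0.81)])
        assert kernel(p, q, 4) == pytest.approx(0.6561, abs=1e-12)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            kernel(np.array([2.0, 0.0]), np.array([1.0, 0.0]), 2)

    def test_raising_zeta_never_increases_similarity(self, spec, rng):
        p = rng.standard_normal(10)
        p /= np.linalg.norm(p)
        q = rng.standard_normal(10)
        q /= np.linalg.norm(q)
        ks = [kernel(p, q, z) for z in (1, 2, 4, 8)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))


class TestSelector:
    def test_self_match_never_selected(self, spec, water_calc, hexaaqua):
        from solvshell.reference import label_dataset

        ds = label_dataset([hexaaqua], water_calc)
        rec = similarity_select(hexaaqua, ds, spec, k_T=1.0)
        assert rec.max_similarity == pytest.approx(1.0, abs=1e-10)
        assert not rec.selected

    def test_empty_training_set_selects(self, spec, hexaaqua):
        rec = similarity_select(hexaaqua, LabeledDataset([]), spec, k_T=0.5)
        assert rec.selected
        assert rec.similarities.size == 0

    def test_threshold_boundary_is_strict(self, spec, hexaaqua, water_calc):
        from solvshell.reference import label_dataset

        ds = label_dataset([hexaaqua], water_calc)
        displaced = hexaaqua.copy()
        displaced.positions = displaced.positions.copy()
        displaced.positions[4] += 0.5
        rec = similarity_select(displaced, ds, spec, k_T=1.0)
        # exact boundary: k_T equal to max K must NOT select
        rec_at = similarity_select(displaced, ds, spec, k_T=rec.max_similarity)
        assert not rec_at.selected

    def test_selection_monotone_in_threshold(self, spec, hexaaqua, water_calc):
        from solvshell.reference import label_dataset

        ds = label_dataset([hexaaqua], water_calc)
        displaced = hexaaqua.copy()
        displaced.positions = displaced.positions.copy()
        displaced.positions[4] += 0.5
        rec = similarity_select(displaced, ds, spec, k_T=0.9)
        thresholds = np.linspace(0.01, 1.0, 25)
        decisions = [similarity_select(displaced, ds, spec, k_T=t).selected
                     for t in thresholds]
        # once selected at some threshold, selected at every larger one
        first = decisions.index(True) if True in decisions else len(decisions)
        assert all(decisions[first:])

    def test_brute_force_kernel_cross_check(self, spec, hexaaqua, water_calc):
        """Similarity vector matches a direct dot-product computation."""
        from solvshell.reference import label_dataset
        from solvshell.fixtures import random_displace

        pool = random_displace(hexaaqua, 0.1, 4, seed=5)
        ds = label_dataset(pool, water_calc)
        cand = hexaaqua.copy()
        cand.positions = cand.positions.copy()
        cand.positions[7] += 0.5
        rec = similarity_select(cand, ds, spec, k_T=0.9999)
        p0 = global_descriptor(cand, spec)
        manual = np.array(
            [abs(float(np.dot(p0, global_descriptor(c, spec)))) ** spec.zeta for c in ds]
        )
        np.testing.assert_allclose(rec.similarities, manual, atol=1e-12)
        assert rec.selected == (manual.max() < 0.9999)

    def test_invalid_threshold(self, spec, hexaaqua):
        with pytest.raises(ValueError):
            similarity_select(hexaaqua, LabeledDataset([]), spec, k_T=0.0)
        with pytest.raises(ValueError):
            similarity_select(hexaaqua, LabeledDataset([]), spec, k_T=1.5)


class TestSpecValidation:
    @pytest.mark.parametrize("bad", [
        {"r_cut": -1.0}, {"n_max": 0}, {"l_max": 0}, {"zeta": 0}, {"zeta": 2.5},
    ])
    def test_invalid_spec(self, bad):
        with pytest.raises(ValueError):
            SoapSpec(**bad)
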