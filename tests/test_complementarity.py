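"""Electronic-complementarity scoring: density model, sampling, regression."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phytoscreen.complementarity import (
    ComplementarityResult,
    ElementDensity,
    SamplingConfig,
    assess_complementarity,
    cf1_at_point,
    complementarity_profile,
    default_density_params,
    load_density_params,
    molecular_density_at,
    regress_cf1,
    sample_intermolecular_points,
)
from phytoscreen.datasets import data_path
from phytoscreen.errors import InsufficientDataError, UnknownElementError
from phytoscreen.structures import Atom, Molecule
from phytoscreen.synthetic import gen_cf1_cloud, gen_toy_complex

UNIT_H = {"H": ElementDensity(rho_cnt=1.0, zeta=2.0, atomic_number=1)}


class TestDensityModel:
    def test_single_atom_closed_form(self):
        mol = Molecule([Atom("H", (0, 0, 0))])
        rho, idx, dist = molecular_density_at(mol, UNIT_H, (1.0, 0, 0))
        assert rho == pytest.approx(math.exp(-2.0), rel=1e-12)
        assert idx == 0
        assert dist == pytest.approx(1.0)

    def test_two_equidistant_atoms_double_density_tie_to_lowest_index(self):
        mol = Molecule([Atom("H", (-1, 0, 0)), Atom("H", (1, 0, 0))])
        rho, idx, dist = molecular_density_at(mol, UNIT_H, (0, 0, 0))
        assert rho == pytest.approx(2 * math.exp(-2.0), rel=1e-12)
        assert idx == 0
        assert dist == pytest.approx(1.0)

    def test_argmax_matches_exhaustive_search(self, rng):
        """Largest-single-term atom selection vs a brute-force scan."""
        params = default_density_params()
        elements = list(params)
        for _ in range(1000):
            n = rng.integers(2, 21)
            mol = Molecule(
                [Atom(str(rng.choice(elements)), rng.uniform(-4, 4, 3)) for _ in range(n)]
            )
            point = rng.uniform(-6, 6, 3)
            _, idx, _ = molecular_density_at(mol, params, point)
            terms = [
                params[a.element].rho_cnt
                * math.exp(-params[a.element].zeta * np.linalg.norm(point - a.coords))
                for a in mol.atoms
            ]
            assert idx == int(np.argmax(terms))

    def test_missing_element_parameters_named(self):
        mol = Molecule([Atom("Fe", (0, 0, 0))])
        with pytest.raises(UnknownElementError, match="Fe"):
            molecular_density_at(mol, default_density_params(), (1, 0, 0))

    def test_packaged_parameter_table_matches_builtin(self):
        loaded = load_density_params(data_path("density_params.tsv"))
        builtin = default_density_params()
        assert set(loaded) == set(builtin)
        for el in builtin:
            assert loaded[el].zeta == pytest.approx(builtin[el].zeta, abs=1e-5)
            assert loaded[el].rho_cnt == pytest.approx(builtin[el].rho_cnt, abs=1e-5)
            assert loaded[el].atomic_number == builtin[el].atomic_number


class TestCf1AtPoint:
    def test_identity_case(self):
        p = ElementDensity(rho_cnt=1.0, zeta=1.0, atomic_number=1)
        assert cf1_at_point(1.0, 1.0, p, p) == pytest.approx(0.0)

    def test_closed_form(self):
        p = ElementDensity(rho_cnt=1.0, zeta=1.0, atomic_number=1)
        assert cf1_at_point(math.e, math.e, p, p) == pytest.approx(2.0, rel=1e-12)

    def test_symmetric_under_role_swap(self):
        pe = ElementDensity(rho_cnt=2.0, zeta=1.0, atomic_number=6)
        pl = ElementDensity(rho_cnt=5.0, zeta=1.0, atomic_number=8)
        assert cf1_at_point(0.3, 0.7, pe, pl) == pytest.approx(
            cf1_at_point(0.7, 0.3, pl, pe), rel=1e-12
        )

    def test_nonpositive_density_rejected(self):
        p = ElementDensity(rho_cnt=1.0, zeta=1.0, atomic_number=1)
        with pytest.raises(ValueError):
            cf1_at_point(0.0, 1.0, p, p)


class TestSampling:
    def test_distant_atoms_leave_empty_shell(self):
        a = Molecule([Atom("H", (0, 0, 0))])
        b = Molecule([Atom("H", (20, 0, 0))])
        cfg = SamplingConfig(spacing=0.5, band=(1e-2, 1e-1))
        with pytest.warns(UserWarning, match="no intermolecular points"):
            pts = sample_intermolecular_points(a, b, UNIT_H, cfg)
        assert len(pts) == 0

    def test_halving_spacing_grows_count_roughly_8x(self):
        toy = gen_toy_complex(seed=4)
        coarse = SamplingConfig(spacing=0.6)
        fine = SamplingConfig(spacing=0.3)
        n_coarse = len(sample_intermolecular_points(toy.protein, toy.ligand, config=coarse))
        n_fine = len(sample_intermolecular_points(toy.protein, toy.ligand, config=fine))
        assert n_coarse > 0
        assert n_fine == pytest.approx(8 * n_coarse, rel=0.2)

    def test_mirror_symmetric_system_gives_mirror_symmetric_points(self):
        a = Molecule([Atom("H", (-2, 0, 0))])
        b = Molecule([Atom("H", (2, 0, 0))])
        cfg = SamplingConfig(spacing=0.5, band=(1e-4, 1e-1), clash_floor=0.8)
        pts = sample_intermolecular_points(a, b, UNIT_H, cfg)
        assert len(pts) > 0
        mirrored = pts.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        # compare as sets of rounded tuples (grid is mirror-aligned here)
        orig = {tuple(np.round(p, 6)) for p in pts}
        assert {tuple(np.round(p, 6)) for p in mirrored} == orig


class TestProfile:
    def test_single_atom_pair_closed_form(self):
        """With one atom per molecule and shared zeta, CF1 is exactly
        const - zeta * SUMRLRE: slope -zeta, Rcor2 = 1."""
        zeta = 2.0
        params = {"C": ElementDensity(rho_cnt=1.5, zeta=zeta, atomic_number=6)}
        toy = gen_toy_complex(single_atoms=True, separation=3.0, seed=0)
        cfg = SamplingConfig(spacing=0.4, band=(1e-6, 1e-1), clash_floor=0.8)
        result, table = complementarity_profile(toy.protein, toy.ligand, params, cfg)
        assert result.b_cf1 == pytest.approx(-zeta, abs=1e-9)
        assert result.rcor2 == pytest.approx(1.0, abs=1e-9)
        assert result.sigma == pytest.approx(0.0, abs=1e-9)
        assert result.n_points == len(table)
        assert result.min_sumrlre == pytest.approx(table["sumrlre"].min())
        assert result.max_cf1 == pytest.approx(table["cf1"].max())

    def test_invariant_under_common_rigid_transform(self):
        toy = gen_toy_complex(seed=5)
        params = default_density_params()
        cfg = SamplingConfig(spacing=0.5)
        pts = sample_intermolecular_points(toy.protein, toy.ligand, params, cfg)
        base, _ = complementarity_profile(toy.protein, toy.ligand, params, points=pts)
        R = Rotation.random(rng=3).as_matrix()
        t = np.array([4.0, -2.0, 7.0])
        moved, _ = complementarity_profile(
            toy.protein.transformed(R, t),
            toy.ligand.transformed(R, t),
            params,
            points=pts @ R.T + t,
        )
        assert moved.a_cf1 == pytest.approx(base.a_cf1, abs=1e-7)
        assert moved.b_cf1 == pytest.approx(base.b_cf1, abs=1e-7)
        assert moved.rcor2 == pytest.approx(base.rcor2, abs=1e-9)
        assert moved.min_sumrlre == pytest.approx(base.min_sumrlre, abs=1e-9)
        assert moved.max_cf1 == pytest.approx(base.max_cf1, abs=1e-9)

    def test_invariant_under_label_swap(self):
        toy = gen_toy_complex(seed=6)
        params = default_density_params()
        pts = sample_intermolecular_points(
            toy.protein, toy.ligand, params, SamplingConfig(spacing=0.5)
        )
        a, ta = complementarity_profile(toy.protein, toy.ligand, params, points=pts)
        b, tb = complementarity_profile(toy.ligand, toy.protein, params, points=pts)
        assert np.allclose(ta["cf1"], tb["cf1"], atol=1e-12)
        assert np.allclose(ta["sumrlre"], tb["sumrlre"], atol=1e-12)
        assert a.b_cf1 == pytest.approx(b.b_cf1, abs=1e-12)

    def test_too_few_points_rejected(self):
        toy = gen_toy_complex(single_atoms=True, seed=0)
        with pytest.raises(InsufficientDataError):
            complementarity_profile(
                toy.protein, toy.ligand, UNIT_H | {"C": UNIT_H["H"]},
                points=np.array([[0.0, 0.0, 0.0]]),
            )


class TestRegression:
    def test_recovers_known_coefficients(self):
        s, c, truth = gen_cf1_cloud(a=6.4, b=-4.0, noise_sd=0.3, n=400, seed=11)
        a, b, r2, sigma = regress_cf1(s, c)
        assert a == pytest.approx(6.4, abs=0.3)
        assert b == pytest.approx(-4.0, abs=0.1)
        assert sigma == pytest.approx(0.3, rel=0.15)
        assert 0.9 < r2 <= 1.0

    def test_sigma_and_coefficients_converge_with_n(self):
        """Consistency: estimates tighten as the cloud grows."""
        errs = []
        for n in (50, 500, 5000):
            s, c, _ = gen_cf1_cloud(n=n, seed=21)
            a, b, _, sigma = regress_cf1(s, c)
            errs.append(abs(a - 6.4) + abs(b + 4.0) + abs(sigma - 0.3))
        assert errs[2] < errs[0]
        assert abs(errs[2]) < 0.05


class TestAssessment:
    def test_experimental_like_row_passes(self):
        res = ComplementarityResult(
            a_cf1=6.396, b_cf1=-4.031, rcor2=0.918, sigma=0.34,
            n_points=5650, min_sumrlre=2.742, max_cf1=-4.184,
        )
        verdict = assess_complementarity(res)
        assert verdict.passed and verdict.reasons == ()

    def test_low_correlation_fails(self):
        res = ComplementarityResult(
            a_cf1=5.0, b_cf1=-4.0, rcor2=0.50, sigma=0.5,
            n_points=100, min_sumrlre=3.0, max_cf1=-3.0,
        )
        verdict = assess_complementarity(res)
        assert not verdict.passed
        assert any("Rcor2" in r for r in verdict.reasons)

    def test_weak_overlap_fails(self):
        res = ComplementarityResult(
            a_cf1=5.0, b_cf1=-4.0, rcor2=0.95, sigma=0.2,
            n_points=100, min_sumrlre=3.0, max_cf1=-10.0,
        )
        verdict = assess_complementarity(res)
        assert not verdict.passed
        assert any("MAX(CF1)" in r for r in verdict.reasons)

    def test_reference_deltas_reported(self):
        res = ComplementarityResult(6.26, -4.003, 0.840, 0.24, 835, 3.304, -6.776)
        ref = ComplementarityResult(9.041, -4.820, 0.972, 0.29, 5582, 2.420, -2.570)
        verdict = assess_complementarity(res, reference=ref)
        assert verdict.delta_a == pytest.approx(2.781, abs=1e-9)
        assert verdict.delta_b == pytest.approx(0.817, abs=1e-9)

    def test_summary_row_schema(self):
        res = ComplementarityResult(6.26, -4.003, 0.840, 0.24, 835, 3.304, -6.776)
        row = res.to_row("calamenene")
        assert list(row) == [
            "ligand", "aCF1", "bCF1", "Rcor2", "Sigma", "Npoints",
            "MIN(SUMRLRE)", "MAX(CF1)",
        ]
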