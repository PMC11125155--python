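"""Equation system: fixed-ellipticity solve, FOM scan, candidates, pipeline."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pdfshell as ps
from pdfshell import errors
from pdfshell.monomer import derive_monomer_props
from pdfshell.solver import (
    AnalysisSettings,
    EquationSystem,
    FomCurve,
    fom_scan,
    select_candidates,
    solve_at_ellipticity,
)
from helpers import ideal_profile, matched_monomer


def _system_from(profile, model, spec, k_const):
    """Equation system anchored at the generator's true geometry."""
    return EquationSystem(
        measured=ps.measure_moments(profile),
        r_sh=model.R_sh,
        d_max=model.d_max,
        monomer=derive_monomer_props(spec),
        k_contrast=k_const,
    )


@pytest.fixture(scope="module")
def headline_system(headline_setup, headline_profile):
    model, n_agg, spec, k_const = headline_setup
    return _system_from(headline_profile, model, spec, k_const)


class TestSolveAtEllipticity:
    def test_true_ellipticity_solves_cleanly(self, headline_setup, headline_system):
        model, n_agg, _, _ = headline_setup
        res = solve_at_ellipticity(headline_system, "prolate", model.epsilon)
        norm = np.sqrt(np.mean([v**2 for v in res.residuals.values()]))
        assert norm < 1e-3
        assert res.n_agg == n_agg
        assert res.drho_core == pytest.approx(model.drho_core, rel=0.02)
        assert res.drho_shell == pytest.approx(model.drho_shell, rel=0.02)

    def test_wrong_ellipticity_fits_worse(self, headline_setup, headline_system):
        model, *_ = headline_setup
        at_truth = solve_at_ellipticity(headline_system, "prolate", model.epsilon)
        off = solve_at_ellipticity(headline_system, "prolate", model.epsilon * 1.3)
        assert off.fom > 10 * at_truth.fom

    def test_infeasible_geometry_raises(self, headline_system):
        squeezed = dataclasses.replace(headline_system, r_sh=100.0)
        with pytest.raises(errors.GeometryError):
            solve_at_ellipticity(squeezed, "prolate", 1.4)

    def test_fixed_nagg_closure(self, headline_setup, headline_profile):
        model, n_agg, spec, k_const = headline_setup
        system = dataclasses.replace(
            _system_from(headline_profile, model, spec, k_const),
            n_agg_initial=n_agg,
        )
        res = solve_at_ellipticity(
            system, "prolate", model.epsilon, closure="fixed_nagg"
        )
        assert res.n_agg == n_agg
        assert res.drho_shell == pytest.approx(model.drho_shell, rel=0.02)


class TestFomScan:
    def test_minimum_at_true_ellipticity(self, headline_setup, headline_system):
        model, *_ = headline_setup
        grid = np.arange(1.0, 2.0, 0.005)
        curve = fom_scan(headline_system, grid, "prolate")
        best = grid[np.nanargmin(curve.fom)]
        assert best == pytest.approx(model.epsilon, abs=0.05)

    def test_fom_nonnegative_and_nan_for_infeasible(self, headline_system):
        curve = fom_scan(headline_system, np.arange(0.4, 2.5, 0.02), "both")
        finite = curve.fom[np.isfinite(curve.fom)]
        assert (finite >= 0).all()

    def test_sphere_data_minimises_near_unity_on_both_branches(self):
        model = ps.SpheroidModel(44.0, 1.0, 16.0, -0.03, 0.04)
        spec, k_const = matched_monomer(model, 120)
        prof = ideal_profile(model, 120, k_const)
        system = _system_from(prof, model, spec, k_const)
        curve = fom_scan(system, np.arange(0.7, 1.4, 0.005), "both")
        pro = (curve.epsilon >= 1.0) & np.isfinite(curve.fom)
        obl = (curve.epsilon < 1.0) & np.isfinite(curve.fom)
        eps_pro = curve.epsilon[pro][np.argmin(curve.fom[pro])]
        eps_obl = curve.epsilon[obl][np.argmin(curve.fom[obl])]
        assert eps_pro == pytest.approx(1.0, abs=0.05)
        assert eps_obl == pytest.approx(1.0, abs=0.05)

    def test_entirely_infeasible_grid_raises(self, headline_system):
        squeezed = dataclasses.replace(headline_system, r_sh=61.0)
        with pytest.raises(errors.NoSolutionError):
            fom_scan(squeezed, np.arange(1.0, 2.0, 0.1), "prolate")


class TestSelectCandidates:
    def test_probabilities_of_branch_pair(self, headline_system):
        curve = fom_scan(headline_system, np.arange(0.5, 2.2, 0.01), "both")
        cands = select_candidates(curve, headline_system)
        assert len(cands) >= 2
        probs = {c.branch: c.probability for c in cands[:2]}
        assert sum(probs.values()) == pytest.approx(1.0)
        assert cands[0].fom <= cands[1].fom
        assert cands[0].probability >= 0.5

    def test_published_probability_split(self):
        # FOM ratio 0.39 : 0.61 between branches gives probabilities
        # 0.61 and 0.39 regardless of the common scale
        for scale in (1.0, 7.3e-4):
            f_p, f_o = 0.39 * scale, 0.61 * scale
            p_p = 1 - f_p / (f_p + f_o)
            p_o = 1 - f_o / (f_p + f_o)
            assert p_p == pytest.approx(0.61)
            assert p_o == pytest.approx(0.39)

    @given(
        f_p=st.floats(1e-6, 10.0),
        f_o=st.floats(1e-6, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_two_branch_probabilities_always_sum_to_one(self, f_p, f_o):
        p_p = 1 - f_p / (f_p + f_o)
        p_o = 1 - f_o / (f_p + f_o)
        assert 0.0 <= p_p <= 1.0 and 0.0 <= p_o <= 1.0
        assert p_p + p_o == pytest.approx(1.0)

    def test_equal_fom_gives_even_split(self, headline_system):
        # symmetric synthetic curve around eps = 1
        eps = np.arange(0.8, 1.2, 0.01)
        fom = np.abs(eps - 1.0) + 0.05
        fom[np.argmin(np.abs(eps - 0.9))] = 0.01
        fom[np.argmin(np.abs(eps - 1.1))] = 0.01
        curve = FomCurve(
            epsilon=eps, fom=fom,
            branch=np.where(eps < 1, "oblate", "prolate").astype(object),
            r_sh=headline_system.r_sh,
        )
        cands = select_candidates(curve, headline_system)
        # both branch minima solve to nearly identical FOM -> ~50/50 split
        assert cands[0].probability == pytest.approx(0.5, abs=0.1)


class TestCharacterize:
    def test_headline_end_to_end(self, headline_setup):
        model, n_agg, spec, k_const = headline_setup
        prof = ideal_profile(model, n_agg, k_const)
        report = ps.characterize(prof, spec)
        best = report.best
        assert best.branch == "prolate"
        assert best.epsilon == pytest.approx(model.epsilon, abs=0.05)
        assert best.n_agg == pytest.approx(n_agg, abs=0.05 * n_agg)
        assert best.drho_core == pytest.approx(model.drho_core, rel=0.10)
        assert best.drho_shell == pytest.approx(model.drho_shell, rel=0.10)

    def test_best_is_minimum_fom_candidate(self, headline_setup):
        model, n_agg, spec, k_const = headline_setup
        prof = ideal_profile(model, n_agg, k_const)
        report = ps.characterize(prof, spec)
        assert report.best.fom == min(c.fom for c in report.candidates)

    def test_relative_scale_downgrades_to_ratio(self, headline_setup):
        model, n_agg, spec, k_const = headline_setup
        prof = dataclasses.replace(
            ideal_profile(model, n_agg, k_const), scale="relative"
        )
        report = ps.characterize(prof, spec)
        assert report.best.n_agg is None
        assert report.best.drho_core is None
        assert report.best.contrast_ratio == pytest.approx(
            model.drho_core / model.drho_shell, rel=0.15
        )
        assert report.provenance["limitation"] is not None

    def test_absolute_closure_on_relative_profile_raises(self, headline_setup):
        model, n_agg, spec, k_const = headline_setup
        prof = dataclasses.replace(
            ideal_profile(model, n_agg, k_const), scale="relative"
        )
        with pytest.raises(errors.ScaleError):
            ps.characterize(
                prof, spec, AnalysisSettings(closure="electron_balance")
            )

    def test_report_serialises_to_json(self, headline_setup):
        import json

        model, n_agg, spec, k_const = headline_setup
        prof = ideal_profile(model, n_agg, k_const)
        report = ps.characterize(prof, spec)
        data = json.loads(report.to_json())
        assert data["best"]["branch"] == "prolate"
        assert len(data["fom_curve"]["epsilon"]) > 100
        assert data["provenance"]["closure"] == "electron_balance"

    def test_scale_factor_leaves_shape_quantities_invariant(self, headline_setup):
        model, n_agg, spec, k_const = headline_setup
        prof = ideal_profile(model, n_agg, k_const)
        rel_a = dataclasses.replace(prof, scale="relative")
        rel_b = dataclasses.replace(prof.rescaled(137.0), scale="relative")
        rep_a = ps.characterize(rel_a, spec)
        rep_b = ps.characterize(rel_b, spec)
        assert rep_b.best.epsilon == pytest.approx(rep_a.best.epsilon, abs=1e-6)
        assert rep_b.best.contrast_ratio == pytest.approx(
            rep_a.best.contrast_ratio, rel=1e-6
        )


class TestRecoveryProperties:
    """Statistical recovery properties over random synthetic micelles."""

    def test_recovery_over_random_models_with_known_geometry(self):
        """Given the true sizes, the ellipticity scan pins epsilon to 0.05,
        the contrasts to 10 % and N_agg to 5 % on both branches."""
        rng = np.random.default_rng(17)
        checked = 0
        for i in range(20):
            branch = "prolate" if i < 10 else "oblate"
            eps = rng.uniform(1.1, 1.8) if branch == "prolate" else rng.uniform(0.55, 0.9)
            r_sh = rng.uniform(8, 20)
            d_max = rng.uniform(80, 140)
            drho_shell = rng.uniform(0.03, 0.05)
            drho_core = -rng.uniform(0.02, 0.04)
            n_agg = int(rng.uniform(60, 160))
            core = d_max / 2 - r_sh
            if core <= 5:
                continue
            model = ps.SpheroidModel(
                core / eps if eps >= 1 else core, eps, r_sh, drho_core, drho_shell
            )
            spec, k_const = matched_monomer(model, n_agg)
            prof = ps.synthesize_pdf(
                model, n_agg, k_const, grid_step=0.25, n_pairs=2**23, seed=1000 + i
            )
            system = _system_from(prof, model, spec, k_const)
            curve = fom_scan(system, np.arange(0.45, 2.2, 0.005), "both")
            best = select_candidates(curve, system)[0]
            assert best.epsilon == pytest.approx(eps, abs=0.05)
            assert best.n_agg == pytest.approx(n_agg, abs=0.05 * n_agg)
            assert best.drho_core == pytest.approx(drho_core, rel=0.10)
            assert best.drho_shell == pytest.approx(drho_shell, rel=0.10)
            checked += 1
        assert checked >= 15

    def test_degrades_gracefully_with_noise_and_smearing(self):
        """With 1 % additive noise and a 3 A diffuse-interface smearing the
        full pipeline still localises epsilon to 0.1 and identifies the true
        branch with majority probability in at least 8 of 10 trials."""
        rng = np.random.default_rng(23)
        eps_ok = branch_ok = 0
        n_trials = 10
        for i in range(n_trials):
            branch = "prolate" if i < 5 else "oblate"
            eps = rng.uniform(1.2, 1.6) if branch == "prolate" else rng.uniform(0.65, 0.85)
            r_sh = rng.uniform(13, 18)
            d_max = rng.uniform(105, 135)
            drho_shell = rng.uniform(0.03, 0.05)
            drho_core = -rng.uniform(0.02, 0.04)
            n_agg = int(rng.uniform(80, 160))
            core = d_max / 2 - r_sh
            model = ps.SpheroidModel(
                core / eps if eps >= 1 else core, eps, r_sh, drho_core, drho_shell
            )
            spec, k_const = matched_monomer(model, n_agg)
            prof = ps.synthesize_pdf(
                model, n_agg, k_const, grid_step=0.25, n_pairs=2**23,
                sigma_interface=3.0, noise_fraction=0.01, seed=2000 + i,
            )
            report = ps.characterize(prof, spec)
            p_true = max(
                (c.probability for c in report.candidates if c.branch == branch),
                default=0.0,
            )
            eps_ok += abs(report.best.epsilon - eps) <= 0.1
            branch_ok += p_true > 0.5
        assert eps_ok >= 8
        assert branch_ok >= 8
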