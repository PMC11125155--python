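"""Analytical stage: solve the overdetermined moment system and scan shape.

At fixed geometry (R_sh, D_max, branch, epsilon) the model moments depend on
the contrasts only through the ratio drho_core / drho_shell (homogeneity),
so the n = 2 moment equation reduces to a quadratic in
eta = drho_core / drho_shell - 1.  The remaining moment equations
(n = 1, 4, 6) are left as relative residuals whose weighted RMS is the
Figure of Merit (FOM).  Scanning the FOM over an ellipticity grid on both
the prolate and the oblate branch yields candidate solutions; the relative
probability of the two branch minima is

    P[eps_P,O] = 1 - FOM[eps_P,O] / (FOM[eps_P] + FOM[eps_O]).

The absolute scale (N_agg and the individual contrasts) comes from the
forward intensity I(0) = K S^2 / N_agg closed with the electron balance
N_agg (N_e - V_mon rho_s) = S, where S is the total excess electron count
of one micelle.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Any

import numpy as np

from . import __version__ as _version
from .errors import (
    DegenerateContrastError,
    GeometryError,
    NoSolutionError,
    ScaleError,
)
from .graphical import (
    GeometryEstimate,
    derive_geometry,
    estimate_dmax,
    estimate_shell_size,
    locate_extrema,
    smooth_and_differentiate,
)
from .moments import MomentSet, measure_moments
from .monomer import (
    DerivedMonomerProps,
    MonomerSpec,
    derive_monomer_props,
    initial_nagg_estimate,
    nagg_from_forward_scattering,
)
from .profile_io import PDFProfile
from .spheroid import pair_coefficients

RESIDUAL_ORDERS = (1, 4, 6)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisSettings:
    """Tunable knobs of the pipeline (defaults match the documented method)."""

    eps_min: float = 0.4
    eps_max: float = 2.5
    eps_step: float = 0.005
    mode: str = "auto"  # shell-size rule: auto | minima_pair | max_to_left_min
    ideal_spacing: bool = False
    smoothing_window: float | None = None  # A; None -> 5% of D_max
    poly_order: int = 3
    dmax_threshold: float = 0.005
    dmax_tail_extrapolate: bool = True
    closure: str = "auto"  # electron_balance | fixed_nagg | ratio_only | auto
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # n = 1, 4, 6
    refine_shell: bool = True
    shell_window: tuple[float, float] = (-12.0, 2.0)  # A around graphical R_sh
    shell_step: float = 0.25
    refine_dmax: bool = False
    dmax_window: float = 3.0  # A around the estimated D_max
    dmax_step: float = 0.25
    refine_top_k: int = 600
    quad_coarse: int = 32
    quad_fine: int = 48
    asymmetry_threshold: float = 0.25


@dataclass(frozen=True)
class EquationSystem:
    """Measured side + geometry + monomer anchoring of the equation system."""

    measured: MomentSet
    r_sh: float
    d_max: float
    r_sh_err: float = 0.5
    d_max_err: float = 0.5
    monomer: DerivedMonomerProps | None = None
    k_contrast: float | None = None
    n_agg_initial: int | None = None
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def geometry_prolate(self) -> GeometryEstimate:
        return derive_geometry(
            self.r_sh, self.d_max, "prolate",
            r_sh_err=self.r_sh_err, d_max_err=self.d_max_err,
        )

    def geometry_oblate(self, epsilon: float) -> GeometryEstimate:
        return derive_geometry(
            self.r_sh, self.d_max, "oblate", epsilon=epsilon,
            r_sh_err=self.r_sh_err, d_max_err=self.d_max_err,
        )


@dataclass(frozen=True)
class SolveResult:
    """Output of the fixed-ellipticity solve."""

    branch: str
    epsilon: float
    eta: float  # drho_core/drho_shell - 1
    residuals: dict[int, float]
    fom: float
    n_agg: int | None
    n_agg_exact: float | None
    drho_core: float | None
    drho_shell: float | None
    s_electrons: float | None  # total excess electrons of one micelle


@dataclass(frozen=True)
class SolutionCandidate:
    branch: str
    epsilon: float
    epsilon_err: float
    fom: float
    probability: float
    n_agg: int | None
    n_agg_err: float
    drho_core: float | None
    drho_core_err: float | None
    drho_shell: float | None
    drho_shell_err: float | None
    r_sh: float
    contrast_ratio: float


@dataclass(frozen=True)
class FomCurve:
    epsilon: np.ndarray
    fom: np.ndarray  # NaN where infeasible
    branch: np.ndarray  # array of "prolate"/"oblate"
    r_sh: float

    def feasible(self) -> np.ndarray:
        return np.isfinite(self.fom)


@dataclass(frozen=True)
class AnalysisReport:
    geometry: GeometryEstimate
    moments: MomentSet
    candidates: tuple[SolutionCandidate, ...]
    best: SolutionCandidate
    fom_curve: FomCurve
    n_agg_initial: int | None
    provenance: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        d = {
            "geometry": asdict(self.geometry),
            "moments": asdict(self.moments),
            "candidates": [asdict(c) for c in self.candidates],
            "best": asdict(self.best),
            "n_agg_initial": self.n_agg_initial,
            "fom_curve": {
                "epsilon": self.fom_curve.epsilon.tolist(),
                "fom": [None if not np.isfinite(v) else v for v in self.fom_curve.fom],
                "branch": self.fom_curve.branch.tolist(),
                "r_sh": self.fom_curve.r_sh,
            },
            "provenance": self.provenance,
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


# ---------------------------------------------------------------------------
# vectorised core
# ---------------------------------------------------------------------------

def _fom_arrays(
    measured: MomentSet,
    weights: tuple[float, ...],
    req: np.ndarray,
    epsilon: np.ndarray,
    r_sh: np.ndarray,
    orders: tuple[int, ...],
    quad: int,
) -> tuple[np.ndarray, np.ndarray]:
    """FOM and contrast-ratio eta over arbitrary geometry arrays.

    The n = 2 equation fixes eta (quadratic; the root with the smaller
    residual norm over ``orders`` wins); the weighted RMS of the relative
    residuals of ``orders`` is the FOM.  Infeasible points are NaN.
    """
    coeffs = {n: pair_coefficients(req, epsilon, r_sh, n, quad) for n in (2, *orders)}
    a_mm, a_me, a_ee, v_m, v_e = coeffs[2]
    m2p = 2.0 * measured.m2
    qa = a_ee - m2p * v_e**2
    qb = 2.0 * (a_me - m2p * v_m * v_e)
    qc = a_mm - m2p * v_m**2
    disc = qb * qb - 4 * qa * qc
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        lin = np.abs(qa) < 1e-300
        roots = np.stack(
            [
                np.where(lin, -qc / np.where(qb == 0, np.nan, qb), (-qb + sq) / (2 * qa)),
                np.where(lin, np.nan, (-qb - sq) / (2 * qa)),
            ]
        )
        s_eff = v_m + roots * v_e
        bad = ~np.isfinite(roots) | (np.abs(s_eff) < 1e-9 * v_m)
        w = np.asarray(weights, float)
        res_sq = np.zeros_like(roots)
        for wi, n in zip(w, orders):
            a_mm_n, a_me_n, a_ee_n, _, _ = coeffs[n]
            model_n = (a_mm_n + 2 * roots * a_me_n + roots**2 * a_ee_n) / s_eff**2
            rel = model_n / (2 ** (n - 1) * measured.moment(n)) - 1.0
            res_sq += wi * rel**2
        fom_roots = np.sqrt(res_sq / w.sum())
        fom_roots[bad] = np.nan
    pick = np.argmin(np.where(np.isnan(fom_roots), np.inf, fom_roots), axis=0)
    fom = np.take_along_axis(fom_roots, pick[None, ...], axis=0)[0]
    eta = np.take_along_axis(roots, pick[None, ...], axis=0)[0]
    fom = np.where(np.isfinite(fom), fom, np.nan)
    return fom, eta


def _branch_req(core: float, epsilon: np.ndarray, branch: str) -> np.ndarray:
    """Equatorial core half-size of the scan geometry for one branch."""
    if branch == "prolate":
        return core / epsilon
    if branch == "oblate":
        return np.full_like(epsilon, core)
    raise GeometryError(f"unknown branch {branch!r}")


def _scan_geometry(
    system: EquationSystem,
    epsilon: np.ndarray,
    branch: str,
    r_sh: float | None = None,
    quad: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """FOM and contrast-ratio arrays over an epsilon grid at fixed R_sh.

    Returns ``(fom, eta)``; infeasible grid points are NaN.
    """
    r_sh = system.r_sh if r_sh is None else r_sh
    epsilon = np.atleast_1d(np.asarray(epsilon, float))
    core = system.d_max / 2.0 - r_sh
    if core <= 0:
        nan = np.full(epsilon.shape, np.nan)
        return nan, nan.copy()
    req = _branch_req(core, epsilon, branch)
    return _fom_arrays(
        system.measured,
        system.weights,
        req,
        epsilon,
        np.full_like(epsilon, r_sh),
        RESIDUAL_ORDERS,
        quad,
    )


def _absolute_scale(
    system: EquationSystem, eta: float, req: float, epsilon: float, r_sh: float
) -> tuple[int | None, float | None, float | None, float | None, float | None]:
    """(n_agg, n_agg_exact, drho_core, drho_shell, S) from I(0) + closure."""
    i0 = system.measured.i0
    mono = system.monomer
    k = system.k_contrast
    if i0 is None or k is None or mono is None:
        return None, None, None, None, None
    a_e, c_e = req, epsilon * req
    a_m, c_m = req + r_sh, epsilon * req + r_sh
    v_e = 4 * math.pi / 3 * a_e * a_e * c_e
    v_m = 4 * math.pi / 3 * a_m * a_m * c_m
    s_eff = v_m + eta * v_e
    excess = mono.excess_electrons
    if excess == 0:
        raise DegenerateContrastError("monomer is contrast-matched to the buffer")
    n_exact = i0 / (k * excess**2)
    s_signed = n_exact * excess
    drho_shell = s_signed / s_eff
    drho_core = (1.0 + eta) * drho_shell
    return int(round(n_exact)), n_exact, drho_core, drho_shell, s_signed


def solve_at_ellipticity(
    system: EquationSystem,
    branch: str,
    epsilon: float,
    r_sh: float | None = None,
    quad: int = 48,
    closure: str = "electron_balance",
) -> SolveResult:
    """Solve the moment system at one fixed ellipticity.

    The contrast ratio comes from the n = 2 equation (quadratic; the root
    with the smaller n = 1, 4, 6 residual norm is kept), the absolute scale
    from I(0) with the requested closure:

    * ``electron_balance`` (default): N_agg = I0 / (K dNe^2) with
      dNe = N_e - V_mon rho_s, then drho from S = N_agg dNe;
    * ``fixed_nagg``: N_agg = the initial estimate, |S| = sqrt(I0 N_agg / K);
    * ``ratio_only``: no absolute quantities (relative-scale profiles).
    """
    r_sh = system.r_sh if r_sh is None else r_sh
    core = system.d_max / 2.0 - r_sh
    if core <= 0:
        raise GeometryError("2 R_sh >= D_max: no room for a core")
    fom, eta = _scan_geometry(system, np.array([epsilon]), branch, r_sh, quad)
    if not np.isfinite(fom[0]):
        raise NoSolutionError(
            f"no admissible contrast-ratio root at epsilon={epsilon:g} ({branch})"
        )
    eta = float(eta[0])
    req = float(_branch_req(core, np.array([epsilon]), branch)[0])
    n_agg = n_exact = drho_c = drho_s = s_el = None
    if closure == "electron_balance":
        n_agg, n_exact, drho_c, drho_s, s_el = _absolute_scale(
            system, eta, req, epsilon, r_sh
        )
    elif closure == "fixed_nagg":
        i0, k = system.measured.i0, system.k_contrast
        if i0 is not None and k is not None and system.n_agg_initial:
            n_agg = int(system.n_agg_initial)
            n_exact = float(n_agg)
            s_abs = math.sqrt(i0 * n_agg / k)
            sign = 1.0
            if system.monomer is not None and system.monomer.excess_electrons < 0:
                sign = -1.0
            a_m, c_m = req + r_sh, epsilon * req + r_sh
            v_m = 4 * math.pi / 3 * a_m * a_m * c_m
            v_e = 4 * math.pi / 3 * req * req * epsilon * req
            drho_s = sign * s_abs / (v_m + eta * v_e)
            drho_c = (1.0 + eta) * drho_s
            s_el = sign * s_abs
    elif closure != "ratio_only":
        raise ValueError(f"unknown closure {closure!r}")

    # per-order residuals for reporting
    residuals = {}
    for n in RESIDUAL_ORDERS:
        a_mm, a_me, a_ee, v_m, v_e = pair_coefficients(req, epsilon, r_sh, n, quad)
        model_n = float(
            np.squeeze(
                (a_mm + 2 * eta * a_me + eta**2 * a_ee) / (v_m + eta * v_e) ** 2
            )
        )
        residuals[n] = model_n / (2 ** (n - 1) * system.measured.moment(n)) - 1.0
    return SolveResult(
        branch=branch,
        epsilon=float(epsilon),
        eta=eta,
        residuals=residuals,
        fom=float(fom[0]),
        n_agg=n_agg,
        n_agg_exact=n_exact,
        drho_core=drho_c,
        drho_shell=drho_s,
        s_electrons=s_el,
    )


def fom_scan(
    system: EquationSystem,
    epsilon_grid: np.ndarray | None = None,
    branch: str = "both",
    r_sh: float | None = None,
    quad: int = 32,
) -> FomCurve:
    """FOM(epsilon) over a grid, one or both branches.

    The oblate branch occupies epsilon < 1 and the prolate branch
    epsilon >= 1; infeasible points are NaN (never zero).
    """
    if epsilon_grid is None:
        epsilon_grid = np.arange(0.4, 2.5 + 1e-9, 0.005)
    epsilon_grid = np.asarray(epsilon_grid, float)
    r_sh_use = system.r_sh if r_sh is None else r_sh
    fom = np.full(epsilon_grid.shape, np.nan)
    labels = np.where(epsilon_grid < 1.0, "oblate", "prolate").astype(object)
    todo = []
    if branch in ("both", "oblate"):
        todo.append(("oblate", epsilon_grid < 1.0))
    if branch in ("both", "prolate"):
        todo.append(("prolate", epsilon_grid >= 1.0))
    if not todo:
        raise ValueError(f"unknown branch {branch!r}")
    for br, mask in todo:
        if mask.any():
            f, _ = _scan_geometry(system, epsilon_grid[mask], br, r_sh_use, quad)
            fom[mask] = f
    if not np.isfinite(fom).any():
        raise NoSolutionError("entire ellipticity grid is infeasible")
    return FomCurve(epsilon=epsilon_grid, fom=fom, branch=labels, r_sh=r_sh_use)


def _local_minima(curve: FomCurve, side: str) -> list[int]:
    """Indices of local minima of the curve restricted to one branch side."""
    mask = (curve.epsilon < 1.0) if side == "oblate" else (curve.epsilon >= 1.0)
    idx = np.where(mask & np.isfinite(curve.fom))[0]
    if len(idx) == 0:
        return []
    out = []
    for j, i in enumerate(idx):
        f = curve.fom[i]
        left = curve.fom[idx[j - 1]] if j > 0 else np.inf
        right = curve.fom[idx[j + 1]] if j < len(idx) - 1 else np.inf
        if f < left and f <= right:
            out.append(int(i))
    if not out:
        out = [int(idx[np.argmin(curve.fom[idx])])]
    return out


def select_candidates(
    fom_curve: FomCurve,
    system: EquationSystem,
    n_candidates: int = 2,
    closure: str = "electron_balance",
    quad: int = 48,
) -> list[SolutionCandidate]:
    """Turn the FOM curve into ranked solution candidates with probabilities.

    The best local minimum of each branch enters the two-branch relative
    probability P = 1 - FOM / (FOM_P + FOM_O); with a single feasible branch
    its candidate has probability 1.  Candidates are sorted by FOM
    (ties broken toward the less eccentric shape, smaller |eps - 1|).
    """
    step = float(np.median(np.diff(fom_curve.epsilon)))
    per_branch: dict[str, SolveResult] = {}
    extras: list[SolveResult] = []
    for side in ("prolate", "oblate"):
        minima = _local_minima(fom_curve, side)
        results = []
        for i in minima:
            eps = float(fom_curve.epsilon[i])
            # parabolic refinement on the grid
            if 0 < i < len(fom_curve.epsilon) - 1 and np.isfinite(
                fom_curve.fom[i - 1]
            ) and np.isfinite(fom_curve.fom[i + 1]):
                # parabola on FOM^2: the FOM itself is V-shaped near a zero
                y0, y1, y2 = fom_curve.fom[i - 1 : i + 2] ** 2
                denom = y0 - 2 * y1 + y2
                if denom > 0:
                    shift = 0.5 * (y0 - y2) / denom * step
                    eps = eps + float(np.clip(shift, -step, step))
            if side == "prolate":
                eps = max(eps, 1.0)
            else:
                eps = min(eps, 1.0 - 1e-9)
            try:
                results.append(
                    solve_at_ellipticity(
                        system, side, eps, fom_curve.r_sh, quad, closure
                    )
                )
            except (NoSolutionError, GeometryError):
                continue
        if results:
            results.sort(key=lambda s: (s.fom, abs(s.epsilon - 1.0)))
            per_branch[side] = results[0]
            extras.extend(results[1:])
    if not per_branch:
        raise NoSolutionError("FOM curve has no usable minima")

    if len(per_branch) == 2:
        total = per_branch["prolate"].fom + per_branch["oblate"].fom
        probs = {
            side: (1.0 - res.fom / total if total > 0 else 0.5)
            for side, res in per_branch.items()
        }
    else:
        probs = {side: 1.0 for side in per_branch}

    def to_candidate(res: SolveResult, prob: float) -> SolutionCandidate:
        drho_c_err = drho_s_err = None
        if res.drho_core is not None:
            rel = max(res.fom, 0.01)
            drho_c_err = abs(res.drho_core) * rel
            drho_s_err = abs(res.drho_shell) * rel
        return SolutionCandidate(
            branch=res.branch,
            epsilon=res.epsilon,
            epsilon_err=max(step, 0.01),
            fom=res.fom,
            probability=prob,
            n_agg=res.n_agg,
            n_agg_err=1.0,
            drho_core=res.drho_core,
            drho_core_err=drho_c_err,
            drho_shell=res.drho_shell,
            drho_shell_err=drho_s_err,
            r_sh=fom_curve.r_sh,
            contrast_ratio=1.0 + res.eta,
        )

    cands = [to_candidate(res, probs[side]) for side, res in per_branch.items()]
    cands.extend(to_candidate(res, 0.0) for res in extras)
    cands.sort(key=lambda c: (c.fom, abs(c.epsilon - 1.0)))
    return cands[: max(n_candidates, 2)]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def build_system(
    profile: PDFProfile,
    monomer_spec: MonomerSpec | None,
    settings: AnalysisSettings = AnalysisSettings(),
) -> tuple[EquationSystem, dict[str, Any]]:
    """Run the graphical + moment stages and assemble the equation system."""
    # noise must be suppressed before the threshold-based D_max search can
    # apply its "stays below" rule, so size estimators see a smoothed copy
    import dataclasses

    from scipy.signal import savgol_filter

    step = float(np.median(np.diff(profile.r)))
    n_rough = min(11, len(profile.r) // 2 * 2 - 1)
    p_rough = savgol_filter(profile.p, n_rough, min(settings.poly_order, n_rough - 1))
    # point noise from the high-frequency residual; the detection threshold
    # must sit above the noise floor of the smoothed curve or the
    # "stays below" rule never triggers
    sigma_noise = float(np.std(profile.p - p_rough))
    pmax = float(np.abs(p_rough).max())
    thr_rough = max(
        settings.dmax_threshold, 5.0 * sigma_noise / math.sqrt(n_rough) / pmax
    )
    # Savitzky-Golay endpoint artifacts matter only on noisy data; trimming
    # a noise-free profile could eat its whole sub-threshold tail
    noisy = sigma_noise > 1e-4 * pmax
    trim = n_rough // 2 if noisy else 0
    end = -trim if trim else None
    rough_profile = dataclasses.replace(
        profile, r=profile.r[:end], p=p_rough[:end], sigma_p=None
    )
    rough_dmax, _ = estimate_dmax(rough_profile, thr_rough)
    window = (
        settings.smoothing_window
        if settings.smoothing_window is not None
        else 0.05 * rough_dmax
    )
    report = locate_extrema(
        smooth_and_differentiate(profile, window, settings.poly_order)
    )
    r_sh, r_sh_err, mode_used = estimate_shell_size(
        report,
        settings.mode,
        settings.asymmetry_threshold,
        settings.ideal_spacing,
    )
    n_w = int(round(window / step)) // 2 * 2 + 1
    if 5 <= n_w < len(profile.r):
        p_smooth = savgol_filter(profile.p, n_w, settings.poly_order)
    else:
        p_smooth = profile.p
        n_w = 1
    trim = max(n_w // 2, 1) if noisy else 0
    end = -trim if trim else None
    smooth_profile = dataclasses.replace(
        profile, r=profile.r[:end], p=p_smooth[:end], sigma_p=None
    )
    thr = max(
        settings.dmax_threshold,
        5.0 * sigma_noise / math.sqrt(n_w) / max(float(np.abs(p_smooth).max()), 1e-300),
    )
    d_max, d_max_err = estimate_dmax(
        smooth_profile, thr, settings.dmax_tail_extrapolate
    )
    # integrate moments only marginally past the estimated support so that
    # pure-noise tail samples do not enter the r^6-weighted integrals
    pad = max(2.0, 4 * step)
    measured = measure_moments(profile, min(d_max + pad, profile.support))

    mono_props = None
    k = None
    n_ini = None
    estimates = []
    if monomer_spec is not None:
        mono_props = derive_monomer_props(monomer_spec)
        k = mono_props.contrast_constant
        if measured.i0 is not None and monomer_spec.c_mon > 0:
            _, n_fw = nagg_from_forward_scattering(
                measured.i0, monomer_spec.c_mon, mono_props.forward_intensity
            )
            estimates.append(n_fw)
        if mono_props.n_agg_tanford is not None:
            estimates.append(mono_props.n_agg_tanford)
        if estimates:
            n_ini = int(initial_nagg_estimate(estimates)[0])
    system = EquationSystem(
        measured=measured,
        r_sh=r_sh,
        d_max=d_max,
        r_sh_err=r_sh_err,
        d_max_err=d_max_err,
        monomer=mono_props,
        k_contrast=k,
        n_agg_initial=n_ini,
        weights=settings.weights,
    )
    info = {
        "mode_used": mode_used,
        "smoothing_window": window,
        "derivative_extrema": {
            "r_peak": report.r_peak,
            "r_min_left": report.r_min_left,
            "r_min_right": report.r_min_right,
            "extra_minima": list(report.extra_minima),
        },
        "n_agg_estimates": estimates,
    }
    return system, info


def _branch_grids(settings: AnalysisSettings, step: float) -> np.ndarray:
    return np.arange(settings.eps_min, settings.eps_max + 1e-9, step)


def _refine_shape(
    system: EquationSystem, settings: AnalysisSettings
) -> tuple[float, float]:
    """Re-optimise (D_max, R_sh) against the moment system.

    Stage A ranks a full (D_max, R_sh, epsilon) grid by the cheap closed-form
    n = 4, 6 residuals; stage B re-evaluates the best points with the full
    n = 1, 4, 6 FOM.  Returns the refined ``(d_max, r_sh)``.
    """
    lo, hi = settings.shell_window
    shells = np.arange(
        max(1.0, system.r_sh + lo), system.r_sh + hi + 1e-9, settings.shell_step
    )
    if settings.refine_dmax:
        dmaxes = np.arange(
            system.d_max - settings.dmax_window,
            system.d_max + settings.dmax_window + 1e-9,
            settings.dmax_step,
        )
    else:
        dmaxes = np.array([system.d_max])
    eps = _branch_grids(settings, max(settings.eps_step, 0.01))
    dm_g, sh_g, ep_g = np.meshgrid(dmaxes, shells, eps, indexing="ij")
    core = dm_g / 2.0 - sh_g
    req = np.where(ep_g >= 1.0, core / ep_g, core)
    valid = core > 2.0
    req = np.where(valid, req, np.nan)
    w1, w4, w6 = system.weights
    fom46, _ = _fom_arrays(
        system.measured, (w4, w6), req, ep_g, sh_g, (4, 6), settings.quad_coarse
    )
    fom46 = np.where(valid, fom46, np.nan)
    if not np.isfinite(fom46).any():
        return system.d_max, system.r_sh
    # Per (D_max, R_sh) combination the FOM is V-shaped in epsilon (RMS of
    # residuals that are locally linear in epsilon), so the depth of its
    # minimum must be interpolated between grid points before shapes can be
    # compared: evaluate the full n = 1, 4, 6 FOM at the three epsilon grid
    # points around the cheap n = 4, 6 minimum and fit a parabola to FOM^2.
    masked46 = np.where(np.isfinite(fom46), fom46, np.inf)
    i_min = np.argmin(masked46, axis=2)
    i_min = np.clip(i_min, 1, eps.size - 2)
    sel = np.stack([i_min - 1, i_min, i_min + 1], axis=-1)
    dm_c = np.take_along_axis(dm_g, sel, axis=2)
    sh_c = np.take_along_axis(sh_g, sel, axis=2)
    ep_c = np.take_along_axis(ep_g, sel, axis=2)
    req_c = np.take_along_axis(req, sel, axis=2)
    feasible = np.isfinite(np.take_along_axis(np.where(valid, fom46, np.nan), sel, axis=2)).all(axis=2)
    if not feasible.any():
        return system.d_max, system.r_sh
    fom_full, _ = _fom_arrays(
        system.measured,
        system.weights,
        req_c,
        ep_c,
        sh_c,
        RESIDUAL_ORDERS,
        settings.quad_coarse,
    )
    y = fom_full**2  # (..., 3) parabola samples
    y0, y1, y2 = y[..., 0], y[..., 1], y[..., 2]
    curv = y0 - 2 * y1 + y2
    with np.errstate(invalid="ignore", divide="ignore"):
        depth_sq = np.where(
            curv > 0, y1 - (y0 - y2) ** 2 / (8 * curv), np.minimum(np.minimum(y0, y1), y2)
        )
    depth_sq = np.where(feasible & np.isfinite(depth_sq), np.clip(depth_sq, 0, None), np.inf)
    # polish: dense epsilon scan of the best-ranked shapes with the full FOM
    # (the 3-point parabola can misjudge when the n = 1 residual shifts the
    # minimum outside the bracket)
    flat = depth_sq.ravel()
    n_polish = min(40, int(np.isfinite(flat).sum()))
    if n_polish == 0:
        return system.d_max, system.r_sh
    top = np.argpartition(flat, n_polish - 1)[:n_polish]
    best = (np.inf, system.d_max, system.r_sh)
    eps_c = np.take_along_axis(ep_g, i_min[..., None], axis=2)[..., 0].ravel()
    half = 1.5 * max(settings.eps_step, 0.01)
    fine = np.linspace(-half, half, 13)
    for j in top:
        if not np.isfinite(flat[j]):
            continue
        d, s = np.unravel_index(j, depth_sq.shape)
        dm_j, sh_j = float(dmaxes[d]), float(shells[s])
        core_j = dm_j / 2.0 - sh_j
        e_grid = np.clip(eps_c[j] + fine, 0.3, 3.0)
        req_j = np.where(e_grid >= 1.0, core_j / e_grid, core_j)
        fom_j, _ = _fom_arrays(
            system.measured,
            system.weights,
            req_j,
            e_grid,
            np.full_like(e_grid, sh_j),
            RESIDUAL_ORDERS,
            settings.quad_coarse,
        )
        if np.isfinite(fom_j).any():
            f = float(np.nanmin(fom_j))
            if f < best[0]:
                best = (f, dm_j, sh_j)
    return best[1], best[2]


def characterize(
    profile: PDFProfile,
    monomer_spec: MonomerSpec | None = None,
    settings: AnalysisSettings = AnalysisSettings(),
) -> AnalysisReport:
    """Full pipeline: graphical stage, moments, shape scan, candidates.

    Absolute-scale profiles with a monomer description yield N_agg and the
    two contrasts; relative-scale profiles downgrade to (epsilon, contrast
    ratio) with ``closure = "ratio_only"``.
    """
    closure = settings.closure
    if closure == "auto":
        closure = (
            "electron_balance"
            if profile.is_absolute and monomer_spec is not None
            else "ratio_only"
        )
    elif closure in ("electron_balance", "fixed_nagg"):
        if not profile.is_absolute:
            raise ScaleError(
                f"closure {closure!r} needs an absolute-scale profile; "
                "relative-scale input determines only epsilon and the "
                "contrast ratio"
            )
        if monomer_spec is None:
            raise ScaleError(f"closure {closure!r} needs a monomer description")

    system, info = build_system(profile, monomer_spec, settings)

    # optional joint refinement of the shape against the moment system:
    # derivative-spacing shell estimates on sharp-interface profiles
    # overshoot (the spacing rule is calibrated for fluctuation-broadened
    # interfaces) and the D_max reading carries a small bias, so both are
    # re-optimised inside a window anchored at the graphical values.
    best_r_sh = system.r_sh
    best_d_max = system.d_max
    if settings.refine_shell:
        best_d_max, best_r_sh = _refine_shape(system, settings)
        if best_d_max != system.d_max:
            import dataclasses

            system = dataclasses.replace(system, d_max=best_d_max)

    grid = _branch_grids(settings, settings.eps_step)
    curve = fom_scan(system, grid, "both", best_r_sh, settings.quad_coarse)
    candidates = select_candidates(
        curve, system, n_candidates=4, closure=closure, quad=settings.quad_fine
    )
    best = candidates[0]
    geometry = derive_geometry(
        best_r_sh,
        system.d_max,
        best.branch,
        epsilon=best.epsilon,
        r_sh_err=system.r_sh_err,
        d_max_err=system.d_max_err,
        mode=info["mode_used"],
    )
    provenance = {
        "package": f"pdfshell {_version}",
        "profile_source": profile.source,
        "profile_scale": profile.scale,
        "monomer": None if monomer_spec is None else monomer_spec.name,
        "closure": closure,
        "settings": asdict(settings),
        "graphical": info,
        "r_sh_graphical": system.r_sh,
        "r_sh_refined": best_r_sh,
        "limitation": (
            "relative-scale input: only the ellipticity and the contrast "
            "ratio are determined; N_agg and absolute contrasts require an "
            "absolute-scale profile"
            if closure == "ratio_only"
            else None
        ),
    }
    return AnalysisReport(
        geometry=geometry,
        moments=system.measured,
        candidates=tuple(candidates),
        best=best,
        fom_curve=curve,
        n_agg_initial=system.n_agg_initial,
        provenance=provenance,
    )
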