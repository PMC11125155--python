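"""Helper constructors shared across test modules."""
import math

import numpy as np

import pdfshell as ps
from pdfshell.profile_io import PDFProfile
from pdfshell.spheroid import total_excess_electrons

WATER_RHO = 10.0 / 29.9


def sphere_profile(radius: float, n_points: int = 2000, scale: str = "relative",
                   amplitude: float = 1.0) -> PDFProfile:
    """Exact P(r) of a uniform sphere: P = 4 pi r^2 V gamma0(r / 2R)."""
    r = np.linspace(0.0, 2.0 * radius, n_points)
    t = r / (2.0 * radius)
    gamma0 = np.where(t <= 1.0, 1.0 - 1.5 * t + 0.5 * t**3, 0.0)
    vol = 4.0 / 3.0 * math.pi * radius**3
    return PDFProfile(
        r=r, p=amplitude * 4.0 * math.pi * r**2 * vol * gamma0,
        scale=scale, source=f"analytic sphere R={radius}",
    )


def matched_monomer(model: ps.SpheroidModel, n_agg: int):
    """Monomer whose excess electron count closes the electron balance.

    Synthetic stand-in: composition and volume are chosen so that
    N_e - V rho_s equals S / N_agg of the model, making the full absolute
    scale pipeline self-consistent end to end.
    """
    excess = total_excess_electrons(model) / n_agg
    vol = 500.0
    n_e = excess + vol * WATER_RHO
    spec = ps.MonomerSpec(
        composition={"C": n_e / 6.0},
        molar_mass=350.0,
        mass_density=350.0 / (vol * 6.02214076e23) * 1e24,
        c_mon=5.0,
        cmc=0.31,
        name="synthetic-matched",
    )
    return spec, ps.derive_monomer_props(spec).contrast_constant


def ideal_profile(model: ps.SpheroidModel, n_agg: int, k_const: float,
                  step: float = 0.25) -> PDFProfile:
    """Noise-free absolute-scale P(r) from the deterministic evaluator."""
    r = np.arange(step / 2, model.d_max + 1.0, step)
    p = ps.evaluate_pdf(model, r, n_agg, k_const)
    return PDFProfile(r=r, p=p, scale="absolute", source="ideal synthetic")
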