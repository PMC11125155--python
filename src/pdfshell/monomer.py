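"""Surfactant-monomer chemistry for absolute-scale micelle analysis.

Everything the absolute-intensity equations need to know about the monomer is
derived here: the electron count N_e, the molecular volume V_mon, the mean
electron density rho_mon = N_e / V_mon, the concentration-dependent contrast
constant

    K = (c_mon - cmc) * N_A * r_e^2 / MW_mon        [cm^-1 per n_e^2]

(only the monomer excess above the critical micelle concentration scatters as
micelles), the per-monomer forward scattering at unit concentration

    I_mon = (N_A * r_e^2 / MW_mon) * (N_e - V_mon * rho_s)^2 * 1e-3 g/cm^3,

and two independent first guesses of the aggregation number: the measured
I(0) divided by I_mon, and the Tanford packing estimate from the alkyl tail
length.
"""
from __future__ import annotations

import math
import re
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .errors import MonomerSpecError, UnknownElementError

# CODATA values
AVOGADRO = 6.02214076e23  # 1/mol
R_ELECTRON_CM = 2.8179403e-13  # classical electron radius, cm
CM3_TO_A3 = 1.0e24  # Angstrom^3 per cm^3

#: electron density of water, n_e / A^3 (10 electrons in 29.9 A^3 per molecule)
WATER_ELECTRON_DENSITY = 10.0 / 29.9

_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U"
).split()
ATOMIC_NUMBER = {s: z for z, s in enumerate(_SYMBOLS, start=1)}


@dataclass(frozen=True)
class MonomerSpec:
    """Chemical and experimental description of one surfactant monomer."""

    composition: dict[str, float]
    molar_mass: float  # g/mol
    mass_density: float  # g/cm^3
    c_mon: float = 0.0  # mg/mL
    cmc: float = 0.0  # mg/mL
    tail_carbons: int | None = None
    buffer_electron_density: float = WATER_ELECTRON_DENSITY  # n_e/A^3
    name: str = ""

    def __post_init__(self) -> None:
        if self.molar_mass <= 0 or self.mass_density <= 0:
            raise MonomerSpecError("molar_mass and mass_density must be positive")
        if self.cmc < 0 or (self.c_mon and self.cmc >= self.c_mon):
            raise MonomerSpecError("need 0 <= cmc < c_mon")


@dataclass(frozen=True)
class DerivedMonomerProps:
    """Quantities computed from a MonomerSpec (Table-1 style)."""

    n_electrons: float  # N_e per molecule
    volume: float  # A^3
    electron_density: float  # n_e/A^3
    excess_electrons: float  # N_e - V * rho_s
    contrast_constant: float | None  # K, cm^-1 n_e^-2 (None without c_mon)
    forward_intensity: float  # I_mon, cm^-1 per mg/mL
    n_agg_tanford: int | None  # Tanford packing estimate


def parse_composition(formula: str) -> dict[str, float]:
    """Parse a chemical formula string into an element -> count map.

    Supports parenthesised groups and fractional multipliers, e.g. averaged
    PEG repeat units: ``"C33O5H54(CH2CH2O)22.3"``.
    """
    pos = 0

    def parse_group(s: str, i: int) -> tuple[dict[str, float], int]:
        counts: dict[str, float] = {}
        while i < len(s):
            ch = s[i]
            if ch == "(":
                sub, i = parse_group(s, i + 1)
                m = re.match(r"\d+\.?\d*", s[i:])
                mult = float(m.group()) if m else 1.0
                i += m.end() if m else 0
                for el, n in sub.items():
                    counts[el] = counts.get(el, 0.0) + n * mult
            elif ch == ")":
                return counts, i + 1
            elif ch.isalpha():
                m = re.match(r"([A-Z][a-z]?)(\d+\.?\d*)?", s[i:])
                if m is None:
                    raise UnknownElementError(f"cannot parse formula at {s[i:]!r}")
                el = m.group(1)
                if el not in ATOMIC_NUMBER:
                    raise UnknownElementError(f"unknown element symbol {el!r}")
                n = float(m.group(2)) if m.group(2) else 1.0
                counts[el] = counts.get(el, 0.0) + n
                i += m.end()
            elif ch in " \t":
                i += 1
            else:
                raise UnknownElementError(f"unexpected character {ch!r} in formula")
        return counts, i

    counts, pos = parse_group(formula, 0)
    return counts


def electron_count(composition: dict[str, float] | str) -> float:
    """Total electrons per molecule: sum of count * Z over the composition.

    Fractional counts (averaged repeat units) yield fractional totals; round
    for display with ``round()``.
    """
    if isinstance(composition, str):
        composition = parse_composition(composition)
    total = 0.0
    for el, n in composition.items():
        if el not in ATOMIC_NUMBER:
            raise UnknownElementError(f"unknown element symbol {el!r}")
        if n < 0:
            raise MonomerSpecError(f"negative count for {el}")
        total += n * ATOMIC_NUMBER[el]
    return total


def monomer_volume(molar_mass: float, mass_density: float) -> float:
    """Molecular volume in A^3 from molar mass (g/mol) and density (g/cm^3)."""
    if molar_mass <= 0 or mass_density <= 0:
        raise MonomerSpecError("molar_mass and mass_density must be positive")
    return molar_mass / (mass_density * AVOGADRO) * CM3_TO_A3


def contrast_constant(c_mon: float, cmc: float, molar_mass: float) -> float:
    """K = (c_mon - cmc) N_A r_e^2 / MW, in cm^-1 per squared electron.

    Concentrations in mg/mL; only the monomer excess above the CMC
    participates in micelle scattering.
    """
    if molar_mass <= 0:
        raise MonomerSpecError("molar_mass must be positive")
    if cmc < 0 or c_mon <= cmc:
        raise MonomerSpecError("need c_mon > cmc >= 0")
    dc = (c_mon - cmc) * 1.0e-3  # mg/mL -> g/cm^3
    return dc * AVOGADRO * R_ELECTRON_CM**2 / molar_mass


def monomer_forward_intensity(
    n_electrons: float,
    volume: float,
    buffer_electron_density: float = WATER_ELECTRON_DENSITY,
    molar_mass: float = 1.0,
) -> tuple[float, float]:
    """Forward scattering of dispersed monomers at 1 mg/mL, in cm^-1.

    Returns ``(i_mon, excess_electrons)`` where
    ``excess_electrons = N_e - V * rho_s`` is the contrast the monomer carries
    against the buffer.
    """
    if n_electrons <= 0 or volume <= 0 or molar_mass <= 0:
        raise MonomerSpecError("n_electrons, volume, molar_mass must be positive")
    if buffer_electron_density <= 0:
        raise MonomerSpecError("buffer_electron_density must be positive")
    excess = n_electrons - volume * buffer_electron_density
    i_mon = AVOGADRO * R_ELECTRON_CM**2 / molar_mass * excess**2 * 1.0e-3
    return i_mon, excess


def nagg_from_forward_scattering(
    i0: float, c_mon: float, i_mon: float
) -> tuple[float, int]:
    """Aggregation number from absolute forward intensity.

    ``(i0 / c_mon) / i_mon`` with i0 in cm^-1, c_mon in mg/mL and i_mon in
    cm^-1 per mg/mL.  Returns the exact ratio and its nearest integer.
    """
    if i0 <= 0 or c_mon <= 0 or i_mon <= 0:
        raise MonomerSpecError("i0, c_mon and i_mon must all be positive")
    exact = (i0 / c_mon) / i_mon
    return exact, int(round(exact))


def tanford_initial_nagg(tail_carbons: int) -> tuple[float, int]:
    """Tanford packing estimate of the aggregation number.

    A spherical hydrophobic core of radius equal to the fully extended chain
    length l_max = 1.5 + 1.265 n_c (A) is filled with chains of volume
    v_chain = 27.4 + 26.9 n_c (A^3):

        N = (4 pi / 3) l_max^3 / v_chain.

    Returns the exact value and its integer part.
    """
    if tail_carbons < 1:
        raise MonomerSpecError("tail_carbons must be >= 1")
    l_max = 1.5 + 1.265 * tail_carbons
    v_chain = 27.4 + 26.9 * tail_carbons
    exact = 4.0 * math.pi / 3.0 * l_max**3 / v_chain
    return exact, int(exact)


def initial_nagg_estimate(estimates: list[int]) -> tuple[float, float]:
    """Combine independent N_agg first guesses into mean +/- half-spread.

    The mean is rounded half-to-even, the half spread (max-min)/2 half-up;
    this matches how such combined estimates are conventionally printed
    (e.g. 46 and 55 -> 50 +/- 5).
    """
    if not estimates:
        raise MonomerSpecError("need at least one estimate")
    mean = sum(estimates) / len(estimates)
    half_spread = (max(estimates) - min(estimates)) / 2.0
    # round-half-even for the centre, round-half-up for the spread
    return float(round(mean)), float(math.floor(half_spread + 0.5))


def derive_monomer_props(spec: MonomerSpec) -> DerivedMonomerProps:
    """Compute all Table-1 style derived quantities for a monomer."""
    n_e = electron_count(spec.composition)
    vol = monomer_volume(spec.molar_mass, spec.mass_density)
    i_mon, excess = monomer_forward_intensity(
        n_e, vol, spec.buffer_electron_density, spec.molar_mass
    )
    k = None
    if spec.c_mon > 0:
        k = contrast_constant(spec.c_mon, spec.cmc, spec.molar_mass)
    tanford = None
    if spec.tail_carbons is not None:
        tanford = tanford_initial_nagg(spec.tail_carbons)[1]
    return DerivedMonomerProps(
        n_electrons=n_e,
        volume=vol,
        electron_density=n_e / vol,
        excess_electrons=excess,
        contrast_constant=k,
        forward_intensity=i_mon,
        n_agg_tanford=tanford,
    )


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

def load_monomer_spec(path: str | Path) -> MonomerSpec:
    """Load a MonomerSpec from a TOML or YAML key-value file.

    Recognised keys: ``composition`` (formula string), ``molar_mass``,
    ``mass_density``, ``c_mon``, ``cmc``, ``tail_carbons``,
    ``buffer_electron_density``, ``name``.
    """
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        data = yaml.safe_load(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    if not isinstance(data, dict):
        raise MonomerSpecError(f"{path} does not contain a key-value table")
    comp = data.get("composition")
    if isinstance(comp, str):
        comp = parse_composition(comp)
    elif not isinstance(comp, dict):
        raise MonomerSpecError("composition must be a formula string or a map")
    kwargs = dict(
        composition=comp,
        molar_mass=float(data["molar_mass"]),
        mass_density=float(data["mass_density"]),
        c_mon=float(data.get("c_mon", 0.0)),
        cmc=float(data.get("cmc", 0.0)),
        name=str(data.get("name", path.stem)),
    )
    if "tail_carbons" in data:
        kwargs["tail_carbons"] = int(data["tail_carbons"])
    if "buffer_electron_density" in data:
        kwargs["buffer_electron_density"] = float(data["buffer_electron_density"])
    return MonomerSpec(**kwargs)
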