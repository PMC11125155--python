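# pdfshell

Core–shell spheroid micelle structure straight from a SAXS pair-distance
distribution function P(r) — no iterative curve fitting.

Surfactant micelles (polysorbates, phosphocholines, tocopherol-PEG
conjugates, SDS, …) are routinely characterised by small-angle X-ray
scattering. `pdfshell` implements a graphical-analytical alternative to
form-factor fitting for formulators and SAXS beamline users: from a single
P(r) curve it determines

* the shell thickness **R_sh** and the overall size **D_max** from the first
  derivative of P(r) (the spacing between the derivative maximum and its
  flanking minima is 2 R_sh / 4 R_sh for fluctuating hydrophilic shells);
* the ellipticity **ε = R_pol/R_eq**, the aggregation number **N_agg**, and
  the core and shell electron-density contrasts **Δρ_E**, **Δρ_P** by
  matching the measured distance moments

      R_PDF^n = ∫₀^Dmax P(r) rⁿ dr / (2ⁿ⁻¹ ∫₀^Dmax P(r) dr),  n = 1, 2, 4, 6

  against their closed-form counterparts for a two-component spheroid, plus
  the absolute forward intensity I(0) = 4π∫P dr = K S²/N_agg, where S is the
  micelle's total excess electron count and K = (c_mon−cmc)·N_A·r_e²/MW;
* a **figure of merit** FOM(ε) — the RMS misfit of the unused moment
  equations — scanned over both the prolate and the oblate branch, with the
  relative probability P[ε_P,O] = 1 − FOM[ε_P,O]/(FOM[ε_P]+FOM[ε_O])
  quantifying the shape ambiguity.

A seeded synthetic-data module (quasi-Monte-Carlo pair-distance histograms
and a deterministic overlap-volume evaluator for ideal curves) generates
two-component spheroid profiles on absolute scale, so the entire inverse
pipeline is testable end to end without experimental data.

## Worked example

Characterise a synthetic prolate micelle (ε = 1.4, R_sh = 16 Å,
D_max = 120 Å, N_agg = 120, Δρ_E = −0.03, Δρ_P = +0.04 n_e/Å³) from its
noise-free P(r):

```python
import numpy as np
import pdfshell as ps

model = ps.SpheroidModel(R_eq=31.43, epsilon=1.4, R_sh=16.0,
                         drho_core=-0.03, drho_shell=0.04)
r = np.arange(0.125, model.d_max + 1.0, 0.25)
profile = ps.PDFProfile(r=r, p=ps.evaluate_pdf(model, r, 120, 6.41e-7),
                        scale="absolute", source="synthetic example")
spec = ps.MonomerSpec(composition={"C": 41.6}, molar_mass=350.0,
                      mass_density=1.163, c_mon=5.0, cmc=0.31)
report = ps.characterize(profile, spec)
best = report.best
```

which prints (via the fields of `report`):

```
branch       : prolate  (P = 1.00)
ellipticity  : 1.400
N_agg        : 119
drho_core    : -0.0298 e/A^3
drho_shell   : +0.0402 e/A^3
R_sh         : 15.88 A   D_max: 119.96 A
r_g          : 51.97 A   I(0): 0.5205 cm^-1
```

All five structural parameters are recovered (N_agg to better than 1 %; the
example monomer description is rounded); the negative core contrast is
the hydrophobic interior, the positive shell the hydrated head-group region,
and P = 1.00 says the oblate alternative is not competitive here.

The same pipeline is available from the shell:

```bash
pdfshell simulate --preset prolate --seed 3 --out micelle.dat
pdfshell analyze --pdf micelle.dat --monomer ps20.toml --out report.json
pdfshell monomer-props --monomer ps20.toml
pdfshell fom-scan --pdf micelle.dat --out fom.csv
```

`monomer-props` reproduces the classic table values for polysorbate 20
(N_e = 670, V = 1771 Å³, ρ = 0.378 n_e/Å³, K = 1.92×10⁻⁷ cm⁻¹n_e⁻²,
I_mon = 2.35×10⁻⁴ cm⁻¹ per mg/mL, Tanford N_agg = 55 for the C12 tail).

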