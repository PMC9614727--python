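"""Unit conventions and conversion constants.

Internal units are the MD conventions: length nm, time ns, energy kJ/mol,
pressure MPa.  Permeabilities are additionally reported in the cgs-style
units customary for single-channel water transport (cm^5 N^-1 s^-1 for the
hydraulic permeability L_P, cm^3 s^-1 for the osmotic permeability P_f).

Derivations of the less obvious factors:

* ``KJMOL_PER_MPA_NM3``: 1 MPa * 1 nm^3 = 1e6 Pa * 1e-27 m^3 = 1e-21 J per
  molecule = 1e-21 * N_A / 1000 kJ/mol = 0.602214076 kJ/mol.
* ``CM5_PER_N_S_PER_NM3_NS_MPA``: 1 nm^3 ns^-1 MPa^-1
  = 1e-21 cm^3 / (1e-9 s * 100 N cm^-2) = 1e-14 cm^5 N^-1 s^-1.
* ``M3_PER_PA_S_PER_CM5_N_S``: 1 cm^5 N^-1 s^-1 = (1e-2 m)^5 N^-1 s^-1
  = 1e-10 m^5 N^-1 s^-1 = 1e-10 m^3 Pa^-1 s^-1.
"""

#: Avogadro constant, mol^-1 (CODATA exact).
N_A = 6.02214076e23

#: Molar gas constant, J mol^-1 K^-1 (CODATA exact).
R_GAS = 8.314462618

#: kJ/mol per (MPa * nm^3): converts P*V per molecule into molar energy.
KJMOL_PER_MPA_NM3 = 1e-21 * N_A / 1e3  # = 0.602214076

#: pN per (kJ mol^-1 nm^-1): per-molecule force unit conversion.
PN_PER_KJMOL_NM = 1e3 / N_A / 1e-9 * 1e12  # = 1.66054e0

#: cm^5 N^-1 s^-1 per (nm^3 ns^-1 MPa^-1): hydraulic permeability per channel.
CM5_PER_N_S_PER_NM3_NS_MPA = 1e-14

#: m^3 Pa^-1 s^-1 per (cm^5 N^-1 s^-1).
M3_PER_PA_S_PER_CM5_N_S = 1e-10

#: cm s^-1 per (nm ns^-1): linear velocity / per-area volume flux.
CM_S_PER_NM_NS = 100.0

#: Average volume of one bulk water molecule at 300 K, 1 bar, nm^3.
V_WATER_NM3 = 0.0301

#: Molar volume of water, cm^3 mol^-1 (default for L_P <-> P_f conversion).
V_WATER_MOLAR_CM3 = 18.07

#: Angstrom -> nm, ps -> ns (for readers whose native units are Å/ps).
NM_PER_ANGSTROM = 0.1
NS_PER_PS = 1e-3
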