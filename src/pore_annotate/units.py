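"""Physical constants and unit conversions.

Internal unit conventions, used consistently across the package:

* length — ångström (Å)
* energy — kJ/mol
* time — ns
* temperature — K
* charge — elementary charge (e)
* force constants — kJ mol⁻¹ nm⁻² (the convention of MD engines; converted
  explicitly to Å wherever a bias or restraint is evaluated)

Potentials are reported in volts at the output boundary only.
"""

from __future__ import annotations

#: Boltzmann constant times Avogadro's number, kJ mol⁻¹ K⁻¹ (i.e. the molar
#: gas constant R).  kT at 310 K is therefore ≈ 2.577 kJ/mol.
BOLTZMANN_KJ_MOL_K: float = 0.008314462618

#: Elementary charge in coulomb.
ELEMENTARY_CHARGE_C: float = 1.602176634e-19

#: Vacuum permittivity in F/m.
VACUUM_PERMITTIVITY_F_M: float = 8.8541878128e-12

#: Å² per nm² — force constants are quoted per nm² but coordinates are in Å.
A2_PER_NM2: float = 100.0

#: Conversion factor for the 1-D Poisson double integral: a charge density in
#: e/Å³ integrated twice over z in Å, divided by ε₀, yields volts after
#: multiplication by this factor (= e · 10¹⁰ / ε₀ in SI).
POISSON_VOLT_FACTOR: float = ELEMENTARY_CHARGE_C * 1.0e10 / VACUUM_PERMITTIVITY_F_M


def thermal_energy(temperature: float) -> float:
    """kT in kJ/mol at the given temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_KJ_MOL_K * temperature


def bias_energy(z: "float | 'np.ndarray'", center: float, force_constant: float):
    """Harmonic bias ½·k·(z − center)² in kJ/mol.

    ``force_constant`` is in kJ mol⁻¹ nm⁻² and ``z``/``center`` in Å; the
    Å→nm conversion happens here and nowhere else.
    """
    return 0.5 * force_constant * (z - center) ** 2 / A2_PER_NM2
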