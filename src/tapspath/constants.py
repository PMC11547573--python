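"""Physical constants and unit conversions.

Energies are carried internally in kJ/mol; user-facing reports (free-energy
profiles, barrier tables) convert to kcal/mol.
"""

#: Boltzmann constant, kJ/(mol K).
KB = 0.0083144621

#: kJ per kcal.
KJ_PER_KCAL = 4.184

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 310.0


def kt(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol."""
    return KB * temperature


def kj_to_kcal(x):
    return x / KJ_PER_KCAL


def kcal_to_kj(x):
    return x * KJ_PER_KCAL
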