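"""Physical constants and fixed conversion factors (kJ/mol internal unit)."""

#: Molar gas constant, kJ/(mol K) (CODATA 2018).
GAS_CONSTANT = 8.314462618e-3

#: Two-sided 95% normal quantile used for CI <-> SE conversions.
Z_95 = 1.959964

#: Thermochemical calorie: kJ per kcal.
KJ_PER_KCAL = 4.184

#: International (IT) calorie: kJ per kcal.
KJ_PER_KCAL_IT = 4.1868

#: Default temperature for simulated work distributions, K.
SIM_TEMPERATURE = 298.15

#: Default temperature for the enzymatic assay conversion (30 degrees C), K.
ASSAY_TEMPERATURE = 303.15


def beta(temperature: float) -> float:
    """Inverse temperature 1/(R*T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (GAS_CONSTANT * temperature)
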