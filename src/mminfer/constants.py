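"""Physical constants and small numeric helpers shared across the package."""

import numpy as np

#: Boltzmann constant in kJ/(mol K), so that all energies are in kJ/mol.
KB = 0.008314462618

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 300.0

TWO_PI = 2.0 * np.pi


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature


def wrap_angle(x):
    """Wrap angles (scalar or array) to the canonical interval [-pi, pi)."""
    return np.mod(np.asarray(x) + np.pi, TWO_PI) - np.pi
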