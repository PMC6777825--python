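"""Physical constants and empirical thresholds shared across the pipeline.

Temperatures are kelvin internally; °C appears only at I/O boundaries.
Concentrations are μM in binding tables and mM in response tables.
"""

#: Gas constant in kcal·mol⁻¹·K⁻¹.
R_KCAL: float = 1.9872e-3

#: Celsius → kelvin offset.
CELSIUS_OFFSET: float = 273.15

#: Default buffer-only melting temperature (°C), the ligand-free T0 ground truth
#: used by the synthetic plate generator.
DEFAULT_BUFFER_TM_C: float = 53.0

#: Default T0 (K) when fitting dose series with T0 fixed.
DEFAULT_T0_FIT_K: float = 326.2

#: Default T0 (K) for single-point Kd inversion.
DEFAULT_T0_SINGLE_K: float = 326.1

#: Default unfolding enthalpy at T0 (kcal·mol⁻¹) for single-point inversion,
#: the mean of dose-series fits across ligands.
DEFAULT_DH0_KCAL: float = 72.1

#: Fixed maximal receptor response (ΔRFU, AU) for single-point EC50 inversion.
DEFAULT_DRFU_MAX: float = 104.3

# ΔTm window thresholds (K) governing which single-point estimates are adopted.
# Shifts of 6–11 K give estimates in close agreement with orthogonal affinity
# measurements; 2–11 K is acceptable; below 1 K is under the reporting floor.
DELTA_TM_FLOOR_K: float = 1.0
DELTA_TM_ACCEPTABLE_MIN_K: float = 2.0
DELTA_TM_PREFERRED_MIN_K: float = 6.0
DELTA_TM_MAX_K: float = 11.0


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET
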