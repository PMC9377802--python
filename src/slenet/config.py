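"""Flat, unit-checked model configuration.

Every tunable number of the model lives in :class:`ModelConfig`; defaults
are the published parameter set (conductance tables, transporter strengths,
synaptic weights and stimulus amplitudes).  Configurations serialise to a
flat, human-readable YAML mapping ``key: "value unit"`` and load back with
unit validation; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from . import constants as cn
from .biophysics import CONDUCTANCES, CURRENTS
from .gating import IN_SOMA, PY_DEND, PY_SOMA

KIND_NAMES = {PY_SOMA: "py_soma", PY_DEND: "py_dend", IN_SOMA: "in_soma"}
KIND_BY_NAME = {v: k for k, v in KIND_NAMES.items()}


def _default_conductances() -> dict:
    return {k: dict(v) for k, v in CONDUCTANCES.items()}


@dataclass
class ModelConfig:
    """All model parameters; defaults reproduce the published tables."""

    # membrane conductances, S/cm^2, per compartment kind
    conductances: dict = field(default_factory=_default_conductances)
    # Na/K pump strength, mA/cm^2 (printed values; recomputed by calibration)
    imax_pump: dict = field(default_factory=lambda: {
        PY_SOMA: 0.014, PY_DEND: 0.009, IN_SOMA: 0.025})
    km_k: float = cn.KM_K
    km_na: float = cn.KM_NA
    # KCC2 strength, mA/cm^2
    u_kcc2: dict = field(default_factory=lambda: {
        PY_SOMA: cn.U_KCC2, PY_DEND: cn.U_KCC2, IN_SOMA: cn.U_KCC2})
    # calcium pump/buffer (pyramidal compartments only)
    imax_capump: dict = field(default_factory=lambda: {
        PY_SOMA: cn.CA_PUMP_IMAX, PY_DEND: cn.CA_PUMP_IMAX, IN_SOMA: 0.0})
    ca_pump_km: float = cn.CA_PUMP_KM
    ca_buffer_total: float = cn.CA_BUFFER_TOTAL
    ca_kd: float = cn.CA_KD
    # glial buffer
    b_max: float = cn.B_MAX
    k1_glia: float = cn.K1_GLIA
    # synapses
    tau_rise: float = cn.TAU_RISE
    tau_decay: float = cn.TAU_DECAY
    w_ee: float = cn.W_EE
    w_ei: float = cn.W_EI
    w_ie: float = cn.W_IE
    w_input: float = cn.W_INPUT
    e_exc: float = cn.E_EXC
    p_hco3: float = cn.P_HCO3
    poisson_rate_hz: float = 5.0
    # stimulation
    ramp_amp_na: float = 0.35      # nA, initial IN ramp amplitude
    ramp_onset_s: float = 60.0
    ramp_duration_s: float = 40.0
    dc_comp_pa: float = 1.85       # pA, dendritic DC replacing Poisson drive
    probe_period_s: float = 5.0
    # coupling: None derives from R_a and geometry
    gc_total_us: float | None = None
    # shell-to-bath distance: None derives half a somatic shell radius
    bath_distance_um: float | None = None
    # bath composition, mM (Na, K, Cl); defaults to resting extracellular
    bath_na: float = float(cn.C_OUT_REST[cn.NA])
    bath_k: float = float(cn.C_OUT_REST[cn.K])
    bath_cl: float = float(cn.C_OUT_REST[cn.CL])
    # integration
    dt: float = 0.05               # ms
    temperature: float = cn.TEMPERATURE

    def copy(self) -> "ModelConfig":
        new = dataclasses.replace(self)
        new.conductances = {k: dict(v) for k, v in self.conductances.items()}
        new.imax_pump = dict(self.imax_pump)
        new.u_kcc2 = dict(self.u_kcc2)
        new.imax_capump = dict(self.imax_capump)
        return new


# units of the flattened keys
_SCALAR_UNITS = {
    "km_k": "mM", "km_na": "mM", "ca_pump_km": "mM",
    "ca_buffer_total": "mM", "ca_kd": "mM", "b_max": "mM",
    "k1_glia": "1/ms", "tau_rise": "ms", "tau_decay": "ms",
    "w_ee": "uS", "w_ei": "uS", "w_ie": "uS", "w_input": "uS",
    "e_exc": "mV", "p_hco3": "1", "poisson_rate_hz": "Hz",
    "ramp_amp_na": "nA", "ramp_onset_s": "s", "ramp_duration_s": "s",
    "dc_comp_pa": "pA", "probe_period_s": "s", "gc_total_us": "uS",
    "bath_distance_um": "um",
    "bath_na": "mM", "bath_k": "mM", "bath_cl": "mM",
    "dt": "ms", "temperature": "K",
}


def config_units() -> dict[str, str]:
    """Unit string of every flattened configuration key."""
    units = dict(_SCALAR_UNITS)
    for kind, kname in KIND_NAMES.items():
        for cur in CURRENTS:
            units[f"g_{cur}.{kname}"] = "S/cm2"
        units[f"imax_pump.{kname}"] = "mA/cm2"
        units[f"u_kcc2.{kname}"] = "mA/cm2"
        units[f"imax_capump.{kname}"] = "mA/cm2"
    return units


def to_flat(config: ModelConfig) -> dict[str, float | None]:
    flat: dict[str, float | None] = {}
    for kind, kname in KIND_NAMES.items():
        for cur in CURRENTS:
            flat[f"g_{cur}.{kname}"] = config.conductances[kind][cur]
        flat[f"imax_pump.{kname}"] = config.imax_pump[kind]
        flat[f"u_kcc2.{kname}"] = config.u_kcc2[kind]
        flat[f"imax_capump.{kname}"] = config.imax_capump[kind]
    for key in _SCALAR_UNITS:
        flat[key] = getattr(config, key)
    return flat


def from_flat(flat: dict) -> ModelConfig:
    units = config_units()
    config = ModelConfig()
    for key, value in flat.items():
        if key not in units:
            raise KeyError(f"unknown configuration key {key!r}")
        if key.startswith(("g_", "imax_", "u_kcc2")) and "." in key:
            name, kname = key.rsplit(".", 1)
            kind = KIND_BY_NAME[kname]
            if name.startswith("g_"):
                config.conductances[kind][name[2:]] = float(value)
            elif name == "imax_pump":
                config.imax_pump[kind] = float(value)
            elif name == "imax_capump":
                config.imax_capump[kind] = float(value)
            else:
                config.u_kcc2[kind] = float(value)
        else:
            setattr(config, key, None if value is None else float(value))
    return config


def save_config(config: ModelConfig, path) -> None:
    """Write the flat ``key: "value unit"`` YAML representation."""
    units = config_units()
    flat = to_flat(config)
    lines = ["# slenet model configuration (value unit)\n"]
    for key in sorted(flat):
        val = flat[key]
        entry = "derived" if val is None else f"{val!r} {units[key]}"
        lines.append(f"{key}: {entry}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def load_config(path) -> ModelConfig:
    """Load and validate a configuration file; missing keys take defaults.

    Raises on unknown keys and on unit strings that do not match the
    expected unit of the key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a flat key/value mapping")
    units = config_units()
    flat: dict[str, float | None] = {}
    for key, entry in raw.items():
        if key not in units:
            raise KeyError(f"unknown configuration key {key!r}")
        if isinstance(entry, str):
            if entry.strip() == "derived":
                flat[key] = None
                continue
            parts = entry.split()
            value = float(parts[0])
            unit = " ".join(parts[1:]) if len(parts) > 1 else "1"
            if unit != units[key]:
                raise ValueError(
                    f"key {key!r}: unit {unit!r} does not match expected "
                    f"{units[key]!r}")
            flat[key] = value
        else:
            flat[key] = float(entry)
    return from_flat(flat)
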