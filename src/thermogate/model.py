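"""Two-state (bistable) thermodynamic model of temperature-gated channels.

The closed and open conformations of the channel are treated as two
thermodynamic states separated by a conformational free-energy difference

    dG_C(T) = dH - T*dS = dS * (T_half - T),

where the second form absorbs all temperature-independent enthalpy into
``T_half * dS`` and ``T_half`` is the midpoint temperature at which
``dG_C = 0`` and the open probability equals 0.5. The open probability is a
Boltzmann two-state occupancy,

    P_open(T) = 1 / (1 + exp(dG_C(T) / (R*T))).

Entropy (``dS``) and enthalpy (``dH = T_half * dS``) are assumed temperature
independent (dCp = 0). Heat-activated channels (TRPV1-like) have dS > 0
(type-I gating); cold-activated channels (TRPM8-like) have dS < 0 (type-II).
All temperatures are kelvin; Celsius is converted only at I/O boundaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np

from .constants import F, R

__all__ = [
    "GatingParams",
    "Classification",
    "EntropyClass",
    "TemperatureClass",
    "UnreachableProbabilityError",
    "conformational_free_energy",
    "open_probability",
    "open_probability_general",
    "enthalpy",
    "slope_at_midpoint",
    "linear_rise_width",
    "entropy_from_width",
    "delta_enthalpy_for_shift",
    "threshold_temperature",
    "classify",
    "joint_open_probability",
    "load_params",
]

#: Exponent arguments beyond this magnitude are clipped so the Boltzmann
#: factor saturates instead of overflowing a float64.
EXP_CLIP = 700.0

ArrayLike = Union[float, np.ndarray]


class UnreachableProbabilityError(ValueError):
    """The requested open probability lies beyond the curve's saturation level."""


@dataclass(frozen=True)
class GatingParams:
    """Thermodynamic parameters of one two-state channel model.

    Parameters
    ----------
    delta_S : float
        Molar entropy change of opening, J mol^-1 K^-1. Positive for
        heat-activated (type-I) channels, negative for cold-activated
        (type-II) ones. Must be nonzero, otherwise the midpoint
        ``T_half = dH / dS`` is undefined.
    T_half : float
        Midpoint temperature in kelvin, where P_open = 0.5.
    z : float, optional
        Effective gating charge per channel in elementary charges. Only for
        polymodal (temperature + voltage) models; must be given together
        with ``V_half``.
    V_half : float, optional
        Midpoint voltage in volts, paired with ``z``.
    """

    delta_S: float
    T_half: float
    z: float | None = None
    V_half: float | None = None

    def __post_init__(self) -> None:
        if not self.T_half > 0:
            raise ValueError(f"T_half must be a positive absolute temperature, got {self.T_half}")
        if self.delta_S == 0:
            raise ValueError("delta_S must be nonzero (T_half = dH/dS is undefined at dS = 0)")
        if (self.z is None) != (self.V_half is None):
            raise ValueError("z and V_half must be given together or not at all")

    @property
    def delta_S_in_R(self) -> float:
        """Entropy change expressed in units of the gas constant."""
        return self.delta_S / R

    @property
    def has_voltage(self) -> bool:
        return self.z is not None


class EntropyClass(str, Enum):
    """Sign of the opening entropy change: type-I opens on heating (dS > 0),
    type-II opens on cooling (dS < 0)."""

    TYPE_I = "type-I"
    TYPE_II = "type-II"


class TemperatureClass(str, Enum):
    """Position of the midpoint relative to the resting temperature."""

    HYPERTHERMIC = "hyperthermic"
    HYPOTHERMIC = "hypothermic"


@dataclass(frozen=True)
class Classification:
    """Gating-mode labels of a channel model at a given resting temperature."""

    entropy_class: EntropyClass
    temperature_class: TemperatureClass
    T_rest: float


def _check_temperature(T: ArrayLike) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return T


def conformational_free_energy(params: GatingParams, T: ArrayLike) -> ArrayLike:
    """Free-energy difference dG_C = dS * (T_half - T), J mol^-1.

    Negative values favour the open state. Equals dH - T*dS with
    dH = T_half * dS.
    """
    T = _check_temperature(T)
    out = params.delta_S * (params.T_half - T)
    return out if out.ndim else float(out)


def _boltzmann(dG: ArrayLike, T: ArrayLike) -> ArrayLike:
    """Two-state occupancy 1/(1 + exp(dG/(R*T))) with overflow-safe clipping."""
    arg = np.clip(np.asarray(dG, dtype=float) / (R * np.asarray(T, dtype=float)), -EXP_CLIP, EXP_CLIP)
    out = 1.0 / (1.0 + np.exp(arg))
    return out if out.ndim else float(out)


def open_probability(params: GatingParams, T: ArrayLike) -> ArrayLike:
    """Open probability P_open(T) = 1/(1 + exp[(T_half - T) dS / (R T)]).

    Strictly increasing in T for dS > 0, decreasing for dS < 0; equals 0.5
    at T = T_half. Saturates (never overflows) for extreme arguments.
    """
    T = _check_temperature(T)
    return _boltzmann(params.delta_S * (params.T_half - T), T)


def open_probability_general(delta_H: float, delta_S: float, T: ArrayLike) -> ArrayLike:
    """Open probability from the general form dG_C = dH - T*dS.

    Unlike :func:`open_probability` this does not require a midpoint to
    exist (e.g. dS = 0 is allowed). When ``delta_H = T_half * delta_S`` it
    coincides with :func:`open_probability`.
    """
    T = _check_temperature(T)
    return _boltzmann(delta_H - T * delta_S, T)


def enthalpy(params: GatingParams) -> float:
    """Molar opening enthalpy dH = T_half * dS, J mol^-1 (derived, not stored)."""
    return params.T_half * params.delta_S


def slope_at_midpoint(params: GatingParams) -> float:
    """Exact derivative dP_open/dT at T = T_half: dS / (4 R T_half), K^-1.

    Differentiating P_open with argument u(T) = (T_half - T) dS / (R T):
    at T_half, P = 0.5, dP/du = -1/4, and du/dT = -dS/(R T_half) (the
    T_half/T^2 factor from the denominator evaluates to 1/T_half).
    """
    return params.delta_S / (4.0 * R * params.T_half)


def linear_rise_width(params: GatingParams) -> float:
    """Temperature span of the linearized 0-to-1 rise: 4 R T_half / |dS|, K.

    The tangent at the midpoint carries P_open across its full range over
    this span; it is the exact inverse of :func:`entropy_from_width`.
    """
    return 4.0 * R * params.T_half / abs(params.delta_S)


def entropy_from_width(T_half: float, delta_T: float) -> float:
    """|dS| implied by a linear rise of width ``delta_T`` around ``T_half``.

    Returns 4 R T_half / delta_T in J mol^-1 K^-1 (a 10 K rise near 313 K
    gives ~125 R). The result is a magnitude; the caller assigns the sign
    according to the channel type.
    """
    if not T_half > 0:
        raise ValueError("T_half must be positive")
    if not delta_T > 0:
        raise ValueError("delta_T must be positive")
    return 4.0 * R * T_half / delta_T


@dataclass(frozen=True)
class EnthalpyShift:
    """Enthalpy change required to move the midpoint at fixed dS."""

    ddH: float  # J mol^-1
    ddH_in_RT: float  # ddH / (R * original T_half), dimensionless
    new_T_half: float


def delta_enthalpy_for_shift(params: GatingParams, new_T_half: float) -> EnthalpyShift:
    """Enthalpy adjustment ddH = dS * (new_T_half - T_half) at fixed dS.

    Point mutations are assumed to leave dS essentially unchanged, so a
    designed midpoint shift translates directly into an enthalpy change.
    Lowering the midpoint of a heat-activated channel by 10 K costs about
    -4 RT (roughly two hydrogen bonds).
    """
    if not new_T_half > 0:
        raise ValueError("new_T_half must be positive")
    ddH = params.delta_S * (new_T_half - params.T_half)
    return EnthalpyShift(ddH=ddH, ddH_in_RT=ddH / (R * params.T_half), new_T_half=new_T_half)


def threshold_temperature(params: GatingParams, p_thr: float = 0.05) -> float:
    """Temperature at which P_open first reaches ``p_thr``.

    Inverts the open-probability curve in closed form:
    T = T_half / (1 + R*L/dS) with L = ln(1/p_thr - 1). The default
    p_thr = 0.05 operationalizes the activation threshold as the point where
    opening becomes appreciable.

    Raises
    ------
    UnreachableProbabilityError
        If the curve saturates below ``p_thr`` at any positive temperature
        (the high-T limit of P_open is 1/(1 + exp(-dS/R)), not exactly 1).
    """
    if not 0.0 < p_thr < 1.0:
        raise ValueError("p_thr must lie strictly between 0 and 1")
    L = math.log(1.0 / p_thr - 1.0)
    denom = 1.0 + R * L / params.delta_S
    if denom <= 0:
        raise UnreachableProbabilityError(
            f"P_open = {p_thr} is unreachable at positive temperature: the curve "
            f"saturates at 1/(1+exp(-dS/R)) = {_boltzmann(-params.delta_S, 1.0):.6g}"
        )
    return params.T_half / denom


def classify(params: GatingParams, T_rest: float) -> Classification:
    """Classify the gating mode relative to a resting temperature.

    Type-I (dS > 0) channels open on heating, type-II (dS < 0) on cooling;
    the gating is hyperthermic when T_half lies above T_rest and hypothermic
    otherwise. TRPV1 is the archetypal type-I hyperthermic channel, TRPM8
    the type-II hypothermic one.
    """
    if not T_rest > 0:
        raise ValueError("T_rest must be positive (kelvin)")
    entropy_class = EntropyClass.TYPE_I if params.delta_S > 0 else EntropyClass.TYPE_II
    temperature_class = (
        TemperatureClass.HYPERTHERMIC if params.T_half > T_rest else TemperatureClass.HYPOTHERMIC
    )
    return Classification(entropy_class, temperature_class, T_rest)


def joint_open_probability(params: GatingParams, T: ArrayLike, V: ArrayLike) -> ArrayLike:
    """Open probability of a polymodal (temperature + voltage) channel.

    The free energies add: dG_C = dS*(T_half - T) + z*F*(V_half - V), so the
    voltage term vanishes at V = V_half and the curve reduces exactly to
    :func:`open_probability`. ``V`` is in volts.
    """
    if not params.has_voltage:
        raise ValueError("params must carry z and V_half for a polymodal model")
    T = _check_temperature(T)
    dG = params.delta_S * (params.T_half - T) + params.z * F * (params.V_half - np.asarray(V, dtype=float))
    return _boltzmann(dG, T)


def load_params(path: str | Path) -> GatingParams:
    """Read gating parameters from a JSON file.

    Expected keys: ``delta_S_in_R`` (entropy in units of R), ``T_half_K``,
    and optionally ``z`` and ``V_half_mV``. Values are converted to SI and
    validated against the type invariants.
    """
    with open(path) as fh:
        raw = json.load(fh)
    try:
        delta_S = float(raw["delta_S_in_R"]) * R
        T_half = float(raw["T_half_K"])
    except KeyError as exc:
        raise ValueError(f"parameter file {path} is missing required key {exc}") from exc
    z = raw.get("z")
    V_half_mV = raw.get("V_half_mV")
    return GatingParams(
        delta_S=delta_S,
        T_half=T_half,
        z=None if z is None else float(z),
        V_half=None if V_half_mV is None else float(V_half_mV) / 1000.0,
    )
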