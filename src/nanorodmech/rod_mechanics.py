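"""Bending mechanics of a slender rod from its persistence length.

For a thermally fluctuating filament, the persistence length ``lam``
relates to the bending rigidity via ``C_B = lam k_B T``.  Treating the
rod as a solid circular cylinder of diameter ``d``, the second moment of
area is ``I_0 = pi d^4 / 64`` and the elastic (Young's) modulus follows
as ``E = C_B / I_0``.  All functions here work in SI units (m, K, N m^2,
m^4, Pa); :func:`mechanical_summary` accepts a persistence fit in nm and
performs the conversion explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .chain_statistics import PersistenceFit
from .errors import ParameterError

__all__ = [
    "BOLTZMANN",
    "NM",
    "RodGeometry",
    "MechanicalSummary",
    "bending_rigidity",
    "persistence_from_rigidity",
    "moment_of_inertia_circular",
    "elastic_modulus",
    "mechanical_summary",
    "round_sig",
    "format_summary",
]

BOLTZMANN = 1.380649e-23  # J / K (exact, 2019 SI)
NM = 1.0e-9  # m

DEFAULT_TEMPERATURE = 298.0  # K; room temperature / MD thermostat setpoint


@dataclass(frozen=True)
class RodGeometry:
    """Rod cross-section: solid circle of diameter ``diameter_nm`` (nm).

    The solid-circle model is the conservative choice for a filament one
    subunit wide whose effective diameter is taken from the AFM height.
    """

    diameter_nm: float
    cross_section: str = "solid-circle"

    def __post_init__(self) -> None:
        if not self.diameter_nm > 0:
            raise ParameterError("diameter must be positive")
        if self.cross_section != "solid-circle":
            raise ParameterError("only the solid-circle cross-section is implemented")

    @property
    def area_nm2(self) -> float:
        """Cross-sectional area, nm^2."""
        return math.pi * (self.diameter_nm / 2.0) ** 2

    @property
    def area_m2(self) -> float:
        return self.area_nm2 * NM**2


def bending_rigidity(
    lam_m: float, temperature: float, lam_sd_m: float = 0.0
) -> tuple[float, float]:
    """``C_B = lam k_B T`` in N m^2; the SD scales linearly with lam's SD."""
    if not lam_m > 0:
        raise ParameterError("persistence length must be positive")
    if not temperature > 0:
        raise ParameterError("temperature must be positive")
    if lam_sd_m < 0:
        raise ParameterError("persistence-length SD must be non-negative")
    kt = BOLTZMANN * temperature
    return lam_m * kt, lam_sd_m * kt


def persistence_from_rigidity(cb: float, temperature: float) -> float:
    """Invert ``C_B = lam k_B T``; returns lam in metres."""
    if not cb > 0:
        raise ParameterError("bending rigidity must be positive")
    if not temperature > 0:
        raise ParameterError("temperature must be positive")
    return cb / (BOLTZMANN * temperature)


def moment_of_inertia_circular(geometry: RodGeometry) -> float:
    """Second moment of area ``I_0 = pi d^4 / 64`` for a solid circular rod, m^4."""
    d = geometry.diameter_nm * NM
    return math.pi * d**4 / 64.0


def elastic_modulus(
    cb: float,
    i0: float,
    cb_sd: float = 0.0,
    geometry: RodGeometry | None = None,
    diameter_sd_nm: float = 0.0,
) -> tuple[float, float]:
    """``E = C_B / I_0`` in Pa, with SD propagation.

    By default the geometry is treated as exact, so ``SD_E = SD_CB / I_0``.
    If ``diameter_sd_nm`` is given (with ``geometry``), the quartic
    diameter sensitivity ``4 SD_d / d`` is added in quadrature.
    """
    if not cb > 0:
        raise ParameterError("bending rigidity must be positive")
    if not i0 > 0:
        raise ParameterError("moment of inertia must be positive")
    if cb_sd < 0 or diameter_sd_nm < 0:
        raise ParameterError("SDs must be non-negative")
    e = cb / i0
    rel2 = (cb_sd / cb) ** 2
    if diameter_sd_nm:
        if geometry is None:
            raise ParameterError("geometry required to propagate a diameter SD")
        rel2 += (4.0 * diameter_sd_nm / geometry.diameter_nm) ** 2
    return e, e * math.sqrt(rel2)


@dataclass(frozen=True)
class MechanicalSummary:
    """The full lam -> C_B -> I_0 -> E chain with uncertainties (SI units)."""

    lam_m: float
    lam_sd_m: float
    temperature: float
    bending_rigidity: float  # N m^2
    bending_rigidity_sd: float
    moment_of_inertia: float  # m^4
    elastic_modulus: float  # Pa
    elastic_modulus_sd: float
    geometry: RodGeometry

    def __post_init__(self) -> None:
        if not (
            self.lam_m > 0
            and self.temperature > 0
            and self.bending_rigidity > 0
            and self.moment_of_inertia > 0
            and self.elastic_modulus > 0
        ):
            raise ParameterError("all central values must be positive")
        if min(self.lam_sd_m, self.bending_rigidity_sd, self.elastic_modulus_sd) < 0:
            raise ParameterError("SDs must be non-negative")
        resid = abs(
            self.elastic_modulus * self.moment_of_inertia - self.bending_rigidity
        )
        if resid > 1e-9 * self.bending_rigidity:
            raise ParameterError("inconsistent summary: E * I0 != C_B")


def mechanical_summary(
    fit: PersistenceFit,
    geometry: RodGeometry,
    temperature: float = DEFAULT_TEMPERATURE,
) -> MechanicalSummary:
    """Propagate a persistence fit (nm) to rigidity and modulus.

    The persistence length and its SD are converted nm -> m, then
    ``C_B = lam k_B T``, ``I_0 = pi d^4/64``, ``E = C_B / I_0``; the
    geometry is treated as exact in the SD.
    """
    lam_m = fit.lam * NM
    lam_sd_m = fit.lam_sd * NM
    cb, cb_sd = bending_rigidity(lam_m, temperature, lam_sd_m)
    i0 = moment_of_inertia_circular(geometry)
    e, e_sd = elastic_modulus(cb, i0, cb_sd)
    return MechanicalSummary(
        lam_m=lam_m,
        lam_sd_m=lam_sd_m,
        temperature=temperature,
        bending_rigidity=cb,
        bending_rigidity_sd=cb_sd,
        moment_of_inertia=i0,
        elastic_modulus=e,
        elastic_modulus_sd=e_sd,
        geometry=geometry,
    )


def round_sig(x: float, n_sig: int) -> float:
    """Round ``x`` to ``n_sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, n_sig - 1 - exponent)


def format_summary(summary: MechanicalSummary) -> str:
    """Display block: central values at 2 s.f., SDs at 1 s.f.

    Stored values keep full precision; rounding is display-only.
    """
    e_gpa = summary.elastic_modulus / 1e9
    e_sd_gpa = summary.elastic_modulus_sd / 1e9
    lines = [
        "rod mechanics summary",
        f"  persistence length  = {round_sig(summary.lam_m, 2):.3g} m"
        f" +/- {round_sig(summary.lam_sd_m, 1):.1g} m",
        f"  temperature         = {summary.temperature:g} K",
        f"  bending rigidity    = {round_sig(summary.bending_rigidity, 2):.3g} N m^2"
        f" +/- {round_sig(summary.bending_rigidity_sd, 1):.1g} N m^2",
        f"  moment of inertia   = {round_sig(summary.moment_of_inertia, 3):.3g} m^4"
        f"  (solid circle, d = {summary.geometry.diameter_nm:g} nm)",
        f"  elastic modulus     = {round_sig(e_gpa, 2):g} GPa"
        f" +/- {round_sig(e_sd_gpa, 1):g} GPa",
    ]
    return "\n".join(lines)
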