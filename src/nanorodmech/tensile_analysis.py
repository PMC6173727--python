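"""Tensile metrics from force-extension traces of pulled nanorod assemblies.

A pulling trace (displacement nm, force pN) is normalized into an
engineering stress-strain curve using the rod's gauge length ``L0`` and
a solid circular cross-section of diameter ``d``.  From the curve the
module extracts the four standard tensile metrics:

* initial modulus ``E_init`` — through-origin slope of the small-strain
  window;
* tensile strength ``sigma_max`` — the largest stress reached up to
  failure;
* strain to failure ``eps_max`` — strain of the final stick-slip rupture
  (or of the global stress maximum if the curve never ruptures);
* toughness ``U`` — the integral of stress over strain up to failure,
  in GJ m^-3 (numerically GPa times unit strain).

Stick-slip ruptures — the saw-tooth drops left by hydrogen-bonded
interfaces failing one at a time — are detected as local stress maxima
followed by a relative drop of at least ``drop_fraction`` before the
next rise.

Unit conventions: 1 pN / nm^2 = 1e-3 GPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ParameterError
from .rod_mechanics import RodGeometry

__all__ = [
    "ForceExtensionTrace",
    "StressStrainCurve",
    "RuptureEvent",
    "InitialModulus",
    "FailureStrain",
    "TensileProperties",
    "TensileConfig",
    "EnsembleTensileSummary",
    "to_stress_strain",
    "initial_modulus",
    "detect_ruptures",
    "strain_to_failure",
    "toughness",
    "analyze",
    "analyze_ensemble",
]

PN_PER_NM2_TO_GPA = 1.0e-3


@dataclass(frozen=True)
class ForceExtensionTrace:
    """Raw pulling trace: displacement (nm, from 0, non-decreasing) vs force (pN).

    ``meta`` may carry generator ground truth (exact area under the
    force-displacement curve in pN nm, programmed rupture count, ...) or
    file-header provenance.
    """

    displacement: np.ndarray
    force: np.ndarray
    gauge_length: float  # L0, nm
    geometry: RodGeometry
    force_cap: float | None = None  # pN, protocol stop force if any
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if x.ndim != 1 or x.shape != f.shape:
            raise ParameterError("displacement and force must be equal-length 1D arrays")
        if x.size < 2:
            raise ParameterError("a trace needs at least 2 samples")
        if abs(x[0]) > 1e-12:
            raise ParameterError("displacement must start at 0")
        if np.any(np.diff(x) < 0):
            raise ParameterError("displacement must be non-decreasing")
        if not self.gauge_length > 0:
            raise ParameterError("gauge length must be positive")
        object.__setattr__(self, "displacement", x)
        object.__setattr__(self, "force", f)

    @property
    def n_samples(self) -> int:
        return int(self.displacement.size)


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering stress-strain curve with a link back to its trace."""

    strain: np.ndarray  # dimensionless
    stress: np.ndarray  # GPa
    trace: ForceExtensionTrace

    def __post_init__(self) -> None:
        e = np.asarray(self.strain, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        if e.shape != s.shape:
            raise ParameterError("strain and stress must share a shape")
        if np.any(e < 0) or np.any(np.diff(e) < 0):
            raise ParameterError("strain must be non-negative and non-decreasing")
        object.__setattr__(self, "strain", e)
        object.__setattr__(self, "stress", s)


@dataclass(frozen=True)
class RuptureEvent:
    """One stick-slip failure: a stress peak and the drop that follows it."""

    index: int
    strain: float
    peak_stress: float  # GPa
    drop: float  # GPa

    def __post_init__(self) -> None:
        if not self.drop > 0:
            raise ParameterError("a rupture event needs a positive stress drop")


@dataclass(frozen=True)
class InitialModulus:
    """Small-strain modulus with the fit window it used."""

    value: float  # GPa
    window: tuple[float, float]  # strain bounds of the through-origin fit
    n_points: int


@dataclass(frozen=True)
class FailureStrain:
    """Strain to failure, plus the protocol-stop strain when a force cap
    terminated the trace (censoring information, not the metric)."""

    strain: float
    cap_strain: float | None = None


@dataclass(frozen=True)
class TensileProperties:
    """The four tensile metrics plus the rupture-event list for one trace."""

    e_init: InitialModulus  # GPa
    tensile_strength: float  # GPa
    strain_to_failure: FailureStrain  # fraction; report *100 for %
    toughness: float  # GJ m^-3
    events: tuple

    def __post_init__(self) -> None:
        u, smax, emax = self.toughness, self.tensile_strength, self.strain_to_failure.strain
        if u < -1e-12 or u > smax * emax * (1.0 + 1e-9) + 1e-12:
            raise AnalysisError("toughness violates 0 <= U <= sigma_max * eps_max")


@dataclass(frozen=True)
class TensileConfig:
    """Tunable analysis parameters (all recorded in outputs).

    ``drop_fraction``: relative stress drop that qualifies as a rupture.
    ``min_prominence_frac``: absolute drop floor as a fraction of the
    global stress maximum, separating thermal jitter from interface
    failures.  ``modulus_strain_cap``: upper strain bound of the initial
    modulus window (further capped at half the first-rupture strain).
    """

    drop_fraction: float = 0.2
    min_prominence_frac: float = 0.02
    modulus_strain_cap: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.drop_fraction < 1:
            raise ParameterError("drop_fraction must be in (0, 1)")
        if self.min_prominence_frac < 0:
            raise ParameterError("min_prominence_frac must be non-negative")
        if not self.modulus_strain_cap > 0:
            raise ParameterError("modulus_strain_cap must be positive")


def to_stress_strain(trace: ForceExtensionTrace) -> StressStrainCurve:
    """Normalize: strain = displacement / L0; stress = force / (pi (d/2)^2), GPa."""
    area = trace.geometry.area_nm2
    if not area > 0 or not trace.gauge_length > 0:
        raise ParameterError("gauge length and cross-section area must be positive")
    strain = trace.displacement / trace.gauge_length
    stress = trace.force / area * PN_PER_NM2_TO_GPA
    return StressStrainCurve(strain=strain, stress=stress, trace=trace)


def detect_ruptures(
    curve: StressStrainCurve,
    drop_fraction: float = 0.2,
    min_prominence: float | None = None,
) -> list[RuptureEvent]:
    """Find stick-slip ruptures: stress peaks followed by a drop of at
    least ``drop_fraction`` of the peak (and at least ``min_prominence``
    GPa, default 2% of the global maximum) before the next rise.

    On a plateau of equal maxima the first index is reported.  Events
    are returned in strain order; an empty list is a valid result.
    """
    s = curve.stress
    e = curve.strain
    if s.size < 3:
        raise ParameterError("need at least 3 samples to detect ruptures")
    floor = min_prominence if min_prominence is not None else 0.02 * float(s.max())
    events: list[RuptureEvent] = []
    peak_i = 0
    peak_v = s[0]
    trough_v = s[0]
    pending = False  # a qualifying drop below the current peak is in progress
    for i in range(1, s.size):
        v = s[i]
        if v > peak_v and not pending:
            peak_i, peak_v = i, v
            trough_v = v
            continue
        trough_v = min(trough_v, v)
        drop = peak_v - trough_v
        if drop >= max(drop_fraction * peak_v, floor):
            pending = True
        # the decline ends when stress rises again (or the trace ends)
        rises = i + 1 < s.size and s[i + 1] > v
        if pending and (rises or i + 1 == s.size):
            events.append(
                RuptureEvent(
                    index=peak_i,
                    strain=float(e[peak_i]),
                    peak_stress=float(peak_v),
                    drop=float(peak_v - trough_v),
                )
            )
            pending = False
            peak_i, peak_v, trough_v = i, v, v
    return events


def initial_modulus(
    curve: StressStrainCurve,
    events: list[RuptureEvent] | None = None,
    strain_cap: float = 0.05,
) -> InitialModulus:
    """Through-origin least-squares slope over the small-strain window.

    The window runs from 0 to ``min(strain_cap, half the strain at the
    first rupture)`` — a deterministic stand-in for the by-eye "linear
    region"; the bounds used are recorded in the result.
    """
    upper = strain_cap
    if events:
        upper = min(upper, 0.5 * events[0].strain)
    mask = curve.strain <= upper
    eps = curve.strain[mask]
    sig = curve.stress[mask]
    denom = float(np.dot(eps, eps))
    if eps.size < 2 or denom == 0.0:
        raise AnalysisError(
            f"initial-modulus window [0, {upper:g}] holds fewer than 2 usable points"
        )
    slope = float(np.dot(eps, sig)) / denom
    return InitialModulus(value=slope, window=(0.0, float(upper)),
                          n_points=int(eps.size))


def strain_to_failure(
    curve: StressStrainCurve,
    events: list[RuptureEvent],
    force_cap: float | None = None,
) -> FailureStrain:
    """Strain of the last rupture; without ruptures, strain at the global
    stress maximum.  If a force cap terminated the trace, the strain at
    which the cap was reached is reported alongside as censoring info.
    """
    if curve.strain.size == 0:
        raise AnalysisError("empty curve")
    if events:
        eps = events[-1].strain
    else:
        eps = float(curve.strain[int(np.argmax(curve.stress))])
    cap_strain = None
    if force_cap is not None:
        hit = np.nonzero(curve.trace.force >= force_cap - 1e-9)[0]
        if hit.size:
            cap_strain = float(curve.strain[hit[0]])
    return FailureStrain(strain=eps, cap_strain=cap_strain)


def toughness(curve: StressStrainCurve, eps_max: float) -> float:
    """Trapezoidal integral of stress over strain on [0, eps_max], GJ m^-3.

    ``eps_max`` may fall between samples; the endpoint stress is then
    linearly interpolated.
    """
    e, s = curve.strain, curve.stress
    if eps_max < 0 or eps_max > e[-1] * (1.0 + 1e-12):
        raise AnalysisError("eps_max outside the sampled strain range")
    mask = e <= eps_max
    ee = e[mask]
    ss = s[mask]
    if ee.size == 0 or ee[-1] < eps_max:
        s_end = float(np.interp(eps_max, e, s))
        ee = np.append(ee, eps_max)
        ss = np.append(ss, s_end)
    return float(np.trapezoid(ss, ee))


def analyze(
    trace: ForceExtensionTrace, config: TensileConfig = TensileConfig()
) -> TensileProperties:
    """Run the full chain on one trace: normalize, detect ruptures,
    modulus, failure strain, strength, toughness."""
    curve = to_stress_strain(trace)
    events = detect_ruptures(
        curve,
        drop_fraction=config.drop_fraction,
        min_prominence=config.min_prominence_frac * float(curve.stress.max()),
    )
    e_init = initial_modulus(curve, events, strain_cap=config.modulus_strain_cap)
    failure = strain_to_failure(curve, events, force_cap=trace.force_cap)
    upto = curve.strain <= failure.strain
    sigma_max = float(curve.stress[upto].max()) if upto.any() else float(
        curve.stress.max()
    )
    u = toughness(curve, failure.strain)
    return TensileProperties(
        e_init=e_init,
        tensile_strength=sigma_max,
        strain_to_failure=failure,
        toughness=u,
        events=tuple(events),
    )


_METRICS = ("e_init", "tensile_strength", "strain_to_failure", "toughness")


def _metric_values(props: TensileProperties) -> dict[str, float]:
    return {
        "e_init": props.e_init.value,
        "tensile_strength": props.tensile_strength,
        "strain_to_failure": props.strain_to_failure.strain,
        "toughness": props.toughness,
    }


@dataclass(frozen=True)
class EnsembleTensileSummary:
    """Mean +/- SD of the four metrics across replicate traces.

    ``sd`` is None for a single trace (no spread to report).
    """

    per_trace: tuple
    mean: dict
    sd: dict | None


def analyze_ensemble(
    traces: list[ForceExtensionTrace],
    config: TensileConfig = TensileConfig(),
) -> EnsembleTensileSummary:
    """Analyze replicate traces and summarize metric means and SDs."""
    if not traces:
        raise ParameterError("no traces to analyze")
    per = tuple(analyze(t, config) for t in traces)
    vals = {m: np.array([_metric_values(p)[m] for p in per]) for m in _METRICS}
    mean = {m: float(v.mean()) for m, v in vals.items()}
    sd = (
        {m: float(v.std(ddof=1)) for m, v in vals.items()}
        if len(per) > 1
        else None
    )
    return EnsembleTensileSummary(per_trace=per, mean=mean, sd=sd)
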