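"""Synthetic inputs with known ground truth for every downstream stage.

Three generators emulate the three experimental data streams the
analysis consumes:

* planar worm-like-chain contours, standing in for AFM-traced fibril
  backbones (tangent angle performs a Gaussian random walk with variance
  ``step / lam`` per step, giving ``<cos theta(s)> = exp(-s / (2 lam))``
  and the 2D WLC end-to-end law);
* piecewise-linear saw-tooth force-extension traces, standing in for
  MD pulling runs in which hydrogen-bonded ring interfaces fail one at a
  time; the exact area under the trace is stored with it;
* sigmoid titration tables (protonated fraction vs pH) with Gaussian
  noise, standing in for XPS-derived protonation data.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain_statistics import ChainEnsemble, FiberContour
from .errors import ParameterError
from .rod_mechanics import RodGeometry
from .tensile_analysis import ForceExtensionTrace
from .titration import TitrationData, eval_sigmoid

__all__ = [
    "WlcParams",
    "SawtoothSpec",
    "TitrationTruth",
    "generate_wlc_contour",
    "generate_contour_ensemble",
    "generate_sawtooth_trace",
    "generate_titration_data",
]


@dataclass(frozen=True)
class WlcParams:
    """Ground truth for one planar worm-like chain.

    ``step`` is the arc-length increment between sampled points; its
    default of 2 nm matches the rod diameter scale and is finer than a
    typical AFM pixel.
    """

    persistence_length: float  # nm
    contour_length: float  # nm
    step: float = 2.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.persistence_length > 0:
            raise ParameterError("persistence_length must be positive")
        if not self.step > 0:
            raise ParameterError("step must be positive")
        if not self.contour_length >= 2 * self.step:
            raise ParameterError("contour_length must be at least 2 steps")


def generate_wlc_contour(params: WlcParams) -> FiberContour:
    """Sample one equilibrated 2D worm-like chain.

    Returns ``floor(L/step) + 1`` points starting at the origin.  The
    initial heading is uniform on the circle; successive tangent angles
    differ by independent Gaussian increments of variance
    ``step / persistence_length`` (wrapping is immaterial because the
    angle enters only through cos/sin).
    """
    rng = np.random.default_rng(params.seed)
    return FiberContour.from_points(_wlc_points(params, rng))


def generate_contour_ensemble(
    params: WlcParams,
    n_fibers: int,
    length_range: tuple[float, float] = (150.0, 300.0),
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> ChainEnsemble:
    """Generate an ensemble emulating a traced AFM fibril population.

    Fiber contour lengths are uniform on ``length_range`` (default
    150-300 nm, a typical nanorod population); every point is then
    perturbed by isotropic Gaussian tracing noise of SD ``noise_sd``
    (default 0.5 nm, sub-pixel tracing accuracy).  ``params.seed`` is
    used when ``seed`` is None.  The ground-truth persistence length is
    recorded in the metadata.
    """
    if n_fibers < 1:
        raise ParameterError("n_fibers must be at least 1")
    lo, hi = length_range
    if lo > hi:
        raise ParameterError("length_range must satisfy min <= max")
    if lo < 2 * params.step:
        raise ParameterError("minimum length must cover at least 2 steps")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    master = params.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).spawn(n_fibers)
    contours = []
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        length = rng.uniform(lo, hi)
        sub = WlcParams(
            persistence_length=params.persistence_length,
            contour_length=length,
            step=params.step,
            seed=ss,
        )
        # reuse the fiber's stream: heading/angles first, then tracing noise
        contour = _wlc_points(sub, rng)
        if noise_sd > 0:
            contour = contour + rng.normal(0.0, noise_sd, size=contour.shape)
        contours.append(FiberContour.from_points(contour))
    meta = {
        "source": "synthetic 2D worm-like chains",
        "lambda_true_nm": params.persistence_length,
        "step_nm": params.step,
        "noise_sd_nm": noise_sd,
        "length_range_nm": (float(lo), float(hi)),
        "seed": master,
    }
    return ChainEnsemble(contours=contours, metadata=meta)


def _wlc_points(params: WlcParams, rng: np.random.Generator) -> np.ndarray:
    # one heading per segment: theta0 plus (n_steps - 1) angle increments
    n_steps = int(np.floor(params.contour_length / params.step))
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    increments = rng.normal(
        0.0, np.sqrt(params.step / params.persistence_length), size=n_steps - 1
    )
    theta = theta0 + np.concatenate([[0.0], np.cumsum(increments)])
    steps = params.step * np.column_stack([np.cos(theta), np.sin(theta)])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


@dataclass(frozen=True)
class SawtoothSpec:
    """Blueprint of a saw-tooth force-extension trace.

    A rod of ``n_interfaces`` breakable hydrogen-bonded interfaces loads
    linearly at ``rise_stiffness`` until each interface's rupture force,
    drops instantly to ``post_drop_fraction`` of the peak, and finally
    rises to ``force_cap`` — the protocol stop force applied once every
    interface has failed.
    """

    n_interfaces: int
    rise_stiffness: float  # pN / nm
    rupture_forces: tuple  # pN, one per interface
    post_drop_fraction: float = 0.5
    gauge_length: float = 4.0  # nm
    diameter: float = 2.0  # nm
    force_cap: float = 500.0  # pN
    samples_per_rise: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "rupture_forces",
                           tuple(float(f) for f in self.rupture_forces))
        if self.n_interfaces < 1:
            raise ParameterError("n_interfaces must be at least 1")
        if len(self.rupture_forces) != self.n_interfaces:
            raise ParameterError(
                "rupture_forces must list one force per interface"
            )
        if not 0 <= self.post_drop_fraction < 1:
            raise ParameterError("post_drop_fraction must be in [0, 1)")
        if not self.rise_stiffness > 0:
            raise ParameterError("rise_stiffness must be positive")
        if not self.gauge_length > 0 or not self.diameter > 0:
            raise ParameterError("geometry must be positive")
        if self.samples_per_rise < 2:
            raise ParameterError("samples_per_rise must be at least 2")
        prev = 0.0
        for f in self.rupture_forces:
            if not f > prev:
                raise ParameterError(
                    "each rupture force must exceed the preceding post-drop force"
                )
            if not f < self.force_cap:
                raise ParameterError("rupture forces must stay below the force cap")
            prev = self.post_drop_fraction * f
        if not self.force_cap > self.post_drop_fraction * self.rupture_forces[-1]:
            raise ParameterError("force cap must exceed the final post-drop force")


def generate_sawtooth_trace(spec: SawtoothSpec) -> ForceExtensionTrace:
    """Build the piecewise-linear trace described by ``spec``.

    Drops are instantaneous (zero displacement width), so the exact area
    under force-displacement is the sum of the trapezoids under the
    linear rises; it is stored in the trace metadata together with the
    displacement of the last rupture and the programmed event count.
    """
    x: list[float] = []
    f: list[float] = []
    area = 0.0
    x0, f0 = 0.0, 0.0
    last_rupture_x = 0.0

    def rise(f_end: float) -> None:
        nonlocal x0, f0, area
        dx = (f_end - f0) / spec.rise_stiffness
        xs = np.linspace(x0, x0 + dx, spec.samples_per_rise)
        fs = np.linspace(f0, f_end, spec.samples_per_rise)
        start = 1 if x else 0  # skip duplicate joint sample
        x.extend(xs[start:])
        f.extend(fs[start:])
        area += 0.5 * (f0 + f_end) * dx
        x0, f0 = x0 + dx, f_end

    for peak in spec.rupture_forces:
        rise(peak)
        last_rupture_x = x0
        f0 = spec.post_drop_fraction * peak
        x.append(x0)  # instantaneous drop: same displacement, lower force
        f.append(f0)
    rise(spec.force_cap)

    geometry = RodGeometry(diameter_nm=spec.diameter)
    meta = {
        "analytic_area_pn_nm": area,
        "last_rupture_displacement_nm": last_rupture_x,
        "programmed_ruptures": spec.n_interfaces,
        "post_drop_fraction": spec.post_drop_fraction,
    }
    return ForceExtensionTrace(
        displacement=np.array(x),
        force=np.array(f),
        gauge_length=spec.gauge_length,
        geometry=geometry,
        force_cap=spec.force_cap,
        meta=meta,
    )


@dataclass(frozen=True)
class TitrationTruth:
    """Ground truth for a synthetic titration table.

    The noiseless curve is ``f(pH) = A 10^{B(pK-pH)} / (1 + 10^{B(pK-pH)}) + C``:
    amplitude ``A``, transition slope factor ``B``, baseline ``C`` and
    half-maximum ``pK``.
    """

    amplitude: float = 1.0
    slope: float = 0.8
    offset: float = 0.0
    pk: float = 8.0
    noise_sd: float = 0.02
    ph_grid: tuple = tuple(np.arange(2.5, 12.01, 0.5))

    def __post_init__(self) -> None:
        object.__setattr__(self, "ph_grid", tuple(float(p) for p in self.ph_grid))
        if not self.slope > 0:
            raise ParameterError("slope factor B must be positive")
        if self.offset < 0:
            raise ParameterError("offset C must be non-negative")
        if not 0 <= self.amplitude + self.offset <= 1:
            raise ParameterError("A + C must lie in [0, 1] for a fraction")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if len(self.ph_grid) == 0:
            raise ParameterError("pH grid must be non-empty")


def generate_titration_data(
    truth: TitrationTruth, seed: int = 0, n_replicates: int = 3
) -> TitrationData:
    """Draw protonated fractions on the pH grid with Gaussian noise.

    ``n_replicates`` independent measurements per pH (default 3,
    matching triplicate deposition); values are clipped to [0, 1]
    because they are fractions.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be at least 1")
    rng = np.random.default_rng(seed)
    ph = np.repeat(np.asarray(truth.ph_grid, dtype=float), n_replicates)
    f_true = eval_sigmoid(ph, truth.amplitude, truth.slope, truth.offset, truth.pk)
    f = f_true + rng.normal(0.0, truth.noise_sd, size=ph.shape)
    f = np.clip(f, 0.0, 1.0)
    return TitrationData(
        ph=ph,
        f=f,
        n_replicates=n_replicates,
        meta={
            "source": "synthetic sigmoid titration",
            "truth": {
                "A": truth.amplitude,
                "B": truth.slope,
                "C": truth.offset,
                "pK": truth.pk,
                "noise_sd": truth.noise_sd,
            },
            "seed": seed,
        },
    )
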