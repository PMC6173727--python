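"""Chain statistics for traced fibril contours and persistence-length fitting.

Contours are treated as planar (2D) polylines — the geometry of filaments
equilibrated on a flat substrate.  All three persistence-length estimators
therefore use the 2D worm-like-chain conventions:

* mean-squared end-to-end distance of an inner segment of arc length ``l``::

      <R^2>(l) = 4 lam [ l - 2 lam (1 - exp(-l / (2 lam))) ]

* tangent (bond) correlation::

      <cos theta>(l) = exp(-l / (2 lam))

* mean-squared midpoint displacement (weak-bending limit)::

      <u^2>(l) = l^3 / (48 lam)

where ``lam`` is the persistence length.  Profiles pool all internal point
pairs of every fiber into equal-width arc-length bins; the fits are
single-parameter weighted least squares on the binned means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import EmptyEnsembleError, FitError, ModeError, ParameterError

__all__ = [
    "FiberContour",
    "ChainEnsemble",
    "DistanceProfile",
    "PersistenceFit",
    "MODE_MSED",
    "MODE_CORRELATION",
    "MODE_MIDPOINT",
    "filter_fibers",
    "ms_end_to_end_profile",
    "bond_correlation_profile",
    "msmd_profile",
    "eval_wlc_msed",
    "fit_persistence_wlc",
    "fit_persistence_bcf",
    "fit_persistence_msmd",
    "bootstrap_persistence",
]

MODE_MSED = "msed"
MODE_CORRELATION = "correlation"
MODE_MIDPOINT = "midpoint"

_ARC_RTOL = 1e-9


@dataclass(frozen=True)
class FiberContour:
    """One traced fibril backbone: an ordered 2D polyline in nm.

    ``arc`` holds the cumulative Euclidean arc length at each point,
    starting at 0.  Use :meth:`from_points` to build a contour from raw
    coordinates; the constructor validates consistency.
    """

    points: np.ndarray  # (n, 2), nm
    arc: np.ndarray  # (n,), nm, cumulative

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        arc = np.asarray(self.arc, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ParameterError("contour points must be an (n, 2) array")
        if pts.shape[0] < 2:
            raise ParameterError("a contour needs at least 2 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ParameterError("consecutive contour points must be distinct")
        expected = np.concatenate([[0.0], np.cumsum(seg)])
        if arc.shape != (pts.shape[0],) or not np.allclose(
            arc, expected, rtol=_ARC_RTOL, atol=0.0
        ):
            raise ParameterError("stored arc lengths disagree with coordinates")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "arc", arc)

    @classmethod
    def from_points(cls, points: np.ndarray) -> "FiberContour":
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ParameterError("contour points must be an (n>=2, 2) array")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ParameterError("consecutive contour points must be distinct")
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return cls(points=pts, arc=arc)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def length(self) -> float:
        """Total contour (arc) length, nm."""
        return float(self.arc[-1])


@dataclass
class ChainEnsemble:
    """A collection of fiber contours sharing units (nm).

    ``metadata`` records provenance: a source description, the ground-truth
    persistence length for synthetic ensembles, and filtering counts.
    """

    contours: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.contours = list(self.contours)
        self.metadata = dict(self.metadata)
        self.metadata.setdefault("units", "nm")

    def __len__(self) -> int:
        return len(self.contours)


@dataclass(frozen=True)
class DistanceProfile:
    """Binned chain statistic: bin centers ``l`` (nm) vs per-bin means.

    ``values`` are <R^2> (nm^2) in ``msed`` mode, <cos theta> in
    ``correlation`` mode, and <u^2> (nm^2) in ``midpoint`` mode.
    Only bins with at least one pooled pair are retained.
    """

    l: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    mode: str
    n_fibers: int = 0

    def __post_init__(self) -> None:
        l = np.asarray(self.l, dtype=float)
        v = np.asarray(self.values, dtype=float)
        c = np.asarray(self.counts, dtype=np.int64)
        if not (l.shape == v.shape == c.shape):
            raise ParameterError("profile arrays must share one shape")
        if l.size and np.any(np.diff(l) <= 0):
            raise ParameterError("bin centers must be strictly increasing")
        if np.any(c < 1):
            raise ParameterError("retained bins must have at least one pair")
        if self.mode not in (MODE_MSED, MODE_CORRELATION, MODE_MIDPOINT):
            raise ParameterError(f"unknown profile mode {self.mode!r}")
        object.__setattr__(self, "l", l)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class PersistenceFit:
    """Result of a persistence-length fit.

    ``lam`` and ``lam_sd`` are in nm; ``estimator`` is one of
    ``wlc_msed``, ``bond_correlation``, ``msmd``.
    """

    lam: float
    lam_sd: float
    estimator: str
    rss: float
    n_fibers: int
    n_bins: int

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise FitError("fitted persistence length is not positive")
        if self.lam_sd < 0:
            raise FitError("fit SD must be non-negative")


# ---------------------------------------------------------------------------
# filtering

def filter_fibers(ensemble: ChainEnsemble, min_length: float) -> ChainEnsemble:
    """Keep fibers with total arc length >= ``min_length`` nm.

    Mirrors the usual AFM selection step (e.g. discarding traces shorter
    than 50 nm before rigidity analysis).  Raises
    :class:`EmptyEnsembleError` if nothing survives, so downstream fits
    never run silently on an empty set.
    """
    if min_length < 0:
        raise ParameterError("min_length must be non-negative")
    kept = [c for c in ensemble.contours if c.length >= min_length]
    if not kept:
        raise EmptyEnsembleError(
            f"no fibers of length >= {min_length} nm "
            f"(had {len(ensemble.contours)})"
        )
    meta = dict(ensemble.metadata)
    meta["n_before_filter"] = len(ensemble.contours)
    meta["n_after_filter"] = len(kept)
    meta["min_length_nm"] = float(min_length)
    return ChainEnsemble(contours=kept, metadata=meta)


# ---------------------------------------------------------------------------
# profiles

_triu_cache: dict = {}
_midpoint_cache: dict = {}


def _triu_indices(n: int):
    out = _triu_cache.get(n)
    if out is None:
        out = np.triu_indices(n, k=1)
        if len(_triu_cache) > 64:
            _triu_cache.clear()
        _triu_cache[n] = out
    return out


def _midpoint_indices(n: int):
    """Index triples (i, j, m) with j - i even and m the index midpoint."""
    out = _midpoint_cache.get(n)
    if out is None:
        ii, jj, mm = [], [], []
        for h in range(1, (n - 1) // 2 + 1):
            i = np.arange(0, n - 2 * h)
            ii.append(i)
            jj.append(i + 2 * h)
            mm.append(i + h)
        if ii:
            out = (np.concatenate(ii), np.concatenate(jj), np.concatenate(mm))
        else:
            out = (np.empty(0, int), np.empty(0, int), np.empty(0, int))
        if len(_midpoint_cache) > 64:
            _midpoint_cache.clear()
        _midpoint_cache[n] = out
    return out


def _bin_pairs(n_bins: int, l_max: float, chunks) -> DistanceProfile:
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for l_vals, y_vals in chunks:
        if l_vals.size == 0:
            continue
        keep = l_vals <= l_max
        if not np.all(keep):
            l_vals = l_vals[keep]
            y_vals = y_vals[keep]
        idx = np.minimum((l_vals * (n_bins / l_max)).astype(np.int64), n_bins - 1)
        sums += np.bincount(idx, weights=y_vals, minlength=n_bins)
        counts += np.bincount(idx, minlength=n_bins)
    edges = np.linspace(0.0, l_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return centers[keep], sums[keep] / counts[keep], counts[keep]


def _check_profile_inputs(ensemble: ChainEnsemble, n_bins: int) -> float:
    if not ensemble.contours:
        raise EmptyEnsembleError("cannot profile an empty ensemble")
    if n_bins < 2:
        raise ParameterError("n_bins must be at least 2")
    return max(c.length for c in ensemble.contours)


def ms_end_to_end_profile(
    ensemble: ChainEnsemble, n_bins: int = 100, l_max: float | None = None
) -> DistanceProfile:
    """Pooled mean-squared end-to-end distance vs inner contour length.

    Every internal point pair (i < j) of every fiber contributes one
    (arc length, squared chord distance) sample; samples are pooled over
    the whole ensemble into ``n_bins`` equal-width bins on [0, l_max].
    ``l_max`` defaults to the longest fiber.  The default of 100 bins
    matches common fibril-statistics practice.
    """
    auto_l_max = _check_profile_inputs(ensemble, n_bins)
    l_max = float(l_max) if l_max is not None else auto_l_max

    def chunks():
        for c in ensemble.contours:
            i, j = _triu_indices(c.n_points)
            dl = c.arc[j] - c.arc[i]
            d = c.points[j] - c.points[i]
            r2 = np.einsum("ij,ij->i", d, d)
            yield dl, r2

    centers, means, counts = _bin_pairs(n_bins, l_max, chunks())
    return DistanceProfile(
        l=centers, values=means, counts=counts, mode=MODE_MSED,
        n_fibers=len(ensemble.contours),
    )


def bond_correlation_profile(
    ensemble: ChainEnsemble, n_bins: int = 100, l_max: float | None = None
) -> DistanceProfile:
    """Pooled tangent-tangent correlation <cos theta> vs arc separation.

    Tangents are unit vectors of consecutive-point segments, located at
    the segment arc midpoints; all tangent pairs within a fiber
    contribute.
    """
    auto_l_max = _check_profile_inputs(ensemble, n_bins)
    l_max = float(l_max) if l_max is not None else auto_l_max

    def chunks():
        for c in ensemble.contours:
            seg = np.diff(c.points, axis=0)
            t = seg / np.linalg.norm(seg, axis=1)[:, None]
            s = 0.5 * (c.arc[:-1] + c.arc[1:])
            i, j = _triu_indices(t.shape[0])
            if i.size == 0:
                continue
            dl = s[j] - s[i]
            cos = np.einsum("ij,ij->i", t[i], t[j])
            yield dl, cos

    centers, means, counts = _bin_pairs(n_bins, l_max, chunks())
    return DistanceProfile(
        l=centers, values=means, counts=counts, mode=MODE_CORRELATION,
        n_fibers=len(ensemble.contours),
    )


def msmd_profile(
    ensemble: ChainEnsemble, n_bins: int = 100, l_max: float | None = None
) -> DistanceProfile:
    """Pooled mean-squared midpoint displacement <u^2> vs segment length.

    For each internal segment whose arc midpoint falls on a sampled point
    (even index span; exact for uniformly stepped contours), ``u`` is the
    perpendicular deviation of that midpoint from the chord joining the
    segment ends.
    """
    auto_l_max = _check_profile_inputs(ensemble, n_bins)
    l_max = float(l_max) if l_max is not None else auto_l_max

    def chunks():
        for c in ensemble.contours:
            i, j, m = _midpoint_indices(c.n_points)
            if i.size == 0:
                continue
            chord = c.points[j] - c.points[i]
            rel = c.points[m] - c.points[i]
            norm = np.hypot(chord[:, 0], chord[:, 1])
            cross = chord[:, 0] * rel[:, 1] - chord[:, 1] * rel[:, 0]
            ok = norm > 0  # closed loops have coincident segment ends
            u2 = (cross[ok] / norm[ok]) ** 2
            dl = (c.arc[j] - c.arc[i])[ok]
            yield dl, u2

    centers, means, counts = _bin_pairs(n_bins, l_max, chunks())
    return DistanceProfile(
        l=centers, values=means, counts=counts, mode=MODE_MIDPOINT,
        n_fibers=len(ensemble.contours),
    )


# ---------------------------------------------------------------------------
# models and fits

def eval_wlc_msed(l, lam: float):
    """2D worm-like-chain mean-squared end-to-end distance.

    ``<R^2> = 4 lam [l - 2 lam (1 - exp(-l/(2 lam)))]`` with ``l`` and
    ``lam`` in nm; returns nm^2.  Uses ``expm1`` so the stiff limit
    ``l << lam`` (where the result approaches ``l^2``) is evaluated
    without catastrophic cancellation.
    """
    if not lam > 0:
        raise ParameterError("persistence length must be positive")
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ParameterError("arc length must be non-negative")
    x = l / (2.0 * lam)
    # closed form via expm1; for x << 1 the subtraction cancels, so switch
    # to the series l^2 (1 - x/3 + x^2/12 - x^3/60 + x^4/360)
    closed = 4.0 * lam * (l + 2.0 * lam * np.expm1(-x))
    series = l * l * (
        1.0 + x * (-1.0 / 3.0 + x * (1.0 / 12.0 + x * (-1.0 / 60.0
                                                       + x / 360.0)))
    )
    out = np.where(x < 1e-2, series, closed)
    return out if out.ndim else float(out)


_LAM_MIN, _LAM_MAX = 1.0, 1.0e6  # nm, initialization clip


def _profile_weights(profile: DistanceProfile, weights) -> np.ndarray | None:
    """Map a weighting choice to a curve_fit ``sigma`` array."""
    if weights == "counts":
        return 1.0 / np.sqrt(profile.counts.astype(float))
    if weights == "uniform":
        return None
    raise ParameterError(f"unknown weighting {weights!r}")


def _trimmed(profile: DistanceProfile, min_pairs: int) -> DistanceProfile:
    keep = profile.counts >= min_pairs
    return replace(
        profile,
        l=profile.l[keep],
        values=profile.values[keep],
        counts=profile.counts[keep],
    )


def _run_fit(model, l, y, p0, sigma):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            popt, pcov = curve_fit(
                model, l, y, p0=p0, sigma=sigma,
                bounds=(1e-9, np.inf), xtol=1e-12, ftol=1e-12, maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"persistence fit did not converge: {exc}") from exc
    lam = float(popt[0])
    var = float(pcov[0, 0])
    sd = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else 0.0
    rss = float(np.sum((np.asarray(model(l, lam)) - y) ** 2))
    return lam, sd, rss


def fit_persistence_wlc(
    profile: DistanceProfile,
    weights: str = "counts",
    min_pairs: int = 5,
) -> PersistenceFit:
    """Fit the 2D WLC <R^2>(l) model to an end-to-end profile.

    Single-parameter least squares, by default weighted by per-bin pair
    counts (sparse large-l bins would otherwise dominate).  Bins with
    fewer than ``min_pairs`` pairs are dropped first.  Initialization is
    ``lam0 = <R^2>_max / (4 l_max)`` clipped to [1, 1e6] nm — the
    flexible-limit inversion, robust in both stiff and floppy regimes.
    """
    if profile.mode != MODE_MSED:
        raise ModeError(f"expected an {MODE_MSED!r} profile, got {profile.mode!r}")
    prof = _trimmed(profile, min_pairs)
    if prof.l.size < 3:
        raise FitError("need at least 3 populated bins to fit")
    lam0 = float(np.clip(prof.values.max() / (4.0 * prof.l.max()), _LAM_MIN, _LAM_MAX))
    sigma = _profile_weights(prof, weights)
    lam, sd, rss = _run_fit(eval_wlc_msed, prof.l, prof.values, lam0, sigma)
    return PersistenceFit(
        lam=lam, lam_sd=sd, estimator="wlc_msed", rss=rss,
        n_fibers=profile.n_fibers, n_bins=int(prof.l.size),
    )


def _bcf_model(l, lam):
    return np.exp(-np.asarray(l, dtype=float) / (2.0 * lam))


def fit_persistence_bcf(
    profile: DistanceProfile,
    weights: str = "counts",
    min_pairs: int = 5,
) -> PersistenceFit:
    """Fit ``<cos theta>(l) = exp(-l/(2 lam))`` to a correlation profile.

    Bins whose mean correlation is non-positive (pure noise floor, no
    directional memory left) are excluded before fitting.
    """
    if profile.mode != MODE_CORRELATION:
        raise ModeError(
            f"expected a {MODE_CORRELATION!r} profile, got {profile.mode!r}"
        )
    prof = _trimmed(profile, min_pairs)
    keep = prof.values > 0
    prof = replace(prof, l=prof.l[keep], values=prof.values[keep],
                   counts=prof.counts[keep])
    if prof.l.size < 3:
        raise FitError("need at least 3 positive-correlation bins to fit")
    # invert the first decaying bin for a starting value
    lam0 = _LAM_MIN
    for lc, vc in zip(prof.l, prof.values):
        if 0 < vc < 1:
            lam0 = float(np.clip(-lc / (2.0 * np.log(vc)), _LAM_MIN, _LAM_MAX))
            break
    sigma = _profile_weights(prof, weights)
    lam, sd, rss = _run_fit(_bcf_model, prof.l, prof.values, lam0, sigma)
    return PersistenceFit(
        lam=lam, lam_sd=sd, estimator="bond_correlation", rss=rss,
        n_fibers=profile.n_fibers, n_bins=int(prof.l.size),
    )


def _msmd_model(l, lam):
    return np.asarray(l, dtype=float) ** 3 / (48.0 * lam)


def fit_persistence_msmd(
    profile: DistanceProfile,
    weights: str = "counts",
    min_pairs: int = 5,
    l_max: float | None = None,
) -> PersistenceFit:
    """Fit ``<u^2>(l) = l^3/(48 lam)`` to a midpoint-displacement profile.

    The cubic law holds only in the weak-bending window ``l <~ lam/2``.
    If ``l_max`` is not given, the window is chosen self-consistently:
    fit on all bins, restrict to ``l <= lam_hat/2``, and refit (two
    iterations, deterministic).
    """
    if profile.mode != MODE_MIDPOINT:
        raise ModeError(
            f"expected a {MODE_MIDPOINT!r} profile, got {profile.mode!r}"
        )
    prof = _trimmed(profile, min_pairs)
    if prof.l.size < 3:
        raise FitError("need at least 3 populated bins to fit")

    def fit_window(p):
        sigma = _profile_weights(p, weights)
        # closed-form seed: model is linear in 1/lam
        x = p.l ** 3 / 48.0
        denom = float(np.dot(x, p.values))
        lam0 = float(np.clip(np.dot(x, x) / denom, _LAM_MIN, _LAM_MAX)) \
            if denom > 0 else _LAM_MIN
        return _run_fit(_msmd_model, p.l, p.values, lam0, sigma)

    def window(p, cut):
        keep = p.l <= cut
        return replace(p, l=p.l[keep], values=p.values[keep],
                       counts=p.counts[keep])

    if l_max is not None:
        prof = window(prof, float(l_max))
        if prof.l.size < 3:
            raise FitError("fewer than 3 bins inside the requested l_max window")
        lam, sd, rss = fit_window(prof)
        used = prof
    else:
        lam, sd, rss = fit_window(prof)
        used = prof
        for _ in range(2):
            cand = window(prof, lam / 2.0)
            if cand.l.size < 3:
                break
            lam, sd, rss = fit_window(cand)
            used = cand
    return PersistenceFit(
        lam=lam, lam_sd=sd, estimator="msmd", rss=rss,
        n_fibers=profile.n_fibers, n_bins=int(used.l.size),
    )


# ---------------------------------------------------------------------------
# bootstrap

_ESTIMATORS = {
    "wlc_msed": (ms_end_to_end_profile, fit_persistence_wlc),
    "bond_correlation": (bond_correlation_profile, fit_persistence_bcf),
    "msmd": (msmd_profile, fit_persistence_msmd),
}


def bootstrap_persistence(
    ensemble: ChainEnsemble,
    estimator: str = "wlc_msed",
    n_boot: int = 200,
    n_bins: int = 100,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Fiber-bootstrap the persistence length: resample contours with
    replacement, rebuild the profile, refit.

    Returns ``(mean, sd, samples)`` over the replicate fits.  Provided
    because a reported "mean +/- SD over N fibers" can mean either the
    fit-covariance SD or a resampling SD; this is the latter.
    """
    if estimator not in _ESTIMATORS:
        raise ParameterError(f"unknown estimator {estimator!r}")
    if n_boot < 2:
        raise ParameterError("need at least 2 bootstrap replicates")
    profiler, fitter = _ESTIMATORS[estimator]
    rng = np.random.default_rng(seed)
    n = len(ensemble.contours)
    samples = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = ChainEnsemble(
            contours=[ensemble.contours[k] for k in idx],
            metadata=dict(ensemble.metadata),
        )
        samples[b] = fitter(profiler(boot, n_bins=n_bins)).lam
    return float(samples.mean()), float(samples.std(ddof=1)), samples
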