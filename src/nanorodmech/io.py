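"""Plain-text readers and writers for contours, traces, and results.

Formats are deliberately simple and diffable:

* contour ensembles — multi-fiber XY tables: ``x y`` rows in nm,
  fibers separated by blank lines (a leading integer id column is also
  accepted), ``#`` comment lines, ``# units nm`` and ``# key = value``
  metadata headers;
* force-extension traces — two columns (displacement nm, force pN),
  lines starting with ``#`` or ``@`` ignored (xvg-dialect compatible),
  geometry carried in ``# key = value`` headers (``L0``, ``d``,
  ``force_cap``);
* profiles, fits, and tensile metrics — small CSV tables.

Numbers are written with 10 significant digits, so a write-read round
trip reproduces values to that precision and is exactly idempotent.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np

from .chain_statistics import (
    ChainEnsemble,
    DistanceProfile,
    FiberContour,
    PersistenceFit,
)
from .errors import ParseError
from .rod_mechanics import RodGeometry
from .tensile_analysis import ForceExtensionTrace, TensileProperties

__all__ = [
    "read_contours",
    "write_contours",
    "read_force_extension",
    "write_force_extension",
    "write_profile_csv",
    "write_persistence_fit_csv",
    "write_tensile_csv",
]

_FMT = "%.10g"


# ---------------------------------------------------------------------------
# contours

def write_contours(path, ensemble: ChainEnsemble) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# nanorodmech contour ensemble\n")
        fh.write(f"# units {ensemble.metadata.get('units', 'nm')}\n")
        for key in ("lambda_true_nm", "noise_sd_nm", "step_nm", "seed"):
            if key in ensemble.metadata:
                fh.write(f"# {key} = {ensemble.metadata[key]}\n")
        for k, contour in enumerate(ensemble.contours):
            if k:
                fh.write("\n")
            fh.write(f"# fiber {k}\n")
            for xx, yy in contour.points:
                fh.write(f"{_FMT % xx} {_FMT % yy}\n")


def _finish_fiber(rows, contours, n_dropped, line_no):
    if not rows:
        return n_dropped
    if len(rows) < 2:
        warnings.warn(
            f"dropping single-point fiber ending at line {line_no}",
            stacklevel=3,
        )
        return n_dropped + 1
    contours.append(FiberContour.from_points(np.array(rows)))
    return n_dropped


def read_contours(path) -> ChainEnsemble:
    """Parse a multi-fiber XY table into a :class:`ChainEnsemble`.

    Fibers are split on blank lines or on changes of a leading integer
    id column.  Arc lengths are computed on load.  Malformed rows raise
    :class:`ParseError` naming the line; single-point fibers are dropped
    with a warning.
    """
    path = Path(path)
    metadata: dict = {"source": str(path)}
    contours: list[FiberContour] = []
    rows: list[list[float]] = []
    current_id = None
    n_dropped = 0
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("units"):
                    metadata["units"] = body.split(None, 1)[1].strip() \
                        if len(body.split(None, 1)) > 1 else "nm"
                elif "=" in body:
                    key, _, value = body.partition("=")
                    try:
                        metadata[key.strip()] = float(value)
                    except ValueError:
                        metadata[key.strip()] = value.strip()
                continue
            if not line:
                n_dropped = _finish_fiber(rows, contours, n_dropped, line_no)
                rows = []
                current_id = None
                continue
            fields = line.replace(",", " ").split()
            try:
                values = [float(v) for v in fields]
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} line {line_no}: cannot parse row {line!r}"
                ) from exc
            if len(values) == 2:
                rows.append(values)
            elif len(values) == 3:
                fiber_id = values[0]
                if current_id is not None and fiber_id != current_id:
                    n_dropped = _finish_fiber(rows, contours, n_dropped, line_no)
                    rows = []
                current_id = fiber_id
                rows.append(values[1:])
            else:
                raise ParseError(
                    f"{path.name} line {line_no}: expected 2 or 3 columns, "
                    f"got {len(values)}"
                )
    n_dropped = _finish_fiber(rows, contours, n_dropped, line_no="EOF")
    metadata.setdefault("units", "nm")
    if n_dropped:
        metadata["n_dropped_single_point"] = n_dropped
    return ChainEnsemble(contours=contours, metadata=metadata)


# ---------------------------------------------------------------------------
# force-extension traces

def write_force_extension(path, trace: ForceExtensionTrace) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write('@ title "force-extension trace"\n')
        fh.write("@ xaxis label \"displacement (nm)\"\n")
        fh.write("@ yaxis label \"force (pN)\"\n")
        fh.write(f"# L0 = {_FMT % trace.gauge_length}\n")
        fh.write(f"# d = {_FMT % trace.geometry.diameter_nm}\n")
        if trace.force_cap is not None:
            fh.write(f"# force_cap = {_FMT % trace.force_cap}\n")
        for key, value in trace.meta.items():
            if isinstance(value, (int, float)):
                fh.write(f"# {key} = {_FMT % value}\n")
        for xx, ff in zip(trace.displacement, trace.force):
            fh.write(f"{_FMT % xx} {_FMT % ff}\n")


def read_force_extension(
    path,
    gauge_length: float | None = None,
    diameter: float | None = None,
) -> ForceExtensionTrace:
    """Read a two-column (displacement nm, force pN) trace.

    Lines starting with ``@`` or ``#`` are comments; ``# key = value``
    headers supply the geometry (``L0``, ``d``) and optional
    ``force_cap``.  Explicit arguments override the headers; if the
    geometry is available from neither, a :class:`ParseError` explains
    what to pass.  Non-monotone displacement is stably sorted with a
    warning.
    """
    path = Path(path)
    header: dict = {}
    xs: list[float] = []
    fs: list[float] = []
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("@"):
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    try:
                        header[key.strip()] = float(value)
                    except ValueError:
                        header[key.strip()] = value.strip()
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 2:
                raise ParseError(
                    f"{path.name} line {line_no}: expected 2 columns, "
                    f"got {len(fields)}"
                )
            try:
                xs.append(float(fields[0]))
                fs.append(float(fields[1]))
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} line {line_no}: cannot parse row {line!r}"
                ) from exc
    l0 = gauge_length if gauge_length is not None else header.get("L0")
    d = diameter if diameter is not None else header.get("d")
    if l0 is None or d is None:
        raise ParseError(
            f"{path.name}: no geometry header found; pass gauge_length= and "
            "diameter= explicitly (or add '# L0 = ...' / '# d = ...' lines)"
        )
    x = np.array(xs)
    f = np.array(fs)
    if np.any(np.diff(x) < 0):
        warnings.warn(
            f"{path.name}: non-monotone displacement; applying a stable sort",
            stacklevel=2,
        )
        order = np.argsort(x, kind="stable")
        x, f = x[order], f[order]
    meta = {k: v for k, v in header.items() if k not in ("L0", "d", "force_cap")}
    meta["source"] = str(path)
    return ForceExtensionTrace(
        displacement=x,
        force=f,
        gauge_length=float(l0),
        geometry=RodGeometry(diameter_nm=float(d)),
        force_cap=header.get("force_cap"),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# CSV outputs

def write_profile_csv(path, profile: DistanceProfile) -> None:
    value_name = {
        "msed": "mean_r2_nm2",
        "correlation": "mean_cos_theta",
        "midpoint": "mean_u2_nm2",
    }[profile.mode]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["l_nm", value_name, "n_pairs"])
        for l, v, c in zip(profile.l, profile.values, profile.counts):
            writer.writerow([_FMT % l, _FMT % v, int(c)])


def write_persistence_fit_csv(path, fits: list[PersistenceFit]) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["estimator", "lambda_nm", "lambda_sd_nm", "rss", "n_fibers", "n_bins"]
        )
        for fit in fits:
            writer.writerow([
                fit.estimator, _FMT % fit.lam, _FMT % fit.lam_sd,
                _FMT % fit.rss, fit.n_fibers, fit.n_bins,
            ])


def write_tensile_csv(path, props: TensileProperties) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "e_init_gpa", "tensile_strength_gpa", "strain_to_failure_pct",
            "toughness_gj_m3", "n_ruptures", "modulus_window_hi",
            "cap_strain",
        ])
        writer.writerow([
            _FMT % props.e_init.value,
            _FMT % props.tensile_strength,
            _FMT % (100.0 * props.strain_to_failure.strain),
            _FMT % props.toughness,
            len(props.events),
            _FMT % props.e_init.window[1],
            "" if props.strain_to_failure.cap_strain is None
            else _FMT % props.strain_to_failure.cap_strain,
        ])
        writer.writerow([])
        writer.writerow(["event_index", "strain", "peak_stress_gpa", "drop_gpa"])
        for ev in props.events:
            writer.writerow([
                ev.index, _FMT % ev.strain, _FMT % ev.peak_stress, _FMT % ev.drop,
            ])
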