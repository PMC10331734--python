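"""Trajectory-level validation of chromophore behavior.

Internal-coordinate series are extracted frame by frame, summarized by a
Gaussian fit to their histogram (center and width sigma, in degrees), and
compared between a classical trajectory and a reference (e.g. QM/MM)
trajectory: center-center difference in units of the reference sigma, and
the width ratio classical/reference.

Two stability metrics accompany the distribution comparison: the ratio of
standard deviation to fitted slope over an equilibration window (large when
a series has settled), and the slope of a linear fit to per-frame beta-sheet
residue counts (near zero for a stable beta barrel).

Default histogram bin widths: 2 degrees for bond angles, 5 degrees for
intra-ring dihedrals, 15 degrees for the wide ring-planarity dihedral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .chem_model import Structure
from . import geometry

__all__ = [
    "DEFAULT_BIN_WIDTHS",
    "AngleDefinition",
    "GaussianFitResult",
    "DistributionComparison",
    "StabilityReport",
    "angle_series",
    "fit_gaussian",
    "compare_fits",
    "equilibration_ratio",
    "beta_slope",
    "load_angle_definitions",
    "comparison_report",
]

DEFAULT_BIN_WIDTHS = {  # degrees
    "bond_angle": 2.0,
    "dihedral": 5.0,
    "improper": 5.0,
    "ring_planarity": 15.0,
}


@dataclass(frozen=True)
class AngleDefinition:
    label: str
    kind: str  # bond_angle | dihedral | improper
    atom_names: tuple[str, ...]

    def __post_init__(self) -> None:
        need = {"bond_angle": 3, "dihedral": 4, "improper": 4}
        if self.kind not in need:
            raise ValueError(f"unknown angle kind {self.kind!r}")
        if len(self.atom_names) != need[self.kind]:
            raise ValueError(
                f"{self.label}: {self.kind} needs {need[self.kind]} atom names"
            )


@dataclass
class GaussianFitResult:
    center: float  # degrees
    sigma: float  # degrees
    amplitude: float
    bin_width: float  # degrees
    n_samples: int
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and not self.sigma > 0:
            raise ValueError("converged fit must have sigma > 0")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass(frozen=True)
class DistributionComparison:
    label: str
    delta_center: float  # classical - reference, degrees
    delta_center_in_sigma: float  # |delta| / reference sigma
    width_ratio: float  # classical sigma / reference sigma

    def __post_init__(self) -> None:
        if not self.width_ratio > 0:
            raise ValueError("width_ratio must be > 0")


@dataclass(frozen=True)
class StabilityReport:
    metric_name: str
    window: int  # frames
    sd: float
    slope: float  # per frame (or per supplied time unit)
    sd_over_slope_ratio: float  # inf flagged when slope == 0


def angle_series(structure: Structure, definition: AngleDefinition) -> np.ndarray:
    """One value per frame, degrees.

    Dihedrals and impropers are reported on a branch recentered at the
    series' circular mean, so a unimodal distribution straddling the
    +/-180 seam stays contiguous (each value moves only by multiples of
    360 degrees).
    """
    idx = [structure.index_of(name) for name in definition.atom_names]
    n = structure.n_frames
    values = np.empty(n)
    if definition.kind == "bond_angle":
        for f in range(n):
            values[f] = geometry.bond_angle(structure, *idx, frame=f)
        return values
    func = geometry.dihedral if definition.kind == "dihedral" else geometry.improper
    for f in range(n):
        values[f] = func(structure, *idx, frame=f)
    center = float(np.degrees(stats.circmean(np.radians(values),
                                             high=np.pi, low=-np.pi)))
    # re-wrap onto (center - 180, center + 180]
    shifted = np.mod(values - center + 180.0, 360.0) - 180.0 + center
    return shifted


def fit_gaussian(series, bin_width: float) -> GaussianFitResult:
    """Histogram the series at ``bin_width`` and fit A*exp(-(x-c)^2/2s^2).

    Initialized at the sample mean/SD; on optimizer failure the sample
    moments are returned with ``converged=False``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 100:
        raise ValueError(f"need >= 100 samples, got {x.size}")
    spread = float(x.max() - x.min())
    if spread <= bin_width:
        raise ValueError(
            f"degenerate series: spread {spread:.3g} <= bin width {bin_width:.3g}"
        )
    lo = bin_width * np.floor(x.min() / bin_width)
    hi = bin_width * np.ceil(x.max() / bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    mu0, sd0 = float(x.mean()), float(x.std())

    def gauss(t, amp, mu, sd):
        return amp * np.exp(-((t - mu) ** 2) / (2.0 * sd**2))

    try:
        popt, _ = optimize.curve_fit(
            gauss, centers, counts,
            p0=[counts.max(), mu0, max(sd0, bin_width / 2)],
            maxfev=10000,
        )
        amp, mu, sd = popt
        sd = abs(float(sd))
        if not (np.isfinite(mu) and np.isfinite(sd) and sd > 0 and amp > 0):
            raise RuntimeError("non-physical fit")
        return GaussianFitResult(center=float(mu), sigma=sd, amplitude=float(amp),
                                 bin_width=bin_width, n_samples=x.size,
                                 converged=True)
    except (RuntimeError, optimize.OptimizeWarning):
        return GaussianFitResult(center=mu0, sigma=max(sd0, 1e-12),
                                 amplitude=float(counts.max()),
                                 bin_width=bin_width, n_samples=x.size,
                                 converged=False)


def compare_fits(classical: GaussianFitResult,
                 reference: GaussianFitResult,
                 label: str = "") -> DistributionComparison:
    """Center shift (classical - reference), shift in reference sigmas, and
    width ratio classical/reference."""
    if not (classical.converged and reference.converged):
        raise ValueError("compare_fits requires two converged fits")
    delta = classical.center - reference.center
    return DistributionComparison(
        label=label,
        delta_center=delta,
        delta_center_in_sigma=abs(delta) / reference.sigma,
        width_ratio=classical.sigma / reference.sigma,
    )


def equilibration_ratio(series, window: int,
                        metric_name: str = "series") -> StabilityReport:
    """SD of raw values over the trailing window divided by |OLS slope|.

    A large ratio (the convention is > 50 for structural RMSD, > 1000 for
    density and energies) indicates the metric has stopped drifting
    relative to its natural fluctuation.
    """
    x = np.asarray(series, dtype=float)
    if window < 3:
        raise ValueError("window must cover at least 3 points")
    if window > x.size:
        raise ValueError(f"window {window} exceeds series length {x.size}")
    tail = x[-window:]
    t = np.arange(window, dtype=float)
    if np.all(tail == tail[0]):  # constant: avoid a spurious ~1e-16 slope
        slope = 0.0
    else:
        slope = float(np.polyfit(t, tail, 1)[0])
    sd = float(tail.std(ddof=0))
    ratio = float("inf") if slope == 0.0 else sd / abs(slope)
    return StabilityReport(metric_name=metric_name, window=window, sd=sd,
                           slope=slope, sd_over_slope_ratio=ratio)


def beta_slope(per_frame_counts, frame_interval_ns: float,
               trailing_window: int | None = None) -> tuple[float, float]:
    """OLS slope of beta-sheet residue counts, in residues per microsecond,
    plus the SD of counts over a trailing window (default: last 10%,
    at least 3 frames).

    ``frame_interval_ns`` is the time between consecutive counts in ns.
    """
    counts = np.asarray(per_frame_counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 frames of counts")
    if np.any(counts < 0):
        raise ValueError("beta-sheet counts must be nonnegative")
    if not frame_interval_ns > 0:
        raise ValueError("frame interval must be positive")
    t_us = np.arange(counts.size) * frame_interval_ns * 1e-3
    slope = float(np.polyfit(t_us, counts, 1)[0])
    if trailing_window is None:
        trailing_window = max(3, counts.size // 10)
    trailing_window = min(trailing_window, counts.size)
    sd = float(counts[-trailing_window:].std(ddof=0))
    return slope, sd


# ---------------------------------------------------------------------------
# Definition files and reports
# ---------------------------------------------------------------------------

def load_angle_definitions(text: str) -> list[AngleDefinition]:
    """'label kind atom1 atom2 atom3 [atom4]' per line."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) < 5:
            raise ValueError(
                f"line {lineno}: expected 'label kind atom1 atom2 atom3 [atom4]'"
            )
        try:
            out.append(AngleDefinition(label=parts[0], kind=parts[1],
                                       atom_names=tuple(parts[2:])))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return out


def comparison_report(comparisons: list[tuple[DistributionComparison,
                                              GaussianFitResult,
                                              GaussianFitResult]]) -> str:
    """Tab-separated table: label, center, sigma, delta, delta/sigma, ratio."""
    lines = ["label\tcenter\tsigma\tdelta_center\tdelta_in_sigma\twidth_ratio"]
    for comp, classical, _reference in comparisons:
        lines.append(
            f"{comp.label}\t{classical.center:.3f}\t{classical.sigma:.3f}\t"
            f"{comp.delta_center:.3f}\t{comp.delta_center_in_sigma:.3f}\t"
            f"{comp.width_ratio:.3f}"
        )
    return "\n".join(lines) + "\n"
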