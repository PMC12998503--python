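"""AFM force-curve preprocessing and Hertz-model elastic-modulus fitting.

The Hertz contact model for a spherical probe of radius R indenting an
elastic half-space of modulus E and Poisson's ratio mu relates force to
indentation depth delta as

    F(delta) = (4/3) * E / (1 - mu^2) * sqrt(R) * delta^(3/2) + C

with C a constant force offset. Defaults follow a spherical silica probe
of radius 3.31 um and mu = 0.4; the fit uses the first 250 nm of
indentation after contact-point re-zeroing.

Because F is linear in (E, C) once mu and R are fixed, the fit reduces to
ordinary least squares of F on delta^(3/2); no iterative solver is
involved. E is constrained non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

DEFAULT_R_M = 3.31e-6  # probe radius, m
DEFAULT_MU = 0.4  # Poisson's ratio of the tissue
DEFAULT_FIT_RANGE_M = 250e-9  # indentation depth fitted, m

_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}
_FORCE_UNITS = {"n": 1.0, "mn": 1e-3, "un": 1e-6, "nn": 1e-9, "pn": 1e-12}


@dataclass
class ForceCurve:
    """An AFM approach segment: tip-sample separation vs measured force.

    Arrays are stored in SI units (m, N). ``separation`` must be monotone
    non-decreasing on the approach segment.
    """

    separation: np.ndarray  # m
    force: np.ndarray  # N
    R: float = DEFAULT_R_M  # m
    mu: float = DEFAULT_MU
    id: str | None = None
    contact_index: int | None = None  # index into the raw curve, set by preprocessing

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.separation.shape != self.force.shape or self.separation.ndim != 1:
            raise ValueError("separation and force must be equal-length 1-D arrays")
        if len(self.separation) < 20:
            raise ValueError("force curve needs at least 20 samples")
        if np.any(np.diff(self.separation) < 0):
            raise ValueError("separation must be monotone on the approach segment")
        if self.R <= 0:
            raise ValueError("probe radius must be positive")
        if not (0 <= self.mu < 0.5):
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")


@dataclass
class HertzFit:
    """Hertz-model fit result for one curve."""

    E: float  # Pa
    C: float  # N
    rss: float  # N^2
    n_fit: int
    fit_range_m: tuple[float, float] = (0.0, DEFAULT_FIT_RANGE_M)
    id: str | None = None

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError("E must be non-negative")
        if self.n_fit < 10:
            raise ValueError("fewer than 10 points in the fit range")


def hertz_force(
    delta: np.ndarray | float,
    E: float,
    mu: float = DEFAULT_MU,
    R: float = DEFAULT_R_M,
    C: float = 0.0,
) -> np.ndarray | float:
    """Evaluate the Hertz force F(delta) in newtons (delta in m, E in Pa)."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be non-negative")
    out = (4.0 / 3.0) * E / (1.0 - mu**2) * np.sqrt(R) * delta**1.5 + C
    return out if out.ndim else float(out)


def _refine_contact(
    sep: np.ndarray, force: np.ndarray, hi: int, lo: int = 1
) -> tuple[int | None, float]:
    """Locate the contact sample by a piecewise baseline-plus-Hertz scan.

    For each candidate contact index j, fits F ~ C + k * (sep - sep[j])_+^(3/2)
    (k >= 0) over the whole approach segment and keeps the j with minimal
    residual sum of squares — exact for noiseless Hertz curves, and far
    less biased than a threshold crossing, which fires late because the
    Hertz force leaves the baseline with zero slope. Returns the index and
    the fitted rise amplitude (k * max indentation^(3/2)).
    """
    best_rss, best_j, best_rise = np.inf, None, 0.0
    fc = force - force.mean()
    for j in range(max(1, lo), max(2, hi)):
        x = np.clip(sep - sep[j], 0.0, None) ** 1.5
        xc = x - x.mean()
        denom = float(xc @ xc)
        if denom <= 0:
            continue
        slope = float(xc @ fc) / denom
        if slope < 0:
            continue
        resid = fc - slope * xc
        rss = float(resid @ resid)
        if rss < best_rss:
            best_rss, best_j, best_rise = rss, j, slope * float(x.max())
    return best_j, best_rise


def preprocess_force_curve(
    raw: ForceCurve,
    window: int = 11,
    polyorder: int = 3,
    contact_sd_k: float = 3.0,
    baseline_fraction: float = 0.25,
    fit_range_m: float = DEFAULT_FIT_RANGE_M,
) -> ForceCurve:
    """Smooth, locate the contact point, and re-zero to indentation depth.

    The force is Savitzky-Golay smoothed; the pre-contact baseline is the
    first ``baseline_fraction`` of approach samples. A candidate contact is
    the first sample whose smoothed force exceeds baseline mean +
    ``contact_sd_k`` x baseline SD; because the Hertz force leaves the
    baseline with zero slope, that crossing is systematically late at
    realistic noise levels, so the contact is then refined by scanning
    candidate contact samples and keeping the one whose piecewise model
    (flat baseline, Hertz rise) best fits the raw approach segment in the
    least-squares sense — exact on noiseless curves. Separation is
    re-zeroed at the refined contact and samples with indentation in
    [0, ``fit_range_m``] retained; the returned force is the smoothed one.
    """
    f = raw.force
    if window >= len(f):
        raise ValueError("smoothing window exceeds curve length")
    fs = savgol_filter(f, window_length=window, polyorder=polyorder)
    n_base = max(3, int(len(f) * baseline_fraction))
    base = f[:n_base]
    i, rise = _refine_contact(raw.separation, f, hi=len(f) - 10)
    # the fitted rise must stand clear of the baseline noise floor (and of
    # numerical dust on a flat curve) for a contact to be declared
    floor = max(
        contact_sd_k * float(base.std()),
        1e-6 * float(np.max(np.abs(f), initial=0.0)),
    )
    if i is None or rise <= floor:
        raise ValueError("no contact detected: force never rises above baseline")
    delta = raw.separation - raw.separation[i]
    keep = (delta >= 0) & (delta <= fit_range_m)
    if int(keep.sum()) < 10:
        raise ValueError(
            f"only {int(keep.sum())} samples within the {fit_range_m * 1e9:.0f} nm "
            "fit range after contact"
        )
    return ForceCurve(
        separation=delta[keep],
        force=fs[keep],
        R=raw.R,
        mu=raw.mu,
        id=raw.id,
        contact_index=i,
    )


def fit_hertz(
    curve: ForceCurve, fit_range_m: float = DEFAULT_FIT_RANGE_M
) -> HertzFit:
    """Least-squares Hertz fit of a preprocessed (indentation-referenced) curve.

    Regresses F on delta^(3/2) in closed form; the slope maps to E via
    the Hertz prefactor and is clipped at zero (C then refit as the mean
    force). Raises on a rank-deficient design (all depths equal).
    """
    delta = curve.separation
    f = curve.force
    # tolerant upper bound: grids built to end exactly at the fit range can
    # overshoot it by one ulp
    keep = (delta >= 0) & (delta <= fit_range_m * (1 + 1e-9))
    delta, f = delta[keep], f[keep]
    if len(delta) < 10:
        raise ValueError("fewer than 10 points in the fit range")
    x = delta**1.5
    if np.ptp(x) <= 0:
        raise ValueError("rank-deficient design: all indentation depths equal")
    # centered closed form: the raw design [delta^(3/2), 1] spans ~10 orders
    # of magnitude in SI units and is numerically treacherous
    xc = x - x.mean()
    slope = float(xc @ (f - f.mean())) / float(xc @ xc)
    c = float(f.mean() - slope * x.mean())
    prefactor = (4.0 / 3.0) / (1.0 - curve.mu**2) * np.sqrt(curve.R)
    if slope < 0:  # E >= 0 constraint: boundary solution
        slope = 0.0
        c = float(f.mean())
    E = float(slope / prefactor)
    resid = f - (slope * x + c)
    return HertzFit(
        E=E,
        C=float(c),
        rss=float(np.sum(resid**2)),
        n_fit=len(delta),
        fit_range_m=(0.0, fit_range_m),
        id=curve.id,
    )


@dataclass
class RegionSummary:
    """Mean modulus over the curves measured at one tissue region."""

    mean_E: float
    sd_E: float
    n: int
    fits: list[HertzFit] = field(repr=False, default_factory=list)


def summarize_region(fits: list[HertzFit]) -> RegionSummary:
    """Aggregate per-curve moduli for one region (mean over locations).

    No outlier rejection is applied; curves typically come from up to a
    handful of locations within the region of interest.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    E = np.array([f.E for f in fits])
    return RegionSummary(
        mean_E=float(E.mean()), sd_E=float(E.std()), n=len(fits), fits=fits
    )


def read_force_curve(
    path: str | Path,
    R: float = DEFAULT_R_M,
    mu: float = DEFAULT_MU,
) -> ForceCurve:
    """Read a two-column (separation, force) text file into SI units.

    A header line of the form ``# units: nm nN`` declares the length and
    force units of the columns; SI (m, N) is assumed otherwise.
    Delimiters may be whitespace, comma or tab.
    """
    path = Path(path)
    len_scale, force_scale = 1.0, 1.0
    with open(path) as fh:
        first = fh.readline()
    if first.lstrip().startswith("#") and "units" in first.lower():
        tokens = first.split(":", 1)[1].replace(",", " ").split()
        if len(tokens) >= 2:
            try:
                len_scale = _LENGTH_UNITS[tokens[0].lower()]
                force_scale = _FORCE_UNITS[tokens[1].lower()]
            except KeyError as e:
                raise ValueError(f"unknown unit in header: {e}") from None
    try:
        data = np.loadtxt(path, comments="#")
    except ValueError:
        data = np.loadtxt(path, comments="#", delimiter=",")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected two columns: separation, force")
    return ForceCurve(
        separation=data[:, 0] * len_scale,
        force=data[:, 1] * force_scale,
        R=R,
        mu=mu,
        id=path.stem,
    )


def write_force_curve(curve: ForceCurve, path: str | Path) -> None:
    """Write a curve as nm / nN columns with a units header."""
    out = np.column_stack([curve.separation * 1e9, curve.force * 1e9])
    np.savetxt(path, out, header="units: nm nN", comments="# ")
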