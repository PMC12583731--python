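"""Experimental chemical-shift distributions.

Solid-state spectra of amorphous solids show inhomogeneously broadened
peaks; each assigned atomic site is modelled by a Gaussian distribution
of chemical shifts with mean ``mu`` and width ``sigma`` (both ppm).
This module fits those Gaussians to 1D spectrum slices, converts
computed shieldings to the experimental shift scale, and refines
solution-state assignments to the nearest solid-state peaks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ShiftDistribution",
    "ShiftReferencing",
    "SpectrumSlice",
    "AssignmentTable",
    "fit_gaussian_peak",
    "shielding_to_shift",
    "refine_assignment",
    "read_distributions",
    "write_distributions",
    "read_spectrum_slice",
]

VALID_NUCLEI = ("1H", "13C", "15N")

#: Default shielding -> shift referencing offsets (ppm) per nucleus,
#: used with a slope of -1.
DEFAULT_OFFSETS = {"1H": 30.78, "13C": 170.04, "15N": 227.9}

#: Default maximum solution <-> solid deviation (ppm) accepted by
#: :func:`refine_assignment`, per nucleus.
DEFAULT_MAX_DEVIATION = {"1H": 1.0, "13C": 5.0, "15N": 5.0}


class EmptyWindowError(ValueError):
    """No positive signal inside the requested fit window."""


class FitFailedError(RuntimeError):
    """Gaussian peak fit did not converge within the restart budget."""


@dataclass(frozen=True)
class ShiftDistribution:
    """Experimental shift distribution of one assigned site.

    Parameters
    ----------
    atom_label : str
        Site identifier, e.g. ``"H1"`` or ``"C14"``.
    nucleus : str
        One of ``1H``, ``13C``, ``15N``.
    mu : float
        Mean shift in ppm.
    sigma : float
        Gaussian width (standard deviation) in ppm; must be positive.
    source : str
        Free-text identifier of the spectrum the peak was fitted from.
    lumped_with : tuple of str
        Other atom labels sharing this distribution (overlapping peaks
        fitted together to a single Gaussian).
    """

    atom_label: str
    nucleus: str
    mu: float
    sigma: float
    source: str = ""
    lumped_with: tuple = ()
    amplitude: float = float("nan")

    def __post_init__(self):
        if self.nucleus not in VALID_NUCLEI:
            raise ValueError(f"unknown nucleus {self.nucleus!r}; expected one of {VALID_NUCLEI}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def members(self) -> tuple:
        """All atom labels covered by this distribution (self + lumped)."""
        return (self.atom_label, *self.lumped_with)


@dataclass(frozen=True)
class ShiftReferencing:
    """Affine shielding -> shift conversion, delta = slope * sigma_calc + offset."""

    slopes: dict = field(default_factory=lambda: {n: -1.0 for n in VALID_NUCLEI})
    offsets: dict = field(default_factory=lambda: dict(DEFAULT_OFFSETS))


@dataclass(frozen=True)
class SpectrumSlice:
    """A 1D slice of a spectrum: a ppm axis and non-negative intensities."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if axis.shape != intensity.shape or axis.ndim != 1:
            raise ValueError("axis and intensity must be 1D arrays of equal length")
        d = np.diff(axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)


def _gaussian_sum(x, *params):
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        amp, mu, sigma = params[i : i + 3]
        y = y + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return y


def fit_gaussian_peak(slice_, window, n_components=1, *, nucleus="1H",
                      source="", max_restarts=5, rng=None):
    """Fit a sum of ``n_components`` Gaussians to a spectrum slice.

    Parameters
    ----------
    slice_ : SpectrumSlice
    window : (float, float)
        ppm interval (order irrelevant) restricting the fit.
    n_components : int
        Number of Gaussian components.
    nucleus, source :
        Metadata attached to the returned distributions.
    max_restarts : int
        Jittered re-initialisations attempted before giving up.
    rng : numpy.random.Generator, optional
        Source of jitter for the restarts; a fixed default keeps the
        fit deterministic.

    Returns
    -------
    (dists, residual) : (list of ShiftDistribution, float)
        Fitted components sorted by mu, and the root-mean-square fit
        residual inside the window.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    lo, hi = sorted(window)
    mask = (slice_.axis >= lo) & (slice_.axis <= hi)
    x = slice_.axis[mask]
    y = slice_.intensity[mask]
    if x.size == 0 or not np.any(y > 0):
        raise EmptyWindowError(f"no positive signal in window [{lo}, {hi}] ppm")
    if rng is None:
        rng = np.random.default_rng(0)

    width = hi - lo
    # argmax initialisation; extra components seeded at evenly spaced
    # positions across the window.
    mu0 = [float(x[np.argmax(y)])]
    if n_components > 1:
        mu0 = list(lo + (np.arange(n_components) + 0.5) * width / n_components)
        mu0[int(np.argmin(np.abs(np.asarray(mu0) - x[np.argmax(y)])))] = float(x[np.argmax(y)])
    sigma0 = width / 4.0 / max(1, n_components)
    amp0 = float(np.max(y))

    p0 = []
    for m in mu0:
        p0.extend([amp0, m, sigma0])
    lower = [0.0, lo, 1e-6] * n_components
    upper = [np.inf, hi, width] * n_components

    last_err = None
    for attempt in range(max_restarts + 1):
        trial = np.asarray(p0, dtype=float)
        if attempt > 0:
            jitter = rng.normal(scale=[0.1 * amp0, 0.1 * width, 0.1 * sigma0] * n_components)
            trial = np.clip(trial + jitter, lower, upper)
            trial = np.clip(trial, np.asarray(lower) + 1e-9, None)
        try:
            popt, _ = curve_fit(_gaussian_sum, x, y, p0=trial,
                                bounds=(lower, upper), maxfev=20000)
        except RuntimeError as err:  # pragma: no cover - rare non-convergence
            last_err = err
            continue
        resid = float(np.sqrt(np.mean((y - _gaussian_sum(x, *popt)) ** 2)))
        comps = sorted(
            (popt[i : i + 3] for i in range(0, len(popt), 3)),
            key=lambda t: t[1],
        )
        dists = [
            ShiftDistribution(atom_label="", nucleus=nucleus, mu=float(m),
                              sigma=float(s), source=source, amplitude=float(a))
            for a, m, s in comps
        ]
        return dists, resid
    raise FitFailedError(
        f"Gaussian fit failed after {max_restarts + 1} attempts in window "
        f"[{lo}, {hi}] ppm: {last_err}"
    )


def shielding_to_shift(value, nucleus, ref=None):
    """Convert a computed shielding (ppm) to the experimental shift scale.

    delta = slope * value + offset with per-nucleus slope and offset
    (slope -1 by default; offsets 30.78 / 170.04 / 227.9 ppm for
    1H / 13C / 15N).
    """
    if ref is None:
        ref = ShiftReferencing()
    if nucleus not in ref.offsets or nucleus not in ref.slopes:
        raise ValueError(f"unknown nucleus {nucleus!r}")
    return ref.slopes[nucleus] * np.asarray(value) + ref.offsets[nucleus]


def nucleus_of(atom_label: str) -> str:
    """Infer the nucleus from an atom label's element prefix (H1 -> 1H)."""
    el = atom_label.rstrip("0123456789ab")
    table = {"H": "1H", "C": "13C", "N": "15N"}
    if el not in table:
        raise ValueError(f"cannot infer nucleus from label {atom_label!r}")
    return table[el]


@dataclass
class AssignmentTable:
    """Result of refining solution-state shifts to solid-state peaks."""

    table: pd.DataFrame  # atom_label, nucleus, solution_shift, solid_shift, deviation, status
    counts: dict  # nucleus -> number of assigned sites

    @property
    def max_deviation(self) -> dict:
        """Per-nucleus maximum deviation (ppm) among assigned sites."""
        assigned = self.table[self.table.status == "assigned"]
        return assigned.groupby("nucleus")["deviation"].max().to_dict()


def refine_assignment(solution_shifts, solid_peaks, max_deviation=None):
    """Match solution-state shifts to the nearest solid-state peak.

    Peak positions shift little between solution and solid relative to
    their linewidths, so each assigned solution shift is refined to the
    nearest solid-state peak of the same nucleus; matches farther than
    ``max_deviation`` are flagged unassigned.  Matching is per-site
    independent: several sites may share one solid peak (overlapping
    sites are routinely lumped into a single fitted peak).

    Parameters
    ----------
    solution_shifts : dict
        atom_label -> solution shift (ppm).
    solid_peaks : dict
        nucleus -> list of solid-state peak positions (ppm).
    max_deviation : dict or float, optional
        Per-nucleus (or scalar) acceptance threshold in ppm; defaults
        to 1.0 for 1H and 5.0 for 13C/15N.

    Returns
    -------
    AssignmentTable
    """
    if max_deviation is None:
        max_deviation = dict(DEFAULT_MAX_DEVIATION)
    if np.isscalar(max_deviation):
        max_deviation = {n: float(max_deviation) for n in VALID_NUCLEI}

    rows = []
    counts = {}
    for label, sol in solution_shifts.items():
        nuc = nucleus_of(label)
        peaks = np.asarray(solid_peaks.get(nuc, ()), dtype=float)
        if peaks.size == 0:
            raise ValueError(f"no solid-state peaks supplied for nucleus {nuc}")
        j = int(np.argmin(np.abs(peaks - sol)))
        dev = float(abs(peaks[j] - sol))
        if dev <= max_deviation[nuc]:
            rows.append((label, nuc, sol, float(peaks[j]), dev, "assigned"))
            counts[nuc] = counts.get(nuc, 0) + 1
        else:
            rows.append((label, nuc, sol, np.nan, np.nan, "unassigned"))
            counts.setdefault(nuc, counts.get(nuc, 0))
    table = pd.DataFrame(
        rows,
        columns=["atom_label", "nucleus", "solution_shift", "solid_shift",
                 "deviation", "status"],
    )
    return AssignmentTable(table=table, counts=counts)


# ---------------------------------------------------------------------------
# CSV dialects

def write_distributions(dists, path_or_buf, header_lines=()):
    """Write ShiftDistributions to CSV (lumped_with semicolon separated)."""
    df = pd.DataFrame(
        [
            {
                "atom_label": d.atom_label,
                "nucleus": d.nucleus,
                "mu_ppm": d.mu,
                "sigma_ppm": d.sigma,
                "source": d.source,
                "lumped_with": ";".join(d.lumped_with),
            }
            for d in dists
        ]
    )
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_distributions(path_or_buf):
    """Read a shift-distribution CSV written by :func:`write_distributions`."""
    df = pd.read_csv(path_or_buf, comment="#",
                     dtype={"source": str, "lumped_with": str},
                     keep_default_na=False)
    dists = []
    for _, row in df.iterrows():
        lumped = tuple(s for s in str(row.get("lumped_with", "")).split(";") if s)
        dists.append(
            ShiftDistribution(
                atom_label=row["atom_label"],
                nucleus=row["nucleus"],
                mu=float(row["mu_ppm"]),
                sigma=float(row["sigma_ppm"]),
                source=str(row.get("source", "")),
                lumped_with=lumped,
            )
        )
    return dists


def read_spectrum_slice(path_or_buf):
    """Read a two-column (ppm, intensity) CSV; either axis direction accepted."""
    df = pd.read_csv(path_or_buf, comment="#")
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    inten = df.iloc[:, 1].to_numpy(dtype=float)
    if axis.size > 1 and axis[0] > axis[-1]:
        axis, inten = axis[::-1], inten[::-1]
    return SpectrumSlice(axis=axis, intensity=inten)
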