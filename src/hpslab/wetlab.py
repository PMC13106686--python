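"""Small bespoke computations for the accompanying wet-lab readouts.

Covers the combined 1H/15N chemical shift perturbation of HSQC spectra,
relative cross-peak intensities between two spectra, and single
exponential fitting of background-corrected FRAP recovery curves.
Peak lists are read from simple delimited text (residue, delta_h,
delta_n, intensity); raw spectrometer formats are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def chemical_shift_perturbation(delta_h, delta_n, nitrogen_scale: float = 5.0):
    """Combined amide chemical shift perturbation (ppm).

    delta = sqrt( ((delta_N / s)^2 + delta_H^2) / 2 ) with the nitrogen
    scaling divisor s = 5 by default (appropriate for 1H/15N amide
    pairs; configurable for other nuclei).
    """
    delta_h = np.asarray(delta_h, dtype=float)
    delta_n = np.asarray(delta_n, dtype=float)
    if not (np.all(np.isfinite(delta_h)) and np.all(np.isfinite(delta_n))):
        raise ValueError("shift differences must be finite")
    out = np.sqrt(((delta_n / nitrogen_scale) ** 2 + delta_h**2) / 2.0)
    return out if out.ndim else float(out)


@dataclass
class PeakRecord:
    """One amide cross peak of an HSQC spectrum."""

    residue: int
    delta_h: float = np.nan  # ppm
    delta_n: float = np.nan  # ppm
    intensity: float = np.nan
    present: bool = True

    def __post_init__(self):
        if self.present and not (
                np.isfinite(self.delta_h) and np.isfinite(self.delta_n)):
            raise ValueError(f"residue {self.residue}: present peak with "
                             "non-finite shifts")


def read_peak_table(path: str | Path, sep: str | None = None) -> list[PeakRecord]:
    """Read a peak list from delimited text.

    Columns: residue, delta_h, delta_n, intensity (header required;
    comma or tab delimited, auto-detected unless ``sep`` is given).
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    return [PeakRecord(int(r.residue), float(r.delta_h), float(r.delta_n),
                       float(r.intensity)) for r in df.itertuples(index=False)]


def relative_intensities(reference: list[PeakRecord],
                         perturbed: list[PeakRecord]) -> pd.DataFrame:
    """Per-residue intensity ratios perturbed / reference.

    Peaks absent from either spectrum (or with zero reference intensity)
    are flagged and excluded from the summary mean, never imputed.
    Returns a DataFrame with columns residue, ratio, flag; the mean of
    the unflagged ratios is stored in ``df.attrs['mean_ratio']``.
    """
    ref = {p.residue: p for p in reference}
    per = {p.residue: p for p in perturbed}
    rows = []
    for residue in sorted(set(ref) | set(per)):
        a = ref.get(residue)
        b = per.get(residue)
        if a is None or not a.present or b is None or not b.present:
            rows.append((residue, np.nan, "absent"))
        elif a.intensity == 0:
            rows.append((residue, np.nan, "zero_reference"))
        else:
            rows.append((residue, b.intensity / a.intensity, "ok"))
    df = pd.DataFrame(rows, columns=["residue", "ratio", "flag"])
    ok = df["flag"] == "ok"
    df.attrs["mean_ratio"] = float(df.loc[ok, "ratio"].mean()) if ok.any() else np.nan
    return df


@dataclass
class FrapCurve:
    """A FRAP recording: bleached-ROI and reference-ROI time series."""

    times: np.ndarray  # s
    bleached: np.ndarray  # ROI1 intensities
    reference: np.ndarray  # ROI2 intensities (background/photofade control)
    bleach_index: int | None = None  # first post-bleach sample; auto-detected

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.bleached.shape or \
                self.times.shape != self.reference.shape:
            raise ValueError("times / ROI series length mismatch")

    def corrected(self) -> np.ndarray:
        """Bleached ROI divided by the reference ROI."""
        return self.bleached / self.reference

    def normalized(self):
        """(bleach index, normalized recovery with pre-bleach mean = 1)."""
        corr = self.corrected()
        idx = self.bleach_index
        if idx is None:
            idx = int(np.argmin(np.diff(corr))) + 1  # largest single-step drop
        if idx < 1:
            raise ValueError("no pre-bleach samples")
        baseline = float(corr[:idx].mean())
        return idx, corr / baseline


@dataclass
class FrapFitResult:
    """Single-exponential recovery fit I(t) = I0 + M (1 - exp(-t/tau))."""

    mobile_fraction: float
    recovery_tau: float  # s
    bleach_floor: float  # I0
    amplitude: float  # M
    se_tau: float = np.nan
    se_mobile_fraction: float = np.nan
    converged: bool = True


def frap_fit(curve: FrapCurve) -> FrapFitResult:
    """Fit the background-corrected, normalized recovery curve.

    The post-bleach signal is fitted with I(t) = I0 + M (1 - e^(-t/tau));
    the mobile fraction is (plateau - bleach floor) / (1 - bleach floor)
    = M / (1 - I0).  Invariant to affine rescaling of the raw
    intensities because of the reference-ROI correction and pre-bleach
    normalization.
    """
    idx, norm = curve.normalized()
    post = norm[idx:]
    if post.size < 10:
        raise ValueError("need at least 10 post-bleach points")
    t = curve.times[idx:] - curve.times[idx]

    def model(tt, i0, m, tau):
        return i0 + m * (1.0 - np.exp(-tt / tau))

    i0_guess = float(post[0])
    m_guess = max(float(post[-1] - post[0]), 1e-6)
    tau_guess = max(float(t[-1]) / 5.0, float(t[1]) if t.size > 1 else 1.0)
    try:
        popt, pcov = curve_fit(
            model, t, post, p0=[i0_guess, m_guess, tau_guess],
            bounds=([-0.5, 0.0, 1e-9], [1.5, 2.0, np.inf]), maxfev=20000)
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return FrapFitResult(np.nan, np.nan, np.nan, np.nan, converged=False)
    i0, m, tau = popt
    se = np.sqrt(np.abs(np.diag(pcov)))
    denom = 1.0 - i0
    mobile = m / denom if abs(denom) > 1e-9 else np.nan
    # first-order error propagation for M / (1 - I0)
    se_mobile = np.nan
    if np.isfinite(mobile):
        dm = 1.0 / denom
        di0 = m / denom**2
        se_mobile = float(np.sqrt((dm * se[1]) ** 2 + (di0 * se[0]) ** 2))
    return FrapFitResult(
        mobile_fraction=float(mobile),
        recovery_tau=float(tau),
        bleach_floor=float(i0),
        amplitude=float(m),
        se_tau=float(se[2]),
        se_mobile_fraction=se_mobile,
        converged=converged,
    )
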