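"""Reflectance spectra and colour metrics.

A feather's reflectance spectrum R(lambda), expressed as percent of a white
standard, carries the three colour metrics used throughout the plumage
analysis:

* hue (lambda_R50): the wavelength at which reflectance is halfway between
  its mid-wavelength minimum and its long-wavelength maximum on [450, 700] nm
  -- higher values mean redder feathers;
* mean brightness: the arithmetic mean reflectance over [400, 700] nm;
* carotenoid chroma: (R700 - R450) / R700, a saturation proxy for
  carotenoid-absorbing spectra.

Spectra are measured in replicates per sample; replicates are averaged
pointwise before metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

HUE_RANGE_NM = (450.0, 700.0)
BRIGHTNESS_RANGE_NM = (400.0, 700.0)
CHROMA_WAVELENGTHS_NM = (450.0, 700.0)


class UndefinedMetricError(ValueError):
    """Raised when a colour metric is undefined for a spectrum (e.g. flat
    spectrum for hue, zero R700 for chroma)."""


@dataclass(frozen=True)
class Spectrum:
    """One reflectance curve on an ascending wavelength grid."""

    wavelengths_nm: np.ndarray
    reflectance_pct: np.ndarray
    sample_id: str
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        rf = np.asarray(self.reflectance_pct, dtype=float)
        if wl.ndim != 1 or rf.shape != wl.shape:
            raise ValueError("wavelengths and reflectance must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("spectrum needs at least two points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError(
                f"wavelengths must be strictly increasing "
                f"(sample={self.sample_id}, replicate={self.replicate_id})"
            )
        if np.any(~np.isfinite(rf)):
            raise ValueError("non-finite reflectance values")
        if np.any(rf < 0):
            raise ValueError("negative reflectance values are not allowed")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance_pct", rf)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths_nm[0] <= lo and self.wavelengths_nm[-1] >= hi

    def interp(self, wavelengths: np.ndarray) -> np.ndarray:
        """Linear interpolation of reflectance at the given wavelengths."""
        return np.interp(np.asarray(wavelengths, dtype=float),
                         self.wavelengths_nm, self.reflectance_pct)


@dataclass(frozen=True)
class ColourMetrics:
    """Per-sample colour metrics; hue/chroma are None when undefined."""

    sample_id: str
    hue_r50_nm: float | None
    mean_brightness_pct: float
    carotenoid_chroma: float | None
    multiple_hue_crossings: bool = False


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def read_spectra(path, dialect: str = "long") -> list[Spectrum]:
    """Read spectra from CSV.

    ``long`` dialect: columns sample, replicate, wavelength, reflectance.
    ``wide`` dialect: one wavelength column (first column, or named ``wl`` /
    ``wavelength``) and one reflectance column per (sample, replicate) named
    ``<sample>_<replicate>`` (a column without ``_`` becomes replicate "1").
    """
    df = pd.read_csv(path)
    if dialect == "long":
        required = {"sample", "replicate", "wavelength", "reflectance"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long-format spectra CSV missing columns: {sorted(missing)}")
        out = []
        for (sample, rep), grp in df.groupby(["sample", "replicate"], sort=True):
            grp = grp.sort_values("wavelength")
            wl = grp["wavelength"].to_numpy(dtype=float)
            if np.unique(wl).size != wl.size:
                raise ValueError(f"duplicated wavelength in sample={sample} replicate={rep}")
            out.append(Spectrum(wl, grp["reflectance"].to_numpy(dtype=float),
                                str(sample), str(rep)))
        return out
    if dialect == "wide":
        cols = list(df.columns)
        wl_col = next((c for c in cols if c.lower() in ("wl", "wavelength")), cols[0])
        wl = pd.to_numeric(df[wl_col], errors="raise").to_numpy(dtype=float)
        if np.unique(wl).size != wl.size:
            raise ValueError("duplicated wavelength in wide-format spectra CSV")
        order = np.argsort(wl)
        out = []
        for c in cols:
            if c == wl_col:
                continue
            sample, _, rep = c.rpartition("_")
            if not sample:
                sample, rep = c, "1"
            refl = pd.to_numeric(df[c], errors="raise").to_numpy(dtype=float)
            out.append(Spectrum(wl[order], refl[order], sample, rep))
        return out
    raise ValueError(f"unknown spectra dialect: {dialect!r}")


def average_replicates(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra of one sample.

    Replicates on different grids are linearly resampled to a common 1-nm
    grid on the intersection of their wavelength ranges.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    ids = {s.sample_id for s in spectra}
    if len(ids) != 1:
        raise ValueError(f"replicates from different samples: {sorted(ids)}")
    grids = [s.wavelengths_nm for s in spectra]
    if all(np.array_equal(g, grids[0]) for g in grids[1:]):
        common = grids[0]
    else:
        lo = max(g[0] for g in grids)
        hi = min(g[-1] for g in grids)
        if lo >= hi:
            raise ValueError("replicate wavelength ranges do not overlap")
        common = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    mean = np.mean([s.interp(common) for s in spectra], axis=0)
    return Spectrum(common, mean, spectra[0].sample_id, "mean")


def boxcar_smooth(s: Spectrum, width: int) -> Spectrum:
    """Optional boxcar smoothing (off by default in the pipeline)."""
    if width <= 1:
        return s
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(s.reflectance_pct, pad, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="same")[pad:pad + s.reflectance_pct.size]
    return replace(s, reflectance_pct=smoothed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def hue_lambda_r50(s: Spectrum, *, return_flags: bool = False):
    """Hue as the half-rise wavelength lambda_R50 on [450, 700] nm.

    Finds the long-wavelength maximum (smallest wavelength on ties), the
    minimum to its left, and returns the first wavelength at which the
    spectrum crosses the midpoint of the two, linearly interpolated between
    grid points. Raises :class:`UndefinedMetricError` on a flat spectrum.
    """
    lo, hi = HUE_RANGE_NM
    if not s.covers(lo, hi):
        raise ValueError(f"spectrum does not cover [{lo:g}, {hi:g}] nm")
    mask = (s.wavelengths_nm >= lo) & (s.wavelengths_nm <= hi)
    wl = s.wavelengths_nm[mask]
    rf = s.reflectance_pct[mask]
    i_max = int(np.argmax(rf))                       # argmax keeps first on ties
    r_max = rf[i_max]
    i_min = int(np.argmin(rf[: i_max + 1]))
    r_min = rf[i_min]
    if r_max <= r_min:
        raise UndefinedMetricError(
            f"flat or non-rising spectrum: hue undefined (sample={s.sample_id})")
    target = 0.5 * (r_min + r_max)

    seg_wl = wl[i_min: i_max + 1]
    seg_rf = rf[i_min: i_max + 1]
    above = seg_rf >= target
    crossings = np.flatnonzero(~above[:-1] & above[1:])
    if above[0]:
        hue = float(seg_wl[0])
        n_cross = 1 + crossings.size
    else:
        if crossings.size == 0:       # target touched exactly at the max only
            hue = float(seg_wl[-1])
            n_cross = 1
        else:
            j = crossings[0]
            x0, x1 = seg_wl[j], seg_wl[j + 1]
            y0, y1 = seg_rf[j], seg_rf[j + 1]
            hue = float(x0 + (target - y0) * (x1 - x0) / (y1 - y0))
            n_cross = crossings.size
    if return_flags:
        return hue, n_cross > 1
    return hue


def mean_brightness(s: Spectrum) -> float:
    """Mean reflectance at grid points within [400, 700] nm inclusive."""
    lo, hi = BRIGHTNESS_RANGE_NM
    if not s.covers(lo, hi):
        raise ValueError(f"spectrum does not cover [{lo:g}, {hi:g}] nm")
    mask = (s.wavelengths_nm >= lo) & (s.wavelengths_nm <= hi)
    wl = s.wavelengths_nm[mask]
    step = np.median(np.diff(s.wavelengths_nm))
    if np.max(np.diff(wl)) > 2 * step:
        raise ValueError("coverage gap inside [400, 700] nm")
    return float(np.mean(s.reflectance_pct[mask]))


def carotenoid_chroma(s: Spectrum) -> float:
    """(R700 - R450) / R700, interpolating R at 450 and 700 nm if needed."""
    w450, w700 = CHROMA_WAVELENGTHS_NM
    if not s.covers(w450, w700):
        raise ValueError("spectrum does not cover 450 and 700 nm")
    r450, r700 = s.interp([w450, w700])
    if r700 <= 0:
        raise UndefinedMetricError(f"R700 = 0: chroma undefined (sample={s.sample_id})")
    return float((r700 - r450) / r700)


def colour_metrics(s: Spectrum) -> ColourMetrics:
    """All three metrics for one (usually replicate-averaged) spectrum."""
    try:
        hue, multi = hue_lambda_r50(s, return_flags=True)
    except UndefinedMetricError:
        hue, multi = None, False
    try:
        chroma = carotenoid_chroma(s)
    except UndefinedMetricError:
        chroma = None
    return ColourMetrics(s.sample_id, hue, mean_brightness(s), chroma, multi)


def metrics_per_sample(spectra: list[Spectrum]) -> pd.DataFrame:
    """Average replicates per sample, compute metrics, return a tidy table."""
    rows = []
    by_sample: dict[str, list[Spectrum]] = {}
    for s in spectra:
        by_sample.setdefault(s.sample_id, []).append(s)
    for sample_id in sorted(by_sample):
        m = colour_metrics(average_replicates(by_sample[sample_id]))
        rows.append({
            "sample_id": sample_id,
            "hue_r50_nm": m.hue_r50_nm,
            "mean_brightness_pct": m.mean_brightness_pct,
            "carotenoid_chroma": m.carotenoid_chroma,
            "multiple_hue_crossings": m.multiple_hue_crossings,
        })
    return pd.DataFrame(rows)


def summarize_colour_by_group(metrics: pd.DataFrame, groups: dict[str, str],
                              ci_level: float = 0.95) -> pd.DataFrame:
    """Per-group mean and normal-theory CI (mean +/- t_{n-1} * SE) per metric.

    Groups of size 1 get the mean with CI columns set to NaN.
    """
    unknown = set(metrics["sample_id"]) - set(groups)
    if unknown:
        raise ValueError(f"samples without a group label: {sorted(unknown)}")
    df = metrics.copy()
    df["group"] = df["sample_id"].map(groups)
    value_cols = [c for c in ("hue_r50_nm", "mean_brightness_pct", "carotenoid_chroma")
                  if c in df.columns]
    rows = []
    for group, grp in df.groupby("group", sort=True):
        for col in value_cols:
            vals = grp[col].dropna().to_numpy(dtype=float)
            n = vals.size
            if n == 0:
                continue
            mean = float(np.mean(vals))
            if n >= 2:
                se = float(np.std(vals, ddof=1) / np.sqrt(n))
                tq = float(sps.t.ppf(0.5 + ci_level / 2, df=n - 1))
                lo, hi = mean - tq * se, mean + tq * se
            else:
                lo = hi = np.nan
            rows.append({"group": group, "metric": col, "n": n,
                         "mean": mean, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
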