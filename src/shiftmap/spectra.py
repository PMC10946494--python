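"""Minimal 1D spectrum handling.

Enough spectrum plumbing to turn a 1D trace into shift-table entries: reading
two-column text or JCAMP-DX, rigid reference calibration, prominence-based
peak picking at 4-decimal ppm, and multiplet centering (the recorded position
of a multiplet is the mean ppm of its components).

This is deliberately not a processing suite: no phasing, baseline correction
or solvent suppression — spectra are expected to arrive already processed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .table import quantize_ppm

__all__ = [
    "Spectrum1D",
    "Peak",
    "PeakList",
    "SpectrumError",
    "read_xy",
    "read_jcamp",
    "pick_peaks",
    "calibrate",
    "multiplet_center",
]


class SpectrumError(ValueError):
    pass


@dataclass
class Spectrum1D:
    """A processed 1D spectrum: strictly monotone ppm axis + intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise SpectrumError("ppm and intensity must be 1-D and equally long")
        if self.ppm.size < 2:
            raise SpectrumError("need at least 2 points")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise SpectrumError("ppm axis must be strictly monotone")

    @property
    def descending(self) -> bool:
        return bool(self.ppm[0] > self.ppm[-1])


@dataclass(frozen=True)
class Peak:
    ppm: float
    intensity: float
    prominence: float


@dataclass
class PeakList:
    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def ppms(self) -> list[float]:
        return [p.ppm for p in self.peaks]


# ---- readers -----------------------------------------------------------


def read_xy(path: str | Path, meta: dict | None = None) -> Spectrum1D:
    """Read a two-column ppm / intensity text file (whitespace or tab)."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise SpectrumError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum1D(data[:, 0], data[:, 1], meta=dict(meta or {}))


_LDR = re.compile(r"^##(.+?)=\s*(.*)$")


def read_jcamp(path: str | Path) -> Spectrum1D:
    """Read a JCAMP-DX 1D spectrum (``##XYDATA=(X++(Y..Y))``, AFFN/fixed form).

    Supports the plain-number variant of XYDATA where each line starts with an
    X value followed by one or more Y values; X/Y factors, FIRSTX/LASTX and
    NPOINTS labelled-data records are honoured. Compressed forms (SQZ/DIF/DUP)
    are not supported.
    """
    labels: dict[str, str] = {}
    ydata: list[float] = []
    in_xydata = False
    with open(path, encoding="utf-8", errors="replace") as fh:
        for raw in fh:
            line = raw.split("$$")[0].rstrip()
            if not line:
                continue
            m = _LDR.match(line)
            if m:
                key = m.group(1).strip().upper().replace(" ", "")
                val = m.group(2).strip()
                if key == "XYDATA":
                    in_xydata = True
                    continue
                if in_xydata:  # any new LDR ends the data block
                    in_xydata = False
                labels[key] = val
                continue
            if in_xydata:
                parts = line.replace(",", " ").split()
                try:
                    nums = [float(p) for p in parts]
                except ValueError as exc:
                    raise SpectrumError(
                        f"{path}: unsupported XYDATA encoding near {line!r} "
                        "(only AFFN/fixed numeric form is handled)"
                    ) from exc
                ydata.extend(nums[1:])  # first number on each line is X

    if not ydata:
        raise SpectrumError(f"{path}: no XYDATA block found")

    def _get(key: str, default: float | None = None) -> float:
        if key in labels:
            return float(labels[key])
        if default is None:
            raise SpectrumError(f"{path}: missing ##{key}=")
        return default

    firstx = _get("FIRSTX")
    lastx = _get("LASTX")
    npoints = int(_get("NPOINTS", len(ydata)))
    xfactor = _get("XFACTOR", 1.0)
    yfactor = _get("YFACTOR", 1.0)
    if npoints != len(ydata):
        raise SpectrumError(
            f"{path}: NPOINTS={npoints} but {len(ydata)} Y values read"
        )
    ppm = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    intensity = np.asarray(ydata) * yfactor
    meta = {"title": labels.get("TITLE", ""), "xunits": labels.get("XUNITS", "PPM")}
    return Spectrum1D(ppm, intensity, meta=meta)


# ---- operations --------------------------------------------------------


def pick_peaks(
    s: Spectrum1D,
    min_prominence: float = 0.05,
    window: tuple[float, float] | None = None,
) -> PeakList:
    """Local maxima within a ppm window, thresholded by topographic prominence.

    ``min_prominence`` is a fraction of the maximum intensity *inside the
    window* (so crowded and sparse regions use comparable thresholds). Peak
    positions are the axis values at the sampled maxima, reported to 4
    decimals and sorted by descending intensity. A flat window yields an
    empty list.
    """
    if not 0.0 < min_prominence <= 1.0:
        raise SpectrumError("min_prominence must be in (0, 1]")
    lo, hi = (float(np.min(s.ppm)), float(np.max(s.ppm))) if window is None else (
        min(window), max(window))
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if mask.sum() < 3:
        raise SpectrumError(f"window ({lo}, {hi}) ppm does not overlap the axis")
    ppm = s.ppm[mask]
    y = s.intensity[mask]
    span = float(np.max(y) - np.min(y))
    if span == 0.0:
        return PeakList([])
    threshold = min_prominence * float(np.max(y))
    idx, props = find_peaks(y, prominence=threshold)
    peaks = [
        Peak(quantize_ppm(float(ppm[i]), 4), float(y[i]), float(prom))
        for i, prom in zip(idx, props["prominences"])
    ]
    peaks.sort(key=lambda p: (-p.intensity, p.ppm))
    return PeakList(peaks)


def calibrate(
    s: Spectrum1D, observed_ref_ppm: float, target_ref_ppm: float
) -> Spectrum1D:
    """Rigidly shift the ppm axis so the observed reference lands on target.

    Standard usage: calibrate to the glucose anomeric doublet (5.243 ppm) or
    TMSP (0 ppm). The whole axis moves by ``target - observed``; intensities
    are untouched, so all pairwise ppm differences are preserved exactly.
    A shift larger than 0.5 ppm is suspicious (wrong reference picked) and is
    flagged with a warning but still applied.
    """
    lo, hi = float(np.min(s.ppm)) - 1.0, float(np.max(s.ppm)) + 1.0
    for name, v in (("observed", observed_ref_ppm), ("target", target_ref_ppm)):
        if not lo <= v <= hi:
            raise SpectrumError(
                f"{name} reference {v} ppm outside axis range +/- 1 ppm"
            )
    shift = target_ref_ppm - observed_ref_ppm
    if abs(shift) > 0.5:
        warnings.warn(
            f"calibration shift {shift:+.4f} ppm exceeds 0.5 ppm - "
            "check the reference assignment", stacklevel=2,
        )
    return Spectrum1D(s.ppm + shift, s.intensity.copy(), meta=dict(s.meta))


def multiplet_center(component_ppms: list[float], precision: int = 4) -> float:
    """Recorded position of a multiplet: the mean ppm of its components.

    For a singlet this is the identity; for a symmetric multiplet it is the
    central position. Partially overlapped multiplets must be resolved by the
    caller (e.g. via J-coupling arithmetic) before averaging — only visible
    components should be passed.
    """
    if len(component_ppms) == 0:
        raise SpectrumError("multiplet_center needs at least one component")
    if len(component_ppms) > 16:
        raise SpectrumError("more than 16 components is not a multiplet")
    return quantize_ppm(float(np.mean(component_ppms)), precision)
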