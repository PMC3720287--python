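"""Chromatogram correction, peak detection and cross-sample alignment.

A chromatogram is a 1-D intensity trace over retention time. Before
multivariate analysis the traces must be "corrected": instrumental noise
smoothed out, baseline drift removed, peaks detected and quantified, and
retention-time variation between samples removed by aligning per-sample
peak lists into a samples x consensus-peaks height matrix.

HPTLC lane densitograms are handled by the same code path, with the
retention coordinate interpreted as the relative front (Rf) instead of
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d

TECHNIQUES = ("HPTLC", "LC-PDA", "LC-MS", "synthetic")

__all__ = [
    "Chromatogram",
    "PeakList",
    "AlignedPeakMatrix",
    "smooth",
    "correct_baseline",
    "estimate_noise",
    "detect_peaks",
    "align_peaks",
    "peak_count_summary",
    "TECHNIQUES",
]


@dataclass
class Chromatogram:
    """One sample's retention-time grid and intensity trace.

    Parameters
    ----------
    rt : array
        Strictly increasing retention times (minutes; Rf for HPTLC).
    intensity : array
        Intensity trace in arbitrary units, same length as ``rt``.
    sample_id : str
        Sample identifier.
    technique : str
        One of ``TECHNIQUES``.
    group : str or None
        Optional group label (e.g. phytogeographic origin).
    """

    rt: np.ndarray
    intensity: np.ndarray
    sample_id: str
    technique: str = "synthetic"
    group: str | None = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("rt and intensity must be 1-D")
        if self.rt.size != self.intensity.size:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size < 8:
            raise ValueError("chromatogram needs at least 8 points")
        if np.any(np.diff(self.rt) <= 0):
            raise ValueError("rt must be strictly increasing")
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")

    def replace_intensity(self, intensity: np.ndarray) -> "Chromatogram":
        return Chromatogram(self.rt, intensity, self.sample_id, self.technique, self.group)


@dataclass
class PeakList:
    """Detected peaks of one chromatogram, sorted by apex retention time."""

    apex_rt: np.ndarray
    height: np.ndarray
    snr: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.apex_rt = np.asarray(self.apex_rt, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (self.apex_rt.size == self.height.size == self.snr.size):
            raise ValueError("apex_rt, height, snr must have equal length")
        if np.any(np.diff(self.apex_rt) < 0):
            raise ValueError("apexes must be sorted by rt")
        if np.any(self.height <= 0):
            raise ValueError("peak heights must be positive")

    def __len__(self) -> int:
        return int(self.apex_rt.size)


@dataclass
class AlignedPeakMatrix:
    """Samples x consensus-peaks height matrix after retention-time alignment.

    A zero entry means the peak was not detected in that sample.
    """

    heights: np.ndarray
    consensus_rt: np.ndarray
    sample_ids: list[str]
    technique: str = "synthetic"

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.consensus_rt = np.asarray(self.consensus_rt, dtype=float)
        if self.heights.shape != (len(self.sample_ids), self.consensus_rt.size):
            raise ValueError("heights shape must be (n_samples, n_consensus_peaks)")
        if np.any(np.diff(self.consensus_rt) < 0):
            raise ValueError("consensus_rt must be sorted")
        if self.consensus_rt.size and np.any((self.heights > 0).sum(axis=0) == 0):
            raise ValueError("every consensus column needs at least one detection")

    @property
    def n_peaks(self) -> int:
        return int(self.consensus_rt.size)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"rt_{t:.4f}" for t in self.consensus_rt]
        return pd.DataFrame(self.heights, index=self.sample_ids, columns=cols)


def smooth(c: Chromatogram, window: int = 5) -> Chromatogram:
    """Centered moving-average smoothing; ends use a shrunken window.

    ``window`` must be odd and no longer than the trace; ``window=1`` is the
    identity. Near the ends the window shrinks symmetrically so the average
    stays centered.
    """
    n = c.intensity.size
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 1 or window > n:
        raise ValueError("window must be in [1, trace length]")
    if window == 1:
        return c.replace_intensity(c.intensity.copy())
    r = window // 2
    idx = np.arange(n)
    radius = np.minimum(r, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate([[0.0], np.cumsum(c.intensity)])
    lo = idx - radius
    hi = idx + radius
    out = (csum[hi + 1] - csum[lo]) / (2 * radius + 1)
    return c.replace_intensity(out)


def correct_baseline(
    c: Chromatogram,
    window_fraction: float = 0.10,
    clip_negative: bool = False,
) -> Chromatogram:
    """Subtract a smoothed rolling-minimum baseline envelope.

    The envelope is the rolling minimum over a window of
    ``window_fraction`` of the trace length, smoothed with a moving average
    of the same width so peak-shaped dips do not leave steps. Residuals may
    be slightly negative (noise scale); ``clip_negative`` clips them at 0.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    n = c.intensity.size
    w = max(3, int(round(window_fraction * n)))
    envelope = minimum_filter1d(c.intensity, size=w, mode="nearest")
    envelope = uniform_filter1d(envelope, size=w, mode="nearest")
    out = c.intensity - envelope
    if clip_negative:
        out = np.clip(out, 0.0, None)
    return c.replace_intensity(out)


def estimate_noise(intensity: np.ndarray) -> float:
    """Robust noise scale: MAD of first differences, Gaussian-consistent.

    First differences suppress slowly varying signal (peaks, residual
    baseline); the median absolute difference is insensitive to the sparse
    large differences on peak flanks. For i.i.d. Gaussian noise of sd s the
    differences have sd s*sqrt(2), hence the 1/sqrt(2) factor; 1.4826 makes
    the MAD consistent for the Gaussian sd.
    """
    d = np.diff(np.asarray(intensity, dtype=float))
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def _parabolic_apex(rt: np.ndarray, y: np.ndarray, i: int) -> float:
    """Refine apex position by a parabola through (i-1, i, i+1)."""
    if i == 0 or i == y.size - 1:
        return float(rt[i])
    x0, x1, x2 = rt[i - 1], rt[i], rt[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom == 0:
        return float(x1)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # not concave; keep grid apex
        return float(x1)
    vertex = -b / (2 * a)
    # keep the refinement inside the bracketing interval
    return float(min(max(vertex, x0), x2))


def detect_peaks(
    c: Chromatogram,
    snr_min: float = 3.0,
    min_separation: float = 0.1,
    noise: float | None = None,
) -> PeakList:
    """Detect peaks as strict local maxima above an SNR threshold.

    The trace is assumed baseline-corrected. Noise defaults to
    :func:`estimate_noise` of the input; maxima with height < ``snr_min``
    x noise are discarded; surviving maxima closer than
    ``min_separation`` (in rt units) are merged keeping the taller; apex
    rt is refined by 3-point parabolic interpolation. An all-zero trace
    yields an empty PeakList.

    The default estimator assumes uncorrelated noise. On a smoothed
    trace first differences shrink much faster than the noise itself, so
    when detecting after smoothing pass ``noise`` estimated from the
    unsmoothed trace.
    """
    y = c.intensity
    if noise is None:
        noise = estimate_noise(y)
    interior = np.arange(1, y.size - 1)
    is_max = (y[interior] > y[interior - 1]) & (y[interior] > y[interior + 1])
    cand = interior[is_max]
    threshold = snr_min * noise
    cand = cand[(y[cand] >= threshold) & (y[cand] > 0)]
    if cand.size == 0:
        return PeakList(np.empty(0), np.empty(0), np.empty(0), c.sample_id)
    # merge near-coincident maxima, tallest first
    order = cand[np.argsort(-y[cand], kind="stable")]
    kept: list[int] = []
    for i in order:
        if all(abs(c.rt[i] - c.rt[j]) >= min_separation for j in kept):
            kept.append(i)
    kept_arr = np.array(sorted(kept))
    apex = np.array([_parabolic_apex(c.rt, y, i) for i in kept_arr])
    height = y[kept_arr]
    snr = height / noise if noise > 0 else np.full(height.shape, np.inf)
    srt = np.argsort(apex, kind="stable")
    return PeakList(apex[srt], height[srt], snr[srt], c.sample_id)


def align_peaks(
    lists: Sequence[PeakList] | Mapping[str, PeakList],
    rt_tol: float = 0.2,
    technique: str = "synthetic",
) -> AlignedPeakMatrix:
    """Greedy single-linkage alignment of peak lists into consensus columns.

    All apexes are pooled and visited in descending height order. An apex
    joins the nearest existing consensus column iff it lies within
    ``rt_tol`` of the column's running-median rt and its sample is not
    already represented there; otherwise it founds a new column. Undetected
    entries are encoded as 0.
    """
    if isinstance(lists, Mapping):
        items = list(lists.items())
    else:
        items = [(pl.sample_id or f"sample_{i}", pl) for i, pl in enumerate(lists)]
    if not items:
        raise ValueError("no peak lists to align")
    sample_ids = [sid for sid, _ in items]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")

    records = []  # (height, rt, sample_index)
    for si, (_, pl) in enumerate(items):
        for rt, h in zip(pl.apex_rt, pl.height):
            records.append((float(h), float(rt), si))
    # tallest first; ties broken by rt then sample index for determinism
    records.sort(key=lambda r: (-r[0], r[1], r[2]))

    columns: list[dict] = []  # {"rts": [..], "members": {si: (rt, h)}, "med": float}
    for h, rt, si in records:
        best = None
        best_dist = rt_tol
        for col in columns:
            if si in col["members"]:
                continue
            d = abs(rt - col["med"])
            if d <= best_dist:
                best, best_dist = col, d
        if best is None:
            columns.append({"rts": [rt], "members": {si: (rt, h)}, "med": rt})
        else:
            best["rts"].append(rt)
            best["members"][si] = (rt, h)
            best["med"] = float(np.median(best["rts"]))

    columns.sort(key=lambda col: col["med"])
    heights = np.zeros((len(items), len(columns)))
    consensus = np.array([col["med"] for col in columns])
    for j, col in enumerate(columns):
        for si, (_, h) in col["members"].items():
            heights[si, j] = h
    # sorting by running median can, in principle, leave adjacent columns
    # out of order relative to their final medians; enforce order
    srt = np.argsort(consensus, kind="stable")
    return AlignedPeakMatrix(heights[:, srt], consensus[srt], sample_ids, technique)


def peak_count_summary(
    peaklists_by_technique: Mapping[str, Sequence[PeakList]],
) -> pd.DataFrame:
    """Mean +/- sample sd of per-sample detected-peak counts per technique.

    A technique with a single sample reports sd 0 and ``single_sample``
    True so the degenerate case is visible downstream.
    """
    rows = []
    for tech, pls in peaklists_by_technique.items():
        counts = np.array([len(pl) for pl in pls], dtype=float)
        if counts.size == 0:
            raise ValueError(f"no peak lists for technique {tech!r}")
        single = counts.size == 1
        rows.append(
            {
                "technique": tech,
                "n_samples": int(counts.size),
                "mean_peaks": float(counts.mean()),
                "sd_peaks": 0.0 if single else float(counts.std(ddof=1)),
                "single_sample": single,
            }
        )
    return pd.DataFrame(rows).set_index("technique")
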