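"""Baseline correction, peak detection, integration and cross-run matching.

The processing chain turns the five chromatograms of a screen (blank,
experimental, one probe-blocked control per target) into per-compound
area triples (A_a, A_b, A_c per target) that feed the S/N and S-S/N
ratios.

Baseline model: morphological opening (rolling minimum then rolling
maximum) followed by a rolling mean, all over the same window, on a
lightly pre-smoothed trace.  The minimum ignores sparse peaks, the
maximum undoes the half-window lag the minimum leaves on drifting
baselines, and the mean smooths the remaining staircase.  The filters
sit slightly below the noise centre; peak integration therefore
subtracts a per-peak local offset measured in guarded flanking
windows, keeping each peak's area a function of its own neighbourhood
only.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks
from scipy.stats import trim_mean

from .chrom_model import Chromatogram, Peak, PeakTable, ScreenDesign, ValidationError

__all__ = [
    "CompoundPanel",
    "PeakAreaTriple",
    "estimate_baseline",
    "estimate_noise",
    "detect_peaks",
    "integrate_peak",
    "match_peaks",
    "read_panel",
    "write_panel",
    "triples_to_frame",
    "DEFAULT_WINDOW",
    "DEFAULT_MIN_SNR",
    "DEFAULT_RT_TOLERANCE",
]

DEFAULT_WINDOW = 2.0  # baseline window, minutes
DEFAULT_MIN_SNR = 5.0  # detection threshold in noise-sd units
DEFAULT_RT_TOLERANCE = 0.2  # cross-run matching tolerance, minutes

#: samples in the pre-detection moving average
_SMOOTH_SAMPLES = 5


@dataclass(frozen=True)
class CompoundPanel:
    """Compounds to quantify, identified by reference retention time."""

    compounds: tuple[tuple[str, float], ...]  # (compound_id, reference_rt)
    rt_tolerance: float = DEFAULT_RT_TOLERANCE

    def __post_init__(self):
        object.__setattr__(self, "compounds", tuple(tuple(c) for c in self.compounds))
        if self.rt_tolerance <= 0:
            raise ValidationError("rt_tolerance must be positive")
        ids = [c for c, _ in self.compounds]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate compound_id in panel")
        rts = sorted(rt for _, rt in self.compounds)
        for a, b in zip(rts, rts[1:]):
            if b - a < 2 * self.rt_tolerance - 1e-12:
                raise ValidationError(
                    f"reference RTs {a} and {b} closer than twice the "
                    f"matching tolerance ({self.rt_tolerance} min)"
                )


@dataclass(frozen=True)
class PeakAreaTriple:
    """Areas of one compound across the three conditions.

    ``A_a``: experimental run; ``A_b``: blank run; ``A_c_by_target``:
    the probe-blocked control run of each target.  A compound absent
    from a run contributes area 0.
    """

    compound_id: str
    A_a: float
    A_b: float
    A_c_by_target: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "A_c_by_target", dict(self.A_c_by_target))
        areas = [self.A_a, self.A_b, *self.A_c_by_target.values()]
        if any(a < 0 for a in areas):
            raise ValidationError("peak areas must be non-negative")


def _window_samples(chrom: Chromatogram, window: float) -> int:
    dt = chrom.sampling_interval
    n = int(round(window / dt))
    if window <= 0 or window >= chrom.time[-1] - chrom.time[0]:
        raise ValueError("window must be positive and shorter than the run")
    if n < 3:
        raise ValueError(
            f"window {window} min spans fewer than 3 sampling intervals ({dt} min)"
        )
    return n


def estimate_baseline(
    chrom: Chromatogram, window: float = DEFAULT_WINDOW
) -> np.ndarray:
    """Estimate the slow baseline under a chromatogram.

    Morphological opening (rolling minimum then rolling maximum) and a
    rolling mean, all over ``window`` minutes.  Exact for constant
    signals, tracks linear drift to within filter edge effects, and
    passes under peaks narrower than the window.  On noisy traces the
    estimate sits slightly below the noise centre (the floor rides the
    smoothed noise minima); downstream integration corrects for this
    locally per peak.
    """
    n = _window_samples(chrom, window)
    # Pad by odd reflection so every filter sees a linear continuation
    # of the trace at the run edges: drift is tracked without the
    # half-window edge lag that constant padding would leave.
    sig = np.pad(chrom.signal, n, mode="reflect", reflect_type="odd")
    # Take the floor on a pre-smoothed trace: on the raw signal the
    # rolling minimum rides the extremes of the noise, and wherever a
    # peak covers part of the window fewer noise samples remain to set
    # the floor, lifting the baseline under exactly the peaks being
    # integrated.  Smoothing over window/8 shrinks that lift ~5-fold.
    pre = uniform_filter1d(sig, size=max(3, n // 8), mode="nearest")
    # Morphological opening (rolling minimum, then rolling maximum over
    # the same window) erases peaks narrower than the window but tracks
    # linear drift without the half-window lag a bare minimum leaves;
    # the rolling mean smooths the remaining staircase.  Every step is
    # local to +-1.5 windows, so the baseline under a peak never
    # depends on what other peaks elsewhere in the run are doing.
    floor = minimum_filter1d(pre, size=n, mode="nearest")
    opened = maximum_filter1d(floor, size=n, mode="nearest")
    return uniform_filter1d(opened, size=n, mode="nearest")[n:-n]


def estimate_noise(residual: np.ndarray) -> float:
    """Robust noise scale of a baseline-subtracted trace, in mAU.

    Median absolute first difference scaled to the standard deviation
    of Gaussian noise: ``1.4826 * median(|diff|) / sqrt(2)``.  First
    differences suppress the slow peak component, so sparse peaks
    barely move the estimate.
    """
    residual = np.asarray(residual, dtype=float)
    if residual.size < 10:
        raise ValueError("need at least 10 samples to estimate noise")
    return float(1.4826 * np.median(np.abs(np.diff(residual))) / np.sqrt(2.0))


def _walk_to_bound(smooth: np.ndarray, apex: int, noise_sd: float, step: int) -> int:
    """Walk from the apex until the trace drops into the noise floor
    (below 1x noise-sd) or passes a flanking local minimum, whichever
    comes first.  A sample only counts as a local minimum once the
    trace has climbed more than one noise-sd back out of it, so the
    noise-scale upticks on a peak's flank do not truncate the bound."""
    i = apex
    min_i = apex
    min_v = smooth[apex]
    last = smooth.size - 1
    while 0 < i < last:
        i += step
        v = smooth[i]
        if v < noise_sd:
            return i
        if v < min_v:
            min_i, min_v = i, v
        elif v - min_v > noise_sd:
            return min_i
    return i


def _peak_bounds(smooth: np.ndarray, apex: int, noise_sd: float) -> tuple[int, int]:
    lo = _walk_to_bound(smooth, apex, noise_sd, -1)
    hi = _walk_to_bound(smooth, apex, noise_sd, +1)
    return lo, hi


def detect_peaks(
    chrom: Chromatogram,
    min_snr: float = DEFAULT_MIN_SNR,
    window: float = DEFAULT_WINDOW,
) -> PeakTable:
    """Detect and integrate peaks in one chromatogram.

    The signal is baseline-corrected, lightly smoothed with a 5-sample
    moving average, and searched for local maxima at least
    ``min_snr`` times the noise level.  Reported peak bounds sit at the
    flanking minima / noise-floor crossings of the smoothed residual.

    The reported area is computed from the peak's own neighbourhood
    only: a fixed radius of three half-height-derived widths around the
    apex, a local baseline offset taken from guarded flanking windows,
    and the 0.27% Gaussian tail beyond that radius added back
    analytically.  Keeping every input local means two runs whose
    traces agree around a compound's retention time yield bit-identical
    areas for it, so equal true areas never produce spurious ratio
    differences.
    """
    if min_snr <= 0:
        raise ValueError("min_snr must be positive")
    baseline = estimate_baseline(chrom, window)
    residual = chrom.signal - baseline
    noise_sd = estimate_noise(residual)
    smooth = uniform_filter1d(residual, size=_SMOOTH_SAMPLES, mode="nearest")

    height = min_snr * noise_sd
    if height == 0.0:
        height = np.finfo(float).tiny  # noise-free trace: any rise counts
    # prominence at the detection threshold suppresses the duplicate
    # local maxima noise creates on a single peak's flat top
    apexes, _ = find_peaks(smooth, height=height, prominence=height)

    peaks: list[Peak] = []
    last_end = -1
    for apex in apexes:
        lo, hi = _peak_bounds(smooth, apex, noise_sd)
        if hi - lo < 2:
            continue
        if lo < last_end:  # shoulders sharing a valley: split at the valley
            lo = last_end
        if not (lo < apex < hi):
            continue
        offset, area = _local_area(residual, smooth, chrom.time, apex, lo, hi)
        peaks.append(
            Peak(
                apex_rt=float(chrom.time[apex]),
                start_rt=float(chrom.time[lo]),
                end_rt=float(chrom.time[hi]),
                height=float(max(residual[apex] - offset, 0.0)),
                area=area,
            )
        )
        last_end = hi
    return PeakTable(chrom.run_id, chrom.group, chrom.control_target, tuple(peaks))


#: integration radius in half-height-derived sigma units; erf(3/sqrt 2)
#: of a Gaussian lies inside +-3 sigma
_RADIUS_SIGMA = 3.0
_GAUSS_FRACTION = math.erf(_RADIUS_SIGMA / math.sqrt(2.0))
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _half_width(smooth: np.ndarray, apex: int, step: int) -> int | None:
    """Samples from the apex to the half-height crossing, or None."""
    half = smooth[apex] / 2.0
    i = apex
    last = smooth.size - 1
    while 0 < i < last:
        i += step
        if smooth[i] < half:
            return abs(i - apex)
    return None


def _local_area(
    residual: np.ndarray,
    smooth: np.ndarray,
    time: np.ndarray,
    apex: int,
    lo: int,
    hi: int,
) -> tuple[float, float]:
    """Baseline offset and area of one peak from its neighbourhood only.

    The peak's width is read off the half-height crossings of the
    smoothed residual; the integration window is +-3 of the implied
    Gaussian sigma around the apex, the local baseline offset is the
    trimmed mean of the residual in guarded windows flanking that
    radius, and the 1 - erf(3/sqrt 2) tail fraction outside the window
    is restored analytically.  Falls back to the valley-to-valley
    bounds [lo, hi] when no half-height crossing exists.
    """
    dt = time[1] - time[0]
    n = residual.size
    wl = _half_width(smooth, apex, -1)
    wr = _half_width(smooth, apex, +1)
    if wl is None or wr is None:
        seg = residual[lo : hi + 1]
        return 0.0, round(max(0.0, float(np.trapezoid(seg, time[lo : hi + 1]))), 9)
    sigma_samples = (wl + wr) / _FWHM_TO_SIGMA  # full half-width pair -> sigma
    radius = max(2, int(round(_RADIUS_SIGMA * sigma_samples)))
    gap = max(1, int(round(0.5 * radius)))
    flank = max(10, int(round(2.0 / dt)))  # offset window, ~2 min each side
    ilo, ihi = max(0, apex - radius), min(n - 1, apex + radius)
    left = residual[max(0, ilo - gap - flank) : max(0, ilo - gap)]
    right = residual[ihi + gap : ihi + gap + flank]
    near = np.concatenate([left, right])
    offset = float(trim_mean(near, 0.25)) if near.size >= 10 else 0.0
    seg = residual[ilo : ihi + 1] - offset
    area = float(np.trapezoid(seg, time[ilo : ihi + 1])) / _GAUSS_FRACTION
    # areas are reported to nAU*min: keeps them stable against the
    # last-bit accumulation differences global filters leave behind, so
    # equal true areas compare exactly equal across runs
    return offset, round(max(0.0, area), 9)


def _trapz_clipped(residual: np.ndarray, time: np.ndarray, lo: int, hi: int) -> float:
    seg = np.clip(residual[lo : hi + 1], 0.0, None)
    return float(np.trapezoid(seg, time[lo : hi + 1]))


def integrate_peak(
    chrom: Chromatogram,
    baseline: np.ndarray,
    start_rt: float,
    end_rt: float,
) -> float:
    """Trapezoidal area of (signal - baseline) over [start_rt, end_rt].

    Negative baseline-subtracted samples are clipped at zero so the
    area is non-negative, as the screening ratios require.
    """
    if start_rt >= end_rt:
        raise ValueError("start_rt must be before end_rt")
    if start_rt < chrom.time[0] - 1e-12 or end_rt > chrom.time[-1] + 1e-12:
        raise ValueError(
            f"integration bounds [{start_rt}, {end_rt}] outside the time grid"
        )
    lo = int(np.searchsorted(chrom.time, start_rt - 1e-12, side="left"))
    hi = int(np.searchsorted(chrom.time, end_rt + 1e-12, side="right")) - 1
    residual = chrom.signal - baseline
    return _trapz_clipped(residual, chrom.time, lo, hi)


def match_peaks(
    tables: Sequence[PeakTable],
    panel: CompoundPanel,
    design: ScreenDesign,
) -> list[PeakAreaTriple]:
    """Assign detected peaks to panel compounds across the screen's runs.

    For each compound and each run, the peak whose apex lies nearest
    the compound's reference RT and within the panel tolerance is
    assigned; ties break toward the smaller apex RT.  A peak may serve
    at most one compound per run; a compound without an in-tolerance
    peak gets area 0 in that run.
    """
    by_run = {t.run_id: t for t in tables}
    design_runs = {r for r, _, _ in design.runs}
    if set(by_run) != design_runs:
        raise ValidationError(
            f"peak tables {sorted(by_run)} do not match design runs "
            f"{sorted(design_runs)}"
        )

    # per run: compound -> assigned peak area
    areas: dict[str, dict[str, float]] = {}
    for run_id, table in by_run.items():
        assigned: dict[int, str] = {}  # peak index -> compound
        run_areas: dict[str, float] = {}
        for compound_id, ref_rt in panel.compounds:
            best = None
            for k, peak in enumerate(table.peaks):
                dist = abs(peak.apex_rt - ref_rt)
                if dist > panel.rt_tolerance:
                    continue
                key = (dist, peak.apex_rt)
                if best is None or key < best[0]:
                    best = (key, k)
            if best is None:
                run_areas[compound_id] = 0.0
                continue
            _, k = best
            if k in assigned:
                raise ValidationError(
                    f"run {run_id!r}: peak at {table.peaks[k].apex_rt:.3f} min "
                    f"claimed by both {assigned[k]!r} and {compound_id!r}"
                )
            assigned[k] = compound_id
            run_areas[compound_id] = table.peaks[k].area
        areas[run_id] = run_areas

    blank = areas[design.blank_run]
    exp = areas[design.experimental_run]
    triples = []
    for compound_id, _ in panel.compounds:
        triples.append(
            PeakAreaTriple(
                compound_id=compound_id,
                A_a=exp[compound_id],
                A_b=blank[compound_id],
                A_c_by_target={
                    t: areas[design.control_run(t)][compound_id]
                    for t in design.targets
                },
            )
        )
    return triples


# ---------------------------------------------------------------------------
# Plain-text I/O


def read_panel(path: str | Path, rt_tolerance: float = DEFAULT_RT_TOLERANCE) -> CompoundPanel:
    """Read a compound panel CSV with columns compound_id, reference_rt."""
    df = pd.read_csv(path, comment="#")
    compounds = tuple(
        (str(r.compound_id), float(r.reference_rt)) for r in df.itertuples()
    )
    return CompoundPanel(compounds, rt_tolerance)


def write_panel(panel: CompoundPanel, path: str | Path) -> None:
    pd.DataFrame(panel.compounds, columns=["compound_id", "reference_rt"]).to_csv(
        path, index=False
    )


def triples_to_frame(
    triples: Sequence[PeakAreaTriple], targets: Sequence[str]
) -> pd.DataFrame:
    """Tabulate area triples with one A_c column per target."""
    rows = []
    for t in triples:
        row = {"compound_id": t.compound_id, "A_a": t.A_a, "A_b": t.A_b}
        for target in targets:
            row[f"A_c_{target}"] = t.A_c_by_target[target]
        rows.append(row)
    return pd.DataFrame(rows)
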