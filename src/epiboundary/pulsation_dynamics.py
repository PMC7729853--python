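"""Pulsed apical-contraction analysis of cell-area time series.

Epithelial cells pulse: the apical area oscillates as the apicomedial
actomyosin network contracts and relaxes.  This module segments a cell's
area series into **expansion** phases (local minimum to the next local
maximum) and **contraction** phases (everything else), and scores the
**degree of area fluctuation** F over a time window:

    F = (pulse frequency: complete min-max cycles in the window)
        x (sum over adjacent-extrema pairs of |area change|)
        / (time-average area over the window)

The frequency is a per-window cycle count — adjacent-extrema pairs are
half-cycles, so it equals (number of pairs) / 2 — not a per-minute rate;
together with the area normalisation this makes F dimensionless, and the
0.6 cutoff then sits between genuinely pulsing cells (relative amplitude
around 10 %, a few cycles per 15-min window give F well above 1) and
near-quiescent ones (F a few tenths).  Cells with F > 0.6 are classed as
high-fluctuation, F <= 0.6 as low-fluctuation.

Extremum detection runs on a Savitzky-Golay-smoothed copy of the series
(window 5 frames, quadratic, mirror padding by default): local extrema are
sign changes of the first difference, classified min/max by the sign of the
second difference.  Flat plateaus resolve to their middle frame; extrema
closer than a minimum separation (2 frames) are merged keeping the more
extreme, and strict min/max alternation is enforced by dropping the lesser
of adjacent same-kind extrema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

SG_WINDOW = 5          # frames, odd
SG_POLYORDER = 2
MIN_SEPARATION = 2     # frames between retained extrema
FLUCTUATION_CUTOFF = 0.6

EXPANSION = "expansion"
CONTRACTION = "contraction"


def smooth_series(values, window_frames: int = SG_WINDOW,
                  polyorder: int = SG_POLYORDER) -> np.ndarray:
    """Savitzky-Golay smoothing with mirror-padded edges (length preserved).

    Polynomials of degree <= ``polyorder`` are reproduced exactly away from
    edge effects.
    """
    x = np.asarray(values, dtype=float)
    if window_frames % 2 == 0 or window_frames <= polyorder:
        raise ValueError(f"window_frames must be odd and > polyorder "
                         f"(got {window_frames}, {polyorder})")
    if window_frames > len(x):
        raise ValueError(f"window_frames={window_frames} exceeds series length {len(x)}")
    return savgol_filter(x, window_frames, polyorder, mode="mirror")


@dataclass(frozen=True)
class Extremum:
    frame: int
    kind: str          # "min" | "max"
    value: float       # smoothed series value at the extremum


@dataclass
class PhaseSegmentation:
    """Alternating extrema plus a phase label per inter-frame interval.

    ``phases[i]`` labels the interval between frame i and frame i+1.  Every
    interval inside a min->max run is expansion, all others contraction;
    runs before the first / after the last extremum are labelled by their
    slope (rising -> expansion), so that reversing time swaps the labels.
    """

    extrema: list[Extremum]
    phases: list[str]
    smoothed: np.ndarray
    cell_id: int | None = None

    @property
    def minima(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "min"]

    @property
    def maxima(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "max"]

    def phase_of_interval(self, i: int) -> str:
        return self.phases[i]


def _raw_extrema(s: np.ndarray) -> list[Extremum]:
    """Sign changes of the first difference; plateau -> middle frame."""
    d = np.diff(s)
    signs = np.sign(d)
    nz = [(k, sg) for k, sg in enumerate(signs) if sg != 0]
    out: list[Extremum] = []
    for (k1, s1), (k2, s2) in zip(nz, nz[1:]):
        if s1 == s2:
            continue
        lo, hi = k1 + 1, k2           # frames sitting at the extreme value
        frame = (lo + hi) // 2
        kind = "max" if s1 > 0 else "min"
        out.append(Extremum(frame, kind, float(s[frame])))
    return out


def _enforce_alternation(extrema: list[Extremum]) -> list[Extremum]:
    out: list[Extremum] = []
    for e in extrema:
        if out and out[-1].kind == e.kind:
            prev = out[-1]
            better = (e.value > prev.value) if e.kind == "max" else (e.value < prev.value)
            if better:
                out[-1] = e
        else:
            out.append(e)
    return out


def _merge_close(extrema: list[Extremum], min_sep: int, scale: float) -> list[Extremum]:
    changed = True
    ext = list(extrema)
    while changed:
        changed = False
        for i in range(len(ext) - 1):
            a, b = ext[i], ext[i + 1]
            if b.frame - a.frame < min_sep:
                # keep the one deviating more from the series median
                keep = a if abs(a.value - scale) >= abs(b.value - scale) else b
                ext = ext[:i] + [keep] + ext[i + 2:]
                changed = True
                break
    return ext


def detect_phases(area, dt: float, window_frames: int = SG_WINDOW,
                  polyorder: int = SG_POLYORDER,
                  min_separation: int = MIN_SEPARATION,
                  cell_id: int | None = None) -> PhaseSegmentation:
    """Segment a cell-area series into expansion/contraction phases.

    Needs >= 5 frames.  A monotone (or extremum-free) series is labelled
    entirely by its global slope sign: rising -> expansion.
    """
    x = np.asarray(area, dtype=float)
    if len(x) < 5:
        raise ValueError(f"need >=5 frames, got {len(x)}")
    s = smooth_series(x, window_frames, polyorder)

    ext = _raw_extrema(s)
    ext = _merge_close(ext, min_separation, float(np.median(s)))
    ext = _enforce_alternation(ext)

    n_int = len(x) - 1
    phases = [CONTRACTION] * n_int
    if not ext:
        label = EXPANSION if s[-1] > s[0] else CONTRACTION
        phases = [label] * n_int
    else:
        # interior runs
        for a, b in zip(ext, ext[1:]):
            label = EXPANSION if a.kind == "min" else CONTRACTION
            for i in range(a.frame, b.frame):
                phases[i] = label
        # edge runs labelled by slope so time reversal swaps labels exactly
        lead = EXPANSION if ext[0].kind == "max" else CONTRACTION
        for i in range(0, ext[0].frame):
            phases[i] = lead
        trail = EXPANSION if ext[-1].kind == "min" else CONTRACTION
        for i in range(ext[-1].frame, n_int):
            phases[i] = trail
    return PhaseSegmentation(ext, phases, s, cell_id=cell_id)


@dataclass(frozen=True)
class FluctuationScore:
    cell_id: int | None
    window: float          # minutes
    F: float
    label: str             # "high" | "low"


def fluctuation_degree(area, dt: float, window: float = 15.0,
                       start_frame: int = 0,
                       cutoff: float = FLUCTUATION_CUTOFF,
                       segmentation: PhaseSegmentation | None = None,
                       cell_id: int | None = None) -> FluctuationScore:
    """Degree of area fluctuation F over a time window, with high/low class.

    F multiplies the pulse frequency (complete cycles in the window, i.e.
    adjacent-extrema pairs / 2) by the summed absolute area change between
    adjacent extrema, normalised by the window's time-average area.  Fewer
    than two extrema in the window give F = 0 (low).
    """
    x = np.asarray(area, dtype=float)
    n_frames = int(round(window / dt)) + 1
    stop = start_frame + n_frames
    if stop > len(x):
        raise ValueError(f"window [{start_frame}, {stop}) exceeds series length {len(x)}")
    seg = segmentation if segmentation is not None else detect_phases(x, dt, cell_id=cell_id)
    inside = [e for e in seg.extrema if start_frame <= e.frame < stop]
    n_pairs = max(len(inside) - 1, 0)
    frequency = n_pairs / 2.0   # complete cycles in the window
    abs_change = sum(abs(b.value - a.value) for a, b in zip(inside, inside[1:]))
    mean_area = float(np.mean(seg.smoothed[start_frame:stop]))
    if mean_area <= 0:
        raise ValueError("non-positive mean area in window")
    F = frequency * abs_change / mean_area
    return FluctuationScore(cell_id, window, float(F),
                            "high" if F > cutoff else "low")
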