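"""Ricker-wavelet peak extraction from SEC elution profiles.

A protein's crosslinked elution profile may contain several discrete peaks
(assembly forms, monomer, void aggregates).  Peaks are located with a
continuous wavelet transform using Ricker (Mexican-hat) kernels spanning 2-8
fractions: apexes are CWT ridge maxima that persist across at least two
adjacent widths.  The Ricker kernel of width ``w`` is positive on (-w, w)
(its zero crossings sit at +/- w, with the negative side-lobes and their
minima just beyond), so the peak window is ``[apex - w, apex + w]`` (clipped
to the fraction grid) with all profile values outside the window set to 0.

Four filters are then applied, in order:

1. amplitude below 15% of the profile maximum (noise);
2. apex apparent MW at or below the protein dimer MW (monomer/dimer peaks);
3. apex inside the void region (fractions 1-4, unresolved material);
4. apexes closer than 3 fractions (keep the larger peak).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .profile_io import CalibrationCurve, MeanProfile, ReplicateProfile

DEFAULT_WIDTHS = range(2, 9)
DEFAULT_VOID_FRACTIONS = frozenset(range(1, 5))


@dataclass
class Peak:
    """A contiguous elution window around a single apex fraction."""

    group_id: str
    source: str  # "mean" or "rep1".."rep3"
    apex_fraction: int  # 1-based
    lo_fraction: int
    hi_fraction: int
    values: np.ndarray  # full profile length, zeros outside the window
    amplitude: float
    apex_mw_kda: float | None = None
    monomer_mw_kda: float | None = None

    @property
    def window_values(self) -> np.ndarray:
        return self.values[self.lo_fraction - 1 : self.hi_fraction]


def ricker(n_points: int, width: float) -> np.ndarray:
    """Ricker (Mexican hat) wavelet: normalized negative second derivative
    of a Gaussian with scale ``width``, sampled at ``n_points`` centred
    integer offsets.  Positive on (-width, width); minima at +/- sqrt(3)*width."""
    a = float(width)
    amp = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25)
    x = np.arange(n_points) - (n_points - 1) / 2.0
    return amp * (1.0 - (x / a) ** 2) * np.exp(-(x**2) / (2.0 * a**2))


def cwt_ricker(v: np.ndarray, widths) -> np.ndarray:
    """CWT matrix, one row per width, zero-padded 'same' convolution."""
    v = np.asarray(v, dtype=float)
    rows = []
    max_pts = len(v) if len(v) % 2 == 1 else len(v) - 1
    for w in widths:
        kernel = ricker(min(10 * int(w) + 1, max_pts), w)
        rows.append(np.convolve(v, kernel, mode="same"))
    return np.vstack(rows)


def _local_maxima(row: np.ndarray) -> list[int]:
    """Indices of strict local maxima (plateaus yield their left edge)."""
    out = []
    n = len(row)
    for i in range(n):
        left = row[i - 1] if i > 0 else -np.inf
        right = row[i + 1] if i < n - 1 else -np.inf
        if row[i] > 0 and row[i] > left and row[i] >= right:
            out.append(i)
    return out


def _link_ridges(maxima_per_row: list[list[int]], max_gap: int = 2):
    """Greedy ridge linking across adjacent widths.

    Each ridge is a list of (row, position); a maximum in row r+1 extends
    the ridge whose last position is nearest within ``max_gap`` fractions.
    """
    ridges: list[list[tuple[int, int]]] = [[(0, p)] for p in maxima_per_row[0]]
    open_ridges = list(range(len(ridges)))
    for r in range(1, len(maxima_per_row)):
        positions = list(maxima_per_row[r])
        next_open = []
        taken = set()
        for ri in open_ridges:
            last_pos = ridges[ri][-1][1]
            best, best_d = None, max_gap + 1
            for j, p in enumerate(positions):
                if j in taken:
                    continue
                d = abs(p - last_pos)
                if d < best_d:
                    best, best_d = j, d
            if best is not None:
                taken.add(best)
                ridges[ri].append((r, positions[best]))
                next_open.append(ri)
        for j, p in enumerate(positions):
            if j not in taken:
                ridges.append([(r, p)])
                next_open.append(len(ridges) - 1)
        open_ridges = next_open
    return ridges


def extract_peaks(
    profile: MeanProfile | ReplicateProfile | np.ndarray,
    widths=DEFAULT_WIDTHS,
    calibration: CalibrationCurve | None = None,
    monomer_mw_kda: float | None = None,
    group_id: str | None = None,
    source: str = "mean",
    min_ridge_length: int = 2,
) -> list[Peak]:
    """Extract peaks from a 0-1 normalized profile via the Ricker CWT.

    The apex is snapped to the profile's local maximum within +/- 1 fraction
    of the ridge position (the wavelet response of a broad kernel can sit one
    fraction off a sharp apex).  Returns peaks sorted by apex; a flat or
    all-zero profile yields an empty list.
    """
    if isinstance(profile, MeanProfile):
        v = np.asarray(profile.mean, dtype=float)
        group_id = group_id or profile.group_id
    elif isinstance(profile, ReplicateProfile):
        v = np.asarray(profile.intensities, dtype=float)
        group_id = group_id or profile.group_id
        if source == "mean":
            source = f"rep{profile.replicate_index}"
    else:
        v = np.asarray(profile, dtype=float)
        group_id = group_id or ""
    n = len(v)
    if n == 0 or v.max() <= 0 or np.ptp(v) == 0:
        return []

    widths = list(widths)
    mat = cwt_ricker(v, widths)
    maxima_per_row = [_local_maxima(mat[r]) for r in range(len(widths))]
    ridges = _link_ridges(maxima_per_row)

    found: dict[int, Peak] = {}
    for ridge in ridges:
        if len(ridge) < min_ridge_length:
            continue
        # apex position from the smallest (most localized) width on the
        # ridge; the best-responding width sets the window size
        r_best, p_best = max(ridge, key=lambda rp: mat[rp[0], rp[1]])
        p_small = min(ridge)[1]
        # snap to the profile's local max within +/- 1 fraction
        lo_s, hi_s = max(0, p_small - 1), min(n, p_small + 2)
        apex0 = lo_s + int(np.argmax(v[lo_s:hi_s]))
        if v[apex0] <= 0:
            continue
        w = int(widths[r_best])
        lo = max(1, apex0 + 1 - w)
        hi = min(n, apex0 + 1 + w)
        vals = np.zeros(n)
        vals[lo - 1 : hi] = v[lo - 1 : hi]
        peak = Peak(
            group_id=group_id,
            source=source,
            apex_fraction=apex0 + 1,
            lo_fraction=lo,
            hi_fraction=hi,
            values=vals,
            amplitude=float(vals.max()),
            apex_mw_kda=(
                calibration.fraction_to_mw(apex0 + 1) if calibration else None
            ),
            monomer_mw_kda=monomer_mw_kda,
        )
        prev = found.get(peak.apex_fraction)
        if prev is None or mat[r_best, p_best] > prev.amplitude:
            found[peak.apex_fraction] = peak
    return [found[a] for a in sorted(found)]


def filter_peaks(
    peaks: list[Peak],
    profile_max: float,
    calibration: CalibrationCurve | None = None,
    void_fractions=DEFAULT_VOID_FRACTIONS,
    noise_frac: float = 0.15,
    min_apex_sep: int = 3,
    dimer_slack: float = 1.0,
) -> list[Peak]:
    """Apply the four peak filters in their stated order.

    A peak survives the dimer rule only if its apex apparent MW is strictly
    above ``dimer_slack * 2 * monomer MW``; "approximately equal to" the
    dimer MW is absorbed by the configurable slack (default 1.0).
    """
    void = set(void_fractions)

    # 1. noise floor relative to the profile maximum
    peaks = [p for p in peaks if p.amplitude >= noise_frac * profile_max]

    # 2. monomer/dimer rule
    survivors = []
    for p in peaks:
        apex_mw = p.apex_mw_kda
        if apex_mw is None and calibration is not None:
            apex_mw = calibration.fraction_to_mw(p.apex_fraction)
            p = replace(p, apex_mw_kda=apex_mw)
        if apex_mw is None or p.monomer_mw_kda is None:
            survivors.append(p)  # no MW information: rule not applicable
        elif apex_mw > dimer_slack * 2.0 * p.monomer_mw_kda:
            survivors.append(p)
    peaks = survivors

    # 3. void region
    peaks = [p for p in peaks if p.apex_fraction not in void]

    # 4. minimum apex separation: greedily keep larger amplitude
    #    (ties: smaller apex)
    accepted: list[Peak] = []
    for p in sorted(peaks, key=lambda q: (-q.amplitude, q.apex_fraction)):
        if all(abs(p.apex_fraction - a.apex_fraction) >= min_apex_sep for a in accepted):
            accepted.append(p)
    return sorted(accepted, key=lambda q: q.apex_fraction)


def peaks_to_table(peaks: list[Peak]):
    """Flatten peaks to the exported TSV schema."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "group_id": p.group_id,
                "source": p.source,
                "apex_fraction": p.apex_fraction,
                "lo": p.lo_fraction,
                "hi": p.hi_fraction,
                "amplitude": p.amplitude,
                "apex_mw_kda": p.apex_mw_kda,
            }
            for p in peaks
        ],
        columns=[
            "group_id", "source", "apex_fraction", "lo", "hi",
            "amplitude", "apex_mw_kda",
        ],
    )
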