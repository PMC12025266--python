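"""Non-NMR study formulas: recognition memory, turning bias, beam
traversal censoring, ECoG band power, mitochondrial membrane potential.

These are the study's small defined quantities, implemented exactly as
stated: the discrimination index with its 10-second exploration exclusion
rule, left/right corner-test percentages over valid trials, the 60-second
beam-walk censoring rule, Welch-periodogram band power over the canonical
delta-gamma bands, and the JC-1 aggregate/monomer ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .numutils import trapezoid_band

MIN_EXPLORATION_S = 10.0
BEAM_CUTOFF_S = 60.0


@dataclass(frozen=True)
class BandDef:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_lo < self.f_hi:
            raise ValueError(f"{self.name}: need 0 <= f_lo < f_hi")


#: Canonical ECoG bands (Hz). Adjacent bands share an edge; trapezoid
#: endpoints give the shared frequency half weight in each band, so band
#: powers are exactly additive over a partition.
DEFAULT_BANDS = (
    BandDef("Delta", 0.5, 4.0),
    BandDef("Theta", 4.0, 8.0),
    BandDef("Alpha", 8.0, 13.0),
    BandDef("Beta", 13.0, 30.0),
    BandDef("Gamma", 30.0, 100.0),
)


@dataclass(frozen=True)
class DiscriminationResult:
    di: float | None
    excluded: bool
    total_s: float


def discrimination_index(t_novel: float, t_familiar: float) -> DiscriminationResult:
    """DI = (T_novel - T_familiar) / (T_novel + T_familiar), in [-1, 1].

    Animals with under 10 s total object exploration are excluded: the
    result carries ``excluded=True`` and no numeric index.
    """
    if t_novel < 0 or t_familiar < 0:
        raise ValueError("exploration times must be >= 0")
    total = t_novel + t_familiar
    if total < MIN_EXPLORATION_S:
        return DiscriminationResult(di=None, excluded=True, total_s=total)
    return DiscriminationResult(
        di=(t_novel - t_familiar) / total, excluded=False, total_s=total)


def turn_ratio(turns) -> tuple[float, float, int]:
    """Left/right turn percentages over valid trials: (left%, right%, n_valid).

    ``turns`` is a sequence of 'left' / 'right' / 'invalid' labels;
    invalid trials (no >90-degree rotation, caller-declared) are dropped
    from the denominator. Percentages sum to 100 exactly.
    """
    counts = {"left": 0, "right": 0, "invalid": 0}
    for t in turns:
        if t not in counts:
            raise ValueError(f"unknown turn label {t!r}")
        counts[t] += 1
    n_valid = counts["left"] + counts["right"]
    if n_valid == 0:
        raise ValueError("no valid trials")
    return (100.0 * counts["left"] / n_valid,
            100.0 * counts["right"] / n_valid, n_valid)


@dataclass(frozen=True)
class BeamTime:
    seconds: float
    censored: bool


def censor_beam_time(raw_s: float | None = None, fell: bool = False,
                     timeout: bool = False) -> BeamTime:
    """Beam traversal time with the 60 s rule.

    Trials terminated at 60 s (timeout) or ended by a fall are recorded as
    60 s; times beyond the cutoff are clamped. The censoring flag is kept
    for downstream summaries.
    """
    if fell or timeout:
        return BeamTime(seconds=BEAM_CUTOFF_S, censored=True)
    if raw_s is None:
        raise ValueError("need a raw time or a fall/timeout event")
    if raw_s < 0:
        raise ValueError("traversal time must be >= 0")
    if raw_s >= BEAM_CUTOFF_S:
        return BeamTime(seconds=BEAM_CUTOFF_S, censored=True)
    return BeamTime(seconds=float(raw_s), censored=False)


def band_power(signal, fs: float, band: BandDef,
               segment_s: float = 2.0) -> float:
    """Band-integrated Welch power (signal-units^2) over [f_lo, f_hi].

    Welch periodogram with Hann-windowed segments (default 2 s, 50%
    overlap), integrated over the band by trapezoid with interpolated
    endpoints. Requires fs > 2 x f_hi and at least 4 s of signal.
    """
    x = np.asarray(signal, dtype=float)
    if fs <= 2.0 * band.f_hi:
        raise ValueError(
            f"sampling rate {fs} Hz too low for band {band.name} "
            f"(needs > {2 * band.f_hi} Hz)")
    if len(x) < 4.0 * fs:
        raise ValueError("need at least 4 s of signal")
    nperseg = int(round(segment_s * fs))
    f, pxx = welch(x, fs=fs, window="hann", nperseg=nperseg,
                   noverlap=nperseg // 2)
    if not np.any(pxx):
        return 0.0
    return trapezoid_band(f, pxx, band.f_lo, band.f_hi, min_points=2)


def band_powers(signal, fs: float, bands=DEFAULT_BANDS) -> dict:
    return {b.name: band_power(signal, fs, b) for b in bands}


def mito_potential_index(aggregate_fl: float, monomer_fl: float) -> float:
    """JC-1 mitochondrial membrane-potential index: aggregate / monomer.

    High ratios mark polarised mitochondria (dye aggregates); NaN with a
    diagnostic-friendly message when the monomer signal is non-positive.
    """
    if monomer_fl <= 0:
        return math.nan
    if aggregate_fl < 0:
        raise ValueError("fluorescence intensities must be >= 0")
    return aggregate_fl / monomer_fl
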