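"""Compose EV + IV signals, fit relaxation rates, ΔR2(*) and ΔBOLD.

The total magnitude signal of a lamina is

    S(t) = S_EV(t) + S_aIV(t) + S_vIV(t)

with the extravascular term ``(1 - bCBVa - bCBVv) * |A(t)| * exp(-t/T2_0)``
(only macrovessel blood volume is subtracted from the water pool; the
microvessel volume is deliberately left in, matching the reference signal
model — a corrected mode exists), and each intravascular term
``bCBV * exp(-t / T2_blood)``.  Venous blood T2 depends on oxygen
saturation through an empirical 7T lookup; the microvascular intravascular
contribution is null by assumption.

Relaxation rates are estimated by a degree-one polynomial fit to
``ln S(t)`` over a window (default [0, TE]); the two reported metrics are
the relative rate change ΔR2(*) and the relative signal change ΔBOLD, both
versus the pure-tissue baseline ``exp(-t / T2_0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .montecarlo import LaminarAttenuation

# ---------------------------------------------------------------------------
# empirical blood/tissue relaxation constants at 7T (ms)
# ---------------------------------------------------------------------------

#: venous-table oxygen saturation grid (fractions)
BLOOD_TABLE_SO2 = np.array(
    [0.50, 0.53, 0.56, 0.59, 0.62, 0.65, 0.68, 0.71, 0.74, 0.77,
     0.80, 0.83, 0.86, 0.89, 0.90]
)
#: venous blood T2* (GE) at 7T, ms
VENOUS_T2_GE = np.array(
    [4.41, 4.72, 5.05, 5.40, 5.78, 6.17, 6.59, 7.01, 7.45, 7.89,
     8.31, 8.72, 9.09, 9.42, 9.68]
)
#: venous blood T2 (SE) at 7T, ms
VENOUS_T2_SE = np.array(
    [5.75, 6.42, 7.20, 8.13, 9.23, 10.56, 12.17, 14.12, 16.51, 19.44,
     23.03, 27.38, 32.52, 38.32, 44.33]
)
#: arterial blood T2(*) at SO2 = 95 %, ms
ARTERIAL_T2 = {"GE": 9.87, "SE": 49.67}
ARTERIAL_SO2 = 0.95
#: intrinsic blood relaxation times, ms (the oxygenation-independent part)
BLOOD_T2_INTRINSIC = {"GE": 10.00, "SE": 53.82}
#: cortical grey-matter tissue T2(*) at 7T, ms
TISSUE_T2 = {"GE": 28.57, "SE": 48.30}
#: echo times, ms
ECHO_TIME = {"GE": 27.0, "SE": 50.0}

#: upper venous saturation accepted by the lookup; the sweep extends to 0.92
#: while the empirical table ends at 0.90, so the monotone interpolant is
#: extrapolated over that last step (in rate space)
VENOUS_SO2_MAX = 0.92

_interp_cache: dict[str, PchipInterpolator] = {}


def _venous_rate_interpolator(seq: str) -> PchipInterpolator:
    if seq not in _interp_cache:
        t2 = VENOUS_T2_GE if seq == "GE" else VENOUS_T2_SE
        # interpolate monotone rates R2 = 1/T2 (rates add across mechanisms)
        _interp_cache[seq] = PchipInterpolator(BLOOD_TABLE_SO2, 1.0 / t2, extrapolate=False)
    return _interp_cache[seq]


def _venous_rate(seq: str, so2: float) -> float:
    itp = _venous_rate_interpolator(seq)
    hi = BLOOD_TABLE_SO2[-1]
    if so2 <= hi:
        return float(itp(so2))
    # beyond the table (0.90 -> 0.92) extend linearly with the endpoint
    # derivative: the cubic tail of the interpolant is not monotone
    return float(itp(hi) + itp.derivative()(hi) * (so2 - hi))


def blood_relaxation_lookup(compartment: str, so2: float, seq: str) -> float:
    """Blood T2(*) in ms for an intravascular compartment.

    Veins use monotone piecewise-cubic interpolation of the empirical rate
    table versus SO2 (extrapolated over 0.90–0.92); arteries use the fixed
    95 %-saturation value.  The microvascular IV contribution is null by
    model assumption, so asking for it is an error.
    """
    if seq not in ("GE", "SE"):
        raise ValueError("seq must be 'GE' or 'SE'")
    if compartment == "artery":
        return ARTERIAL_T2[seq]
    if compartment == "microvessel":
        raise ValueError("microvascular intravascular signal is null by assumption")
    if compartment != "vein":
        raise ValueError(f"unknown compartment {compartment!r}")
    if not BLOOD_TABLE_SO2[0] - 1e-9 <= so2 <= VENOUS_SO2_MAX + 1e-9:
        raise ValueError(
            f"venous so2 {so2} outside the supported range "
            f"[{BLOOD_TABLE_SO2[0]}, {VENOUS_SO2_MAX}]"
        )
    so2 = float(np.clip(so2, BLOOD_TABLE_SO2[0], VENOUS_SO2_MAX))
    return 1.0 / _venous_rate(seq, so2)


def intravascular_signal(bcbv: float, blood_t2: float, times: np.ndarray) -> np.ndarray:
    """CBV-weighted mono-exponential blood decay ``bcbv * exp(-t/T2)``."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if not 0.0 <= bcbv < 1.0:
        raise ValueError("blood volume fraction must lie in [0, 1)")
    return bcbv * np.exp(-times / blood_t2)


def extravascular_signal(
    attenuation: np.ndarray,
    bcbv_a: float,
    bcbv_v: float,
    seq: str,
    times: np.ndarray,
    bcbv_micro: float = 0.0,
    subtract_micro: bool = False,
    tissue_t2: float | None = None,
) -> np.ndarray:
    """Tissue-water signal: volume weight x |A(t)| x intrinsic decay.

    By default only the macrovascular blood volume is subtracted from the
    water pool; ``subtract_micro=True`` also removes the microvessel volume
    (sensitivity mode).
    """
    attenuation = np.asarray(attenuation, dtype=float)
    times = np.asarray(times, dtype=float)
    if attenuation.shape != times.shape:
        raise ValueError("attenuation and time axes do not match")
    t2 = TISSUE_T2[seq] if tissue_t2 is None else tissue_t2
    weight = 1.0 - (bcbv_a + bcbv_v) - (bcbv_micro if subtract_micro else 0.0)
    return weight * attenuation * np.exp(-times / t2)


@dataclass
class SignalTimecourse:
    """EV, arterial-IV and venous-IV components and their sum per lamina."""

    times: np.ndarray
    ev: np.ndarray
    iv_art: np.ndarray
    iv_vein: np.ndarray

    def __post_init__(self) -> None:
        for comp in (self.ev, self.iv_art, self.iv_vein):
            if np.asarray(comp).shape != np.asarray(self.times).shape:
                raise ValueError("component time axes do not match")

    @property
    def total(self) -> np.ndarray:
        return self.ev + self.iv_art + self.iv_vein

    def at(self, t: float) -> tuple[float, float, float, float]:
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-6:
            raise ValueError(f"time {t} not on the stored axis")
        return (
            float(self.ev[idx]),
            float(self.iv_art[idx]),
            float(self.iv_vein[idx]),
            float(self.total[idx]),
        )

    def shares_at(self, t: float) -> tuple[float, float, float]:
        """(EV, arterial-IV, venous-IV) percent shares of the total at t."""
        ev, ia, iv, tot = self.at(t)
        if tot <= 0:
            raise ValueError("non-positive total signal")
        return 100.0 * ev / tot, 100.0 * ia / tot, 100.0 * iv / tot


def total_signal(ev, iv_art, iv_vein, times) -> SignalTimecourse:
    return SignalTimecourse(np.asarray(times, float), np.asarray(ev, float),
                            np.asarray(iv_art, float), np.asarray(iv_vein, float))


def compose_lamina_signal(
    times: np.ndarray,
    attenuation_mag: np.ndarray,
    bcbv_a: float,
    bcbv_v: float,
    so2_vein: float,
    seq: str,
    bcbv_micro: float = 0.0,
    subtract_micro: bool = False,
) -> SignalTimecourse:
    """Assemble the three components of one lamina for one sequence/state."""
    ev = extravascular_signal(
        attenuation_mag, bcbv_a, bcbv_v, seq, times,
        bcbv_micro=bcbv_micro, subtract_micro=subtract_micro,
    )
    iv_a = intravascular_signal(bcbv_a, blood_relaxation_lookup("artery", ARTERIAL_SO2, seq), times)
    iv_v = intravascular_signal(bcbv_v, blood_relaxation_lookup("vein", so2_vein, seq), times)
    return SignalTimecourse(np.asarray(times, float), ev, iv_a, iv_v)


# ---------------------------------------------------------------------------
# rate fitting and the two reported metrics
# ---------------------------------------------------------------------------


def fit_relaxation_rate(times: np.ndarray, signal: np.ndarray,
                        window: tuple[float, float] | None = None) -> float:
    """Log-linear least-squares rate (1/ms) over a time window.

    The multi-exponential S(t) is summarized by the slope of the best-fit
    line through ``(t, ln S)``; the default window is the full stored axis.
    """
    times = np.asarray(times, float)
    signal = np.asarray(signal, float)
    if window is not None:
        sel = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
        times, signal = times[sel], signal[sel]
    if len(times) < 2:
        raise ValueError("need at least two samples to fit a rate")
    if np.any(signal <= 0):
        raise ValueError("non-positive signal inside the fit window")
    slope = np.polyfit(times, np.log(signal), 1)[0]
    return float(-slope)


def tissue_rate(seq: str) -> float:
    return 1.0 / TISSUE_T2[seq]


def relative_delta_r2(rate_state: float, rate_tissue: float) -> float:
    """Relative relaxation-rate change in percent versus the tissue rate."""
    if rate_tissue <= 0:
        raise ValueError("tissue rate must be positive")
    return (rate_state / rate_tissue - 1.0) * 100.0


def relative_delta_bold(s_state_te: float, s_tissue_te: float) -> float:
    """Relative signal change in percent at TE versus the tissue baseline."""
    if s_tissue_te <= 0:
        raise ValueError("tissue baseline signal must be positive")
    return (s_state_te / s_tissue_te - 1.0) * 100.0


def tissue_signal_at_te(seq: str, te: float | None = None) -> float:
    te = ECHO_TIME[seq] if te is None else te
    return float(np.exp(-te / TISSUE_T2[seq]))


def delta_r2_prime(att: LaminarAttenuation, te: float) -> np.ndarray:
    """Point-estimate dephasing rate ``-ln|A(TE)| / TE`` per rep and lamina.

    Units 1/ms; multiply by 1e3 for 1/s.  This is the standard summary for
    phantom regime curves where the attenuation alone is of interest.
    """
    idx = att.time_index(te)
    mag = att.magnitude[:, :, idx]
    return -np.log(np.maximum(mag, 1e-300)) / te
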