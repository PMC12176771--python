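"""The 48 glottal parameters computed from a GAW and its phonation cycles.

Feature families
----------------
* fundamental frequency: per-cycle F0 mean/std
* perturbation: cycle-to-cycle period/amplitude/energy variability
  (mJit, PVI, TP, mShim, AVI, AP, EPF) — correlates of vocal roughness
* glottal dynamics: open/closing/plateau/speed quotients, glottal area and
  gap indices — closure behavior, related to breathiness
* mechanical: amplitude-length ratio, stiffness, amplitude quotient —
  extent and velocity of vocal-fold deflection
* symmetry: left-right phase asymmetry (PA) and phase asymmetry index (PAI)
* noise: cepstral (CPM, CPPS), harmonic-energy (HI, HNR), waveform matching
  (WMC), windowed noise energies (NNE, SNR) and spectral flatness (SF)
* Nyquist-plane: trajectory consistency (TC) and within-trajectory
  variability (WTV) of per-cycle analytic-signal orbits

The literature gives these quantities by name with varying formulations; the
definitions below are this package's normative forms, chosen to match the
standard descriptions, with every tunable (baseline fraction, window sizes,
harmonic bandwidth, resampling length) explicit in :class:`FeatureConfig`.
Sample standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.fft import irfft, rfft
from scipy.ndimage import uniform_filter1d

from .extraction import CycleSegmentation, GAWRecord

__all__ = [
    "FEATURE_NAMES",
    "AnalysisWindows",
    "FeatureConfig",
    "GlottalFeatureVector",
    "FeatureExtractionError",
    "compute_f0_stats",
    "compute_perturbation",
    "compute_dynamics",
    "compute_mechanical",
    "compute_symmetry",
    "compute_noise",
    "compute_nyquist",
    "extract_all",
]

#: canonical CSV schema: the 48 feature names in fixed order
FEATURE_NAMES = [
    "F0_mean", "F0_std",
    "mJit", "PVI", "TP_mean", "TP_std", "mShim", "AVI", "AP_mean", "AP_std", "EPF",
    "CQ_mean", "CQ_std", "OQ_mean", "OQ_std", "PQ_mean", "PQ_std",
    "SQ_mean", "SQ_std", "GAI_mean", "GAI_std", "GGI_mean", "GGI_std",
    "ALR_mean", "ALR_std", "STF_mean", "STF_std", "AQ_mean", "AQ_std",
    "PA_mean", "PA_std", "PAI_mean", "PAI_std",
    "CPM", "CPPS", "HI", "HNR", "WMC_mean", "WMC_max",
    "NNE_mean", "NNE_std", "SNR_mean", "SNR_std", "SF",
    "TC_mean", "TC_std", "WTV_mean", "WTV_std",
]

_EPS = 1e-12


class FeatureExtractionError(ValueError):
    """Raised when a feature family cannot be computed from the given input."""


@dataclass(frozen=True)
class AnalysisWindows:
    """Windowing for the signal-level noise measures (NNE, SNR): window length
    in phonation cycles and hop in cycles (50% overlap by default)."""

    cycles: int = 5
    hop: int = 2

    def __post_init__(self) -> None:
        if self.cycles < 3:
            raise ValueError("analysis window must span at least 3 cycles")
        if self.hop < 1:
            raise ValueError("hop must be at least 1 cycle")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable constants of the feature extractor.

    ``glottal_length`` (px) normalizes the amplitude-length ratio; when masks
    are available it is taken as the 97.5th percentile of the per-frame
    glottal extent along the midline, otherwise it must be supplied here.
    """

    baseline_frac: float = 0.05  # open-phase baseline above cycle min
    plateau_frac: float = 0.9  # plateau threshold of cycle range
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    harmonic_halfwidth: int = 1  # +- DFT bins kept around each harmonic
    resample_points: int = 100  # cycle resampling for WMC and Nyquist
    f0_range: tuple[float, float] = (50.0, 500.0)
    cpps_frame: int = 256
    cpps_hop: int = 64
    cpps_time_smooth: int = 5
    cpps_quef_smooth: int = 11
    glottal_length: float | None = None


@dataclass
class GlottalFeatureVector:
    """The 48 named glottal parameters in fixed canonical order."""

    values: np.ndarray

    NAMES = tuple(FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (48,):
            raise ValueError("GlottalFeatureVector requires exactly 48 values")

    @classmethod
    def from_dict(cls, d: dict) -> "GlottalFeatureVector":
        missing = [n for n in FEATURE_NAMES if n not in d]
        if missing:
            raise ValueError(f"missing features: {missing}")
        return cls(np.array([d[n] for n in FEATURE_NAMES], dtype=float))

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def to_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.values))

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values, index=list(FEATURE_NAMES))


def _std(x: np.ndarray) -> float:
    """Sample std (n-1); 0.0 for fewer than two observations."""
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def _cycle_segments(gaw: GAWRecord, cycles: CycleSegmentation):
    return [gaw.total[sl] for sl in cycles.slices()]


def _amplitudes(gaw: GAWRecord, cycles: CycleSegmentation) -> np.ndarray:
    if cycles.peak_amplitudes is not None:
        return np.asarray(cycles.peak_amplitudes, dtype=float)
    return np.array([seg.max() - seg.min() for seg in _cycle_segments(gaw, cycles)])


def compute_f0_stats(gaw: GAWRecord, cycles: CycleSegmentation) -> dict:
    """Per-cycle fundamental frequency f_i = 1/T_i: mean and sample std (Hz)."""
    if cycles.n_cycles < 2:
        raise FeatureExtractionError("F0 statistics require at least 2 cycles")
    f = 1.0 / np.asarray(cycles.periods, dtype=float)
    return {"F0_mean": float(f.mean()), "F0_std": _std(f)}


def compute_perturbation(gaw: GAWRecord, cycles: CycleSegmentation) -> dict:
    """Cycle-to-cycle perturbation of period, amplitude, and energy.

    mJit = mean |T_{i+1}-T_i| (s); PVI = 100 mJit / mean(T);
    TP_i = min/max of consecutive periods; mShim = mean |A_{i+1}-A_i|/mean(A);
    AVI = 100 mShim; AP_i = min/max of consecutive amplitudes;
    EPF = mean |E_{i+1}-E_i| / mean(E) with E_i the within-cycle energy
    sum(a[n]^2).
    """
    if cycles.n_cycles < 3:
        raise FeatureExtractionError("perturbation measures require at least 3 cycles")
    t = np.asarray(cycles.periods, dtype=float)
    a = _amplitudes(gaw, cycles)
    if np.all(a <= 0):
        raise FeatureExtractionError("degenerate all-zero cycles")
    e = np.array([float(np.sum(seg**2)) for seg in _cycle_segments(gaw, cycles)])

    dt = np.abs(np.diff(t))
    da = np.abs(np.diff(a))
    de = np.abs(np.diff(e))
    tp = np.minimum(t[:-1], t[1:]) / np.maximum(t[:-1], t[1:])
    ap = np.minimum(a[:-1], a[1:]) / np.maximum(np.maximum(a[:-1], a[1:]), _EPS)
    m_shim = float(da.mean() / max(a.mean(), _EPS))
    return {
        "mJit": float(dt.mean()),
        "PVI": float(100.0 * dt.mean() / t.mean()),
        "TP_mean": float(tp.mean()),
        "TP_std": _std(tp),
        "mShim": m_shim,
        "AVI": 100.0 * m_shim,
        "AP_mean": float(ap.mean()),
        "AP_std": _std(ap),
        "EPF": float(de.mean() / max(e.mean(), _EPS)),
    }


def _phase_landmarks(seg: np.ndarray, baseline_frac: float):
    """(open_start, peak, open_end) sample indices of one cycle."""
    mn, mx = seg.min(), seg.max()
    baseline = mn + baseline_frac * (mx - mn)
    open_idx = np.flatnonzero(seg > baseline)
    pk = int(np.argmax(seg))
    return int(open_idx[0]), pk, int(open_idx[-1])


def compute_dynamics(
    gaw: GAWRecord, cycles: CycleSegmentation, config: FeatureConfig | None = None
) -> dict:
    """Per-cycle open/closing/plateau/speed quotients and area/gap indices.

    The open phase is where the area exceeds cycle min + 5% of the cycle
    range; opening runs from open-phase start to the cycle maximum, closing
    from the maximum to open-phase end.  OQ/CQ/PQ are fractions of the cycle,
    SQ = opening/closing, GAI = cycle mean / cycle max, GGI = cycle min /
    cycle max (degree of incomplete closure).
    """
    config = config or FeatureConfig()
    if cycles.n_cycles < 2:
        raise FeatureExtractionError("dynamics require at least 2 cycles")
    oq, cq, pq, sq, gai, ggi = [], [], [], [], [], []
    for seg in _cycle_segments(gaw, cycles):
        mn, mx = seg.min(), seg.max()
        if mx - mn <= 0:
            raise FeatureExtractionError("zero-range cycle")
        os_, pk, oe = _phase_landmarks(seg, config.baseline_frac)
        length = len(seg)
        opening = max(pk - os_, 0)
        closing = max(oe - pk, 0)
        oq.append((oe - os_ + 1) / length)
        cq.append(closing / length)
        sq.append(opening / max(closing, 1))
        pq.append(np.sum(seg >= mn + config.plateau_frac * (mx - mn)) / length)
        gai.append(seg.mean() / mx if mx > 0 else 0.0)
        ggi.append(mn / mx if mx > 0 else 0.0)
    return {
        "CQ_mean": float(np.mean(cq)), "CQ_std": _std(cq),
        "OQ_mean": float(np.mean(oq)), "OQ_std": _std(oq),
        "PQ_mean": float(np.mean(pq)), "PQ_std": _std(pq),
        "SQ_mean": float(np.mean(sq)), "SQ_std": _std(sq),
        "GAI_mean": float(np.mean(gai)), "GAI_std": _std(gai),
        "GGI_mean": float(np.mean(ggi)), "GGI_std": _std(ggi),
    }


def compute_mechanical(
    gaw: GAWRecord,
    cycles: CycleSegmentation,
    glottal_length: float,
    config: FeatureConfig | None = None,
) -> dict:
    """Amplitude-length ratio, stiffness, and amplitude quotient per cycle.

    ALR_i = A_i / glottal_length; STF_i = mean |dA/dt| over the cycle / A_i;
    AQ_i = A_i / max |dA/dt| during the closing phase.
    """
    config = config or FeatureConfig()
    if glottal_length is None or glottal_length <= 0:
        raise FeatureExtractionError("glottal_length must be positive")
    if cycles.n_cycles < 2:
        raise FeatureExtractionError("mechanical measures require at least 2 cycles")
    a = _amplitudes(gaw, cycles)
    d = np.diff(gaw.total) * gaw.fs
    alr, stf, aq = [], [], []
    for i, sl in enumerate(cycles.slices()):
        seg = gaw.total[sl]
        dseg = d[sl.start : sl.stop - 1]
        amp = max(a[i], _EPS)
        os_, pk, oe = _phase_landmarks(seg, config.baseline_frac)
        # closing window: peak to open-phase end; when noise puts the
        # detected open end at/before the peak, fall back to the cycle tail
        stop = sl.start + oe if oe > pk else sl.stop - 1
        d_close = d[sl.start + pk : stop]
        alr.append(a[i] / glottal_length)
        stf.append(float(np.mean(np.abs(dseg))) / amp)
        if len(d_close) and np.max(np.abs(d_close)) > 0:
            aq.append(a[i] / float(np.max(np.abs(d_close))))
    if not aq:
        raise FeatureExtractionError("zero closing velocity")
    return {
        "ALR_mean": float(np.mean(alr)), "ALR_std": _std(alr),
        "STF_mean": float(np.mean(stf)), "STF_std": _std(stf),
        "AQ_mean": float(np.mean(aq)), "AQ_std": _std(aq),
    }


def _circular_ncc(a: np.ndarray, b: np.ndarray):
    """Circular normalized cross-correlation; returns (values, lags)."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom <= 0:
        raise FeatureExtractionError("constant segment in cross-correlation")
    fa = np.fft.rfft(a)
    fb = np.fft.rfft(b)
    c = np.fft.irfft(fa * np.conj(fb), n=len(a)) / denom
    lags = np.arange(len(a))
    lags = np.where(lags > len(a) // 2, lags - len(a), lags)
    return c, lags


def compute_symmetry(gaw: GAWRecord, cycles: CycleSegmentation) -> dict:
    """Left-right phase asymmetry of the partial GAWs.

    PA_i is the signed left-minus-right peak-time difference as a fraction of
    the cycle, wrapped to [-0.5, 0.5]; PAI_i is |lag| / T_i at the maximum of
    the circular normalized cross-correlation between the left and right
    half-waveforms of the cycle.  Swapping left and right negates PA and
    leaves PAI unchanged.
    """
    if cycles.n_cycles < 2:
        raise FeatureExtractionError("symmetry measures require at least 2 cycles")
    if np.ptp(gaw.left) <= 0 or np.ptp(gaw.right) <= 0:
        raise FeatureExtractionError("constant half-signals")
    pa, pai = [], []
    for sl in cycles.slices():
        l_seg = gaw.left[sl]
        r_seg = gaw.right[sl]
        length = len(l_seg)
        diff = (int(np.argmax(l_seg)) - int(np.argmax(r_seg))) / length
        diff = (diff + 0.5) % 1.0 - 0.5
        pa.append(diff)
        c, lags = _circular_ncc(l_seg, r_seg)
        pai.append(abs(int(lags[int(np.argmax(c))])) / length)
    return {
        "PA_mean": float(np.mean(pa)), "PA_std": _std(pa),
        "PAI_mean": float(np.mean(pai)), "PAI_std": _std(pai),
    }


def _normalized_signal(gaw: GAWRecord) -> np.ndarray:
    x = gaw.total - gaw.total.mean()
    peak = np.max(np.abs(x))
    if peak <= 0:
        raise FeatureExtractionError("constant signal")
    return x / peak


def _harmonic_mask(n_bins: int, df: float, f0: float, halfwidth: int) -> np.ndarray:
    mask = np.zeros(n_bins, dtype=bool)
    k = 1
    while True:
        center = int(round(k * f0 / df))
        if center - halfwidth >= n_bins:
            break
        lo = max(center - halfwidth, 0)
        hi = min(center + halfwidth + 1, n_bins)
        mask[lo:hi] = True
        k += 1
    return mask


def _resample_cycle(seg: np.ndarray, k: int) -> np.ndarray:
    pos = np.linspace(0.0, 1.0, num=len(seg), endpoint=False)
    tgt = np.linspace(0.0, 1.0, num=k, endpoint=False)
    return np.interp(tgt, pos, seg)


def compute_noise(
    gaw: GAWRecord, cycles: CycleSegmentation, config: FeatureConfig | None = None
) -> dict:
    """Cepstral, harmonic-energy, waveform-matching, and windowed noise
    measures on the mean-removed, amplitude-normalized total GAW.

    CPM is the cepstral peak magnitude in the quefrency band of the F0 search
    range; CPPS the smoothed cepstral peak prominence above a linear
    quefrency regression; HI the fraction of spectral energy within +-1 bin
    of the harmonics k*F0; HNR = 10 log10(harmonic / non-harmonic energy);
    WMC the maximum circular normalized cross-correlation between consecutive
    cycles resampled to a common length; NNE and SNR are per-window
    (5 cycles, 50% hop) noise-to-total and harmonic-to-noise energy ratios in
    dB; SF the geometric-to-arithmetic mean ratio of the Welch power
    spectrum.
    """
    config = config or FeatureConfig()
    win = config.windows
    if cycles.n_cycles < win.cycles:
        raise FeatureExtractionError(
            f"analysis window of {win.cycles} cycles exceeds the {cycles.n_cycles}-cycle signal"
        )
    x = _normalized_signal(gaw)
    n = len(x)
    f0 = float(np.mean(1.0 / np.asarray(cycles.periods)))
    hw = config.harmonic_halfwidth

    # full-signal spectrum -> HI, HNR
    w = _sig.windows.hann(n, sym=False)
    p = np.abs(rfft(x * w)) ** 2
    df = gaw.fs / n
    mask = _harmonic_mask(len(p), df, f0, hw)
    e_tot = float(p.sum())
    e_h = float(p[mask].sum())
    e_n = max(e_tot - e_h, _EPS * e_tot)
    hi = e_h / e_tot
    hnr = 10.0 * np.log10(max(e_h, _EPS * e_tot) / e_n)

    # full-signal cepstrum -> CPM
    s_db = 10.0 * np.log10(p + _EPS * p.max())
    cep = irfft(s_db, n=n)
    q_lo = max(2, int(np.floor(gaw.fs / config.f0_range[1])))
    q_hi = min(n // 2, int(np.ceil(gaw.fs / config.f0_range[0])))
    cpm = float(np.max(cep[q_lo : q_hi + 1]))

    # short-time smoothed cepstrum -> CPPS
    frame = min(config.cpps_frame, n)
    hop = max(1, min(config.cpps_hop, frame // 2))
    starts = np.arange(0, n - frame + 1, hop)
    wf = _sig.windows.hann(frame, sym=False)
    ceps = []
    for st in starts:
        pf = np.abs(rfft(x[st : st + frame] * wf)) ** 2
        ceps.append(irfft(10.0 * np.log10(pf + _EPS * max(pf.max(), _EPS)), n=frame))
    ceps = np.asarray(ceps)
    if len(ceps) > 1:
        ceps = uniform_filter1d(ceps, size=min(config.cpps_time_smooth, len(ceps)), axis=0)
    ceps = uniform_filter1d(ceps, size=config.cpps_quef_smooth, axis=1)
    fq_lo = max(2, int(np.floor(gaw.fs / config.f0_range[1])))
    fq_hi = min(frame // 2 - 1, int(np.ceil(gaw.fs / config.f0_range[0])))
    quef = np.arange(fq_lo, frame // 2)
    prominences = []
    for c in ceps:
        band = c[fq_lo : frame // 2]
        slope, intercept = np.polyfit(quef, band, 1)
        pk_rel = int(np.argmax(c[fq_lo : fq_hi + 1]))
        pk_q = fq_lo + pk_rel
        prominences.append(c[pk_q] - (slope * pk_q + intercept))
    cpps = float(np.mean(prominences))

    # waveform matching between consecutive resampled cycles
    k = config.resample_points
    resampled = [_resample_cycle(seg, k) for seg in _cycle_segments(gaw, cycles)]
    wmc = []
    for a, b in zip(resampled[:-1], resampled[1:]):
        c, _ = _circular_ncc(a, b)
        wmc.append(min(float(c.max()), 1.0))  # guard FFT rounding above 1
    wmc = np.asarray(wmc)

    # windowed NNE / SNR
    nne, snr = [], []
    b = cycles.boundaries
    j = 0
    while j + win.cycles <= cycles.n_cycles:
        seg = x[b[j] : b[j + win.cycles]]
        wseg = _sig.windows.hann(len(seg), sym=False)
        pw = np.abs(rfft(seg * wseg)) ** 2
        dur = len(seg) / gaw.fs
        f0w = win.cycles / dur
        mw = _harmonic_mask(len(pw), gaw.fs / len(seg), f0w, hw)
        et = float(pw.sum())
        eh = float(pw[mw].sum())
        en = max(et - eh, _EPS * et)
        nne.append(10.0 * np.log10(en / et))
        snr.append(10.0 * np.log10(max(eh, _EPS * et) / en))
        j += win.hop

    # spectral flatness on the Welch-averaged power spectrum
    nper = min(256, n)
    _, pxx = _sig.welch(x, fs=gaw.fs, nperseg=nper)
    pxx = pxx[1:]  # drop DC
    pxx = pxx + _EPS * pxx.max()
    sf = float(np.exp(np.mean(np.log(pxx))) / np.mean(pxx))

    return {
        "CPM": cpm,
        "CPPS": cpps,
        "HI": float(hi),
        "HNR": float(hnr),
        "WMC_mean": float(wmc.mean()),
        "WMC_max": float(wmc.max()),
        "NNE_mean": float(np.mean(nne)),
        "NNE_std": _std(nne),
        "SNR_mean": float(np.mean(snr)),
        "SNR_std": _std(snr),
        "SF": sf,
    }


def compute_nyquist(
    gaw: GAWRecord, cycles: CycleSegmentation, config: FeatureConfig | None = None
) -> dict:
    """Consistency of per-cycle orbits in the amplitude-quadrature plane.

    The analytic signal of the normalized GAW embeds each cycle as a closed
    planar trajectory (resampled to ``resample_points``); TC_i = 1 - RMS
    distance of cycle i's trajectory from the pointwise mean trajectory
    (clipped to [0, 1]); WTV_i = std of the radial coordinate along the
    trajectory normalized by its mean radius.
    """
    config = config or FeatureConfig()
    if cycles.n_cycles < 3:
        raise FeatureExtractionError("Nyquist measures require at least 3 cycles")
    x = _normalized_signal(gaw)
    analytic = _sig.hilbert(x)
    k = config.resample_points
    trajs, wtv = [], []
    for sl in cycles.slices():
        z = analytic[sl]
        z = z - z.mean()
        scale = np.max(np.abs(z))
        if scale <= 0:
            raise FeatureExtractionError("zero-amplitude cycle")
        z = z / scale
        # radial variability from the raw samples (resampling would add
        # chord-interpolation ripple to a perfect circle)
        radii = np.abs(z)
        wtv.append(float(np.std(radii, ddof=1) / max(radii.mean(), _EPS)))
        trajs.append(_resample_cycle(z.real, k) + 1j * _resample_cycle(z.imag, k))
    trajs = np.asarray(trajs)
    wtv = np.asarray(wtv)
    mean_traj = trajs.mean(axis=0)
    tc = np.clip(
        1.0 - np.sqrt(np.mean(np.abs(trajs - mean_traj) ** 2, axis=1)), 0.0, 1.0
    )
    return {
        "TC_mean": float(tc.mean()), "TC_std": _std(tc),
        "WTV_mean": float(wtv.mean()), "WTV_std": _std(wtv),
    }


def extract_all(
    gaw: GAWRecord, cycles: CycleSegmentation, config: FeatureConfig | None = None
) -> GlottalFeatureVector:
    """Compute all 48 glottal parameters in the canonical order.

    Family errors are re-raised annotated with the family name.  The
    mechanical family needs ``config.glottal_length``; supply it explicitly
    for GAW-only input (no mask geometry to derive it from).
    """
    config = config or FeatureConfig()
    out: dict = {}
    families = [
        ("fundamental frequency", lambda: compute_f0_stats(gaw, cycles)),
        ("perturbation", lambda: compute_perturbation(gaw, cycles)),
        ("dynamics", lambda: compute_dynamics(gaw, cycles, config)),
        (
            "mechanical",
            lambda: compute_mechanical(gaw, cycles, config.glottal_length, config),
        ),
        ("symmetry", lambda: compute_symmetry(gaw, cycles)),
        ("noise", lambda: compute_noise(gaw, cycles, config)),
        ("nyquist", lambda: compute_nyquist(gaw, cycles, config)),
    ]
    for family, fn in families:
        try:
            out.update(fn())
        except FeatureExtractionError as exc:
            raise FeatureExtractionError(f"[{family}] {exc}") from exc
    return GlottalFeatureVector.from_dict(out)
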