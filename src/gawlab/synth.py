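"""Synthetic glottal area waveforms, glottis mask stacks, and visit cohorts.

The generator defines the study conditions every downstream stage is tested
against: severity-graded cycle-to-cycle perturbation (jitter/shimmer),
incomplete glottal closure, left-right phase asymmetry, additive noise, an
acoustic feature block partially redundant with the glottal block, a clinical
block with strongly anti-correlated VHI/VRQOL questionnaires, repeated visits
per subject, and ordinal rater noise on the hoarseness score H.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .extraction import CycleSegmentation, GAWRecord, MaskStack

__all__ = [
    "GAWSynthesisParams",
    "SyntheticGAW",
    "CohortSynthesisParams",
    "SyntheticCohort",
    "generate_gaw",
    "generate_mask_stack",
    "generate_cohort",
    "ACOUSTIC_COLUMNS",
    "CLINICAL_COLUMNS",
]

#: acoustic feature block recorded synchronously with HSV
ACOUSTIC_COLUMNS = ["ac_CPPS_mean", "ac_HI", "ac_mJit", "ac_Scentroid_std", "ac_A_mean"]
#: clinical feature block from the conventional voice examination
CLINICAL_COLUMNS = ["VRQOL", "VHI", "Fmax", "Imax", "Jit_pct"]


@dataclass(frozen=True)
class GAWSynthesisParams:
    """Generative controls for one synthetic glottal area waveform.

    Parameters
    ----------
    f0 : float
        Fundamental frequency in Hz (habitual pitch for sustained /i/).
    duration : float
        Nominal signal duration in seconds; ``duration * f0 >= 2``.
    fs : float
        Sampling (frame) rate in Hz, default 4000.
    amplitude : float
        Baseline cycle peak area in px^2.
    jitter, shimmer : float
        Relative standard deviations of cycle periods and peak amplitudes.
    snr_db : float
        Additive white-noise SNR in dB; ``inf`` disables noise.
    gap : float
        Residual closed-phase area as a fraction of ``amplitude``, in [0, 1).
    open_quotient : float
        Fraction of each cycle the glottis is open, in (0, 1].
    speed_ratio : float
        Opening/closing duration ratio (> 0).
    phase_lag : float
        Left-vs-right lag as a fraction of the period, in [-0.5, 0.5].
    seed : int
        Seed of the private random stream; identical params+seed reproduce
        the output bit-for-bit.
    """

    f0: float = 120.0
    duration: float = 0.3
    fs: float = 4000.0
    amplitude: float = 400.0
    jitter: float = 0.0
    shimmer: float = 0.0
    snr_db: float = math.inf
    gap: float = 0.0
    open_quotient: float = 0.7
    speed_ratio: float = 1.2
    phase_lag: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.f0 <= 0 or self.fs <= 2 * self.f0:
            raise ValueError("require f0 > 0 and fs > 2*f0")
        if self.duration * self.f0 < 2:
            raise ValueError("duration*f0 must be >= 2 (at least two cycles)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not 0 <= self.gap < 1:
            raise ValueError("gap must be in [0, 1)")
        if not 0 < self.open_quotient <= 1:
            raise ValueError("open_quotient must be in (0, 1]")
        if self.speed_ratio <= 0:
            raise ValueError("speed_ratio must be positive")
        if not -0.5 <= self.phase_lag <= 0.5:
            raise ValueError("phase_lag must be in [-0.5, 0.5]")
        if self.jitter < 0 or self.shimmer < 0:
            raise ValueError("jitter and shimmer must be nonnegative")


@dataclass
class SyntheticGAW:
    """A generated GAW plus its ground truth (realized cycles and boundaries)."""

    gaw: GAWRecord
    params: GAWSynthesisParams
    periods: np.ndarray  # realized cycle periods, seconds
    amplitudes: np.ndarray  # realized cycle peak areas, px^2
    boundaries: np.ndarray  # cycle start sample indices, len = n_cycles + 1

    @property
    def n_cycles(self) -> int:
        return len(self.periods)

    def cycle_segmentation(self) -> CycleSegmentation:
        """Ground-truth cycle segmentation (no detection involved)."""
        return CycleSegmentation(
            boundaries=self.boundaries,
            fs=self.gaw.fs,
            periods=self.periods,
            peak_amplitudes=self.amplitudes - self.params.gap * self.params.amplitude,
        )


def _pulse(v: np.ndarray, rise_frac: float) -> np.ndarray:
    """Squared-sine pulse on [0, 1): rise to 1 at ``rise_frac``, fall to 0 at 1."""
    p = np.empty_like(v)
    r = rise_frac
    up = v <= r
    p[up] = np.sin(0.5 * np.pi * v[up] / r) ** 2
    p[~up] = np.sin(0.5 * np.pi * (1.0 - v[~up]) / (1.0 - r)) ** 2
    return p


def generate_gaw(params: GAWSynthesisParams) -> SyntheticGAW:
    """Synthesize a total/left/right GAW cycle by cycle.

    Periods are T_i = (1/f0)(1 + jitter*eps_i) and peak areas
    A_i = amplitude(1 + shimmer*eta_i) with eps, eta standard normal.  Each
    cycle holds a closed phase at ``gap*amplitude`` followed by a smooth
    squared-sine pulse whose rise/fall split is set by ``speed_ratio``; the
    closed-first layout places the closure minima exactly at cycle starts.
    Left and right are the half-areas shifted by +-phase_lag/2 of a period;
    white noise scaled to ``snr_db`` is added per side, halves are clipped at
    zero and recombined into the total.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_cycles = int(math.floor(params.duration * params.f0))

    # one (eps, eta) pair per cycle, in cycle order: common random numbers
    # across jitter/shimmer levels at a fixed seed
    eps = np.empty(n_cycles)
    eta = np.empty(n_cycles)
    for i in range(n_cycles):
        eps[i] = rng.standard_normal()
        eta[i] = rng.standard_normal()
    periods = (1.0 + params.jitter * eps) / params.f0
    amplitudes = params.amplitude * (1.0 + params.shimmer * eta)
    if np.any(periods <= 0):
        raise ValueError("jitter too large: nonpositive cycle period drawn")
    if np.any(amplitudes <= 0):
        raise ValueError("shimmer too large: nonpositive cycle amplitude drawn")

    starts = np.concatenate([[0.0], np.cumsum(periods)])  # seconds
    boundaries = np.round(starts * params.fs).astype(int)
    n_samples = boundaries[-1]
    total = np.empty(n_samples)
    floor_area = params.gap * params.amplitude
    closed_frac = 1.0 - params.open_quotient
    rise_frac = params.speed_ratio / (1.0 + params.speed_ratio)
    for i in range(n_cycles):
        idx = np.arange(boundaries[i], boundaries[i + 1])
        if len(idx) == 0:
            continue
        # integer sample offsets: equal-period cycles are bit-identical
        u = (idx - boundaries[i]) / (boundaries[i + 1] - boundaries[i])
        seg = np.full(len(idx), floor_area)
        open_mask = u >= closed_frac
        if params.open_quotient == 1.0:
            open_mask[:] = True
        v = (u[open_mask] - closed_frac) / params.open_quotient
        seg[open_mask] = floor_area + (amplitudes[i] - floor_area) * _pulse(
            np.clip(v, 0.0, 1.0), rise_frac
        )
        total[idx[0] : idx[-1] + 1] = seg

    left = total / 2.0
    right = total / 2.0
    if params.phase_lag != 0.0:
        shift = int(round(params.phase_lag * params.fs / params.f0 / 2.0))
        left = np.roll(left, shift)
        right = np.roll(right, -shift)

    if math.isfinite(params.snr_db):
        p_sig = float(np.var(total))
        p_noise = p_sig / 10.0 ** (params.snr_db / 10.0)
        sd_half = math.sqrt(p_noise / 2.0)
        left = left + rng.normal(0.0, sd_half, n_samples)
        right = right + rng.normal(0.0, sd_half, n_samples)

    left = np.maximum(left, 0.0)
    right = np.maximum(right, 0.0)
    total = left + right

    gaw = GAWRecord(total=total, left=left, right=right, fs=params.fs)
    return SyntheticGAW(
        gaw=gaw,
        params=params,
        periods=periods,
        amplitudes=amplitudes,
        boundaries=boundaries,
    )


@dataclass(frozen=True)
class MaskGeometry:
    """Frame geometry and glottis template for mask-stack rendering.

    The glottis is rendered as an elongated lens (elliptical level sets of an
    anisotropic radius), mirror-symmetric about its long axis, centered in the
    frame at an in-plane ``rotation_deg``.
    """

    height: int = 64
    width: int = 64
    elongation: float = 6.0
    rotation_deg: float = 0.0


def generate_mask_stack(sg: SyntheticGAW, geometry: MaskGeometry | None = None) -> MaskStack:
    """Render the total GAW as a stack of binary glottis masks.

    Frame ``n`` contains a lens-shaped mask of ``round(total[n])`` pixels (up
    to whole symmetric tie-groups of equidistant pixels, so a symmetric
    template at rotation 0 has exactly equal left/right half areas).
    """
    geometry = geometry or MaskGeometry()
    h, w = geometry.height, geometry.width
    areas = np.round(sg.gaw.total).astype(int)
    if areas.max() > h * w:
        raise ValueError("area exceeds frame capacity; enlarge geometry")

    rows, cols = np.mgrid[0:h, 0:w]
    cy = (h - 1) / 2.0
    cx = (w - 1) / 2.0 if w % 2 else w / 2.0 - 0.5
    dy = rows - cy
    dx = cols - cx
    th = math.radians(geometry.rotation_deg)
    # long axis along image rows when rotation is 0
    u = math.cos(th) * dy + math.sin(th) * dx
    v = -math.sin(th) * dy + math.cos(th) * dx
    rho = np.sqrt((u / geometry.elongation) ** 2 + v**2).ravel()
    order = np.argsort(rho, kind="stable")
    rho_sorted = np.round(rho[order], 6)
    # cumulative pixel counts at whole tie-group boundaries
    _, group_start = np.unique(rho_sorted, return_index=True)
    group_cum = np.append(group_start[1:], len(rho_sorted))

    frames = np.zeros((len(areas), h, w), dtype=bool)
    flat_order = order
    for n, a in enumerate(areas):
        if a <= 0:
            continue
        j = np.searchsorted(group_cum, a)
        if j == 0:
            k = group_cum[0]
        else:
            below, above = group_cum[j - 1], group_cum[min(j, len(group_cum) - 1)]
            k = below if a - below <= above - a else above
        if k > 0:
            frames[n].ravel()[flat_order[:k]] = True
    return MaskStack(frames=frames, fs=sg.gaw.fs)


def _default_effect_map(s: float) -> GAWSynthesisParams:
    """Monotone link from latent severity s in [0, 1] to GAW synthesis controls.

    Ranges are chosen to span habitual phonation (s=0: near-periodic, closed,
    symmetric, 40 dB SNR) through severe dysphonia (s=1: 3% jitter, 10%
    shimmer, wide glottal gap, marked phase asymmetry, 15 dB SNR).
    """
    return GAWSynthesisParams(
        jitter=0.002 + 0.028 * s,
        shimmer=0.01 + 0.09 * s,
        snr_db=40.0 - 25.0 * s,
        gap=0.05 + 0.40 * s,
        phase_lag=0.15 * s,
    )


@dataclass(frozen=True)
class CohortSynthesisParams:
    """Controls for a multimodal visit cohort with known ground truth.

    ``questionnaire_r`` is the target Pearson correlation between the VHI and
    VRQOL questionnaires (default -0.949, the value observed clinically on
    paired questionnaires).  ``mode`` selects how the glottal block is built:
    ``"fast"`` draws the 48 feature columns directly from the severity link
    (exactly the five clinically selected features WTV_mean, NNE_std, HI,
    GGI_std, CQ_std carry the signal), ``"full"`` synthesizes a GAW per visit
    and runs cycle detection plus feature extraction, and ``"mask"``
    additionally routes each GAW through a rendered mask stack.
    """

    n_subjects: int = 400
    revisit_fraction: float = 0.1
    severity_distribution: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    rater_sd: float = 0.25
    questionnaire_r: float = -0.949
    modality_sd: float = 0.15
    n_redundant: int = 3
    mode: str = "fast"
    gaw_duration: float = 0.3
    seed: int = 0
    effect_map: object = field(default=None, compare=False)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 <= self.revisit_fraction <= 1:
            raise ValueError("revisit_fraction must be in [0, 1]")
        w = np.asarray(self.severity_distribution, dtype=float)
        if len(w) != 4 or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("severity_distribution must be 4 nonnegative weights summing to 1")
        if not -1 < self.questionnaire_r < 0:
            raise ValueError("questionnaire_r must be in (-1, 0)")
        if self.rater_sd < 0:
            raise ValueError("rater_sd must be nonnegative")
        if self.mode not in ("fast", "full", "mask"):
            raise ValueError("mode must be 'fast', 'full', or 'mask'")


@dataclass
class SyntheticCohort:
    """Visit table plus the generator's truth table."""

    visits: pd.DataFrame
    truth: pd.DataFrame
    params: CohortSynthesisParams

    def to_csv(self, visits_path, truth_path=None) -> None:
        self.visits.to_csv(visits_path, index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False)


def _fast_glottal_block(s_v: np.ndarray, rng: np.random.Generator, n_redundant: int) -> pd.DataFrame:
    """48 glottal feature columns with the severity signal planted in exactly
    the five clinically selected features; redundant pairs live among the
    noise columns.

    Each informative feature reads severity through its own independent
    channel latent (clip(s_v + noise)): the five measures quantify distinct
    physiological aspects of vocal-fold irregularity and are complementary,
    not copies of one another.
    """
    from .features import FEATURE_NAMES

    n = len(s_v)

    def channel():
        return np.clip(s_v + rng.normal(0, 0.18, n), 0.0, 1.0)

    informative = {
        "WTV_mean": 0.05 + 0.25 * channel() + rng.normal(0, 0.01, n),
        "NNE_std": 1.0 + 3.0 * channel() + rng.normal(0, 0.12, n),
        "HI": 0.95 - 0.35 * channel() + rng.normal(0, 0.014, n),
        "GGI_std": 0.02 + 0.10 * channel() + rng.normal(0, 0.004, n),
        "CQ_std": 0.02 + 0.10 * channel() + rng.normal(0, 0.004, n),
    }
    cols = {}
    noise_names = [f for f in FEATURE_NAMES if f not in informative]
    for name in noise_names:
        cols[name] = rng.normal(0.0, 1.0, n)
    # redundant pairs among noise features (|Spearman| >= 0.9 by construction)
    for j in range(min(n_redundant, len(noise_names) // 2)):
        a, b = noise_names[2 * j], noise_names[2 * j + 1]
        cols[b] = cols[a] + rng.normal(0, 0.1, n)
    cols.update(informative)
    return pd.DataFrame({name: cols[name] for name in FEATURE_NAMES})


def _full_glottal_block(
    s_v: np.ndarray, rng: np.random.Generator, params: CohortSynthesisParams
) -> pd.DataFrame:
    from .extraction import assemble_gaws, detect_cycles
    from .features import FeatureConfig, extract_all

    effect = params.effect_map or _default_effect_map
    rows = []
    config = FeatureConfig(glottal_length=8.0 * math.sqrt(400.0))
    for s in s_v:
        gp = effect(float(s))
        gp = replace(
            gp,
            duration=params.gaw_duration,
            f0=float(rng.uniform(140.0, 240.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sg = generate_gaw(gp)
        if params.mode == "mask":
            amp = sg.gaw.total.max()
            side = int(math.ceil(math.sqrt(amp * 4))) + 8
            stack = generate_mask_stack(sg, MaskGeometry(height=max(side, 48), width=max(side, 48)))
            gaw = assemble_gaws(stack)
        else:
            gaw = sg.gaw
        cycles = detect_cycles(gaw)
        fv = extract_all(gaw, cycles, config)
        rows.append(fv.to_dict())
    return pd.DataFrame(rows)


def generate_cohort(params: CohortSynthesisParams) -> SyntheticCohort:
    """Generate a multimodal visit cohort with known latent severity.

    Each subject receives a latent severity s in [0, 1] drawn from the
    configured H-level weights; modality blocks read s through independent
    per-block latents (partial redundancy between blocks), the H rating adds
    Gaussian rater noise before round-and-clamp to {0..3}, and a
    ``revisit_fraction`` of subjects contribute a second visit at a shifted
    severity.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects

    h_target = rng.choice(4, size=n, p=np.asarray(params.severity_distribution, dtype=float))
    # stay strictly inside the rating's rounding cell so the noiseless rater
    # maps s back to the drawn level (0.499 keeps float round-off out of it)
    s = np.clip((h_target + rng.uniform(-0.499, 0.499, n)) / 3.0, 0.0, 1.0)

    n_revisit = int(round(params.revisit_fraction * n))
    revisit_subjects = rng.choice(n, size=n_revisit, replace=False)
    is_revisit = np.zeros(n, dtype=bool)
    is_revisit[revisit_subjects] = True

    subj_ids, visit_ids, visit_order, s_all = [], [], [], []
    for i in range(n):
        subj_ids.append(i)
        visit_ids.append(f"S{i:04d}V1")
        visit_order.append(1)
        s_all.append(s[i])
        if is_revisit[i]:
            subj_ids.append(i)
            visit_ids.append(f"S{i:04d}V2")
            visit_order.append(2)
            s_all.append(float(np.clip(s[i] + rng.normal(0.0, 0.3), 0.0, 1.0)))
    s_all = np.asarray(s_all)
    m = len(s_all)

    # per-block latents: each modality reads severity with independent noise
    s_v = np.clip(s_all + rng.normal(0, params.modality_sd, m), 0, 1)
    s_a = np.clip(s_all + rng.normal(0, params.modality_sd, m), 0, 1)
    s_c = np.clip(s_all + rng.normal(0, 0.12, m), 0, 1)

    if params.mode == "fast":
        glottal = _fast_glottal_block(s_v, rng, params.n_redundant)
    else:
        glottal = _full_glottal_block(s_v, rng, params)

    acoustic = pd.DataFrame(
        {
            "ac_CPPS_mean": 18.0 - 8.0 * s_a + rng.normal(0, 1.2, m),
            "ac_HI": 0.95 - 0.30 * s_a + rng.normal(0, 0.05, m),
            "ac_mJit": (1e-4 + 8e-4 * s_a) * (1.0 + rng.normal(0, 0.15, m)),
            "ac_Scentroid_std": 80.0 + 180.0 * s_a + rng.normal(0, 25.0, m),
            "ac_A_mean": 1.0 - 0.5 * s_a + rng.normal(0, 0.08, m),
        }
    )

    vhi = 8.0 + 90.0 * s_c + rng.normal(0, 10.0, m)
    beta = -0.75
    r = params.questionnaire_r
    var_e = beta**2 * float(np.var(vhi)) * (1.0 / r**2 - 1.0)
    vrqol = 95.0 + beta * (vhi - vhi.mean()) + rng.normal(0, math.sqrt(var_e), m)
    clinical = pd.DataFrame(
        {
            "VRQOL": vrqol,
            "VHI": vhi,
            "Fmax": 550.0 - 180.0 * s_c + rng.normal(0, 60.0, m),
            "Imax": 95.0 - 15.0 * s_c + rng.normal(0, 6.0, m),
            "Jit_pct": 0.3 + 2.5 * s_c + rng.normal(0, 0.3, m),
        }
    )

    h = np.clip(np.round(3.0 * s_all + rng.normal(0, params.rater_sd, m)), 0, 3).astype(int)
    # R and B such that H = max(R, B): one of the two attains H
    attains_r = rng.integers(0, 2, m).astype(bool)
    other = np.clip(h - rng.integers(0, 2, m), 0, 3)
    rr = np.where(attains_r, h, other)
    bb = np.where(attains_r, other, h)

    visits = pd.concat(
        [
            pd.DataFrame(
                {"subject_id": subj_ids, "visit_id": visit_ids, "visit_order": visit_order}
            ),
            glottal.reset_index(drop=True),
            acoustic,
            clinical,
        ],
        axis=1,
    )
    visits["R"] = rr
    visits["B"] = bb
    visits["H"] = h
    visits["label"] = (h >= 2).astype(int)

    truth = pd.DataFrame(
        {
            "visit_id": visit_ids,
            "subject_id": subj_ids,
            "s": s_all,
            "s_glottal": s_v,
            "s_acoustic": s_a,
            "s_clinical": s_c,
            "H": h,
        }
    )
    return SyntheticCohort(visits=visits, truth=truth, params=params)
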