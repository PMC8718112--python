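"""Ground-truth phantom generators for all three pipelines.

Every generator is deterministic under a fixed seed and returns, next to
the synthetic data, a machine-readable truth record sufficient to compute
each downstream expected output in closed form — so segmentation, membrane
profiling, compartment ratios, spike metrics and binding fits can all be
validated without any external data.

The defaults emulate the published study conditions: 512 × 512 px planes
at 0.08 µm/px, ten optical slices at 0.5 µm, a convex soma with a bright
one-to-few-pixel Alexa594 rim over a dim cytoplasm, spontaneous firing at
1.5 Hz with agonist-onset inhibition and exponential recovery, and
six-concentration (0–100 nM) binding plates in triplicate with duplicate
blocked wells.

What the phantoms do *not* emulate: dendritic arbors and branch-plane
truncation artifacts, photon-accurate (Poisson) microscope statistics,
bursting or rhythmic spike-train structure, and well-position plate
effects.  Passing recovery tests therefore demonstrate correctness of the
measurement arithmetic and geometry, not robustness to every property of
real tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as disk_element

import pandas as pd

from receptorquant.endocytosis import compartment_fractions, cytoplasm_region
from receptorquant.membrane_quant import mask_to_contour, membrane_mean
from receptorquant.binding_fit import BindingPlate
from receptorquant.spike_metrics import SpikeExperiment, EARLY_WINDOW_S, LATE_WINDOW_S
from receptorquant.stack_model import TwoChannelStack

__all__ = [
    "CellPhantomParams",
    "CellPhantomTruth",
    "make_cell_stack",
    "FiringPhantomParams",
    "FiringPhantomTruth",
    "firing_params_from_targets",
    "make_spike_experiment",
    "render_trace",
    "make_binding_plate",
]


# --------------------------------------------------------------------------
# imaging phantom
# --------------------------------------------------------------------------

@dataclass
class CellPhantomParams:
    """Parameters of a two-channel cell phantom.

    Intensities are arbitrary units on the scale of the published group
    means (membrane ~170 AU).  ``internalized_fraction`` moves that share
    of the total rim signal into cytoplasmic puncta, conserving summed
    intensity.
    """

    shape: str = "disk"  # disk | ellipse | blob
    image_size: int = 512
    radius_px: float = 120.0
    membrane_rim_width_px: int = 2
    membrane_intensity: float = 170.0
    membrane_intensity_sd_per_slice: float = 0.0
    cytoplasm_a594_intensity: float = 20.0
    gfp_fill_intensity: float = 150.0
    background: float = 10.0
    puncta_count: int = 10
    puncta_radius_px: int = 4
    internalized_fraction: float = 0.0
    noise_sd: float = 5.0
    psf_sigma_px: float = 1.0
    n_slices: int = 10
    pixel_size_um: float = 0.08
    erosion_px: int = 8  # band assumed by the analytic truth record
    rng_seed: int = 0
    cell_id: str = "phantom"
    condition: str = ""

    def __post_init__(self) -> None:
        if self.membrane_rim_width_px < 1:
            raise ValueError("membrane rim width must be >= 1 px")
        if not 0.0 <= self.internalized_fraction <= 1.0:
            raise ValueError("internalized_fraction must be in [0, 1]")
        for name in (
            "membrane_intensity",
            "cytoplasm_a594_intensity",
            "gfp_fill_intensity",
            "background",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.shape not in ("disk", "ellipse", "blob"):
            raise ValueError("shape must be 'disk', 'ellipse' or 'blob'")
        margin = self.radius_px * (1.25 if self.shape == "blob" else 1.0)
        if margin + 2 > self.image_size / 2:
            raise ValueError("cell rim would extend outside the image bounds")


@dataclass
class CellPhantomTruth:
    """Closed-form expectations for a generated cell stack.

    ``f_memb_true`` / ``f_cyt_true`` are the noiseless-field means along
    the true mask's membrane line and over the true erosion-defined
    cytoplasm region, so downstream measurements can be compared at the
    discretization level actually generated.
    """

    true_masks: np.ndarray
    rim_masks: np.ndarray
    per_slice_rim_intensity: np.ndarray
    f_memb_true: float
    f_cyt_true: float
    memb_fraction_true: float
    cyt_fraction_true: float
    params: CellPhantomParams


def _cell_footprint(params: CellPhantomParams, rng: np.random.Generator) -> np.ndarray:
    n = params.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - c, xx - c
    if params.shape == "disk":
        return dx**2 + dy**2 <= params.radius_px**2
    if params.shape == "ellipse":
        return (dx / params.radius_px) ** 2 + (dy / (0.7 * params.radius_px)) ** 2 <= 1.0
    # blob: low-order radial Fourier perturbation of a disk (star-convex)
    theta = np.arctan2(dy, dx)
    r_th = np.ones_like(theta)
    for k in range(2, 6):
        amp = 0.06 * rng.uniform(0.3, 1.0)
        r_th = r_th + amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return np.hypot(dx, dy) <= params.radius_px * r_th


def make_cell_stack(
    params: CellPhantomParams,
) -> tuple[TwoChannelStack, CellPhantomTruth]:
    """Generate a two-channel phantom stack with its closed-form truth.

    The GFP channel is a uniform fill over the cell footprint; the Alexa594
    channel carries a rim at ``membrane_intensity × (1 − internalized
    fraction)``, a dim cytoplasm base, and puncta holding the internalized
    signal (summed intensity conserved).  An optional Gaussian PSF blurs
    the noiseless fields; additive Gaussian noise (clipped at zero) is
    applied last.
    """
    rng = np.random.default_rng(params.rng_seed)
    n = params.image_size
    footprint = _cell_footprint(params, rng)
    interior = ndimage.binary_erosion(
        footprint, structure=disk_element(params.membrane_rim_width_px).astype(bool)
    )
    rim = footprint & ~interior

    # puncta fully inside the measured cytoplasm region
    placement_margin = params.erosion_px + params.puncta_radius_px + 1
    allowed = ndimage.binary_erosion(
        footprint, structure=disk_element(placement_margin).astype(bool)
    )
    rows, cols = np.nonzero(allowed)

    gfp_clean = np.where(footprint, params.background + params.gfp_fill_intensity,
                         params.background)
    rim_area = int(rim.sum())

    gfp = np.empty((params.n_slices, n, n))
    a594 = np.empty((params.n_slices, n, n))
    a594_clean_stack = np.empty((params.n_slices, n, n))
    rim_values = np.empty(params.n_slices)
    f = params.internalized_fraction
    for s in range(params.n_slices):
        rim_nominal = params.membrane_intensity + (
            rng.normal(0.0, params.membrane_intensity_sd_per_slice)
            if params.membrane_intensity_sd_per_slice > 0
            else 0.0
        )
        rim_values[s] = rim_nominal * (1.0 - f)
        a594_clean = np.full((n, n), params.background)
        a594_clean[interior] += params.cytoplasm_a594_intensity
        # rim is an absolute level: the membrane label dominates background,
        # so the nominal membrane intensity is directly recoverable
        a594_clean[rim] = rim_values[s]
        if params.puncta_count > 0 and rows.size:
            idx = rng.choice(rows.size, size=params.puncta_count, replace=False)
            punct = np.zeros((n, n), dtype=bool)
            for r, c in zip(rows[idx], cols[idx]):
                rr0 = slice(r - params.puncta_radius_px, r + params.puncta_radius_px + 1)
                cc0 = slice(c - params.puncta_radius_px, c + params.puncta_radius_px + 1)
                punct[rr0, cc0] |= disk_element(params.puncta_radius_px).astype(bool)
            punct_area = int(punct.sum())
            if f > 0 and punct_area > 0:
                # internalized rim signal spread uniformly over the puncta
                amplitude = f * rim_nominal * rim_area / punct_area
                a594_clean[punct] += amplitude
        if params.psf_sigma_px > 0:
            a594_clean = ndimage.gaussian_filter(
                a594_clean, params.psf_sigma_px, mode="reflect"
            )
            gfp_s = ndimage.gaussian_filter(gfp_clean, params.psf_sigma_px, mode="reflect")
        else:
            gfp_s = gfp_clean
        a594_clean_stack[s] = a594_clean
        if params.noise_sd > 0:
            gfp[s] = np.clip(gfp_s + rng.normal(0, params.noise_sd, (n, n)), 0, None)
            a594[s] = np.clip(a594_clean + rng.normal(0, params.noise_sd, (n, n)), 0, None)
        else:
            gfp[s] = gfp_s
            a594[s] = a594_clean

    stack = TwoChannelStack(
        gfp=gfp,
        a594=a594,
        pixel_size_um=params.pixel_size_um,
        cell_id=params.cell_id,
        condition=params.condition,
    )

    # truth: noiseless-field means over the true geometry
    memb_means = []
    cyt_means = []
    cyt_region = cytoplasm_region(footprint, params.erosion_px)
    for s in range(params.n_slices):
        contour = mask_to_contour(footprint, rng_seed=params.rng_seed + s)
        memb_means.append(membrane_mean(contour, a594_clean_stack[s]))
        cyt_means.append(float(a594_clean_stack[s][cyt_region].mean()))
    f_memb_true = float(np.mean(memb_means))
    f_cyt_true = float(np.mean(cyt_means))
    frac = compartment_fractions(f_memb_true, f_cyt_true)
    truth = CellPhantomTruth(
        true_masks=np.repeat(footprint[np.newaxis], params.n_slices, axis=0),
        rim_masks=np.repeat(rim[np.newaxis], params.n_slices, axis=0),
        per_slice_rim_intensity=rim_values,
        f_memb_true=f_memb_true,
        f_cyt_true=f_cyt_true,
        memb_fraction_true=frac.memb_fraction,
        cyt_fraction_true=frac.cyt_fraction,
        params=params,
    )
    return stack, truth


# --------------------------------------------------------------------------
# firing phantom
# --------------------------------------------------------------------------

@dataclass
class FiringPhantomParams:
    """Inhomogeneous-Poisson model of agonist-inhibited spontaneous firing.

    The rate is ``baseline`` until agonist onset, drops to
    ``baseline × (1 − inhibition_depth)`` for ``recovery_delay_s`` (agonists
    reach maximal effect within the first two minutes and hold it), then
    recovers exponentially with time constant ``desens_tau_s`` toward
    ``baseline × (1 − inhibition_depth × (1 − desens_plateau))``;
    ``desens_plateau`` is the fraction of the suppression ultimately
    released by desensitization.
    """

    baseline_rate_hz: float = 1.5
    baseline_duration_s: float = 120.0
    agonist_duration_s: float = 300.0
    inhibition_depth: float = 1.0
    desens_plateau: float = 0.0
    desens_tau_s: float = 90.0
    recovery_delay_s: float = 120.0
    rng_seed: int = 0
    cell_id: str = "phantom"
    condition: str = ""

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.inhibition_depth <= 1.0:
            raise ValueError("inhibition_depth must be in [0, 1]")
        if not 0.0 <= self.desens_plateau <= 1.0:
            raise ValueError("desens_plateau must be in [0, 1]")
        if self.desens_tau_s <= 0:
            raise ValueError("desens_tau_s must be positive")

    @property
    def agonist_onset_s(self) -> float:
        return self.baseline_duration_s

    def rate(self, t: np.ndarray) -> np.ndarray:
        """Programmed instantaneous rate r(t), vectorized."""
        t = np.asarray(t, dtype=np.float64)
        t0 = self.agonist_onset_s
        b, d, p, tau = (
            self.baseline_rate_hz,
            self.inhibition_depth,
            self.desens_plateau,
            self.desens_tau_s,
        )
        u = t - t0 - self.recovery_delay_s
        recovered = np.where(u > 0, p * (1.0 - np.exp(-np.maximum(u, 0) / tau)), 0.0)
        r = np.where(t < t0, b, b * (1.0 - d * (1.0 - recovered)))
        return r

    def mean_rate_in(self, t0: float, t1: float) -> float:
        """Analytic window-averaged rate over [t0, t1) (closed form)."""
        b, d, p, tau = (
            self.baseline_rate_hz,
            self.inhibition_depth,
            self.desens_plateau,
            self.desens_tau_s,
        )
        onset = self.agonist_onset_s
        rec_start = onset + self.recovery_delay_s

        def integral(a: float, c: float) -> float:
            """∫ r dt over [a, c] assuming a <= c."""
            total = 0.0
            # baseline segment
            lo, hi = a, min(c, onset)
            if hi > lo:
                total += b * (hi - lo)
            # suppressed plateau segment
            lo, hi = max(a, onset), min(c, rec_start)
            if hi > lo:
                total += b * (1.0 - d) * (hi - lo)
            # exponential recovery segment
            lo, hi = max(a, rec_start), c
            if hi > lo:
                u0, u1 = lo - rec_start, hi - rec_start
                # ∫ b(1 - d(1 - p(1 - e^{-u/tau}))) du
                const = b * (1.0 - d * (1.0 - p))
                total += const * (u1 - u0) + b * d * p * tau * (
                    np.exp(-u1 / tau) - np.exp(-u0 / tau)
                )
            return total

        if not t1 > t0:
            raise ValueError("window must have positive length")
        return integral(t0, t1) / (t1 - t0)


@dataclass
class FiringPhantomTruth:
    """Analytic epoch rates and percent metrics of a firing phantom."""

    baseline_rate_hz: float
    early_rate_hz: float
    late_rate_hz: float
    percent_inhibition: float
    percent_desensitization: float
    expected_spike_count: float
    params: FiringPhantomParams


def firing_params_from_targets(
    inhibition_pct: float,
    desensitization_pct: float,
    baseline_rate_hz: float = 1.5,
    desens_tau_s: float = 90.0,
    rng_seed: int = 0,
    **kwargs,
) -> FiringPhantomParams:
    """Parameterize the firing phantom by target epoch metrics.

    The early-window (1–2 min) inhibition equals ``inhibition_pct``
    directly (full suppression is held through the early window).  The
    recovered plateau is solved so the 4.5–5 min window inhibition equals
    ``inhibition_pct − desensitization_pct``; when that target is below
    what full recovery can reach (desensitization larger than inhibition
    allows), the plateau clamps at 1 and the truth record carries the
    attainable analytic values.
    """
    d = inhibition_pct / 100.0
    target_late = max(inhibition_pct - desensitization_pct, 0.0) / 100.0
    params = FiringPhantomParams(
        baseline_rate_hz=baseline_rate_hz,
        inhibition_depth=d,
        desens_plateau=0.0,
        desens_tau_s=desens_tau_s,
        rng_seed=rng_seed,
        **kwargs,
    )
    if d > 0 and desensitization_pct > 0:
        a = LATE_WINDOW_S[0] - params.recovery_delay_s
        b_ = LATE_WINDOW_S[1] - params.recovery_delay_s
        if b_ <= 0:
            raise ValueError("late window precedes recovery onset")
        e2 = (
            desens_tau_s
            / (b_ - a)
            * (np.exp(-a / desens_tau_s) - np.exp(-b_ / desens_tau_s))
        )
        p = (1.0 - target_late / d) / (1.0 - e2)
        params.desens_plateau = float(min(max(p, 0.0), 1.0))
    return params


def make_spike_experiment(
    params: FiringPhantomParams,
) -> tuple[SpikeExperiment, FiringPhantomTruth]:
    """Sample an inhomogeneous-Poisson spike experiment plus analytic truth.

    Spikes are drawn by thinning a homogeneous process at the baseline rate
    (the programmed rate never exceeds baseline).
    """
    rng = np.random.default_rng(params.rng_seed)
    duration = params.baseline_duration_s + params.agonist_duration_s
    rmax = params.baseline_rate_hz
    if rmax < 0:
        raise ValueError("negative rate")
    if rmax == 0:
        times = np.array([])
    else:
        n_cand = rng.poisson(rmax * duration)
        cand = np.sort(rng.uniform(0.0, duration, n_cand))
        accept = rng.uniform(0.0, rmax, n_cand) < params.rate(cand)
        times = np.unique(cand[accept])
    exp = SpikeExperiment(
        spike_times=times,
        agonist_onset_s=params.agonist_onset_s,
        agonist_end_s=duration,
        baseline_start_s=0.0,
        cell_id=params.cell_id,
        condition=params.condition,
    )
    onset = params.agonist_onset_s
    base = params.mean_rate_in(0.0, onset)
    early = params.mean_rate_in(onset + EARLY_WINDOW_S[0], onset + EARLY_WINDOW_S[1])
    late = params.mean_rate_in(onset + LATE_WINDOW_S[0], onset + LATE_WINDOW_S[1])
    inh_early = min(max(100.0 * (1.0 - early / base), 0.0), 100.0) if base > 0 else np.nan
    inh_late = min(max(100.0 * (1.0 - late / base), 0.0), 100.0) if base > 0 else np.nan
    truth = FiringPhantomTruth(
        baseline_rate_hz=base,
        early_rate_hz=early,
        late_rate_hz=late,
        percent_inhibition=inh_early,
        percent_desensitization=min(max(inh_early - inh_late, 0.0), 100.0),
        expected_spike_count=params.mean_rate_in(0.0, duration) * duration,
        params=params,
    )
    return exp, truth


def render_trace(
    exp: SpikeExperiment,
    sampling_rate_hz: float = 10_000.0,
    duration_s: float | None = None,
    noise_sd: float = 1.0,
    spike_amplitude_sd_units: float = 8.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """Render spike times into a noisy extracellular-style trace.

    Each spike contributes a biphasic waveform (first derivative of a
    Gaussian, ~1 ms wide) whose peak is ``spike_amplitude_sd_units`` times
    the Gaussian noise SD.
    """
    if duration_s is None:
        end = exp.agonist_end_s
        duration_s = float(end if np.isfinite(end) else exp.spike_times[-1] + 1.0)
    n = int(round(duration_s * sampling_rate_hz))
    rng = np.random.default_rng(rng_seed)
    trace = rng.normal(0.0, noise_sd, n)
    # dominant negative peak exactly at the spike time plus a smaller
    # repolarization rebound (sub-threshold, so each spike is one event)
    sigma_s = 3e-4  # 0.3 ms waveform width
    half = int(round(8 * sigma_s * sampling_rate_hz))
    tt = (np.arange(-half, half + 1)) / sampling_rate_hz
    wave = -np.exp(-(tt**2) / (2 * sigma_s**2)) + 0.35 * np.exp(
        -((tt - 2.5 * sigma_s) ** 2) / (2 * (1.5 * sigma_s) ** 2)
    )
    wave = wave / np.abs(wave).max() * spike_amplitude_sd_units * noise_sd
    for t in exp.spike_times:
        i = int(round(t * sampling_rate_hz))
        lo, hi = i - half, i + half + 1
        if lo < 0 or hi > n:
            continue
        trace[lo:hi] += wave
    return trace


# --------------------------------------------------------------------------
# binding phantom
# --------------------------------------------------------------------------

def make_binding_plate(
    kd_nM: float = 5.0,
    bmax: float = 1.0,
    ns_slope: float = 0.001,
    noise_frac: float = 0.0,
    concentrations: tuple[float, ...] = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0),
    replicates: int = 3,
    blocked_replicates: int = 2,
    rng_seed: int = 0,
) -> tuple[BindingPlate, dict]:
    """Generate a two-wavelength plate following the one-site model.

    Total wells follow ``Bmax·L/(Kd+L) + ns·L`` and blocked wells ``ns·L``
    in ratio units; signals at both wavelengths are constructed so that
    background subtraction and 784/658 normalization recover the ratios
    exactly in the noise-free case.  Noise is multiplicative Gaussian with
    relative SD ``noise_frac`` on each well's ratio and 658-nm signal.

    Returns the plate and a truth record with the generating parameters
    and per-concentration true ratios.
    """
    conc = np.asarray(concentrations, dtype=np.float64)
    if np.unique(conc[conc > 0]).size < 4:
        raise ValueError(
            "degenerate design: need at least 4 distinct nonzero concentrations"
        )
    if kd_nM <= 0 or bmax <= 0:
        raise ValueError("kd_nM and bmax must be positive")
    rng = np.random.default_rng(rng_seed)
    bg784, bg658, receptor_signal = 100.0, 150.0, 900.0
    rows = []

    def add_wells(L: float, ratio_true: float, blocked: bool, n_rep: int) -> None:
        for rep in range(n_rep):
            s658 = bg658 + receptor_signal * (
                1.0 + (rng.normal(0.0, noise_frac) if noise_frac > 0 else 0.0)
            )
            ratio = ratio_true * (
                1.0 + (rng.normal(0.0, noise_frac) if noise_frac > 0 else 0.0)
            )
            rows.append(
                {
                    "concentration_nM": L,
                    "signal_784": bg784 + ratio * (s658 - bg658),
                    "signal_658": s658,
                    "blocked": blocked,
                    "no_primary": False,
                    "replicate_id": rep,
                }
            )

    true_total = {}
    for L in conc:
        total = bmax * L / (kd_nM + L) + ns_slope * L
        nonspec = ns_slope * L
        true_total[float(L)] = total
        add_wells(float(L), total, blocked=False, n_rep=replicates)
        add_wells(float(L), nonspec, blocked=True, n_rep=blocked_replicates)
    for rep in range(3):  # background wells: labeled, no primary antibody
        rows.append(
            {
                "concentration_nM": float(conc.max()),
                "signal_784": bg784,
                "signal_658": bg658,
                "blocked": False,
                "no_primary": True,
                "replicate_id": rep,
            }
        )
    plate = BindingPlate(pd.DataFrame(rows))
    truth = {
        "kd_nM": kd_nM,
        "bmax": bmax,
        "ns_slope": ns_slope,
        "true_total_ratio": true_total,
    }
    return plate, truth
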