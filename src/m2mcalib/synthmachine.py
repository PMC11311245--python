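"""Synthetic dual-machine RF generator.

Implements the product model of the echo spectrum — a machine system
response multiplying a tissue signal — with two virtual scanners and
parametric phantoms, so that the whole calibration pipeline can be
exercised with a known, analytic ground-truth transfer function.

Per scan line the medium is a Poisson stream of point scatterers with
i.i.d. Gaussian amplitudes (fully developed speckle).  Scatterers are
drawn in continuous depth and binned to the machine's axial sample grid;
binned amplitudes are scaled by ``Fs / 40 MHz`` so the continuous-
equivalent reflectivity is sampling-rate invariant and two machines
digitizing at different rates see the same medium (this is what makes
*stable* acquisitions — shared scatterer realization across machines —
meaningful when the grids differ).

The depth-dependent system response is piecewise-stationary: the axial
range is split into 100-sample blocks (on the 40 MHz reference grid)
aligned with the half-zones of the patch grid, and within each block the
line is filtered with

    H(d, f) = gain * focal(d) * exp(-(f - fc)^2 / (2 sigma^2))
              * 10^(-alpha * f[MHz] * 2 d[cm] / 20)

i.e. a Gaussian pulse spectrum (sigma from the fractional bandwidth, FWHM
convention), a Lorentzian-shaped focal gain profile centred on the focal
depth, and round-trip frequency-linear attenuation owned by the phantom.
The tissue spectral signature (power-law slope plus a Gaussian bump
emulating bead-size-dependent backscatter) shapes the reflectivity
spectrum independently of depth.  White electronic noise is added at the
machine's noise-floor amplitude and the frame is uniformly quantized to
the machine's bit depth.

Because patch axial zones overlap by half a patch, each zone spans two
blocks; the analytic transfer magnitude between machines is the
root-mean-square over a zone's two blocks of the machine response ratio
(attenuation and tissue signature cancel between machines).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import List, Optional, Tuple

import numpy as np

from .patching import PatchGridConfig
from .rf_io import AcquisitionMeta, RFDataset, RFFrame, quantize_frame, resample_frame

__all__ = [
    "MachineProfile",
    "PhantomProfile",
    "SimConfig",
    "StudyBundle",
    "simulate_frame",
    "simulate_dataset",
    "simulate_calibration_pair",
    "simulate_calibration_spectra",
    "simulate_study",
    "true_transfer_magnitude",
    "default_machine_pair",
    "default_phantoms",
    "standardize_dataset",
]

#: Reference grid every dataset is brought to before patching.
REF_FS = 40e6
REF_N_AXIAL = 2080


@dataclass(frozen=True)
class MachineProfile:
    """Virtual scanner: Gaussian pulse, focal gain profile, noise, ADC."""

    machine_id: str
    pulse_center: float  # Hz
    fractional_bandwidth: float  # FWHM of amplitude spectrum / pulse_center
    sampling_rate: float  # Hz
    gain: float = 1.0
    noise_floor: float = 0.0  # white-noise amplitude (std), linear
    focal_depth: float = 0.02  # m
    focal_width: float = 0.015  # m, half-width of the focal gain profile
    bit_depth: int = 16
    rolloff_order: int = 1  # super-Gaussian order of the pulse band edges
    ripple_amp: float = 0.0  # in-band spectral ripple depth (reverberation comb)
    ripple_period: float = 1.2e6  # Hz

    def __post_init__(self) -> None:
        if not 0 < self.pulse_center < self.sampling_rate / 2:
            raise ValueError("pulse_center must lie in (0, sampling_rate/2)")
        if self.fractional_bandwidth <= 0:
            raise ValueError("fractional_bandwidth must be positive")
        if self.noise_floor < 0 or self.gain <= 0:
            raise ValueError("gain must be positive and noise_floor nonnegative")

    @property
    def n_axial(self) -> int:
        """Native axial samples covering the reference imaging depth."""
        return int(round(REF_N_AXIAL * self.sampling_rate / REF_FS))

    def pulse_amplitude(self, f: np.ndarray) -> np.ndarray:
        # super-Gaussian amplitude spectrum, FWHM = fractional_bandwidth * fc;
        # rolloff_order = 1 is a plain Gaussian, higher orders give the
        # steeper band edges of heavily damped transducers
        p = self.rolloff_order
        sigma = (
            self.pulse_center
            * self.fractional_bandwidth
            / (2.0 * (2.0 * np.log(2.0)) ** (1.0 / (2.0 * p)))
        )
        u = (f - self.pulse_center) / sigma
        amp = np.exp(-0.5 * u ** (2 * p))
        if self.ripple_amp:
            # multiplicative comb from internal reverberation (echo at lag
            # 1/ripple_period), normalized to unit maximum
            amp = amp * (
                (1.0 + self.ripple_amp * np.cos(2.0 * np.pi * f / self.ripple_period))
                / (1.0 + self.ripple_amp)
            )
        return amp

    def focal_gain(self, depth: float) -> float:
        return 1.0 / np.sqrt(1.0 + ((depth - self.focal_depth) / self.focal_width) ** 2)


@dataclass(frozen=True)
class PhantomProfile:
    """Parametric uniform phantom.

    ``spectral signature`` amplitude: ``(f / 5 MHz)**powerlaw_exponent *
    (1 + sum_i bump_amp_i * exp(-(f - bump_center_i)**2 / (2 bump_width_i**2)))``
    with up to two Gaussian bumps (a bimodal bead-size mixture uses both).
    ``attenuation_slope`` is in dB/cm/MHz (round-trip path applied).
    """

    phantom_id: str
    scatterer_density: float = 5.2e4  # per metre per scan line (~1 per 40 MHz sample)
    powerlaw_exponent: float = 1.0
    bump_center: float = 5e6  # Hz
    bump_width: float = 2e6  # Hz
    bump_amp: float = 0.0
    bump2_center: float = 10e6  # Hz
    bump2_width: float = 2e6  # Hz
    bump2_amp: float = 0.0
    attenuation_slope: float = 0.5  # dB / cm / MHz
    sos: float = 1540.0  # m/s
    class_label: Optional[int] = None  # None => calibration phantom

    def __post_init__(self) -> None:
        if self.attenuation_slope < 0:
            raise ValueError("attenuation_slope must be >= 0")
        if self.scatterer_density < 0:
            raise ValueError("scatterer_density must be >= 0")

    def signature_amplitude(self, f: np.ndarray) -> np.ndarray:
        base = (np.asarray(f, dtype=np.float64) / 5e6) ** self.powerlaw_exponent
        bump = 1.0 + self.bump_amp * np.exp(
            -((f - self.bump_center) ** 2) / (2.0 * self.bump_width**2)
        )
        if self.bump2_amp:
            bump = bump + self.bump2_amp * np.exp(
                -((f - self.bump2_center) ** 2) / (2.0 * self.bump2_width**2)
            )
        return base * bump

    def attenuation_amplitude(self, f: np.ndarray, depth: float) -> np.ndarray:
        # round-trip path 2*depth, frequency-linear slope in dB/cm/MHz
        db = self.attenuation_slope * (f / 1e6) * (2.0 * depth * 100.0)
        return 10.0 ** (-db / 20.0)


def default_machine_pair() -> Tuple[MachineProfile, MachineProfile]:
    """The study's asymmetric pair: 9 MHz pulse at 40 MHz sampling vs.
    5 MHz pulse at 50 MHz sampling (resampled to 40 MHz downstream)."""
    a = MachineProfile(
        machine_id="machineA",
        pulse_center=8.9e6,
        fractional_bandwidth=0.7,
        sampling_rate=40e6,
        gain=1.0,
        noise_floor=0.0002,
        focal_depth=0.020,
        focal_width=0.018,
    )
    b = MachineProfile(
        machine_id="machineB",
        pulse_center=5.2e6,
        fractional_bandwidth=0.8,
        sampling_rate=50e6,
        gain=20.0,  # scanners' output scales are arbitrary and unmatched
        noise_floor=0.03,
        rolloff_order=2,  # heavily damped transducer: steep band edges
        ripple_amp=0.45,  # lens-reverberation comb inside the band,
        ripple_period=4.0e6,  # period well above the patch spectral resolution
        focal_depth=0.028,  # different focal configuration -> different
        focal_width=0.010,  # depth-gain profile than the training machine
    )
    return a, b


def default_phantoms() -> Tuple[PhantomProfile, PhantomProfile, PhantomProfile]:
    """Two classification phantoms with distinct bead-size-like spectral
    signatures, plus a uniform calibration phantom."""
    # Class contrast is purely spectral (attenuation and power-law are
    # matched, so no machine-invariant amplitude cue shortcuts the task).
    # Each class is a bimodal bead mixture: a loud backscatter bump in the
    # training machine's exclusive band (9.0 vs 10.6 MHz -- invisible to
    # the 5 MHz machine behind its steep band edge) and a moderate bump
    # inside the mutual band (5.7 vs 6.7 MHz).  A model trained on the
    # high-frequency machine leans on the loud exclusive-band cue, which
    # on the other machine contains only noise-floor energy, while the
    # mutual-band contrast remains fully recoverable by calibration.
    cls0 = PhantomProfile(
        phantom_id="classA",
        powerlaw_exponent=0.0,
        bump_center=9.0e6,
        bump_width=1.0e6,
        bump_amp=2.6,
        bump2_center=5.7e6,
        bump2_width=0.9e6,
        bump2_amp=1.4,
        attenuation_slope=0.3,
        sos=1540.0,
        class_label=0,
    )
    cls1 = PhantomProfile(
        phantom_id="classB",
        powerlaw_exponent=0.0,
        bump_center=10.6e6,
        bump_width=1.0e6,
        bump_amp=2.6,
        bump2_center=6.7e6,
        bump2_width=0.9e6,
        bump2_amp=1.4,
        attenuation_slope=0.3,
        sos=1539.0,
        class_label=1,
    )
    calib = PhantomProfile(
        phantom_id="calib1",
        powerlaw_exponent=1.5,
        bump_amp=0.0,
        attenuation_slope=0.7,
        sos=1545.0,
        class_label=None,
    )
    return cls0, cls1, calib


@dataclass
class SimConfig:
    """Study-scale configuration (desk defaults)."""

    n_frames_per_phantom: int = 100
    n_adapt_frames_per_phantom: int = 50
    n_calib_stable: int = 10
    n_calib_freehand: int = 50
    n_lateral: int = 256
    seed: int = 0


@dataclass
class StudyBundle:
    """Everything a calibration experiment needs, on the reference grid."""

    train_data: RFDataset  # training machine, both classes, labelled
    test_data: RFDataset  # testing machine, both classes, labelled
    adapt_data: RFDataset  # testing machine, adaptation frames (fine-tune/AUC)
    calib_stable: Tuple[RFDataset, RFDataset]  # (train side, test side)
    calib_freehand: Tuple[RFDataset, RFDataset]
    machines: Tuple[MachineProfile, MachineProfile] = None
    phantoms: Tuple[PhantomProfile, ...] = None


# ---------------------------------------------------------------------------
# block geometry


def _block_edges_ref(grid: PatchGridConfig = PatchGridConfig()) -> np.ndarray:
    """Depth-block edges on the reference grid: the patch half-zones plus
    leading and trailing blocks."""
    inner = [
        grid.axial_skip + k * grid.axial_step
        for k in range(grid.n_axial_positions + 2)
    ]  # 540, 640, ..., 1540 for the default grid
    return np.array([0] + inner + [REF_N_AXIAL])


def _machine_blocks(machine: MachineProfile, sos: float):
    """(native start row, native stop row, block center depth [m]) triples."""
    scale = machine.sampling_rate / REF_FS
    edges_ref = _block_edges_ref()
    edges = np.round(edges_ref * scale).astype(int)
    edges[-1] = machine.n_axial
    dz = sos / (2.0 * machine.sampling_rate)
    out = []
    for r0, r1 in zip(edges[:-1], edges[1:]):
        if r1 > r0:
            out.append((int(r0), int(r1), (r0 + r1) / 2.0 * dz))
    return out


def _zone_block_depths(zone: int, grid: PatchGridConfig = PatchGridConfig()):
    """Center depths (reference grid, in m at 1540-equivalent rows) of the two
    half-zone blocks a patch axial zone spans -- expressed as reference rows."""
    r0 = grid.axial_skip + zone * grid.axial_step
    return (r0 + 50.0, r0 + 150.0)  # centers of the two 100-row blocks


# ---------------------------------------------------------------------------
# frame synthesis


def _reflectivity(rng: np.random.Generator, machine, phantom, n_lines: int) -> np.ndarray:
    """Binned scatterer amplitudes, (n_lines, n_axial), 40 MHz-normalized.

    Scatterers are deposited with linear interpolation between the two
    neighbouring samples (triangle kernel); :func:`_synthesize` divides the
    spectrum by the kernel's sinc^2 response, so the sampled sequence
    represents the same continuous medium on any grid — a stable pair
    digitized at 40 and 50 MHz stays coherent in the shared band.
    """
    na = machine.n_axial
    dz = phantom.sos / (2.0 * machine.sampling_rate)
    depth_total = na * dz
    lam = phantom.scatterer_density * depth_total
    counts = rng.poisson(lam, n_lines)
    total = int(counts.sum())
    r = np.zeros(n_lines * na)
    if total:
        pos = rng.uniform(0.0, depth_total, total)
        amp = rng.normal(0.0, 1.0, total)
        line = np.repeat(np.arange(n_lines), counts)
        x = pos / dz
        lo = np.minimum(x.astype(np.int64), na - 1)
        frac = x - lo
        hi = np.minimum(lo + 1, na - 1)
        base = line * na
        r = np.bincount(base + lo, weights=amp * (1.0 - frac), minlength=n_lines * na)
        r += np.bincount(base + hi, weights=amp * frac, minlength=n_lines * na)
    return (r * (machine.sampling_rate / REF_FS)).reshape(n_lines, na)


def _system_filter_bank(machine: MachineProfile, phantom: PhantomProfile):
    """Per-block complex-spectrum gains on the native rfft grid, and the
    tissue signature gain (depth-independent)."""
    na = machine.n_axial
    f = np.fft.rfftfreq(na, d=1.0 / machine.sampling_rate)
    sig = phantom.signature_amplitude(f)
    blocks = _machine_blocks(machine, phantom.sos)
    gains = [
        machine.gain
        * machine.focal_gain(d)
        * machine.pulse_amplitude(f)
        * phantom.attenuation_amplitude(f, d)
        for (_, _, d) in blocks
    ]
    return blocks, gains, sig


def _synthesize(
    machine: MachineProfile,
    phantom: PhantomProfile,
    noise_rng: np.random.Generator,
    refl_rng: np.random.Generator,
    n_lines: int,
) -> np.ndarray:
    r = _reflectivity(refl_rng, machine, phantom, n_lines)
    blocks, gains, sig = _system_filter_bank(machine, phantom)
    na_f = np.fft.rfftfreq(machine.n_axial, d=1.0 / machine.sampling_rate)
    deposit = np.sinc(na_f / machine.sampling_rate) ** 2  # triangle-kernel response
    spec = np.fft.rfft(r, axis=1) * (sig / deposit)
    na = machine.n_axial
    out = np.empty((n_lines, na))
    for (r0, r1, _), g in zip(blocks, gains):
        y = np.fft.irfft(spec * g, n=na, axis=1)
        out[:, r0:r1] = y[:, r0:r1]
    if machine.noise_floor > 0:
        out += noise_rng.normal(0.0, machine.noise_floor, out.shape)
    return out.T  # (n_axial, n_lines)


def simulate_frame(
    machine: MachineProfile,
    phantom: PhantomProfile,
    seed: int,
    reflectivity_seed: Optional[int] = None,
    n_lateral: int = 256,
    acquisition_mode: str = "freehand",
    frame_index: int = 0,
) -> RFFrame:
    """One native-rate RF frame.

    ``seed`` drives machine-side randomness (electronic noise);
    ``reflectivity_seed`` drives the scatterer realization (defaults to
    ``seed``), so a stable acquisition pair is produced by giving two
    machines the same ``reflectivity_seed`` and different ``seed``.
    Deterministic: same seeds give bit-identical frames.
    """
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    refl_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed if reflectivity_seed is None else reflectivity_seed), 0])
    )
    samples = _synthesize(machine, phantom, noise_rng, refl_rng, n_lateral).astype(np.float32)
    frame = RFFrame(
        samples=samples,
        meta=AcquisitionMeta(
            machine_id=machine.machine_id,
            phantom_id=phantom.phantom_id,
            sampling_rate=machine.sampling_rate,
            acquisition_mode=acquisition_mode,
            frame_index=frame_index,
            class_label=phantom.class_label,
        ),
    )
    return quantize_frame(frame, machine.bit_depth)


def standardize_dataset(ds: RFDataset, target_rate: float = REF_FS) -> RFDataset:
    """Bring a dataset to the reference sampling rate (rational resampling)."""
    if not len(ds):
        return ds
    rate = ds.sampling_rate()
    if rate == target_rate:
        return ds
    frac = Fraction(target_rate / rate).limit_denominator(64)
    frames = []
    for fr in ds:
        out = resample_frame(fr, frac.numerator, frac.denominator)
        out.samples = out.samples.astype(np.float32)
        frames.append(out)
    return RFDataset(
        frames=frames,
        provenance=ds.provenance + f" | resampled x{frac.numerator}/{frac.denominator}",
        format_version=ds.format_version,
    )


def simulate_dataset(
    machine: MachineProfile,
    phantom: PhantomProfile,
    n_frames: int,
    seed: int,
    n_lateral: int = 256,
    acquisition_mode: str = "freehand",
    reflectivity_seeds: Optional[List[int]] = None,
    standardize: bool = False,
) -> RFDataset:
    """Simulate ``n_frames`` independent frames (optionally with pinned
    reflectivity seeds, optionally resampled to the reference rate)."""
    frames = []
    for k in range(n_frames):
        frames.append(
            simulate_frame(
                machine,
                phantom,
                seed=seed + 7919 * k,
                reflectivity_seed=None if reflectivity_seeds is None else reflectivity_seeds[k],
                n_lateral=n_lateral,
                acquisition_mode=acquisition_mode,
                frame_index=k,
            )
        )
    ds = RFDataset(
        frames=frames,
        provenance=f"synthetic | machine={machine.machine_id} phantom={phantom.phantom_id} seed={seed}",
    )
    return standardize_dataset(ds) if standardize else ds


def simulate_calibration_pair(
    machine_a: MachineProfile,
    machine_b: MachineProfile,
    calib_phantom: PhantomProfile,
    n_frames: int,
    seed: int,
    acquisition_mode: str = "stable",
    n_lateral: int = 256,
) -> Tuple[RFDataset, RFDataset]:
    """Calibration-phantom acquisitions on both machines (native rates).

    Stable mode: frame ``k`` on both machines shares one scatterer
    realization (the clamped-transducer protocol); electronic noise stays
    machine-specific.  Free-hand mode: every frame on every machine has an
    independent realization.
    """
    if acquisition_mode == "stable":
        refl = [seed + 104729 + 7919 * k for k in range(n_frames)]
        refl_a = refl_b = refl
    elif acquisition_mode == "freehand":
        refl_a = [seed + 104729 + 7919 * k for k in range(n_frames)]
        refl_b = [seed + 224737 + 7919 * k for k in range(n_frames)]
    else:
        raise ValueError(f"unknown acquisition_mode {acquisition_mode!r}")
    ds_a = simulate_dataset(
        machine_a, calib_phantom, n_frames, seed=seed + 1_000_003,
        n_lateral=n_lateral, acquisition_mode=acquisition_mode, reflectivity_seeds=refl_a,
    )
    ds_b = simulate_dataset(
        machine_b, calib_phantom, n_frames, seed=seed + 2_000_003,
        n_lateral=n_lateral, acquisition_mode=acquisition_mode, reflectivity_seeds=refl_b,
    )
    return ds_a, ds_b


def _merge(datasets: List[RFDataset], provenance: str) -> RFDataset:
    frames = []
    for ds in datasets:
        frames.extend(ds.frames)
    for k, fr in enumerate(frames):
        fr.meta = replace(fr.meta, frame_index=k)
    return RFDataset(frames=frames, provenance=provenance)


def simulate_study(
    config: SimConfig = SimConfig(),
    machines: Optional[Tuple[MachineProfile, MachineProfile]] = None,
    phantoms: Optional[Tuple[PhantomProfile, ...]] = None,
) -> StudyBundle:
    """Full two-machine study: class-balanced labelled data on both
    machines, adaptation frames on the test machine, and stable plus
    free-hand calibration pairs — all standardized to the 40 MHz grid."""
    mach_a, mach_b = machines or default_machine_pair()
    cls0, cls1, calib = phantoms or default_phantoms()
    s = config.seed

    def _class_data(machine, n_frames, base_seed):
        parts = [
            simulate_dataset(machine, ph, n_frames, seed=base_seed + 17 * i,
                             n_lateral=config.n_lateral)
            for i, ph in enumerate((cls0, cls1))
        ]
        return standardize_dataset(
            _merge(parts, f"synthetic study | machine={machine.machine_id}")
        )

    train_data = _class_data(mach_a, config.n_frames_per_phantom, s + 11)
    test_data = _class_data(mach_b, config.n_frames_per_phantom, s + 311)
    adapt_data = _class_data(mach_b, config.n_adapt_frames_per_phantom, s + 611)

    stab_a, stab_b = simulate_calibration_pair(
        mach_a, mach_b, calib, config.n_calib_stable, seed=s + 911,
        acquisition_mode="stable", n_lateral=config.n_lateral,
    )
    free_a, free_b = simulate_calibration_pair(
        mach_a, mach_b, calib, config.n_calib_freehand, seed=s + 1211,
        acquisition_mode="freehand", n_lateral=config.n_lateral,
    )
    return StudyBundle(
        train_data=train_data,
        test_data=test_data,
        adapt_data=adapt_data,
        calib_stable=(standardize_dataset(stab_a), standardize_dataset(stab_b)),
        calib_freehand=(standardize_dataset(free_a), standardize_dataset(free_b)),
        machines=(mach_a, mach_b),
        phantoms=(cls0, cls1, calib),
    )


def simulate_calibration_spectra(
    machine_a: MachineProfile,
    machine_b: MachineProfile,
    calib_phantom: PhantomProfile,
    n_frames: int,
    seed: int,
    acquisition_mode: str = "stable",
    n_lateral: int = 256,
    chunk: int = 25,
    n_zones: int = 9,
):
    """Averaged per-zone calibration spectra for both machines, streamed.

    Simulates the calibration pair in chunks, standardizes to the
    reference grid, extracts patches, accumulates the per-zone averaged
    power spectra, and discards the frames — memory stays bounded
    regardless of ``n_frames`` (free-hand acquisitions use many hundreds
    of frames).  Returns ``(DepthSpectra_a, DepthSpectra_b)``.
    """
    from .patching import extract_patches_dataset
    from .transfer import DepthSpectra, average_power_spectra

    sums = [None, None]
    counts = [None, None]
    freq = None
    done = 0
    while done < n_frames:
        k = min(chunk, n_frames - done)
        ds_a, ds_b = simulate_calibration_pair(
            machine_a, machine_b, calib_phantom, n_frames=k,
            seed=seed + 611 * done, acquisition_mode=acquisition_mode,
            n_lateral=n_lateral,
        )
        for i, ds in enumerate((ds_a, ds_b)):
            ds = standardize_dataset(ds)
            X, z, _ = extract_patches_dataset(ds)
            spec = average_power_spectra(X, n_zones=n_zones, sampling_rate=REF_FS, zones=z)
            freq = spec.freq_grid
            w = spec.n_source_patches_per_zone[:, None]
            if sums[i] is None:
                sums[i] = spec.power * w
                counts[i] = spec.n_source_patches_per_zone.copy()
            else:
                sums[i] += spec.power * w
                counts[i] += spec.n_source_patches_per_zone
        done += k
    return tuple(
        DepthSpectra(
            power=sums[i] / counts[i][:, None],
            freq_grid=freq,
            n_source_patches_per_zone=counts[i],
        )
        for i in (0, 1)
    )


# ---------------------------------------------------------------------------
# analytic oracle


def true_transfer_magnitude(
    machine_a: MachineProfile,
    machine_b: MachineProfile,
    zone: int,
    n_fft: int = 200,
    sampling_rate: float = REF_FS,
    sos: float = 1540.0,
    grid: PatchGridConfig = PatchGridConfig(),
) -> np.ndarray:
    """Analytic ``|S_b(z, f) / S_a(z, f)|`` on the patch frequency grid.

    A patch axial zone spans two piecewise-stationary depth blocks, so the
    machine power responses are averaged over the zone's two block-center
    depths before taking the ratio.  Tissue factors (signature,
    attenuation) are common to both machines and cancel.
    """
    f = np.fft.rfftfreq(n_fft, d=1.0 / sampling_rate)
    dz = sos / (2.0 * sampling_rate)
    depths = [r * dz for r in _zone_block_depths(zone, grid)]

    def power(machine):
        return np.mean(
            [
                (machine.gain * machine.focal_gain(d) * machine.pulse_amplitude(f)) ** 2
                for d in depths
            ],
            axis=0,
        )

    return np.sqrt(power(machine_b) / power(machine_a))
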