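"""Machine-to-machine spectral transfer function estimation and application.

The echo spectrum factors into a machine-dependent system response and a
medium-dependent tissue signal, ``I(x, f) = S(x, f) P(x, f)``.  Imaging one
uniform calibration phantom on two machines therefore lets the tissue
factor cancel in the ratio of the two measured spectra, leaving the ratio
of system responses: the transfer-function magnitude

    |Gamma(z, f)| = sqrt( P_test(z, f) / P_train(z, f) )

estimated per axial zone ``z`` from averaged one-sided power spectra of
calibration patches.  The raw gain is regularized with an SNR-weighted,
Wiener-inspired rule

    Gamma_W = |Gamma|^-1 / (|Gamma|^-2 + SNR^-1)
            = |Gamma| * SNR / (SNR + |Gamma|^2)

which leaves the gain unchanged where the SNR is high and damps it to zero
where the SNR vanishes (a denoising behaviour).  Per-bin SNR on each side
is ``(P - floor) / floor`` with the noise floor taken as the minimum of the
zone's averaged spectrum; the combined SNR is the per-bin minimum of the
two sides.

The regularized gain is applied to RF patches zone-by-zone as a zero-phase
filter: per column, forward real FFT, multiply by the real gain, inverse
real FFT.  A linear-convolution variant with a symmetric FIR kernel
(frequency-sampling design) is available via ``mode="fir"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .errors import CoverageError, DegenerateInputError
from .patching import Patch, _as_stack

__all__ = [
    "DepthSpectra",
    "SNRProfile",
    "TransferFunction",
    "average_power_spectra",
    "estimate_snr_profile",
    "estimate_transfer_magnitude",
    "wiener_regularize",
    "apply_transfer",
    "build_bidirectional",
    "M2MCalibrator",
]


@dataclass
class DepthSpectra:
    """Averaged one-sided power spectrum per axial zone.

    ``power[z, k]`` is the periodogram ``|rfft(column)|**2 / n_fft``
    averaged over all columns of all patches of zone ``z`` (rectangular
    window, no zero-padding, ``n_fft = patch_axial``).
    """

    power: np.ndarray  # (n_zones, n_freq_bins)
    freq_grid: np.ndarray  # Hz
    n_source_patches_per_zone: np.ndarray

    @property
    def n_zones(self) -> int:
        return self.power.shape[0]


@dataclass
class SNRProfile:
    """Per-zone, per-bin SNR for both calibration sides and their minimum."""

    snr_train: np.ndarray
    snr_test: np.ndarray
    snr: np.ndarray  # elementwise min(snr_train, snr_test)
    noise_floor_train: np.ndarray  # per-zone scalars
    noise_floor_test: np.ndarray


@dataclass
class TransferFunction:
    """Per-zone spectral magnitude gain between two machine domains."""

    gamma_raw: np.ndarray  # (n_zones, n_freq_bins), >= 0
    freq_grid: np.ndarray
    direction: str  # "train_to_test" | "test_to_train"
    gamma_wiener: Optional[np.ndarray] = None
    provenance: str = ""

    @property
    def n_zones(self) -> int:
        return self.gamma_raw.shape[0]


def average_power_spectra(
    patches, n_zones: int = 9, sampling_rate: float = 40e6, zones=None
) -> DepthSpectra:
    """Average one-sided column periodograms per axial zone.

    Accepts a list of :class:`~m2mcalib.patching.Patch` (zones read from
    the patches) or an ``(N, H, W)`` array plus a ``zones`` vector.
    """
    if isinstance(patches, np.ndarray):
        X = patches
        if zones is None:
            raise ValueError("zones must be given with an array input")
        z = np.asarray(zones)
    else:
        X = _as_stack(patches)
        z = np.asarray([p.axial_zone for p in patches])
    n_fft = X.shape[1]
    present = set(np.unique(z).tolist())
    missing = [k for k in range(n_zones) if k not in present]
    if missing:
        raise CoverageError(f"no patches for axial zones {missing}")
    freq = np.fft.rfftfreq(n_fft, d=1.0 / sampling_rate)
    power = np.empty((n_zones, freq.size))
    counts = np.empty(n_zones, dtype=np.int64)
    for k in range(n_zones):
        sel = X[z == k]
        spec = np.abs(np.fft.rfft(sel.astype(np.float64, copy=False), axis=1)) ** 2
        power[k] = spec.mean(axis=(0, 2)) / n_fft
        counts[k] = sel.shape[0]
    return DepthSpectra(power=power, freq_grid=freq, n_source_patches_per_zone=counts)


def _check_grids(a: DepthSpectra, b: DepthSpectra) -> None:
    if a.power.shape != b.power.shape or not np.allclose(a.freq_grid, b.freq_grid):
        raise ValueError("spectra have mismatched zone/frequency grids")


def estimate_snr_profile(spec_train: DepthSpectra, spec_test: DepthSpectra) -> SNRProfile:
    """Noise-floor SNR per zone and frequency bin.

    Per zone the noise floor is the minimum of the averaged spectrum over
    all bins; ``SNR = (P - floor) / floor`` on each side, combined by the
    elementwise minimum.  The floor bin itself has SNR exactly 0.
    """
    _check_grids(spec_train, spec_test)
    floors_tr = spec_train.power.min(axis=1)
    floors_te = spec_test.power.min(axis=1)
    if np.any(floors_tr <= 0) or np.any(floors_te <= 0):
        raise DegenerateInputError(
            "zero noise floor: some zone's averaged spectrum has a non-positive "
            "minimum; SNR estimation is undefined"
        )
    snr_tr = (spec_train.power - floors_tr[:, None]) / floors_tr[:, None]
    snr_te = (spec_test.power - floors_te[:, None]) / floors_te[:, None]
    return SNRProfile(
        snr_train=snr_tr,
        snr_test=snr_te,
        snr=np.minimum(snr_tr, snr_te),
        noise_floor_train=floors_tr,
        noise_floor_test=floors_te,
    )


def estimate_transfer_magnitude(
    spec_train: DepthSpectra,
    spec_test: DepthSpectra,
    direction: str = "train_to_test",
    provenance: str = "",
) -> TransferFunction:
    """Raw transfer magnitude ``sqrt(P_test / P_train)`` (or its reciprocal).

    The denominator is floored at ``1e-12`` times its maximum so degenerate
    bins cannot produce infinities.
    """
    _check_grids(spec_train, spec_test)
    if direction == "train_to_test":
        num, den = spec_test.power, spec_train.power
    elif direction == "test_to_train":
        num, den = spec_train.power, spec_test.power
    else:
        raise ValueError(f"unknown direction {direction!r}")
    den = np.maximum(den, 1e-12 * den.max())
    gamma = np.sqrt(num / den)
    return TransferFunction(
        gamma_raw=gamma,
        freq_grid=spec_train.freq_grid.copy(),
        direction=direction,
        provenance=provenance,
    )


def wiener_regularize(tf: TransferFunction, snr: SNRProfile) -> TransferFunction:
    """Fill ``gamma_wiener`` with the SNR-damped gain.

    ``gamma_wiener = |Gamma| * SNR / (SNR + |Gamma|**2)``, the numerically
    stable form of ``|Gamma|^-1 / (|Gamma|^-2 + SNR^-1)``.  Limits:
    infinite SNR returns ``|Gamma|``; zero SNR or zero ``|Gamma|`` returns 0.
    """
    if tf.gamma_raw.shape != snr.snr.shape:
        raise ValueError("transfer function and SNR profile shapes differ")
    if np.any(snr.snr < 0):
        raise ValueError("SNR must be nonnegative")
    g = tf.gamma_raw
    s = snr.snr
    with np.errstate(invalid="ignore"):
        gw = np.where(np.isinf(s), g, g * s / np.where(s + g**2 > 0, s + g**2, 1.0))
    gw = np.where((s == 0) | (g == 0), 0.0, gw)
    return replace(tf, gamma_wiener=gw)


def apply_transfer(patches, tf: TransferFunction, zones=None, mode: str = "fft", n_taps: int = 129):
    """Filter patches with their zone-matched regularized gain.

    Zero-phase: per column, forward real FFT, multiply the complex spectrum
    by the real gain of the patch's axial zone, inverse real FFT
    (``mode="fft"``, circular).  ``mode="fir"`` instead convolves each
    column with a symmetric FIR kernel obtained by frequency sampling of
    the gain (linear convolution, ``same`` output length).

    Accepts a Patch list (zones carried by the patches) or an ``(N, H, W)``
    array plus a ``zones`` vector; labels and zones are preserved.
    """
    if tf.gamma_wiener is None:
        raise ValueError("transfer function has no regularized gain; run wiener_regularize")
    if isinstance(patches, np.ndarray):
        X = patches
        if zones is None:
            raise ValueError("zones must be given with an array input")
        z = np.asarray(zones)
        return _apply_gain(X, z, tf, mode, n_taps).astype(patches.dtype, copy=False)
    X = _as_stack(patches)
    z = np.asarray([p.axial_zone for p in patches])
    out = _apply_gain(X, z, tf, mode, n_taps)
    return [
        Patch(data=out[i], axial_zone=p.axial_zone, class_label=p.class_label, source=p.source)
        for i, p in enumerate(patches)
    ]


def _apply_gain(X: np.ndarray, z: np.ndarray, tf: TransferFunction, mode: str, n_taps: int):
    n_fft = X.shape[1]
    gain = tf.gamma_wiener
    if gain.shape[1] != n_fft // 2 + 1:
        raise ValueError(
            f"patch axial length {n_fft} does not match the transfer function "
            f"grid of {gain.shape[1]} bins"
        )
    if z.min() < 0 or z.max() >= tf.n_zones:
        raise ValueError(
            f"patch zones span [{z.min()}, {z.max()}] but the transfer function "
            f"covers zones [0, {tf.n_zones - 1}]"
        )
    out = np.empty_like(X, dtype=np.float64)
    if mode == "fft":
        for k in np.unique(z):
            sel = z == k
            spec = np.fft.rfft(X[sel].astype(np.float64, copy=False), axis=1)
            out[sel] = np.fft.irfft(spec * gain[k][None, :, None], n=n_fft, axis=1)
    elif mode == "fir":
        from scipy.signal import firwin2, oaconvolve

        nyq = tf.freq_grid[-1]
        for k in np.unique(z):
            h = firwin2(n_taps, tf.freq_grid / nyq, gain[k])
            sel = z == k
            full = oaconvolve(X[sel].astype(np.float64, copy=False), h[None, :, None], axes=1)
            lag = (n_taps - 1) // 2
            out[sel] = full[:, lag : lag + n_fft, :]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def build_bidirectional(
    spec_train: DepthSpectra, spec_test: DepthSpectra, provenance: str = ""
) -> Tuple[TransferFunction, TransferFunction, SNRProfile]:
    """Both transfer directions plus the shared SNR profile.

    The two directions are estimated from the same averaged spectra (the
    raw magnitudes are exact reciprocals) and independently
    Wiener-regularized with the same combined SNR.
    """
    snr = estimate_snr_profile(spec_train, spec_test)
    fwd = estimate_transfer_magnitude(spec_train, spec_test, "train_to_test", provenance)
    bwd = estimate_transfer_magnitude(spec_train, spec_test, "test_to_train", provenance)
    return wiener_regularize(fwd, snr), wiener_regularize(bwd, snr), snr


class M2MCalibrator(BaseEstimator):
    """Sklearn-style machine-to-machine calibration transformer.

    ``fit`` takes calibration-phantom patches from the training machine
    (``X``) and the testing machine (``X_other``), averages their per-zone
    power spectra, and builds Wiener-regularized transfer functions in both
    directions.  ``transform`` moves RF patches between the two domains.

    Parameters
    ----------
    n_zones : number of axial zones tracked (default 9).
    sampling_rate : common post-resampling rate in Hz (default 40 MHz).
    direction : default direction used by :meth:`transform`.
    mode : "fft" (zero-phase circular) or "fir" (linear convolution).

    Attributes
    ----------
    tf_forward_ : TransferFunction, train -> test.
    tf_backward_ : TransferFunction, test -> train.
    snr_profile_ : SNRProfile shared by both directions.
    """

    def __init__(
        self,
        n_zones: int = 9,
        sampling_rate: float = 40e6,
        direction: str = "train_to_test",
        mode: str = "fft",
    ):
        self.n_zones = n_zones
        self.sampling_rate = sampling_rate
        self.direction = direction
        self.mode = mode

    def fit(self, X, X_other, zones=None, zones_other=None):
        spec_tr = average_power_spectra(X, self.n_zones, self.sampling_rate, zones)
        spec_te = average_power_spectra(X_other, self.n_zones, self.sampling_rate, zones_other)
        return self.fit_spectra(spec_tr, spec_te)

    def fit_spectra(self, spec_train: DepthSpectra, spec_test: DepthSpectra):
        """Fit from precomputed per-zone averaged spectra (e.g. streamed
        over a large free-hand acquisition)."""
        self.spectra_train_ = spec_train
        self.spectra_test_ = spec_test
        self.tf_forward_, self.tf_backward_, self.snr_profile_ = build_bidirectional(
            spec_train, spec_test
        )
        return self

    def transform(self, X, zones=None, direction: Optional[str] = None):
        direction = direction or self.direction
        if direction == "train_to_test":
            tf = self.tf_forward_
        elif direction == "test_to_train":
            tf = self.tf_backward_
        else:
            raise ValueError(f"unknown direction {direction!r}")
        return apply_transfer(X, tf, zones=zones, mode=self.mode)
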