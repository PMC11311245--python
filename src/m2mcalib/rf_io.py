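"""RF frame containers, HDF5 persistence, and sampling-rate conversion.

Post-beamformed RF data are stored as 2-D arrays of shape
``(n_axial, n_lateral)`` — axial (depth) samples along axis 0 with index 0
at the transducer face, scan lines along axis 1.  Depth of axial sample
``i`` is ``i * c / (2 * Fs)`` with ``c`` the nominal speed of sound
(default 1540 m/s), so 2080 samples at 40 MHz span 4 cm.

Frames from machines with different digitizer rates are brought onto a
common grid with a polyphase FIR rational resampler (e.g. interpolation 4 /
decimation 5 converts 50 MHz data to 40 MHz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import h5py
import numpy as np
from scipy.signal import firwin, resample_poly

from .errors import FormatError

__all__ = [
    "AcquisitionMeta",
    "RFFrame",
    "RFDataset",
    "read_dataset",
    "write_dataset",
    "resample_frame",
    "quantize_frame",
    "NOMINAL_SOS",
    "FORMAT_VERSION",
]

#: Nominal speed of sound used for the axial sample <-> depth convention [m/s].
NOMINAL_SOS = 1540.0

FORMAT_VERSION = "1.0"

_MODES = ("stable", "freehand")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata attached to one RF frame.

    ``class_label`` is present only for classification phantoms; calibration
    phantoms carry ``None``.
    """

    machine_id: str
    phantom_id: str
    sampling_rate: float  # Hz
    acquisition_mode: str  # "stable" | "freehand"
    frame_index: int
    transducer_id: str = ""
    class_label: Optional[int] = None
    bit_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.acquisition_mode not in _MODES:
            raise ValueError(
                f"acquisition_mode must be one of {_MODES}, "
                f"got {self.acquisition_mode!r}"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.class_label is not None and self.class_label not in (0, 1):
            raise ValueError("class_label must be 0, 1 or None")


@dataclass
class RFFrame:
    """One post-beamformed RF image: ``samples[axial, lateral]`` plus meta."""

    samples: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D array (axial x lateral)")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.samples.shape[1]


@dataclass
class RFDataset:
    """Ordered collection of RF frames with free-text provenance."""

    frames: list = field(default_factory=list)
    provenance: str = ""
    format_version: str = FORMAT_VERSION

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[RFFrame]:
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def sampling_rate(self) -> float:
        """Common sampling rate of the dataset (raises if frames disagree)."""
        rates = {f.meta.sampling_rate for f in self.frames}
        if len(rates) > 1:
            raise ValueError(f"frames have mixed sampling rates: {sorted(rates)}")
        if not rates:
            raise ValueError("empty dataset has no sampling rate")
        return rates.pop()


_REQUIRED_ATTRS = (
    "machine_id",
    "phantom_id",
    "sampling_rate",
    "acquisition_mode",
    "frame_index",
)


def write_dataset(ds: RFDataset, path) -> None:
    """Write a dataset to an ``.rfh5`` container (one group per frame).

    Layout: root attrs ``format_version`` / ``provenance``; group
    ``frames/<k>`` holds dataset ``samples`` and the meta fields as attrs.
    Deterministic for a fixed input.
    """
    for fr in ds.frames:
        if not np.isfinite(fr.samples).all():
            raise ValueError("frame contains non-finite samples")
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = ds.format_version
        h5.attrs["provenance"] = ds.provenance
        grp = h5.create_group("frames")
        for k, fr in enumerate(ds.frames):
            g = grp.create_group(f"{k:06d}")
            g.create_dataset("samples", data=fr.samples)
            m = fr.meta
            g.attrs["machine_id"] = m.machine_id
            g.attrs["phantom_id"] = m.phantom_id
            g.attrs["sampling_rate"] = float(m.sampling_rate)
            g.attrs["acquisition_mode"] = m.acquisition_mode
            g.attrs["frame_index"] = int(m.frame_index)
            if m.transducer_id:
                g.attrs["transducer_id"] = m.transducer_id
            if m.class_label is not None:
                g.attrs["class_label"] = int(m.class_label)
            if m.bit_depth is not None:
                g.attrs["bit_depth"] = int(m.bit_depth)


def read_dataset(path) -> RFDataset:
    """Read an ``.rfh5`` container written by :func:`write_dataset`."""
    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open container {path!s}: {exc}") from exc
    with h5:
        version = str(h5.attrs.get("format_version", ""))
        provenance = str(h5.attrs.get("provenance", ""))
        frames = []
        grp = h5.get("frames")
        if grp is None:
            raise FormatError("container missing 'frames' group")
        for key in sorted(grp.keys()):
            g = grp[key]
            if "samples" not in g:
                raise FormatError(f"frame {key} missing 'samples' dataset")
            for attr in _REQUIRED_ATTRS:
                if attr not in g.attrs:
                    raise FormatError(f"frame {key} missing attribute '{attr}'")
            meta = AcquisitionMeta(
                machine_id=str(g.attrs["machine_id"]),
                phantom_id=str(g.attrs["phantom_id"]),
                sampling_rate=float(g.attrs["sampling_rate"]),
                acquisition_mode=str(g.attrs["acquisition_mode"]),
                frame_index=int(g.attrs["frame_index"]),
                transducer_id=str(g.attrs.get("transducer_id", "")),
                class_label=(
                    int(g.attrs["class_label"]) if "class_label" in g.attrs else None
                ),
                bit_depth=(
                    int(g.attrs["bit_depth"]) if "bit_depth" in g.attrs else None
                ),
            )
            frames.append(RFFrame(samples=g["samples"][()], meta=meta))
    return RFDataset(frames=frames, provenance=provenance, format_version=version)


def _rational_fir(up: int, down: int) -> np.ndarray:
    """Anti-alias FIR for a rational rate change.

    Windowed-sinc low-pass at ``min(pi/up, pi/down)`` with
    ``24 * max(up, down) + 1`` taps and a Kaiser window (beta = 5).  The
    polyphase implementation scales by the interpolation factor, giving
    unity passband gain.
    """
    m = max(up, down)
    n_taps = 24 * m + 1
    # firwin cutoff is relative to Nyquist of the upsampled stream.
    return firwin(n_taps, 1.0 / m, window=("kaiser", 5.0))


def resample_frame(frame: RFFrame, up: int, down: int) -> RFFrame:
    """Rational axial resampling of a frame by ``up/down``.

    Polyphase FIR implementation; output axial length is
    ``ceil(n_axial * up / down)``, output rate ``Fs * up / down``.  The
    filter's group delay is compensated so output sample 0 stays aligned
    with input sample 0 (depth registration is preserved for patching).
    """
    if not (isinstance(up, (int, np.integer)) and isinstance(down, (int, np.integer))):
        raise ValueError("up and down must be integers")
    if up <= 0 or down <= 0:
        raise ValueError("up and down must be positive")
    if math.gcd(int(up), int(down)) != 1:
        raise ValueError("up and down must be coprime")
    up, down = int(up), int(down)
    if up == 1 and down == 1:
        return RFFrame(samples=frame.samples.copy(), meta=frame.meta)
    h = _rational_fir(up, down)
    out = resample_poly(frame.samples, up, down, axis=0, window=h)
    n_out = math.ceil(frame.n_axial * up / down)
    out = out[:n_out]
    meta = replace(frame.meta, sampling_rate=frame.meta.sampling_rate * up / down)
    return RFFrame(samples=out, meta=meta)


def quantize_frame(frame: RFFrame, bits: int) -> RFFrame:
    """Uniformly quantize samples to ``2**bits`` levels over their min-max.

    Idempotent on data already on the same grid; the maximum quantization
    error is half the step size.
    """
    if not 2 <= bits <= 32:
        raise ValueError("bits must be in [2, 32]")
    x = frame.samples
    lo = float(x.min())
    hi = float(x.max())
    if hi == lo:
        q = x.copy()
    else:
        step = (hi - lo) / (2**bits - 1)
        q = np.round((x - lo) / step) * step + lo
    meta = replace(frame.meta, bit_depth=int(bits))
    return RFFrame(samples=q, meta=meta)
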