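"""Synthetic cross-sectional cartilage FLIm scans with known ground truth.

The generator emulates a fiber-based point-scanning FLIm instrument: a
355-nm pulsed excitation (~600 ps FWHM) and three spectral detection bands
(375–410, 450–485, 530–565 nm) that are temporally multiplexed by delay
fibers onto a single detector, so each pixel yields one digitized record
containing three time-shifted decays.

The simulated specimen is a cartilage cross-section imaged through its
depth: a PBS (buffer) region above the tissue surface, a channel-1
lifetime that ramps from its superficial to its deep value over the first
half millimetre, and — for the enzyme-treated presets — a superficial
GAG-depleted layer with shortened channel-2/3 lifetimes and a shifted
intensity-ratio triple.  The ground truth (surface position, per-pixel
lifetimes/ratios, depleted mask and thickness) is returned alongside the
raw records, standing in for the histology that validated the real scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import h5py
import numpy as np
from scipy.optimize import brentq
from scipy.signal import fftconvolve

__all__ = [
    "AcquisitionConfig",
    "TissuePreset",
    "PhantomTruth",
    "RawScan",
    "make_irf",
    "synth_decay",
    "make_phantom",
    "preset",
    "save_scan",
    "load_scan",
]

#: healthy (control) intensity-ratio triple.  The depleted triple is the
#: element-wise product with the relative changes (0.63, 0.69, 1.23),
#: i.e. −37% / −31% / +23%; this control point is the member of the
#: closure-consistent one-parameter family with ch1 above, and depleted
#: ch1 below, the 0.25 segmentation threshold.
RATIOS_HEALTHY = (0.323, 0.0362 / 0.54, 1.0 - 0.323 - 0.0362 / 0.54)
RATIO_CHANGE = (0.63, 0.69, 1.23)

_BI_TAU_FACTORS = (0.6, 1.8)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and digitizer settings of a simulated scan.

    Times are in ns, lateral sizes in mm.  The three spectral channels
    arrive at ``channel_delays`` within one record and are each analyzed
    over a ``channel_window``-long slice.  ``peak_snr_db`` is the ratio of
    the brightest noiseless sample in the scan to the additive noise
    standard deviation; ``None`` disables noise.
    """

    dt: float = 0.08
    n_samples: int = 1875
    channel_delays: tuple[float, float, float] = (4.0, 54.0, 104.0)
    channel_window: float = 45.0
    irf_fwhm: float = 0.6
    irf_peak: float = 1.0
    #: detection-path gain per channel (ND-filter equalization): recorded
    #: amplitudes are true intensities times these known gains, so all
    #: three channels reach the detector at comparable strength; analysis
    #: divides them back out before forming intensity ratios
    channel_gains: tuple[float, float, float] = (2.0, 9.0, 1.0)
    pixel_pitch: float = 0.2
    n_rows: int = 50
    n_cols: int = 50
    peak_snr_db: float | None = 40.0
    dc_offset_frac: float = 0.01
    brightness_cv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.n_rows * self.pixel_pitch > 10.0 + 1e-9 or (
            self.n_cols * self.pixel_pitch > 10.0 + 1e-9
        ):
            raise ValueError("grid exceeds the 10 mm x 10 mm scan field")
        d = self.delay_samples
        w = self.window_samples
        ends = [di + w for di in d]
        if not (d[0] < ends[0] <= d[1] < ends[1] <= d[2] < ends[2] <= self.n_samples):
            raise ValueError("channel windows overlap or exceed the record")

    @property
    def window_samples(self) -> int:
        return int(self.channel_window / self.dt)

    @property
    def delay_samples(self) -> tuple[int, int, int]:
        return tuple(int(round(d / self.dt)) for d in self.channel_delays)

    @property
    def baseline_samples(self) -> int:
        """Pre-pulse region used for baseline estimation: everything before
        the channel-1 delay, capped at 5% of the record."""
        return max(1, min(self.delay_samples[0], int(0.05 * self.n_samples)))


def _default_surface(config: AcquisitionConfig) -> np.ndarray:
    """Surface height (mm from image top) per column: nominally 5 pixels
    deep, with a one-pixel tilt across the field so tissue boundaries and
    layer thicknesses are not aligned to the pixel grid."""
    c = np.arange(config.n_cols)
    return config.pixel_pitch * (5.0 + c / config.n_cols)


@dataclass(frozen=True)
class TissuePreset:
    """Ground-truth tissue parameters for one treatment condition.

    Lifetimes in ns, depths/thicknesses in mm.  Channel 1 reads
    ``lt_ch1_surface`` throughout the superficial zone (the first
    ``lt_plateau_depth`` of tissue), ramps linearly to ``lt_ch1_deep`` at
    ``lt_ramp_depth`` and is constant beyond — so the depth-dependent
    increase happens within the first half millimetre while the zone
    nearest the surface reads the superficial value.  Channels 2 and 3
    are depth-independent but switch
    to their depleted values inside the GAG-depleted superficial layer,
    as does the intensity-ratio triple.
    """

    name: str
    lt_ch1_surface: float = 5.7
    lt_ch1_deep: float = 6.1
    lt_plateau_depth: float = 0.1
    lt_ramp_depth: float = 0.5
    lt_ch2: float = 6.34
    lt_ch3: float = 5.22
    lt_ch2_depleted: float = 6.34 - 0.44
    lt_ch3_depleted: float = 5.22 - 0.75
    ratios_healthy: tuple[float, float, float] = RATIOS_HEALTHY
    ratios_depleted: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]
    depleted_thickness: float = 0.0
    surface_row_fn: Callable[[AcquisitionConfig], np.ndarray] | None = None

    def __post_init__(self):
        if self.ratios_depleted is None:
            r = np.asarray(self.ratios_healthy) * np.asarray(RATIO_CHANGE)
            r = r / r.sum()
            object.__setattr__(self, "ratios_depleted", tuple(r))
        for triple in (self.ratios_healthy, self.ratios_depleted):
            t = np.asarray(triple, dtype=float)
            if abs(t.sum() - 1.0) > 1e-12:
                raise ValueError(f"ratio triple {triple} does not sum to 1")
            if np.any(t <= 0) or np.any(t >= 1):
                raise ValueError("ratio components must lie in (0, 1)")
        if self.depleted_thickness < 0:
            raise ValueError("depleted_thickness must be non-negative")


_PRESET_THICKNESS = {"control": 0.0, "low": 0.3, "high": 0.7}


def preset(name: str, **overrides) -> TissuePreset:
    """Named treatment presets: ``control`` (no depletion), ``low`` and
    ``high`` (0.3 mm and 0.7 mm GAG-depleted superficial layers)."""
    if name not in _PRESET_THICKNESS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESET_THICKNESS)}")
    kw = dict(name=name, depleted_thickness=_PRESET_THICKNESS[name])
    kw.update(overrides)
    return TissuePreset(**kw)


@dataclass
class PhantomTruth:
    """Generator ground truth accompanying a raw scan.

    ``surface_row`` is the surface height in mm per column; ``depth`` is
    each pixel center's vertical depth below the surface (negative above
    it).  Lifetimes/ratios are NaN outside the tissue.
    """

    surface_row: np.ndarray
    true_lt: np.ndarray
    true_ratios: np.ndarray
    depleted_mask: np.ndarray
    depleted_thickness_per_column: np.ndarray
    tissue_mask: np.ndarray
    depth: np.ndarray


@dataclass
class RawScan:
    """A grid of multiplexed waveform records plus the measured iRF."""

    waveforms: np.ndarray  # (n_rows, n_cols, n_samples)
    irf: np.ndarray  # (window_samples,)
    config: AcquisitionConfig


def make_irf(config: AcquisitionConfig) -> np.ndarray:
    """Unit-area Gaussian instrument response with the configured FWHM,
    peaked ``irf_peak`` ns into the channel window."""
    if not config.irf_fwhm > 2 * config.dt:
        raise ValueError(
            f"iRF FWHM {config.irf_fwhm} ns is not resolvable at dt={config.dt} ns"
        )
    n = config.window_samples
    t = np.arange(n) * config.dt
    sigma = config.irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = np.exp(-0.5 * ((t - config.irf_peak) / sigma) ** 2)
    return g / g.sum()


def _discrete_avg(tau: float, t: np.ndarray) -> float:
    e = np.exp(-t / tau)
    return float((t * e).sum() / e.sum())


def synth_decay(
    lt_target: float, window: float, dt: float, shape: str = "bi"
) -> np.ndarray:
    """Pure (pre-convolution) decay whose discrete windowed average
    lifetime equals ``lt_target``.

    ``shape='mono'`` solves the single time constant; ``shape='bi'`` uses
    two fixed time constants (0.6 and 1.8 × the target) and solves the
    mixing fraction, giving a mildly non-exponential decay as real
    autofluorescence is.  Both are exact under the same discrete,
    truncated-window lifetime definition used by the analysis.
    """
    if not 0 < lt_target < window / 3:
        raise ValueError(
            f"target lifetime {lt_target} ns outside (0, window/3 = {window / 3:.3g}) ns"
        )
    n = int(window / dt)
    t = np.arange(n) * dt
    if shape == "mono":
        f = lambda tau: _discrete_avg(tau, t) - lt_target  # noqa: E731
        tau = brentq(f, dt * 1e-3, 50.0 * window, xtol=1e-12, rtol=1e-15)
        return np.exp(-t / tau)
    if shape == "bi":
        tau1, tau2 = (f * lt_target for f in _BI_TAU_FACTORS)
        e1, e2 = np.exp(-t / tau1), np.exp(-t / tau2)
        a1 = float(((t - lt_target) * e1).sum())
        a2 = float(((t - lt_target) * e2).sum())
        if a1 == a2:
            raise ValueError("degenerate time-constant pair")
        frac = a2 / (a2 - a1)
        if not 0.0 <= frac <= 1.0:
            raise ValueError(
                f"lifetime {lt_target} ns not achievable with time constants "
                f"{tau1:.3g}/{tau2:.3g} ns inside a {window} ns window"
            )
        return frac * e1 + (1.0 - frac) * e2
    raise ValueError(f"unknown decay shape {shape!r}")


def make_phantom(
    config: AcquisitionConfig, tissue: TissuePreset
) -> tuple[RawScan, PhantomTruth]:
    """Generate one synthetic scan and its ground truth.

    Reproducible: identical (config, preset) including ``config.seed``
    give bit-identical output.
    """
    p = config.pixel_pitch
    surface = (
        tissue.surface_row_fn(config)
        if tissue.surface_row_fn is not None
        else _default_surface(config)
    )
    surface = np.asarray(surface, dtype=float)
    if surface.shape != (config.n_cols,):
        raise ValueError("surface_row_fn must return one height per column")

    centers = (np.arange(config.n_rows) + 0.5) * p
    depth = centers[:, None] - surface[None, :]  # (rows, cols), mm
    tissue_mask = depth >= 0.0
    if tissue.depleted_thickness > 0 and np.any(
        tissue.depleted_thickness > depth.max(axis=0)
    ):
        raise ValueError("depleted_thickness exceeds the available tissue depth")
    depleted = tissue_mask & (depth < tissue.depleted_thickness)

    # per-pixel true lifetimes
    span = max(tissue.lt_ramp_depth - tissue.lt_plateau_depth, 1e-12)
    ramp = np.clip((depth - tissue.lt_plateau_depth) / span, 0.0, 1.0)
    lt1 = tissue.lt_ch1_surface + (tissue.lt_ch1_deep - tissue.lt_ch1_surface) * ramp
    lt2 = np.where(depleted, tissue.lt_ch2_depleted, tissue.lt_ch2)
    lt3 = np.where(depleted, tissue.lt_ch3_depleted, tissue.lt_ch3)
    true_lt = np.stack([lt1, lt2, lt3], axis=-1)
    true_lt[~tissue_mask] = np.nan

    healthy_r = np.asarray(tissue.ratios_healthy)
    depleted_r = np.asarray(tissue.ratios_depleted)
    true_ratios = np.where(depleted[..., None], depleted_r, healthy_r)
    true_ratios = true_ratios.astype(float)
    true_ratios[~tissue_mask] = np.nan

    irf = make_irf(config)
    win = config.window_samples
    delays = config.delay_samples
    dtns = config.dt

    # one convolved, unit-ratio-normalized decay per distinct lifetime
    uniq = np.unique(true_lt[tissue_mask])
    conv_full = {}
    conv_area = {}
    for lt in uniq:
        d = synth_decay(float(lt), config.channel_window, dtns, shape="bi")
        cf = fftconvolve(d, irf)
        conv_full[lt] = cf
        conv_area[lt] = float(cf[:win].sum() * dtns)

    rng = np.random.default_rng(config.seed)
    brightness = np.ones((config.n_rows, config.n_cols))
    if config.brightness_cv > 0:
        sigma = np.sqrt(np.log1p(config.brightness_cv**2))
        brightness = rng.lognormal(-0.5 * sigma**2, sigma, brightness.shape)

    amp0 = 100.0  # arbitrary digitizer units
    records = np.zeros((config.n_rows, config.n_cols, config.n_samples))
    rows, cols = np.nonzero(tissue_mask)
    for r, c in zip(rows, cols):
        for k in range(3):
            lt = true_lt[r, c, k]
            ratio = true_ratios[r, c, k]
            scale = (
                amp0 * brightness[r, c] * ratio * config.channel_gains[k] / conv_area[lt]
            )
            trace = conv_full[lt]
            start = delays[k]
            stop = min(start + trace.shape[0], config.n_samples)
            records[r, c, start:stop] += scale * trace[: stop - start]

    peak = float(records.max())
    records += config.dc_offset_frac * peak

    if config.peak_snr_db is not None:
        sigma0 = peak / 10.0 ** (config.peak_snr_db / 20.0)
        # additive floor plus a Poisson-like signal-proportional term
        local = np.sqrt(1.0 + np.clip(records - config.dc_offset_frac * peak, 0, None) / peak)
        records = records + rng.normal(0.0, 1.0, records.shape) * (sigma0 * local)

    counts = (depleted & tissue_mask).sum(axis=0)
    truth = PhantomTruth(
        surface_row=surface,
        true_lt=true_lt,
        true_ratios=true_ratios,
        depleted_mask=depleted,
        depleted_thickness_per_column=counts * p,
        tissue_mask=tissue_mask,
        depth=depth,
    )
    return RawScan(records, irf, config), truth


# -- container I/O -------------------------------------------------------


def save_scan(path, scan: RawScan, truth: PhantomTruth | None = None) -> None:
    """Write a scan (and optionally its truth) to an HDF5 container.

    Layout: ``/waveforms``, ``/irf``, ``truth/*`` datasets plus a JSON
    metadata attribute holding the acquisition config.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=scan.waveforms)
        f.create_dataset("irf", data=scan.irf)
        cfg = asdict(scan.config)
        f.attrs["config_json"] = json.dumps(cfg)
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("surface_row", data=truth.surface_row)
            g.create_dataset("true_lt", data=truth.true_lt)
            g.create_dataset("true_ratios", data=truth.true_ratios)
            g.create_dataset("depleted_mask", data=truth.depleted_mask)
            g.create_dataset(
                "depleted_thickness_per_column",
                data=truth.depleted_thickness_per_column,
            )
            g.create_dataset("tissue_mask", data=truth.tissue_mask)
            g.create_dataset("depth", data=truth.depth)


def load_scan(path) -> tuple[RawScan, PhantomTruth | None]:
    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config_json"])
        cfg["channel_delays"] = tuple(cfg["channel_delays"])
        cfg["channel_gains"] = tuple(cfg["channel_gains"])
        config = AcquisitionConfig(**cfg)
        scan = RawScan(f["waveforms"][()], f["irf"][()], config)
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = PhantomTruth(
                surface_row=g["surface_row"][()],
                true_lt=g["true_lt"][()],
                true_ratios=g["true_ratios"][()],
                depleted_mask=g["depleted_mask"][()].astype(bool),
                depleted_thickness_per_column=g["depleted_thickness_per_column"][()],
                tissue_mask=g["tissue_mask"][()].astype(bool),
                depth=g["depth"][()],
            )
    return scan, truth
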