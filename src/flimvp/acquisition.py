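"""Acquisition geometry, instrument response and background descriptions.

These objects describe *how* a time-resolved fluorescence measurement was
made: the time axis (TCSPC bins or arbitrary time gates), the laser
repetition period, the polarisation channels, the measured instrument
response function (IRF, either a direct measurement or a reference-dye
decay of known mono-exponential lifetime) and any background light terms.
Everything downstream (model construction, fitting, simulation) is built
on these descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MAGIC_ANGLE_DEG = np.degrees(np.arccos(np.sqrt(1.0 / 3.0)))


@dataclass(frozen=True)
class AcquisitionScheme:
    """Time axis and channel layout of a time-resolved acquisition.

    Parameters
    ----------
    mode : {"tcspc", "gated"}
        TCSPC histogramming (uniform bins, point-sampled) or time-gated
        widefield imaging (arbitrary gate delays integrated over finite
        gate widths).
    times : array of float
        Bin times or gate opening times in ns, strictly increasing and
        within ``[0, rep_period)``.
    rep_period : float
        Excitation pulse period T in ns (e.g. 12.5 ns for 80 MHz).
    gate_widths : array of float, optional
        Gate integration widths in ns; required in gated mode.
    channel_angles : sequence of float
        Polarisation analyser angle psi of each detection channel in
        degrees.  A single unpolarised/magic-angle channel is the default.
    """

    mode: str
    times: np.ndarray
    rep_period: float
    gate_widths: np.ndarray | None = None
    channel_angles: tuple[float, ...] = (MAGIC_ANGLE_DEG,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.mode not in ("tcspc", "gated"):
            raise ValueError(f"unknown acquisition mode {self.mode!r}")
        if self.rep_period <= 0:
            raise ValueError("rep_period must be positive")
        t = self.times
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("times must be a 1-d array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < 0 or t[-1] >= self.rep_period:
            raise ValueError("times must lie within [0, rep_period)")
        if self.mode == "gated":
            if self.gate_widths is None:
                raise ValueError("gated mode requires gate_widths")
            w = np.asarray(self.gate_widths, dtype=float)
            object.__setattr__(self, "gate_widths", w)
            if w.shape != t.shape or np.any(w <= 0):
                raise ValueError("gate_widths must match times and be > 0")
        else:
            if len(t) > 1:
                dt = np.diff(t)
                if not np.allclose(dt, dt[0], rtol=1e-6):
                    raise ValueError("tcspc mode requires uniform bin spacing")

    @property
    def n_timepoints(self) -> int:
        return len(self.times)

    @property
    def n_channels(self) -> int:
        return len(self.channel_angles)

    @property
    def n_points(self) -> int:
        """Total data points per pixel (time points x channels)."""
        return self.n_timepoints * self.n_channels

    @property
    def bin_width(self) -> float:
        """TCSPC bin width in ns (uniform spacing)."""
        if self.mode != "tcspc":
            raise ValueError("bin_width is defined for tcspc mode only")
        if len(self.times) > 1:
            return float(self.times[1] - self.times[0])
        return float(self.rep_period)

    # -- plain key=value config serialisation ------------------------------
    def to_config(self, path: str | Path) -> None:
        lines = [
            f"mode={self.mode}",
            f"rep_period={self.rep_period!r}",
            "times=" + ",".join(repr(float(x)) for x in self.times),
        ]
        if self.gate_widths is not None:
            lines.append(
                "gate_widths=" + ",".join(repr(float(x)) for x in self.gate_widths)
            )
        lines.append(
            "channel_angles=" + ",".join(repr(float(x)) for x in self.channel_angles)
        )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "AcquisitionScheme":
        kv = parse_config(path)
        gw = kv.get("gate_widths")
        return cls(
            mode=kv["mode"],
            times=np.array([float(x) for x in kv["times"].split(",")]),
            rep_period=float(kv["rep_period"]),
            gate_widths=None if gw is None else np.array([float(x) for x in gw.split(",")]),
            channel_angles=tuple(
                float(x) for x in kv.get("channel_angles", str(MAGIC_ANGLE_DEG)).split(",")
            ),
        )

    @classmethod
    def tcspc(
        cls,
        n_bins: int,
        rep_period: float,
        channel_angles: tuple[float, ...] = (MAGIC_ANGLE_DEG,),
    ) -> "AcquisitionScheme":
        """Uniform TCSPC axis: n_bins bins spanning one repetition period."""
        dt = rep_period / n_bins
        return cls("tcspc", np.arange(n_bins) * dt, rep_period, None, channel_angles)


def parse_config(path: str | Path) -> dict[str, str]:
    """Parse a plain ``key=value`` sidecar file (``#`` comments allowed)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


@dataclass(frozen=True)
class InstrumentResponse:
    """Measured instrument response, directly or via a reference dye.

    ``kind="direct"`` holds a sampled IRF g(t); ``kind="reference"`` holds
    the measured decay of a mono-exponential reference fluorophore with
    known lifetime ``ref_lifetime`` (delta-function convolution method),
    used when a scatter measurement of the IRF is impractical.

    Samples are stored per channel on a uniform fine grid with spacing
    ``timebase`` (ns), starting at t=0.  ``channel_scale`` carries
    per-channel multiplicative factors (g-factor compensation of relative
    detector sensitivities).
    """

    kind: str
    samples: np.ndarray  # (n_channels, n_samples)
    timebase: float
    ref_lifetime: float | None = None
    channel_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", s)
        if self.kind not in ("direct", "reference"):
            raise ValueError(f"unknown IRF kind {self.kind!r}")
        if self.timebase <= 0:
            raise ValueError("timebase must be positive")
        if np.any(s < 0):
            raise ValueError("IRF samples must be non-negative")
        if not np.all(s.max(axis=1) > 0):
            raise ValueError("each IRF channel needs a strictly positive sample")
        if self.kind == "reference" and (self.ref_lifetime is None or self.ref_lifetime <= 0):
            raise ValueError("reference kind requires ref_lifetime > 0")
        if self.channel_scale is None:
            object.__setattr__(self, "channel_scale", np.ones(s.shape[0]))
        else:
            cs = np.asarray(self.channel_scale, dtype=float)
            if cs.shape != (s.shape[0],) or np.any(cs <= 0):
                raise ValueError("channel_scale must be positive, one per channel")
            object.__setattr__(self, "channel_scale", cs)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    def peak_time(self, channel: int = 0) -> float:
        """Time of the IRF peak; used as the time-zero reference."""
        return float(np.argmax(self.samples[channel]) * self.timebase)

    def scaled_samples(self, channel: int) -> np.ndarray:
        return self.samples[channel] * self.channel_scale[channel]

    def with_channel_scale(self, scale: np.ndarray) -> "InstrumentResponse":
        return InstrumentResponse(
            self.kind, self.samples, self.timebase, self.ref_lifetime, np.asarray(scale, float)
        )

    # -- text I/O ----------------------------------------------------------
    @classmethod
    def from_text(
        cls,
        path: str | Path,
        kind: str = "direct",
        ref_lifetime: float | None = None,
    ) -> "InstrumentResponse":
        """Read a two-column (time_ns, counts) delimited text trace.

        Multi-channel traces use extra count columns, parallel channel
        first.
        """
        arr = np.loadtxt(path)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("expected columns: time_ns, counts[, counts_ch2, ...]")
        t = arr[:, 0]
        dt = np.diff(t)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("IRF time axis must be uniform")
        return cls(kind, arr[:, 1:].T, float(dt[0]), ref_lifetime)

    def to_text(self, path: str | Path) -> None:
        t = np.arange(self.samples.shape[1]) * self.timebase
        np.savetxt(path, np.column_stack([t, self.samples.T]))


def gaussian_irf(
    fwhm: float,
    peak_time: float,
    timebase: float,
    n_samples: int,
    n_channels: int = 1,
) -> InstrumentResponse:
    """Synthetic Gaussian IRF with the given FWHM (ns) and peak position."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = np.arange(n_samples) * timebase
    g = np.exp(-0.5 * ((t - peak_time) / sigma) ** 2)
    return InstrumentResponse("direct", np.tile(g, (n_channels, 1)), timebase)


def delta_irf(
    peak_time: float, timebase: float, n_samples: int, n_channels: int = 1
) -> InstrumentResponse:
    """Idealised delta-function IRF (single nonzero sample)."""
    g = np.zeros(n_samples)
    g[int(round(peak_time / timebase))] = 1.0
    return InstrumentResponse("direct", np.tile(g, (n_channels, 1)), timebase)


@dataclass
class BackgroundSpec:
    """Background light model: constant offset, scattered excitation and a
    measured time-varying background.

    Each component is either fitted (as a global or per-pixel linear
    amplitude) or fixed from a background measurement.  Fixed-measured
    components are subtracted/added with their measured magnitude and are
    never altered by the fit.
    """

    constant: str | None = None  # None | "global" | "local" | "fixed"
    constant_value: float = 0.0
    scatter: str | None = None
    scatter_value: float = 0.0
    tv_background: np.ndarray | None = None  # sampled B(t) on the acquisition axis
    tv_scope: str = "fixed"
    tv_intensity: float = 1.0

    _SCOPES = (None, "global", "local", "fixed")

    def __post_init__(self) -> None:
        for scope in (self.constant, self.scatter, self.tv_scope):
            if scope not in self._SCOPES:
                raise ValueError(f"invalid background scope {scope!r}")

    def validate_axis(self, n_points: int) -> None:
        if self.tv_background is not None and len(self.tv_background) != n_points:
            raise ValueError(
                "tv_background must be sampled on the acquisition axis "
                f"({len(self.tv_background)} != {n_points})"
            )
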