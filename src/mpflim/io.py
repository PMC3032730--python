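"""Containers and readers/writers for multi-channel TCSPC image data.

The central objects are the :class:`PhotonList` (a tagged photon stream as
produced by a pulsed-interleaved-excitation, dual-band detection system) and
the :class:`DecayCube` (per-pixel, per-channel micro-time histograms).  Photon
lists are stored as plain CSV or HDF5 tables; decay cubes and fitted kernels
live in a self-describing HDF5 layout; result maps are written as 32-bit
float TIFF and/or CSV.

Conventions
-----------
* Pixel coordinates are 0-based, row-major, origin at the top-left corner.
* Micro-times are picoseconds since the tagged excitation pulse.
* Time channels are half-open intervals ``[origin + i*dt, origin + (i+1)*dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TimeAxis",
    "FlimChannel",
    "PhotonList",
    "DecayCube",
    "CHANNELS",
    "CHANNEL_NAMES",
    "CHANNEL_BY_NAME",
    "DEFAULT_TIME_AXIS",
    "EXCITATION_WAVELENGTHS",
    "SPECTRAL_BANDS",
    "channel_for_tags",
    "read_photon_list",
    "write_photon_list",
    "bin_photons",
    "write_maps",
    "read_map",
    "FormatError",
    "ValidationError",
]

PHOTON_COLUMNS = ("x", "y", "microtime_ps", "excitation", "spectral")
MACROTIME_COLUMN = "macrotime_s"

EXCITATION_WAVELENGTHS = (473, 532)
SPECTRAL_BANDS = ("GFP_band", "RFP_band")


class FormatError(ValueError):
    """A file does not conform to the documented on-disk layout."""


class ValidationError(ValueError):
    """In-memory data violates a container invariant."""


@dataclass(frozen=True)
class TimeAxis:
    """Uniform micro-time binning grid.

    Parameters
    ----------
    n_channels : int
        Number of time channels (>= 2).
    channel_width : float
        Integration time of one channel, picoseconds.
    origin : float
        Lower edge of channel 0, picoseconds.
    """

    n_channels: int
    channel_width: float
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValidationError("TimeAxis needs at least 2 channels")
        if not self.channel_width > 0:
            raise ValidationError("channel_width must be positive")

    @property
    def window(self) -> float:
        """Total covered window in picoseconds."""
        return self.n_channels * self.channel_width

    @property
    def edges(self) -> np.ndarray:
        return self.origin + self.channel_width * np.arange(self.n_channels + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.origin + self.channel_width * (np.arange(self.n_channels) + 0.5)


#: 1024 channels of 48.8 ps: a ~50 ns window that fits inside a ~60 ns
#: excitation interleave while resolving a ~86 ps reference decay.
DEFAULT_TIME_AXIS = TimeAxis(n_channels=1024, channel_width=48.8)


@dataclass(frozen=True)
class FlimChannel:
    """One acquisition channel = (excitation wavelength, emission band)."""

    name: str
    excitation_nm: int
    emission_band: str

    def __post_init__(self) -> None:
        if self.excitation_nm not in EXCITATION_WAVELENGTHS:
            raise ValidationError(f"unknown excitation {self.excitation_nm}")
        if self.emission_band not in SPECTRAL_BANDS:
            raise ValidationError(f"unknown emission band {self.emission_band}")


CHANNELS = (
    FlimChannel("473GFP", 473, "GFP_band"),
    FlimChannel("473RFP", 473, "RFP_band"),
    FlimChannel("532GFP", 532, "GFP_band"),
    FlimChannel("532RFP", 532, "RFP_band"),
)
CHANNEL_NAMES = tuple(c.name for c in CHANNELS)
CHANNEL_BY_NAME = {c.name: c for c in CHANNELS}
_CHANNEL_BY_TAGS = {(c.excitation_nm, c.emission_band): c for c in CHANNELS}


def channel_for_tags(excitation: int, spectral: str) -> FlimChannel:
    """Route a (excitation, spectral) tag pair to its acquisition channel.

    The routing is a pure function of the two tags and independent of the
    photon micro-time.
    """
    try:
        return _CHANNEL_BY_TAGS[(int(excitation), str(spectral))]
    except KeyError:
        raise ValidationError(
            f"no channel for excitation={excitation!r}, spectral={spectral!r}"
        ) from None


@dataclass
class PhotonList:
    """Ordered stream of tagged photons.

    ``frame`` holds one row per photon with columns ``x, y, microtime_ps,
    excitation, spectral`` and, for time-lapse data, an optional
    ``macrotime_s`` acquisition-clock column.
    """

    frame: pd.DataFrame
    image_width: int
    image_height: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_macrotime(self) -> bool:
        return MACROTIME_COLUMN in self.frame.columns

    def validate(self) -> None:
        missing = [c for c in PHOTON_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"photon list missing column(s): {missing}")
        f = self.frame
        if len(f) == 0:
            return
        bad = ~f["excitation"].isin(EXCITATION_WAVELENGTHS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row}: excitation {f['excitation'].iloc[row]!r} not in "
                f"{EXCITATION_WAVELENGTHS}"
            )
        bad = ~f["spectral"].isin(SPECTRAL_BANDS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row}: spectral {f['spectral'].iloc[row]!r} not in "
                f"{SPECTRAL_BANDS}"
            )
        x = f["x"].to_numpy()
        y = f["y"].to_numpy()
        bad = (x < 0) | (x >= self.image_width) | (y < 0) | (y >= self.image_height)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"row {row}: pixel ({x[row]}, {y[row]}) outside "
                f"{self.image_width}x{self.image_height} image"
            )
        if (f["microtime_ps"].to_numpy() < 0).any():
            row = int(np.flatnonzero(f["microtime_ps"].to_numpy() < 0)[0])
            raise ValidationError(f"row {row}: negative microtime")


@dataclass
class DecayCube:
    """Per-pixel photon-count histograms for each acquisition channel.

    ``counts`` is indexed ``[channel][y][x][time_channel]``.
    """

    counts: np.ndarray
    channels: tuple[FlimChannel, ...]
    time_axis: TimeAxis
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise ValidationError("counts must be 4-D [channel, y, x, time]")
        if self.counts.shape[0] != len(self.channels):
            raise ValidationError("counts/channel list length mismatch")
        if self.counts.shape[3] != self.time_axis.n_channels:
            raise ValidationError("counts/time axis length mismatch")
        if (self.counts < 0).any():
            raise ValidationError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (height, width)."""
        return self.counts.shape[1], self.counts.shape[2]

    def channel_index(self, channel: str | FlimChannel) -> int:
        name = channel.name if isinstance(channel, FlimChannel) else channel
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise KeyError(f"channel {name!r} not in cube")

    def channel_counts(self, channel: str | FlimChannel) -> np.ndarray:
        """Histogram stack (y, x, t) of one channel."""
        return self.counts[self.channel_index(channel)]

    def total_photons(self) -> int:
        return int(self.counts.sum())

    # -- HDF5 layout: one group per channel with a (y, x, t) "counts"
    #    dataset; the time axis lives in root attributes.
    def save_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as h5:
            h5.attrs["n_channels"] = self.time_axis.n_channels
            h5.attrs["channel_width_ps"] = self.time_axis.channel_width
            h5.attrs["origin_ps"] = self.time_axis.origin
            for key, value in self.metadata.items():
                h5.attrs[f"meta_{key}"] = value
            for i, ch in enumerate(self.channels):
                g = h5.create_group(ch.name)
                g.attrs["excitation_nm"] = ch.excitation_nm
                g.attrs["emission_band"] = ch.emission_band
                g.create_dataset("counts", data=self.counts[i], compression="gzip")

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "DecayCube":
        with h5py.File(path, "r") as h5:
            axis = TimeAxis(
                n_channels=int(h5.attrs["n_channels"]),
                channel_width=float(h5.attrs["channel_width_ps"]),
                origin=float(h5.attrs["origin_ps"]),
            )
            metadata = {
                k[5:]: h5.attrs[k] for k in h5.attrs if k.startswith("meta_")
            }
            channels = []
            planes = []
            for name in CHANNEL_NAMES:
                if name in h5:
                    g = h5[name]
                    channels.append(
                        FlimChannel(
                            name,
                            int(g.attrs["excitation_nm"]),
                            str(g.attrs["emission_band"]),
                        )
                    )
                    planes.append(np.asarray(g["counts"]))
            if not channels:
                raise FormatError(f"{path}: no channel groups found")
        return cls(np.stack(planes), tuple(channels), axis, metadata)


# ---------------------------------------------------------------------------
# Photon list I/O
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        return "hdf5"
    return "csv"


def read_photon_list(
    path: str | Path,
    dialect: str | None = None,
    image_width: int | None = None,
    image_height: int | None = None,
) -> PhotonList:
    """Read a photon list from CSV or HDF5.

    The CSV dialect is a plain table with header
    ``x,y,microtime_ps,excitation,spectral`` (``macrotime_s`` optional); the
    HDF5 dialect mirrors it with one dataset per column plus image-size
    attributes.  When the image size is not stored (CSV), it defaults to the
    tight bounding box unless given explicitly.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        frame = pd.read_csv(path)
        meta: dict = {}
    elif dialect == "hdf5":
        with h5py.File(path, "r") as h5:
            cols = {}
            for col in PHOTON_COLUMNS + (MACROTIME_COLUMN,):
                if col in h5:
                    data = np.asarray(h5[col])
                    if data.dtype.kind in "SO":
                        data = np.char.decode(data.astype("S"), "utf-8")
                    cols[col] = data
            frame = pd.DataFrame(cols)
            meta = {k: h5.attrs[k] for k in h5.attrs}
            image_width = image_width or int(meta.pop("image_width", 0)) or None
            image_height = image_height or int(meta.pop("image_height", 0)) or None
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    missing = [c for c in PHOTON_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if image_width is None:
        image_width = int(frame["x"].max()) + 1 if len(frame) else 1
    if image_height is None:
        image_height = int(frame["y"].max()) + 1 if len(frame) else 1
    return PhotonList(frame, image_width, image_height, dict(meta))


def write_photon_list(
    photons: PhotonList, path: str | Path, dialect: str | None = None
) -> None:
    """Write a photon list; row order is preserved."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        photons.frame.to_csv(path, index=False)
    elif dialect == "hdf5":
        with h5py.File(path, "w") as h5:
            h5.attrs["image_width"] = photons.image_width
            h5.attrs["image_height"] = photons.image_height
            for key, value in photons.metadata.items():
                h5.attrs[key] = value
            for col in photons.frame.columns:
                data = photons.frame[col].to_numpy()
                if data.dtype.kind in "OU":
                    data = data.astype("S")
                h5.create_dataset(col, data=data)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def bin_photons(
    photons: PhotonList,
    time_axis: TimeAxis = DEFAULT_TIME_AXIS,
    pie_window: float = 60000.0,
) -> DecayCube:
    """Histogram a photon list into a decay cube.

    Each photon is routed to the acquisition channel determined by its
    (excitation, spectral) tag pair and to time channel
    ``floor((microtime - origin) / channel_width)``.  Photons whose
    micro-time falls outside ``[origin, origin + window)`` are dropped and
    counted in ``metadata['n_dropped']``, so that binned + dropped equals the
    input photon number.
    """
    if pie_window < time_axis.window:
        raise ValidationError(
            "pie_window must be at least the time-axis window "
            f"({pie_window} < {time_axis.window})"
        )
    h, w = photons.image_height, photons.image_width
    counts = np.zeros(
        (len(CHANNELS), h, w, time_axis.n_channels), dtype=np.int64
    )
    f = photons.frame
    n_dropped = 0
    if len(f):
        exc = f["excitation"].to_numpy()
        spec = f["spectral"].to_numpy()
        x = f["x"].to_numpy(dtype=np.int64)
        y = f["y"].to_numpy(dtype=np.int64)
        tch = np.floor(
            (f["microtime_ps"].to_numpy(dtype=float) - time_axis.origin)
            / time_axis.channel_width
        ).astype(np.int64)
        inside = (tch >= 0) & (tch < time_axis.n_channels)
        n_dropped = int((~inside).sum())
        chan = np.empty(len(f), dtype=np.int64)
        for i, ch in enumerate(CHANNELS):
            chan[(exc == ch.excitation_nm) & (spec == ch.emission_band)] = i
        flat = np.ravel_multi_index(
            (chan[inside], y[inside], x[inside], tch[inside]), counts.shape
        )
        np.add.at(counts.reshape(-1), flat, 1)
    return DecayCube(
        counts,
        CHANNELS,
        time_axis,
        metadata={"n_dropped": n_dropped, "pie_window_ps": pie_window},
    )


# ---------------------------------------------------------------------------
# Result maps
# ---------------------------------------------------------------------------

def write_maps(
    maps: Mapping[str, np.ndarray],
    out_dir: str | Path,
    formats: Iterable[str] = ("tiff32", "csv"),
) -> list[Path]:
    """Write named 2-D maps as 32-bit float TIFF and/or CSV.

    Undefined (masked) pixels are written as NaN.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    formats = set(formats)
    unknown = formats - {"tiff32", "csv"}
    if unknown:
        raise FormatError(f"unknown map format(s) {sorted(unknown)}")
    shapes = {np.asarray(m).shape for m in maps.values()}
    if len(shapes) > 1:
        raise ValidationError(f"maps do not share dimensions: {shapes}")
    written: list[Path] = []
    for name, data in maps.items():
        plane = np.asarray(data, dtype=np.float32)
        if plane.ndim != 2:
            raise ValidationError(f"map {name!r} is not 2-D")
        if "tiff32" in formats:
            p = out_dir / f"{name}.tif"
            tifffile.imwrite(p, plane)
            written.append(p)
        if "csv" in formats:
            p = out_dir / f"{name}.csv"
            np.savetxt(p, plane, delimiter=",")
            written.append(p)
    return written


def read_map(path: str | Path) -> np.ndarray:
    """Read back a map written by :func:`write_maps`."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return np.loadtxt(path, delimiter=",", dtype=np.float32, ndmin=2)
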