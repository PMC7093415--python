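"""Containers and file I/O for FLIM data cubes, phasor images and contribution maps.

The native on-disk container is a multi-page TIFF time-stack accompanied by a
JSON metadata sidecar (``<stem>.json``); HDF5 is offered for single-file
workflows (datasets ``/counts`` plus a ``/meta`` JSON attribute).  Vendor
TCSPC files (Becker & Hickl ``.sdt``) are read behind the ``vendor_tcspc``
format token via a lazy import so the core never depends on the reader.

All per-pixel real channels are written as 32-bit floats; photon counts are
stored as unsigned 16-bit integers (at ~300 photons per pixel the 65k ceiling
is never approached).  Image coordinates are row-major, 0-based, origin at
the top-left; time bins are 0-based, bin ``k`` spanning ``[k*dt, (k+1)*dt)``
with ``dt = T / n_time_bins``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import tifffile

__all__ = [
    "FLIMImage",
    "PhasorImage",
    "read_flim",
    "write_flim",
    "write_outputs",
    "read_phasor",
    "read_contributions",
    "sidecar_path",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FLIMImage:
    """A raw TCSPC measurement: per-pixel decay histograms plus timing metadata.

    Parameters
    ----------
    counts
        Non-negative integer photon counts indexed ``(row, col, time_bin)``.
    n_time_bins
        Number of time bins; must equal ``counts.shape[2]``.
    repetition_period_ns
        Laser pulse repetition period ``T`` in nanoseconds (e.g. 12.5 ns for
        an 80 MHz source).
    pixel_size_um
        Lateral pixel pitch in micrometres.
    metadata
        Free-form acquisition record (excitation wavelength, emission window,
        acquisition time, ...), preserved verbatim through I/O.
    """

    counts: np.ndarray
    n_time_bins: int
    repetition_period_ns: float
    pixel_size_um: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("inconsistent cube: counts must be 3-D (row, col, time_bin)")
        if self.counts.shape[2] != self.n_time_bins:
            raise ValueError(
                "inconsistent cube: n_time_bins=%d but cube has %d bins"
                % (self.n_time_bins, self.counts.shape[2])
            )
        if np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts < 0):
                raise ValueError("counts must be non-negative")
        else:
            if np.any(self.counts < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
        if not self.repetition_period_ns > 0:
            raise ValueError("repetition_period_ns must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def bin_width_ns(self) -> float:
        return self.repetition_period_ns / self.n_time_bins

    def bin_centers_ns(self) -> np.ndarray:
        """Bin-center times ``(k + 1/2) * dt`` used by the phasor transform."""
        dt = self.bin_width_ns
        return (np.arange(self.n_time_bins) + 0.5) * dt


@dataclass
class PhasorImage:
    """Per-pixel phasor coordinates (G, S) with intensity and validity mask.

    ``g`` and ``s`` are the real and imaginary parts of the normalized Fourier
    transform of each pixel's decay at angular frequency
    ``omega = 2*pi*harmonic / T``.  Masked-out pixels carry no phasor value
    (their g/s entries are zero and must not be interpreted).
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray
    harmonic: int = 1
    angular_frequency_per_ns: float = 2.0 * np.pi / 12.5

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shapes = {self.g.shape, self.s.shape, self.intensity.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("g, s, intensity and mask must share one shape")
        if self.harmonic < 1:
            raise ValueError("harmonic must be >= 1")
        if not self.angular_frequency_per_ns > 0:
            raise ValueError("angular_frequency_per_ns must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.g.shape

    def points(self) -> np.ndarray:
        """Unmasked phasor points as an ``(N, 2)`` array of (g, s) pairs."""
        return np.column_stack([self.g[self.mask], self.s[self.mask]])


# ---------------------------------------------------------------------------
# Sidecar helpers
# ---------------------------------------------------------------------------

def sidecar_path(path: str | Path) -> Path:
    """JSON sidecar accompanying a TIFF container (``image.tif`` -> ``image.json``)."""
    return Path(path).with_suffix(".json")


def _write_sidecar(path: str | Path, meta: Mapping[str, Any]) -> Path:
    sp = sidecar_path(path)
    sp.write_text(json.dumps(meta, indent=2, default=_json_default))
    return sp


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def _read_sidecar(path: str | Path) -> dict:
    sp = sidecar_path(path)
    if not sp.exists():
        raise ValueError(f"metadata required: sidecar {sp} not found")
    return json.loads(sp.read_text())


# ---------------------------------------------------------------------------
# FLIM cube I/O
# ---------------------------------------------------------------------------

def write_flim(img: FLIMImage, path: str | Path, format: str = "tiff_stack") -> list[Path]:
    """Write a FLIM cube to disk; returns the set of files written."""
    path = Path(path)
    meta = {
        "n_time_bins": int(img.n_time_bins),
        "repetition_period_ns": float(img.repetition_period_ns),
        "pixel_size_um": float(img.pixel_size_um),
        "metadata": img.metadata,
    }
    counts = img.counts
    if np.issubdtype(counts.dtype, np.floating):
        counts = np.round(counts)
    store = counts.astype(np.uint16) if counts.max(initial=0) < 2**16 else counts.astype(np.uint32)
    if format == "tiff_stack":
        # pages are time bins: (T, H, W)
        tifffile.imwrite(path, np.moveaxis(store, 2, 0))
        sp = _write_sidecar(path, meta)
        return [path, sp]
    if format == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("counts", data=store, compression=None)
            ds.attrs["axes"] = "row,col,time_bin"
            f.attrs["meta"] = json.dumps(meta, default=_json_default)
        return [path]
    raise ValueError(f"unsupported format: {format!r}")


def read_flim(path: str | Path, format: str = "tiff_stack") -> FLIMImage:
    """Read a FLIM cube from a TIFF time-stack, HDF5 container or vendor file.

    For ``tiff_stack`` a JSON sidecar carrying ``repetition_period_ns`` and
    ``n_time_bins`` must accompany the TIFF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tiff_stack":
        meta = _read_sidecar(path)
        for key in ("n_time_bins", "repetition_period_ns"):
            if key not in meta:
                raise ValueError(f"metadata required: sidecar lacks {key!r}")
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        counts = np.moveaxis(stack, 0, 2)
        return FLIMImage(
            counts=counts,
            n_time_bins=int(meta["n_time_bins"]),
            repetition_period_ns=float(meta["repetition_period_ns"]),
            pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
            metadata=dict(meta.get("metadata", {})),
        )
    if format == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            counts = f["counts"][...]
            meta = json.loads(f.attrs["meta"])
        return FLIMImage(
            counts=counts,
            n_time_bins=int(meta["n_time_bins"]),
            repetition_period_ns=float(meta["repetition_period_ns"]),
            pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
            metadata=dict(meta.get("metadata", {})),
        )
    if format == "vendor_tcspc":
        return _read_vendor_tcspc(path)
    raise ValueError(f"unsupported format: {format!r}")


def _read_vendor_tcspc(path: Path) -> FLIMImage:
    try:
        import sdtfile  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - reader optional
        raise ImportError(
            "vendor_tcspc reading requires the optional 'sdtfile' package"
        ) from exc
    sdt = sdtfile.SdtFile(str(path))  # pragma: no cover
    data = np.asarray(sdt.data[0])  # pragma: no cover
    times = np.asarray(sdt.times[0])  # pragma: no cover
    period_ns = float(times[-1] + (times[1] - times[0])) * 1e9  # pragma: no cover
    return FLIMImage(  # pragma: no cover
        counts=data,
        n_time_bins=data.shape[2],
        repetition_period_ns=period_ns,
        metadata={"source": str(path), "vendor": "becker_hickl"},
    )


# ---------------------------------------------------------------------------
# Derived-image output (phasor images, contribution maps, RGB renderings)
# ---------------------------------------------------------------------------

def write_outputs(obj: Any, path: str | Path, **extra: Any) -> list[Path]:
    """Write a PhasorImage, ContributionMap, FractionMap or RGB array.

    Real-valued channel stacks go out as 32-bit multi-channel TIFFs with a
    JSON sidecar describing the channels (lossless round trip); 8-bit RGB
    maps go to TIFF or PNG depending on the file suffix.  ``extra`` keys are
    merged into the sidecar (e.g. a color legend for an RGB map).
    """
    path = Path(path)
    if isinstance(obj, PhasorImage):
        channels = np.stack(
            [obj.g, obj.s, obj.intensity, obj.mask.astype(np.float32)]
        ).astype(np.float32)
        tifffile.imwrite(path, channels, photometric="minisblack")
        meta = {
            "type": "phasor",
            "channels": ["g", "s", "intensity", "mask"],
            "harmonic": int(obj.harmonic),
            "angular_frequency_per_ns": float(obj.angular_frequency_per_ns),
            **extra,
        }
        return [path, _write_sidecar(path, meta)]

    # ContributionMap / FractionMap are defined in sibling modules; dispatch
    # structurally to avoid circular imports.
    if hasattr(obj, "contributions"):
        arr = np.moveaxis(np.asarray(obj.contributions, dtype=np.float32), 2, 0)
        stack = np.concatenate([arr, obj.mask.astype(np.float32)[None]])
        tifffile.imwrite(path, stack, photometric="minisblack")
        meta = {
            "type": "contributions",
            "channels": list(obj.labels) + ["mask"],
            "labels": list(obj.labels),
            "colors": [list(map(int, c)) for c in obj.colors],
            **extra,
        }
        return [path, _write_sidecar(path, meta)]

    if hasattr(obj, "fraction"):
        stack = np.stack(
            [np.asarray(obj.fraction, dtype=np.float32), obj.mask.astype(np.float32)]
        )
        tifffile.imwrite(path, stack, photometric="minisblack")
        meta = {
            "type": "fraction",
            "channels": ["fraction", "mask"],
            "endo_label": obj.endo_label,
            "exo_label": obj.exo_label,
            **extra,
        }
        return [path, _write_sidecar(path, meta)]

    arr = np.asarray(obj)
    if arr.ndim == 3 and arr.shape[2] in (3, 4) and arr.dtype == np.uint8:
        if path.suffix.lower() == ".png":
            from PIL import Image

            Image.fromarray(arr).save(path)
        else:
            tifffile.imwrite(path, arr)
        meta = {"type": "rgb", **extra}
        return [path, _write_sidecar(path, meta)]

    raise TypeError(f"cannot write object of type {type(obj)!r}")


def read_phasor(path: str | Path) -> PhasorImage:
    """Round-trip reader for phasor images written by :func:`write_outputs`."""
    meta = _read_sidecar(path)
    if meta.get("type") != "phasor":
        raise ValueError("not a phasor container")
    stack = tifffile.imread(path)
    g, s, intensity, mask = stack
    return PhasorImage(
        g=g.astype(float),
        s=s.astype(float),
        intensity=intensity.astype(float),
        mask=mask > 0.5,
        harmonic=int(meta["harmonic"]),
        angular_frequency_per_ns=float(meta["angular_frequency_per_ns"]),
    )


def read_contributions(path: str | Path):
    """Round-trip reader for contribution maps written by :func:`write_outputs`."""
    from .multicomponent import ContributionMap

    meta = _read_sidecar(path)
    if meta.get("type") != "contributions":
        raise ValueError("not a contribution container")
    stack = tifffile.imread(path)
    mask = stack[-1] > 0.5
    contributions = np.moveaxis(stack[:-1], 0, 2).astype(float)
    return ContributionMap(
        contributions=contributions,
        mask=mask,
        labels=tuple(meta["labels"]),
        colors=tuple(tuple(c) for c in meta["colors"]),
    )
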