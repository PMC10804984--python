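"""Pixel-grid model for centroided MSI data, region masks and ion images.

Datasets are grids of centroid spectra acquired at a fixed step size
(100 µm in the default scenario).  The on-disk format is deliberately plain:
a JSON header (grid, condition, metadata) next to a TSV peak table with
columns x, y, mz, intensity.  Coordinates are 0-based, x rightward,
y downward, row-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import ppm_error

__all__ = [
    "CONDITIONS",
    "PixelSpectrum",
    "MSIDataset",
    "RegionMask",
    "IonImage",
    "read_dataset",
    "write_dataset",
    "extract_ion_image",
    "colocalization",
]

CONDITIONS = ("EDC_PLUS", "EDC_MINUS", "UNDERIVATIZED")
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PixelSpectrum:
    """One pixel's centroid spectrum (m/z strictly increasing)."""

    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z must be strictly increasing within a pixel")
        if np.any(inten < 0) or not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)


class MSIDataset:
    """Centroided MSI dataset backed by a flat (x, y, mz, intensity) table."""

    def __init__(self, width: int, height: int, peaks: pd.DataFrame,
                 pixel_size_um: float = 100.0,
                 condition: str = "UNDERIVATIZED",
                 metadata: dict | None = None):
        if width <= 0 or height <= 0:
            raise ValueError("grid dimensions must be positive")
        if pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        peaks = pd.DataFrame(peaks, columns=["x", "y", "mz", "intensity"])
        peaks = peaks.astype({"x": int, "y": int,
                              "mz": float, "intensity": float})
        if len(peaks):
            if peaks[["mz", "intensity"]].isna().any().any():
                raise ValueError("NaN peaks are not allowed")
            if (peaks["intensity"] < 0).any():
                raise ValueError("negative peak intensity")
            if ((peaks["x"] < 0) | (peaks["x"] >= width)
                    | (peaks["y"] < 0) | (peaks["y"] >= height)).any():
                raise ValueError("pixel coordinate outside grid")
            peaks = peaks.sort_values(["y", "x", "mz"], kind="mergesort",
                                      ignore_index=True)
            same_pixel = (peaks["x"].diff() == 0) & (peaks["y"].diff() == 0)
            if ((peaks["mz"].diff() <= 0) & same_pixel).any():
                raise ValueError("duplicate centroid m/z within a pixel")
        self.width = int(width)
        self.height = int(height)
        self.pixel_size_um = float(pixel_size_um)
        self.condition = condition
        self.metadata = dict(metadata or {})
        self.peaks = peaks

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_spectra(cls, width, height, spectra, **kw) -> "MSIDataset":
        frames = [pd.DataFrame({"x": s.x, "y": s.y,
                                "mz": s.mz, "intensity": s.intensity})
                  for s in spectra]
        peaks = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=["x", "y", "mz", "intensity"]))
        return cls(width, height, peaks, **kw)

    # -- accessors --------------------------------------------------------
    @property
    def n_pixels(self) -> int:
        """Number of grid pixels (occupied or not)."""
        return self.width * self.height

    def present_pixels(self) -> set[tuple[int, int]]:
        """Pixels that carry at least one centroid."""
        if not len(self.peaks):
            return set()
        return set(map(tuple, self.peaks[["x", "y"]].drop_duplicates()
                       .itertuples(index=False, name=None)))

    def spectrum(self, x: int, y: int) -> PixelSpectrum:
        sel = self.peaks[(self.peaks["x"] == x) & (self.peaks["y"] == y)]
        return PixelSpectrum(x, y, sel["mz"].to_numpy(),
                             sel["intensity"].to_numpy())

    @property
    def edc_used(self) -> bool:
        if self.condition == "UNDERIVATIZED":
            raise ValueError("underivatized dataset has no EDC state")
        return self.condition == "EDC_PLUS"


@dataclass
class RegionMask:
    """Named, pairwise-disjoint sets of pixel coordinates (labels f/b/i...)."""

    regions: dict[str, set[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        labels = list(self.regions)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                overlap = self.regions[a] & self.regions[b]
                if overlap:
                    raise ValueError(f"regions {a!r} and {b!r} overlap")

    def validate_grid(self, width: int, height: int) -> None:
        for label, pix in self.regions.items():
            for x, y in pix:
                if not (0 <= x < width and 0 <= y < height):
                    raise ValueError(
                        f"region {label!r} pixel {(x, y)} outside grid")

    @property
    def labels(self) -> list[str]:
        return sorted(self.regions)

    def __getitem__(self, label: str) -> set[tuple[int, int]]:
        return self.regions[label]

    def to_json(self, path: str | Path) -> None:
        payload = {label: sorted(map(list, pix))
                   for label, pix in self.regions.items()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionMask":
        payload = json.loads(Path(path).read_text())
        return cls({label: {tuple(p) for p in pix}
                    for label, pix in payload.items()})


@dataclass(frozen=True)
class IonImage:
    """Summed intensity per pixel within a ppm window around a target m/z."""

    mz: float
    tol_ppm: float
    values: np.ndarray  # shape (height, width)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("ion image must be 2-D")
        if np.any(values < 0):
            raise ValueError("ion image values must be non-negative")
        object.__setattr__(self, "values", values)

    def total(self) -> float:
        return float(self.values.sum())

    def nonzero_fraction(self) -> float:
        return float(np.count_nonzero(self.values)) / self.values.size


def write_dataset(d: MSIDataset, path: str | Path) -> None:
    """Write the internal format: ``header.json`` + ``peaks.tsv`` in a directory.

    m/z is written with 9 decimals and intensities with full float precision,
    so a round trip is intensity-bitwise and m/z-1e-9 stable.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "format_version": _FORMAT_VERSION,
        "width": d.width,
        "height": d.height,
        "pixel_size_um": d.pixel_size_um,
        "condition": d.condition,
        "metadata": d.metadata,
    }
    (path / "header.json").write_text(json.dumps(header, indent=1, sort_keys=True))
    with open(path / "peaks.tsv", "w") as fh:
        fh.write("x\ty\tmz\tintensity\n")
        for x, y, mz, inten in d.peaks.itertuples(index=False, name=None):
            fh.write(f"{x}\t{y}\t{mz:.9f}\t{float(inten)!r}\n")


def read_dataset(path: str | Path) -> MSIDataset:
    path = Path(path)
    header_file = path / "header.json"
    if not header_file.exists():
        raise FileNotFoundError(f"no header.json under {path}")
    header = json.loads(header_file.read_text())
    for key in ("width", "height", "pixel_size_um", "condition"):
        if key not in header:
            raise ValueError(f"dataset header missing field {key!r}")
    peaks = pd.read_csv(path / "peaks.tsv", sep="\t",
                        float_precision="round_trip")
    return MSIDataset(header["width"], header["height"], peaks,
                      pixel_size_um=header["pixel_size_um"],
                      condition=header["condition"],
                      metadata=header.get("metadata", {}))


def extract_ion_image(d: MSIDataset, mz: float, tol_ppm: float = 3.0) -> IonImage:
    """Sum centroid intensities within a closed ±tol_ppm window, per pixel.

    Pixels with no matching centroid (or no spectrum at all) are 0.
    """
    if mz <= 0:
        raise ValueError("target m/z must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    values = np.zeros((d.height, d.width))
    if len(d.peaks):
        pk = d.peaks
        err = 1e6 * (pk["mz"].to_numpy() - mz) / mz
        sel = np.abs(err) <= tol_ppm
        np.add.at(values, (pk["y"].to_numpy()[sel], pk["x"].to_numpy()[sel]),
                  pk["intensity"].to_numpy()[sel])
    return IonImage(mz, tol_ppm, values)


def window_ppm_errors(d: MSIDataset, mz: float, tol_ppm: float = 3.0) -> np.ndarray:
    """ppm errors of every centroid inside the window (for mean-error reports)."""
    if not len(d.peaks):
        return np.empty(0)
    err = 1e6 * (d.peaks["mz"].to_numpy() - mz) / mz
    return err[np.abs(err) <= tol_ppm]


def colocalization(a: IonImage, b: IonImage) -> float:
    """Cosine similarity of the two flattened (non-negative) images, in [0, 1]."""
    if a.values.shape != b.values.shape:
        raise ValueError("ion image dimensions differ")
    va = a.values.ravel()
    vb = b.values.ravel()
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(va, vb) / (na * nb))
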