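"""On-disk formats for hyperspectral scenes, label masks and dataset manifests.

Two cube dialects are supported and normalized to the same in-memory layout
(H x W x C, channel-last, wavelengths strictly increasing):

* ``envi`` — a plain-text ``.hdr`` header next to a raw binary file, the
  interchange format of most hyperspectral acquisition software.  BSQ, BIL and
  BIP interleaves and uint16/float32 sample types are handled on read; writing
  defaults to BSQ float32.
* ``npz`` — a NumPy array container with keys ``data`` and ``wavelengths_nm``.

Masks are binary tumor maps (0 = normal, 1 = tumor) stored either as 8-bit
grayscale PNGs ({0, 255} on disk) or as integer ``.npy`` arrays.  A manifest
is a CSV with columns ``scene_id, cube, mask, split`` assigning each scene to
the labeled, unlabeled or test pool; paths are resolved relative to the
manifest's directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HyperCube",
    "LabelMask",
    "ManifestEntry",
    "DatasetManifest",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "load_manifest",
    "save_manifest",
]

SPLITS = ("labeled", "unlabeled", "test")

# ENVI numeric codes for the sample types this package reads/writes
_ENVI_DTYPES = {4: np.float32, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}


@dataclass
class HyperCube:
    """An H x W x C reflectance cube with its band wavelengths in nm."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    scene_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube must have 3 axes (H, W, C), got {self.data.ndim}")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.data.shape[2]:
            raise ValueError(
                f"{len(self.wavelengths_nm)} wavelengths for {self.data.shape[2]} bands"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        bad = ~np.isfinite(self.data)
        if np.any(bad):
            bands = np.unique(np.nonzero(bad)[2])
            raise ValueError(f"non-finite values in band(s) {bands.tolist()}")
        if np.any(self.data < 0):
            raise ValueError("reflectance values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMask:
    """An H x W class map over {0: normal, 1: tumor}."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"mask must be 2-D, got {self.data.ndim} axes")
        bad = np.setdiff1d(np.unique(self.data), [0, 1])
        if bad.size:
            raise ValueError(f"mask values outside {{0, 1}}: {bad.tolist()}")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ManifestEntry:
    scene_id: str
    cube_path: str
    mask_path: str | None
    split: str


@dataclass
class DatasetManifest:
    """Scene inventory split into labeled / unlabeled / test pools.

    Masks listed for unlabeled entries (there are normally none) are used only
    for evaluation reporting, never for training.
    """

    entries: list[ManifestEntry]
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.split not in SPLITS:
                raise ValueError(f"unknown split {e.split!r} for scene {e.scene_id!r}")
            if e.scene_id in seen:
                raise ValueError(f"duplicate scene_id {e.scene_id!r}")
            seen.add(e.scene_id)
            if e.split in ("labeled", "test") and not e.mask_path:
                raise ValueError(f"{e.split} scene {e.scene_id!r} has no mask path")

    def split_entries(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]

    def counts(self) -> dict[str, int]:
        return {s: len(self.split_entries(s)) for s in SPLITS}

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p


# ---------------------------------------------------------------------------
# cubes


def _infer_dialect(path: Path) -> str:
    if path.suffix.lower() == ".npz":
        return "npz"
    return "envi"


def read_cube(path: str | Path, dialect: str | None = None) -> HyperCube:
    """Read a cube in either dialect; axis order is normalized to H x W x C."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "npz":
        return _read_npz(path)
    if dialect == "envi":
        return _read_envi(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_cube(cube: HyperCube, path: str | Path, dialect: str | None = None) -> None:
    """Write a cube; the written file round-trips bit-for-bit through read_cube."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "npz":
        np.savez(path, data=cube.data, wavelengths_nm=cube.wavelengths_nm)
    elif dialect == "envi":
        _write_envi(cube, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_npz(path: Path) -> HyperCube:
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as npz:
        if "data" not in npz or "wavelengths_nm" not in npz:
            raise ValueError(f"{path} lacks required keys 'data'/'wavelengths_nm'")
        return HyperCube(npz["data"], npz["wavelengths_nm"], scene_id=path.stem)


def _parse_envi_header(hdr_path: Path) -> dict[str, str]:
    text = hdr_path.read_text()
    fields: dict[str, str] = {}
    buffer = ""
    key = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, _, rest = line.partition("=")
            key = key.strip().lower()
            buffer = rest.strip()
        else:
            buffer += " " + line
        if buffer.count("{") > buffer.count("}"):
            continue  # multi-line value (e.g. the wavelength list)
        fields[key] = buffer.strip().strip("{}").strip()
        key = None
    return fields


def _read_envi(path: Path) -> HyperCube:
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        hdr_path, raw_path = path, path.with_suffix(".raw")
    else:
        hdr_path, raw_path = path.with_suffix(".hdr"), path
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    if not raw_path.exists():
        raise FileNotFoundError(raw_path)
    fields = _parse_envi_header(hdr_path)
    try:
        samples = int(fields["samples"])  # W
        lines = int(fields["lines"])  # H
        bands = int(fields["bands"])  # C
        dtype_code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header {hdr_path} missing field {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) != 0:
        dtype = dtype.newbyteorder(">")
    raw = np.fromfile(raw_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"{raw_path}: header declares {expected} samples "
            f"({lines}x{samples}x{bands}) but file holds {raw.size}"
        )
    if interleave == "bsq":  # (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # (lines, samples, bands)
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    if "wavelength" in fields:
        wavelengths = np.array(
            [float(w) for w in fields["wavelength"].split(",") if w.strip()]
        )
    else:
        wavelengths = np.arange(bands, dtype=np.float64)
    data = np.ascontiguousarray(data.astype(dtype.newbyteorder("="), copy=False))
    return HyperCube(data, wavelengths, scene_id=raw_path.stem)


def _write_envi(cube: HyperCube, path: Path, interleave: str = "bsq") -> None:
    path = Path(path)
    raw_path = path if path.suffix.lower() != ".hdr" else path.with_suffix(".raw")
    hdr_path = raw_path.with_suffix(".hdr")
    data = cube.data
    if data.dtype not in _ENVI_CODES:
        data = data.astype(np.float32)
    h, w, c = data.shape
    if interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    elif interleave == "bip":
        ordered = data
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    np.ascontiguousarray(ordered).tofile(raw_path)
    wl = ", ".join(f"{x:g}" for x in cube.wavelengths_nm)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {c}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[data.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )


# ---------------------------------------------------------------------------
# masks


def read_mask(path: str | Path) -> LabelMask:
    """Read a binary mask from PNG ({0,255} or {0,1} on disk) or .npy."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            raise ValueError(f"{path}: expected single-channel mask, got {arr.shape}")
    values = set(np.unique(arr).tolist())
    if values <= {0, 1}:
        return LabelMask(arr.astype(np.uint8))
    if values <= {0, 255}:
        return LabelMask((arr > 0).astype(np.uint8))
    bad = sorted(values - {0, 1, 255})
    raise ValueError(
        f"{path}: mask values must be {{0,1}} or {{0,255}}, found extras {bad}"
    )


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a mask as {0,255} 8-bit PNG, or as .npy of {0,1}."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        np.save(path, mask.data.astype(np.uint8))
    else:
        iio.imwrite(path, (mask.data * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# manifests


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a scene manifest CSV; logs the split counts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, dtype=str).fillna("")
    required = {"scene_id", "cube", "mask", "split"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    entries = [
        ManifestEntry(
            scene_id=row.scene_id,
            cube_path=row.cube,
            mask_path=row.mask or None,
            split=row.split,
        )
        for row in table.itertuples()
    ]
    manifest = DatasetManifest(entries, base_dir=path.parent)
    counts = manifest.counts()
    logger.info(
        "manifest %s: M=%d labeled, N=%d unlabeled, %d test",
        path.name, counts["labeled"], counts["unlabeled"], counts["test"],
    )
    return manifest


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    rows = [
        {
            "scene_id": e.scene_id,
            "cube": e.cube_path,
            "mask": e.mask_path or "",
            "split": e.split,
        }
        for e in manifest.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
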