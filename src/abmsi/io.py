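"""imzML/table input-output and run manifests.

Datacubes travel as paired .imzML/.ibd files (continuous or processed
binary mode); deposit masks as single-channel 8-bit TIFF/PNG; result tables
as UTF-8 CSV with stable column order and deterministic row order. Every
pipeline invocation can be audited from its JSON run manifest (config
snapshot, seeds, input checksums, stage timings, warnings).
"""

from __future__ import annotations

import hashlib
import json
import re
import time
import uuid as uuid_module
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MSIDataset

__all__ = [
    "DataIntegrityError",
    "FormatError",
    "read_imzml",
    "write_imzml",
    "write_tables",
    "RunManifest",
]


class DataIntegrityError(RuntimeError):
    """Missing ibd or imzML/ibd UUID mismatch."""


class FormatError(RuntimeError):
    """Structurally invalid data (e.g. non-monotone m/z axis)."""


def _ibd_path(imzml_path: Path) -> Path:
    return imzml_path.with_suffix(".ibd")


def _file_uuid(imzml_path: Path) -> str | None:
    text = imzml_path.read_text(errors="ignore")
    m = re.search(r'universally unique identifier"\s+value="\{?([0-9a-fA-F-]+)\}?"', text)
    return m.group(1).replace("-", "").lower() if m else None


def read_imzml(path, pixel_size_um: float | None = None) -> MSIDataset:
    """Read a paired imzML/ibd datacube into memory.

    Continuous mode maps directly onto the shared-axis container; processed
    mode is accepted when all pixels share one axis (the common case for
    re-exported phantoms) and is otherwise linearly interpolated onto the
    axis of the first spectrum. The ibd UUID is checked against the imzML
    header, and the m/z axis is validated monotone.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    ibd = _ibd_path(path)
    if not ibd.exists():
        raise DataIntegrityError(f"missing ibd file for {path.name}")
    declared = _file_uuid(path)
    with open(ibd, "rb") as fh:
        stored = uuid_module.UUID(bytes=fh.read(16)).hex
    if declared is not None and declared != stored:
        raise DataIntegrityError(
            f"imzML/ibd UUID mismatch: {declared} vs {stored}"
        )
    parser = ImzMLParser(str(path))
    try:
        spectra = []
        coords = []
        for i, (x, y, _z) in enumerate(parser.coordinates):
            mz, intens = parser.getspectrum(i)
            mz = np.asarray(mz, dtype=np.float64)
            if np.any(np.diff(mz) <= 0):
                raise FormatError(f"non-monotone m/z axis in pixel {i}")
            spectra.append((mz, np.asarray(intens, dtype=np.float32)))
            coords.append((x, y))
    finally:
        parser.m.close()

    axis = spectra[0][0]
    shared = all(len(mz) == len(axis) and np.array_equal(mz, axis) for mz, _ in spectra)
    if shared:
        Y = np.vstack([s[1] for s in spectra])
    else:
        Y = np.vstack(
            [np.interp(axis, mz, inten).astype(np.float32) for mz, inten in spectra]
        )
    if pixel_size_um is None:
        pixel_size_um = float(
            parser.imzmldict.get("pixel size x", 20.0) or 20.0
        )
    return MSIDataset(
        mz=axis,
        intensities=Y,
        coords=np.asarray(coords, dtype=np.int64),
        pixel_size_um=pixel_size_um,
        metadata={"source": str(path)},
    )


def write_imzml(dataset: MSIDataset, path, mode: str = "continuous") -> None:
    """Write a dataset as paired imzML/ibd ('continuous' or 'processed')."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    if mode not in ("continuous", "processed"):
        raise ValueError("mode must be 'continuous' or 'processed'")
    path = Path(path)
    with ImzMLWriter(str(path), mode=mode) as writer:
        for i in range(dataset.n_pixels):
            x, y = dataset.coords[i]
            writer.addSpectrum(
                dataset.mz, dataset.intensities[i].astype(np.float64), (int(x), int(y), 1)
            )


def write_tables(results: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write result tables as UTF-8 CSV with deterministic ordering.

    Row order is made reproducible by sorting on the leading identifier
    columns present in each table; identical inputs yield byte-identical
    files. Empty tables still emit their header row.
    """
    if not results:
        raise ValueError("no results to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        sort_cols = [c for c in ("subject", "plaque_id", "id", "name") if c in df.columns]
        if sort_cols and len(df):
            df = df.sort_values(sort_cols, kind="mergesort")
        target = out_dir / f"{name}.csv"
        df.to_csv(target, index=False, encoding="utf-8", lineterminator="\n")
        written.append(target)
    return written


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Audit record of one pipeline invocation."""

    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # path -> sha256
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    software_version: str = ""

    def __post_init__(self) -> None:
        if not self.software_version:
            from . import __version__

            self.software_version = __version__

    def add_input(self, path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings_s[name] = round(time.perf_counter() - self.t0, 3)
                return False

        return _Timer()

    def write(self, path) -> None:
        def default(obj):
            if is_dataclass(obj) and not isinstance(obj, type):
                return asdict(obj)
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            if isinstance(obj, (set, frozenset)):
                return sorted(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return str(obj)

        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True, default=default) + "\n",
            encoding="utf-8",
        )
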