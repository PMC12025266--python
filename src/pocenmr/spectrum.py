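"""1D NMR spectrum container and its on-disk CSV dialect.

A spectrum is a pair of equal-length arrays (chemical shift in ppm,
intensity in arbitrary units) plus a scan-type tag: ``reference`` for the
scan that records the total (12C + 13C) proton signal, ``edited`` for the
carbon-edited scan that retains only protons bound to 13C. Every
processing step returns a new spectrum and appends a record to
``processing_log``, so the provenance of any number downstream is
reconstructable.

On disk a spectrum is a two-column ``ppm,intensity`` CSV; acquisition
metadata travel in a JSON sidecar next to it (same stem, ``.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SCAN_TYPES = ("reference", "edited")


@dataclass
class Spectrum1D:
    ppm: np.ndarray
    intensity: np.ndarray
    scan_type: str = "reference"
    sample_id: str = ""
    processing_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D")
        if len(self.ppm) != len(self.intensity):
            raise ValueError(
                f"ppm ({len(self.ppm)}) and intensity ({len(self.intensity)}) "
                "lengths differ"
            )
        if len(self.ppm) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if self.scan_type not in SCAN_TYPES:
            raise ValueError(f"scan_type must be one of {SCAN_TYPES}")

    # -- derived geometry ---------------------------------------------------
    @property
    def ascending(self) -> bool:
        return bool(self.ppm[1] > self.ppm[0])

    @property
    def dx(self) -> float:
        """Median grid spacing (ppm), always positive."""
        return float(np.median(np.abs(np.diff(self.ppm))))

    @property
    def ppm_range(self) -> tuple[float, float]:
        return float(self.ppm.min()), float(self.ppm.max())

    # -- functional updates -------------------------------------------------
    def with_intensity(self, intensity: np.ndarray, step: str, **params) -> "Spectrum1D":
        """New spectrum with replaced intensities and a log entry appended."""
        s = replace(self, intensity=np.asarray(intensity, dtype=float),
                    processing_log=list(self.processing_log))
        s.processing_log.append({"step": step, **params})
        return s

    def with_ppm(self, ppm: np.ndarray, step: str, **params) -> "Spectrum1D":
        """New spectrum with replaced ppm axis (intensities untouched)."""
        s = replace(self, ppm=np.asarray(ppm, dtype=float),
                    processing_log=list(self.processing_log))
        s.processing_log.append({"step": step, **params})
        return s

    def noise_sd_estimate(self) -> float:
        """Robust noise estimate from first differences (MAD-based).

        Differencing removes smooth signal; the MAD is insensitive to the
        sparse large differences across peak flanks.
        """
        d = np.diff(self.intensity)
        mad = np.median(np.abs(d - np.median(d)))
        return float(1.4826 * mad / np.sqrt(2.0))

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path: str | Path, sidecar: dict | None = None) -> Path:
        path = Path(path)
        pd.DataFrame({"ppm": self.ppm, "intensity": self.intensity}).to_csv(
            path, index=False, float_format="%.10g"
        )
        meta = {"sample_id": self.sample_id, "scan_type": self.scan_type,
                "processing_log": self.processing_log}
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum1D":
        path = Path(path)
        df = pd.read_csv(path)
        if not {"ppm", "intensity"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns ppm,intensity")
        meta: dict = {}
        side = path.with_suffix(".json")
        if side.exists():
            meta = json.loads(side.read_text())
        return cls(
            ppm=df["ppm"].to_numpy(),
            intensity=df["intensity"].to_numpy(),
            scan_type=meta.get("scan_type", "reference"),
            sample_id=meta.get("sample_id", path.stem),
            processing_log=meta.get("processing_log", []),
        )
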