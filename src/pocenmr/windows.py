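"""Metabolite integration windows on the chemical-shift axis.

The packaged default table lists the 18 brain-metabolite windows used for
enrichment quantification (internal standard TMSP plus 17 13C-labelled
species, with numeric suffixes marking the labelled carbon, e.g. GABA3 =
GABA labelled at C3). Source tables of this kind are commonly printed with
the two boundaries in either order; :func:`load_windows` canonicalises them
into (lo, hi) and warns about overlapping windows rather than reapportioning
shared signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class MetaboliteWindow:
    """Named integration region [lo, hi] ppm with its nominal peak center."""

    name: str
    center: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: lo must be < hi (got {self.lo}, {self.hi})")
        if not (self.lo <= self.center <= self.hi):
            raise ValueError(
                f"window {self.name!r}: center {self.center} outside "
                f"[{self.lo}, {self.hi}]"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


class OverlappingWindowsWarning(UserWarning):
    pass


def _packaged_table() -> pd.DataFrame:
    with resources.files("pocenmr.data").joinpath("metabolite_windows.csv").open() as fh:
        return pd.read_csv(fh)


def load_windows(source: str | Path | pd.DataFrame | None = None) -> list[MetaboliteWindow]:
    """Load metabolite windows from a CSV (columns Metabolism/Center/From/To).

    ``source=None`` loads the packaged default table. Boundary columns are
    sorted into (lo, hi) regardless of printed order; duplicate names raise;
    overlapping window pairs trigger an :class:`OverlappingWindowsWarning`.
    """
    if source is None:
        df = _packaged_table()
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)

    cols = {c.lower(): c for c in df.columns}
    try:
        name_c = cols.get("metabolism", cols.get("name"))
        center_c, from_c, to_c = cols["center"], cols["from"], cols["to"]
        if name_c is None:
            raise KeyError("name")
    except KeyError as e:
        raise ValueError(
            "windows table needs columns Metabolism/name, Center, From, To"
        ) from e

    names = df[name_c].astype(str).str.strip()
    dup = names[names.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate window names: {sorted(set(dup))}")

    out: list[MetaboliteWindow] = []
    for _, row in df.iterrows():
        a, b = float(row[from_c]), float(row[to_c])
        lo, hi = (a, b) if a < b else (b, a)
        out.append(MetaboliteWindow(name=str(row[name_c]).strip(),
                                    center=float(row[center_c]), lo=lo, hi=hi))

    overlaps = []
    ordered = sorted(out, key=lambda w: w.lo)
    for w1, w2 in zip(ordered, ordered[1:]):
        if w2.lo < w1.hi:
            overlaps.append((w1.name, w2.name))
    if overlaps:
        warnings.warn(
            f"overlapping metabolite windows (integrated as printed): {overlaps}",
            OverlappingWindowsWarning,
            stacklevel=2,
        )
    return out


def default_windows() -> list[MetaboliteWindow]:
    return load_windows(None)


def window_map(windows: list[MetaboliteWindow]) -> dict[str, MetaboliteWindow]:
    return {w.name: w for w in windows}
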