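"""Window integration and 13C-enrichment quantification.

The enrichment of a metabolite is the area ratio of its window on the
edited (13C-only) scan to the same window on the reference (12C + 13C)
scan, expressed as a percentage: 100 x [13C] / [13C + 12C]. Windows are
integrated as printed (straight trapezoidal sum, no peak fitting or
deconvolution); out-of-range ratios are flagged, never clipped, because
clipping would bias cohort means.

The central tabular product is the long-format *enrichment table* with one
row per (sample, metabolite): mouse_id, group, region, metabolite,
ref_integral, edit_integral, enrichment_pct, flags.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import specproc
from .numutils import trapezoid_band
from .spectrum import Spectrum1D
from .synthdata import TMSP, SampleSpec
from .windows import MetaboliteWindow, window_map

ENRICHMENT_COLUMNS = [
    "mouse_id", "group", "region", "metabolite",
    "ref_integral", "edit_integral", "enrichment_pct",
    "out_of_range", "missing", "normalized",
]


def integrate_window(s: Spectrum1D, w: MetaboliteWindow) -> float:
    """Trapezoidal integral of the spectrum over [w.lo, w.hi].

    Partial end bins are linearly interpolated; sign is preserved, so
    negative baseline dips reduce the area. Requires the window to overlap
    the ppm range by at least 3 grid points.
    """
    try:
        return trapezoid_band(s.ppm, s.intensity, w.lo, w.hi, min_points=3)
    except ValueError as e:
        raise ValueError(f"window {w.name!r}: {e}") from e


def enrichment_ratio(edit_integral: float, ref_integral: float) -> float:
    """100 x edited / reference. NaN (with no silent zero) if ref <= 0.

    Values outside [0, 100] are returned as-is — noise can push past the
    bounds and downstream code flags them via :func:`out_of_range`.
    """
    if not ref_integral > 0:
        return math.nan
    return 100.0 * edit_integral / ref_integral


def out_of_range(enrichment_pct: float) -> bool:
    return bool(enrichment_pct < 0.0 or enrichment_pct > 100.0) \
        if not math.isnan(enrichment_pct) else False


def quantify_pair(
    reference: Spectrum1D,
    edited: Spectrum1D,
    windows: list[MetaboliteWindow],
) -> pd.DataFrame:
    """Integrate every window on a processed scan pair; one row per window."""
    rows = []
    for w in windows:
        r = integrate_window(reference, w)
        e = integrate_window(edited, w)
        pct = enrichment_ratio(e, r)
        rows.append({
            "metabolite": w.name, "ref_integral": r, "edit_integral": e,
            "enrichment_pct": pct, "out_of_range": out_of_range(pct),
            "missing": math.isnan(pct), "normalized": False,
        })
    return pd.DataFrame(rows)


def quantify_cohort(
    pairs: list[tuple[Spectrum1D, Spectrum1D]],
    samples: list[SampleSpec],
    windows: list[MetaboliteWindow],
    phi0: float | str = "auto",
    lam: float = specproc.DEFAULT_BASELINE_LAM,
    preprocess: bool = True,
) -> pd.DataFrame:
    """Process and quantify every sample's scan pair into an enrichment table.

    Applies the preprocessing chain (phase -> baseline -> TMSP calibration)
    to each scan, then window integration and the enrichment ratio.
    Deterministic given its inputs.
    """
    if len(pairs) != len(samples):
        raise ValueError("pairs and samples length mismatch")
    wm = window_map(windows)
    if TMSP not in wm:
        raise ValueError("windows must include TMSP for calibration")
    frames = []
    for (ref, edi), spec in zip(pairs, samples):
        if preprocess:
            ref = specproc.process(ref, wm[TMSP], phi0=phi0, lam=lam)
            edi = specproc.process(edi, wm[TMSP], phi0=phi0, lam=lam)
        t = quantify_pair(ref, edi, windows)
        t.insert(0, "region", spec.region)
        t.insert(0, "group", spec.group)
        t.insert(0, "mouse_id", spec.mouse_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)[ENRICHMENT_COLUMNS]


def load_manifest_cohort(manifest: pd.DataFrame | str) -> tuple[
        list[tuple[Spectrum1D, Spectrum1D]], list[SampleSpec]]:
    """Load scan pairs listed in a cohort manifest CSV.

    Required columns: mouse_id, group, region, reference_path, edited_path.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    need = {"mouse_id", "group", "region", "reference_path", "edited_path"}
    if not need <= set(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(need)}")
    pairs, samples = [], []
    for _, row in manifest.iterrows():
        for col in ("reference_path", "edited_path"):
            if pd.isna(row[col]):
                raise ValueError(f"sample {row['mouse_id']}: missing {col}")
        try:
            ref = Spectrum1D.from_csv(row["reference_path"])
            edi = Spectrum1D.from_csv(row["edited_path"])
        except FileNotFoundError as e:
            raise FileNotFoundError(
                f"sample {row['mouse_id']} ({row['region']}): {e}") from e
        pairs.append((ref, edi))
        samples.append(SampleSpec(
            mouse_id=str(row["mouse_id"]), group=str(row["group"]),
            region=str(row["region"]), amounts={}, enrichments={}))
    return pairs, samples


def normalize_to_tmsp(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample loading normalization against the TMSP reference integral.

    Each sample's integrals are divided by its loading factor
    (sample TMSP reference integral / cohort-mean TMSP reference integral),
    which removes sample-loading differences while leaving the
    scale-invariant enrichment ratio untouched. Returns the normalized
    table (TMSP rows dropped from the metabolite records) and a per-sample
    QC table whose ``steady_ratio`` — the dimensionless edited/reference
    TMSP ratio — should scatter tightly around the tracer's isotopic
    steady-state value.
    """
    key = ["mouse_id", "group", "region"]
    tmsp = table[table["metabolite"] == TMSP]
    if tmsp.empty:
        raise ValueError("no TMSP records in table")
    per_sample = table[key].drop_duplicates()
    merged = per_sample.merge(tmsp, on=key, how="left")
    bad = merged[merged["ref_integral"].isna() | (merged["ref_integral"] <= 0)]
    if not bad.empty:
        ids = bad[key].to_records(index=False).tolist()
        raise ValueError(f"samples without usable TMSP record: {ids}")

    qc = merged[key].copy()
    qc["tmsp_ref_integral"] = merged["ref_integral"].to_numpy()
    qc["steady_ratio"] = (merged["edit_integral"] / merged["ref_integral"]).to_numpy()
    qc["loading_factor"] = qc["tmsp_ref_integral"] / qc["tmsp_ref_integral"].mean()

    out = table.merge(qc[key + ["loading_factor"]], on=key, how="left")
    out["ref_integral"] = out["ref_integral"] / out["loading_factor"]
    out["edit_integral"] = out["edit_integral"] / out["loading_factor"]
    out["normalized"] = True
    out = out.drop(columns=["loading_factor"])
    return out[ENRICHMENT_COLUMNS], qc
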