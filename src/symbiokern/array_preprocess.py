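"""Two-color array preprocessing.

Reads GenePix-like scan tables, background-corrects with a positive offset,
computes per-probe (M, A) values with dye-swap orientation, and normalizes
within arrays (print-tip local regression of M on A) and between arrays
(quantile normalization of intensities).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ArgumentError, ConsistencyError, SymbiokernError, ValidationError

GPR_COLUMNS = [
    "Block",
    "Row",
    "Column",
    "ID",
    "F635_Median",
    "B635_Median",
    "F532_Median",
    "B532_Median",
]
DESIGN_COLUMNS = ["array_id", "cy3_sample", "cy5_sample", "dye_swap_of"]

#: long-format per-probe scan columns used internally
SCAN_COLUMNS = [
    "array_id",
    "probe_id",
    "print_tip_group",
    "fg_red",
    "bg_red",
    "fg_green",
    "bg_green",
]


@dataclass
class ArrayScanSet:
    """A set of scanned arrays joined to their hybridization design.

    ``scans`` is long format with :data:`SCAN_COLUMNS`; ``design`` has one row
    per array (array_id, cy3_sample, cy5_sample, dye_swap_of). Red is the Cy5
    (635 nm) channel, green the Cy3 (532 nm) channel.
    """

    scans: pd.DataFrame
    design: pd.DataFrame

    @property
    def array_ids(self) -> list[str]:
        return list(self.design["array_id"])

    def for_array(self, array_id: str) -> pd.DataFrame:
        return self.scans[self.scans["array_id"] == array_id]


@dataclass
class MAMatrix:
    """Per array x probe (M, A) values plus orientation metadata.

    ``values``: long format (array_id, probe_id, M, A, print_tip_group).  M is
    dye-swap sign-corrected so that positive M means the array's
    ``test_sample`` (recorded in ``design``) is higher than ``ref_sample``.
    """

    values: pd.DataFrame
    design: pd.DataFrame = field(repr=False)

    @property
    def array_ids(self) -> list[str]:
        return list(self.design["array_id"])

    def m_wide(self) -> pd.DataFrame:
        """probe x array matrix of M values."""
        return self.values.pivot(index="probe_id", columns="array_id", values="M")

    def a_wide(self) -> pd.DataFrame:
        return self.values.pivot(index="probe_id", columns="array_id", values="A")


def orient_design(design: pd.DataFrame) -> pd.DataFrame:
    """Add test_sample / ref_sample / is_swap columns.

    A dye-swap array inherits the orientation of its primary partner, so both
    members of a pair describe the same sample contrast.
    """
    design = design.copy()
    swap = design["dye_swap_of"].fillna("").astype(str) != ""
    design["is_swap"] = swap
    design["test_sample"] = np.where(swap, design["cy3_sample"], design["cy5_sample"])
    design["ref_sample"] = np.where(swap, design["cy5_sample"], design["cy3_sample"])
    primaries = set(design.loc[~swap, "array_id"])
    bad = design.loc[swap & ~design["dye_swap_of"].isin(primaries), "array_id"]
    if len(bad):
        raise ConsistencyError(
            f"dye_swap_of refers to unknown primary array for: {', '.join(bad)}"
        )
    return design


def read_design(design_path: str) -> pd.DataFrame:
    design = pd.read_csv(design_path, sep="\t", dtype=str).fillna("")
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValidationError(f"design file missing columns: {missing}")
    if design["array_id"].duplicated().any():
        raise ConsistencyError("duplicate array_id in design")
    return design[DESIGN_COLUMNS]


def read_array_scans(path: str, design_path: str) -> ArrayScanSet:
    """Read GPR-like per-array TSV files joined to a design table.

    ``path`` is a directory containing one ``<array_id>.gpr`` TSV per array.
    Replicate spots of a probe are summarized by the median per channel.
    """
    design = read_design(design_path)
    frames = []
    for array_id in design["array_id"]:
        fname = os.path.join(path, f"{array_id}.gpr")
        if not os.path.exists(fname):
            raise ConsistencyError(f"scan file for array '{array_id}' not found: {fname}")
        gpr = pd.read_csv(fname, sep="\t")
        missing = [c for c in GPR_COLUMNS if c not in gpr.columns]
        if missing:
            raise ValidationError(f"array '{array_id}' missing columns: {missing}")
        chans = ["F635_Median", "B635_Median", "F532_Median", "B532_Median"]
        vals = gpr[chans].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError(f"array '{array_id}' has non-finite intensities")
        if (vals < 0).any():
            raise ValidationError(f"array '{array_id}' has negative intensities")
        # replicate-spot summary: median per channel, tip group of first spot
        agg = gpr.groupby("ID", sort=True).agg(
            print_tip_group=("Block", "first"),
            fg_red=("F635_Median", "median"),
            bg_red=("B635_Median", "median"),
            fg_green=("F532_Median", "median"),
            bg_green=("B532_Median", "median"),
        )
        agg.index.name = "probe_id"
        agg = agg.reset_index()
        agg.insert(0, "array_id", array_id)
        frames.append(agg)
    scans = pd.concat(frames, ignore_index=True)
    return ArrayScanSet(scans=scans, design=design)


def write_array_scans(scan_set: ArrayScanSet, path: str) -> None:
    """Write one GPR-like TSV per array (inverse of :func:`read_array_scans`)."""
    os.makedirs(path, exist_ok=True)
    for array_id in scan_set.array_ids:
        sub = scan_set.for_array(array_id)
        n = len(sub)
        out = pd.DataFrame(
            {
                "Block": sub["print_tip_group"].to_numpy(),
                "Row": np.arange(n) + 1,
                "Column": np.ones(n, dtype=int),
                "ID": sub["probe_id"].to_numpy(),
                "F635_Median": sub["fg_red"].to_numpy(),
                "B635_Median": sub["bg_red"].to_numpy(),
                "F532_Median": sub["fg_green"].to_numpy(),
                "B532_Median": sub["bg_green"].to_numpy(),
            }
        )
        out.to_csv(os.path.join(path, f"{array_id}.gpr"), sep="\t", index=False)


def write_design(design: pd.DataFrame, path: str) -> None:
    design[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def collapse_replicates(scan_set: ArrayScanSet) -> ArrayScanSet:
    """Summarize replicate spots of a probe by the median per channel."""
    if not scan_set.scans.duplicated(subset=["array_id", "probe_id"]).any():
        return scan_set
    agg = (
        scan_set.scans.groupby(["array_id", "probe_id"], sort=False)
        .agg(
            print_tip_group=("print_tip_group", "first"),
            fg_red=("fg_red", "median"),
            bg_red=("bg_red", "median"),
            fg_green=("fg_green", "median"),
            bg_green=("bg_green", "median"),
        )
        .reset_index()
    )
    return ArrayScanSet(scans=agg, design=scan_set.design)


BACKGROUND_METHODS = ("subtract_offset", "none")


def background_correct(
    scan_set: ArrayScanSet, method: str = "subtract_offset", offset: float = 50.0
) -> ArrayScanSet:
    """Background-correct both channels.

    ``subtract_offset``: corrected = max(fg - bg, 0.5) + offset, which is
    strictly positive so downstream logs are finite.  ``none`` keeps the
    foreground but still floors it at 0.5 for the same reason.
    """
    if method not in BACKGROUND_METHODS:
        raise ArgumentError(f"unknown background method: {method!r}")
    if offset < 0:
        raise ArgumentError("offset must be >= 0")
    scans = scan_set.scans.copy()
    for ch in ("red", "green"):
        fg = scans[f"fg_{ch}"].to_numpy(dtype=float)
        if method == "subtract_offset":
            bg = scans[f"bg_{ch}"].to_numpy(dtype=float)
            corrected = np.maximum(fg - bg, 0.5) + offset
        else:
            corrected = np.maximum(fg, 0.5)
        scans[f"fg_{ch}"] = corrected
        scans[f"bg_{ch}"] = 0.0
    return ArrayScanSet(scans=scans, design=scan_set.design)


def compute_ma(scan_set: ArrayScanSet) -> MAMatrix:
    """Compute M = log2(red/green) and A = mean log2 intensity per probe.

    The input must be background-corrected.  Dye-swap arrays have M negated so
    both members of a pair share the orientation of the primary array.
    """
    red = scan_set.scans["fg_red"].to_numpy(dtype=float)
    green = scan_set.scans["fg_green"].to_numpy(dtype=float)
    if (red <= 0).any() or (green <= 0).any():
        raise SymbiokernError("zero/negative intensity after correction (internal error)")
    m = np.log2(red) - np.log2(green)
    a = 0.5 * (np.log2(red) + np.log2(green))
    design = orient_design(scan_set.design)
    swap_ids = set(design.loc[design["is_swap"], "array_id"])
    values = pd.DataFrame(
        {
            "array_id": scan_set.scans["array_id"],
            "probe_id": scan_set.scans["probe_id"],
            "M": np.where(scan_set.scans["array_id"].isin(swap_ids), -m, m),
            "A": a,
            "print_tip_group": scan_set.scans["print_tip_group"],
        }
    )
    return MAMatrix(values=values, design=design)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
    iterations: int = 1,
) -> np.ndarray:
    """Local polynomial regression fitted values at the observed x.

    Tricube neighborhood weights on the ``span`` fraction of nearest
    neighbours; ``iterations`` extra robustness passes with bisquare
    reweighting.  Local quadratic by default; points whose neighbourhood is
    strongly one-sided (the x extremes) fall back to a local linear fit,
    which avoids the variance blow-up of boundary extrapolation.
    """
    if not 0.0 < span <= 1.0:
        raise ArgumentError("span must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n == 0:
        return np.array([])
    k = int(np.ceil(span * n))
    k = max(k, degree + 2)
    if k % 2 == 0 and k < n:
        k += 1  # odd window: interior neighbourhoods are symmetric
    k = min(k, n)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    fitted_sorted = np.empty(n)
    robust_w = np.ones(n)
    for _pass in range(iterations + 1):
        lo = 0
        for i in range(n):
            # slide a k-wide window of nearest neighbours in sorted order
            while lo + k < n and xs[lo + k] - xs[i] < xs[i] - xs[lo]:
                lo += 1
            hi = lo + k
            xi = xs[lo:hi]
            yi = ys[lo:hi]
            d = np.abs(xi - xs[i])
            dmax = d.max()
            w = np.ones_like(d) if dmax == 0 else _tricube(d / dmax)
            w = w * robust_w[lo:hi]
            if w.sum() <= 0:
                w = np.ones_like(d)
            sw = np.sqrt(w)
            frac = (i - lo) / max(k - 1, 1)  # window position of the point
            deg = degree if 0.15 <= frac <= 0.85 else min(degree, 1)
            design = np.vander(xi - xs[i], deg + 1, increasing=True)
            beta, *_ = np.linalg.lstsq(design * sw[:, None], yi * sw, rcond=None)
            fitted_sorted[i] = beta[0]
        if _pass < iterations:
            resid = ys - fitted_sorted
            s = np.median(np.abs(resid))
            if s <= 1e-10 * (np.median(np.abs(ys)) + 1.0):
                break  # residuals are numerical dust; already converged
            robust_w = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def normalize_within_array(
    ma: MAMatrix,
    span: float = 0.3,
    min_tip_probes: int = 20,
    iterations: int = 1,
) -> MAMatrix:
    """Print-tip loess normalization: subtract the per-tip M~A trend.

    Print-tip groups with fewer than ``min_tip_probes`` probes fall back to
    the whole-array fit.  A values are unchanged.
    """
    if not 0.0 < span <= 1.0:
        raise ArgumentError("span must be in (0, 1]")
    values = ma.values.copy()
    m = values["M"].to_numpy(dtype=float).copy()
    a = values["A"].to_numpy(dtype=float)
    for array_id, idx in values.groupby("array_id", sort=False).indices.items():
        idx = np.asarray(idx)
        tips = values["print_tip_group"].to_numpy()[idx]
        whole_trend = None
        for tip in np.unique(tips):
            sel = idx[tips == tip]
            if sel.size >= min_tip_probes:
                trend = loess_fit(a[sel], m[sel], span=span, iterations=iterations)
                m[sel] = m[sel] - trend
            else:
                if whole_trend is None:
                    whole_trend = loess_fit(a[idx], m[idx], span=span, iterations=iterations)
                    whole_map = dict(zip(idx, whole_trend))
                m[sel] = m[sel] - np.array([whole_map[j] for j in sel])
    values["M"] = m
    return MAMatrix(values=values, design=ma.design)


def _quantile_normalize_columns(mat: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of ``mat`` to the mean sorted profile.

    Ties within a column share the mean of the tied ranks' reference values
    (implemented by linear interpolation at mid ranks).
    """
    n, p = mat.shape
    ref = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat, dtype=float)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(p):
        ranks = rankdata(mat[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return out


BETWEEN_METHODS = ("aquantile", "quantile")


def normalize_between_arrays(ma: MAMatrix, method: str = "aquantile") -> MAMatrix:
    """Between-array quantile normalization.

    ``aquantile`` quantile-normalizes the A values across arrays, leaving M
    untouched (safe for two-color contrasts).  ``quantile`` reconstructs the
    two channel log-intensities from (M, A), quantile-normalizes all channels
    jointly and recomputes M and A.
    """
    if method not in BETWEEN_METHODS:
        raise ArgumentError(f"unknown between-array method: {method!r}")
    return _normalize_between(ma, ma.m_wide(), ma.a_wide(), method)


def _normalize_between(
    ma: MAMatrix, wide_m: pd.DataFrame, wide_a: pd.DataFrame, method: str
) -> MAMatrix:
    if wide_a.shape[1] < 2:
        raise ArgumentError("between-array normalization needs >= 2 arrays")
    if wide_a.isna().any().any() or wide_m.isna().any().any():
        raise ConsistencyError("arrays do not share an identical probe set")
    arrays = list(wide_a.columns)
    if method == "aquantile":
        norm_a = _quantile_normalize_columns(wide_a.to_numpy(dtype=float))
        new_a = pd.DataFrame(norm_a, index=wide_a.index, columns=arrays)
        new_m = wide_m
    else:
        a = wide_a.to_numpy(dtype=float)
        m = wide_m.to_numpy(dtype=float)
        channels = np.concatenate([a + m / 2.0, a - m / 2.0], axis=1)
        normed = _quantile_normalize_columns(channels)
        k = len(arrays)
        red, green = normed[:, :k], normed[:, k:]
        new_m = pd.DataFrame(red - green, index=wide_a.index, columns=arrays)
        new_a = pd.DataFrame((red + green) / 2.0, index=wide_a.index, columns=arrays)
    values = ma.values.copy()
    probe_pos = {p: i for i, p in enumerate(wide_a.index)}
    rows = values["probe_id"].map(probe_pos).to_numpy()
    cols = values["array_id"].map({a: j for j, a in enumerate(arrays)}).to_numpy()
    values["A"] = new_a.to_numpy()[rows, cols]
    values["M"] = new_m.to_numpy()[rows, cols]
    return MAMatrix(values=values, design=ma.design)


def preprocess(
    scan_set: ArrayScanSet,
    background: str = "subtract_offset",
    offset: float = 50.0,
    within: str = "print-tip-loess",
    between: str = "aquantile",
    span: float = 0.3,
) -> MAMatrix:
    """Full preprocessing chain: collapse replicate spots, correct, MA,
    within- and between-array normalization."""
    corrected = background_correct(collapse_replicates(scan_set), method=background, offset=offset)
    ma = compute_ma(corrected)
    if within == "print-tip-loess":
        ma = normalize_within_array(ma, span=span)
    elif within != "none":
        raise ArgumentError(f"unknown within-array method: {within!r}")
    if between in BETWEEN_METHODS:
        ma = _normalize_between(ma, ma.m_wide(), ma.a_wide(), between)
    elif between != "none":
        raise ArgumentError(f"unknown between-array method: {between!r}")
    return ma


def write_ma(ma: MAMatrix, path: str) -> None:
    ma.values.to_csv(path, sep="\t", index=False)


def read_ma(path: str, design_path: str) -> MAMatrix:
    values = pd.read_csv(path, sep="\t")
    design = orient_design(read_design(design_path))
    unknown = set(values["array_id"]) - set(design["array_id"])
    if unknown:
        raise ConsistencyError(f"MA table references arrays missing from design: {sorted(unknown)}")
    return MAMatrix(values=values, design=design)
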