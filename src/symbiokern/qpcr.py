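"""qPCR quantification.

Standard-curve fitting and absolute copy quantification, symbiont:host
nuclei ratios with calibrator normalization, within-organism locus-ratio
diagnostics, reference-gene stability ranking (average pairwise-variation
statistic) with iterative exclusion, geometric-mean normalization factors,
calibrator-relative expression, and heat-stress time-course folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ArgumentError, ConsistencyError, PreconditionError, SymbiokernError

REPLICATE_SD_FLAG = 0.5  # cycles; replicate scatter beyond this is flagged


def summarize_replicates(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Mean Cq per (sample, assay, role) with an SD flag > 0.5 cycles.

    Undetermined wells (NaN) drop out; a sample/assay with no finite well
    keeps cq = NaN (below detection).
    """
    grouped = cq_table.groupby(
        ["sample", "assay", "role", "log10_copies"], dropna=False
    )
    out = grouped.agg(
        cq=("cq", "mean"),
        cq_sd=("cq", "std"),
        n_wells=("cq", "size"),
    ).reset_index()
    out["sd_flag"] = out["cq_sd"].fillna(0.0) > REPLICATE_SD_FLAG
    return out


@dataclass
class StandardCurve:
    locus: str
    slope: float
    intercept: float
    r2: float
    low_r2: bool = False

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification factor E = 10^(-1/slope)."""
        return float(10.0 ** (-1.0 / self.slope))


def fit_standard_curve(series: pd.DataFrame, locus: str | None = None) -> StandardCurve:
    """Least-squares Cq on log10(copies).

    ``series`` needs columns log10_copies and cq (replicate rows allowed).
    A non-negative slope is a fit failure; r^2 < 0.98 sets a warning flag.
    """
    sub = series.dropna(subset=["log10_copies", "cq"])
    x = sub["log10_copies"].to_numpy(dtype=float)
    y = sub["cq"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise PreconditionError("standard curve needs >= 3 distinct dilution points")
    res = sps.linregress(x, y)
    if res.slope >= 0:
        raise SymbiokernError(f"standard-curve fit failed: slope {res.slope:.3g} >= 0")
    r2 = float(res.rvalue**2)
    low = r2 < 0.98
    if low:
        warnings.warn(f"standard curve r^2 = {r2:.4f} < 0.98")
    if locus is None:
        locus = str(series["assay"].iloc[0]) if "assay" in series else "unknown"
    return StandardCurve(locus=locus, slope=float(res.slope),
                         intercept=float(res.intercept), r2=r2, low_r2=low)


def fit_all_curves(cq_table: pd.DataFrame) -> dict:
    """Fit one standard curve per assay from the role == standard rows."""
    standards = summarize_replicates(cq_table[cq_table["role"] == "standard"])
    return {
        assay: fit_standard_curve(sub, locus=assay)
        for assay, sub in standards.groupby("assay")
    }


def quantify_copies(cq, curve: StandardCurve):
    """Invert the standard curve: copies = 10^((cq - intercept) / slope)."""
    cq = np.asarray(cq, dtype=float)
    out = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return float(out) if out.ndim == 0 else out


def symbiont_host_ratio(
    cq_table: pd.DataFrame,
    curves: dict,
    symbiont_loci,
    host_loci,
    calibrator: str,
    detection_cq: float = 40.0,
) -> pd.DataFrame:
    """Symbiont:host copy ratios per specimen and locus pair.

    Returns one row per specimen x (symbiont locus, host locus) pair with the
    absolute ratio and the calibrator-relative ratio, plus per-specimen
    ``consensus`` rows (geometric mean over pairs).  Undetermined symbiont
    Cq values are reported below the detection limit, never as 0.
    """
    summary = summarize_replicates(cq_table[cq_table["role"] == "unknown"])
    table = summary.pivot(index="sample", columns="assay", values="cq")
    for locus in list(symbiont_loci) + list(host_loci):
        if locus not in curves:
            raise ConsistencyError(f"no standard curve for locus {locus}")
        if locus not in table.columns:
            raise ConsistencyError(f"no unknown-sample measurements for locus {locus}")
    if calibrator not in table.index:
        raise ConsistencyError(f"calibrator specimen {calibrator!r} not measured")
    rows = []
    for specimen in table.index:
        for sym in symbiont_loci:
            for host in host_loci:
                cq_sym = table.loc[specimen, sym]
                cq_host = table.loc[specimen, host]
                copies_host = quantify_copies(cq_host, curves[host])
                if np.isnan(cq_sym):
                    limit = quantify_copies(detection_cq, curves[sym]) / copies_host
                    rows.append((specimen, sym, host, np.nan, np.nan, True, limit))
                    continue
                copies_sym = quantify_copies(cq_sym, curves[sym])
                rows.append(
                    (specimen, sym, host, copies_sym / copies_host, np.nan, False, np.nan)
                )
    out = pd.DataFrame(
        rows,
        columns=["specimen", "symbiont_locus", "host_locus", "ratio", "ratio_rel",
                 "below_detection", "detection_limit"],
    )
    # calibrator-relative ratio per locus pair
    cal = out[out["specimen"] == calibrator].set_index(["symbiont_locus", "host_locus"])["ratio"]
    key = list(zip(out["symbiont_locus"], out["host_locus"]))
    out["ratio_rel"] = out["ratio"].to_numpy() / cal.loc[key].to_numpy()
    return out


def consensus_ratio(ratio_table: pd.DataFrame, relative: bool = True) -> pd.Series:
    """Geometric mean across locus pairs per specimen."""
    col = "ratio_rel" if relative else "ratio"
    ok = ratio_table[~ratio_table["below_detection"]]
    return ok.groupby("specimen")[col].apply(
        lambda v: float(np.exp(np.mean(np.log(v)))) if (v > 0).all() else np.nan
    )


def locus_ratio_diagnostics(
    cq_table: pd.DataFrame,
    curves: dict,
    loci,
    flag_factor: float = 2.0,
) -> pd.DataFrame:
    """Pairwise copy ratios among loci of one organism, per specimen.

    Flags pairs whose ratio deviates from 1 by more than ``flag_factor``.
    """
    loci = list(loci)
    if len(loci) < 2:
        raise PreconditionError("need >= 2 loci for ratio diagnostics")
    summary = summarize_replicates(cq_table[cq_table["role"] == "unknown"])
    table = summary.pivot(index="sample", columns="assay", values="cq")
    rows = []
    for specimen in table.index:
        copies = {
            locus: quantify_copies(table.loc[specimen, locus], curves[locus])
            for locus in loci
        }
        for i, la in enumerate(loci):
            for lb in loci[i + 1:]:
                ratio = copies[la] / copies[lb]
                flagged = bool(ratio > flag_factor or ratio < 1.0 / flag_factor)
                rows.append((specimen, la, lb, ratio, flagged))
    return pd.DataFrame(rows, columns=["specimen", "locus_a", "locus_b", "ratio", "flagged"])


# ---------------------------------------------------------------------------
# reference-gene stability (average pairwise-variation statistic)
# ---------------------------------------------------------------------------

@dataclass
class StabilityRanking:
    m_values: pd.Series  # initial stability per gene (all candidates)
    exclusion_order: list  # least stable first
    panel: list  # retained genes
    stages: list  # list of (genes, m_values Series) per iteration


def stability_m(quantities: pd.DataFrame) -> pd.Series:
    """M_j = mean over partners k != j of SD across samples of log2(q_j/q_k)."""
    if (quantities.to_numpy(dtype=float) <= 0).any():
        raise ArgumentError("quantities must be strictly positive")
    logq = np.log2(quantities.to_numpy(dtype=float))
    genes = list(quantities.index)
    n = len(genes)
    m = np.zeros(n)
    for j in range(n):
        sds = [np.std(logq[j] - logq[k], ddof=1) for k in range(n) if k != j]
        m[j] = float(np.mean(sds))
    return pd.Series(m, index=quantities.index, name="M")


def gene_stability(quantities: pd.DataFrame, panel_size: int = 3) -> StabilityRanking:
    """Iterative exclusion of the least stable reference gene.

    ``quantities`` is genes x samples of relative quantities.  At each step
    the gene with the largest M is removed (ties broken by gene label) until
    ``panel_size`` genes remain.
    """
    if quantities.shape[0] < 3:
        raise PreconditionError("need >= 3 candidate reference genes")
    if quantities.shape[1] < 2:
        raise PreconditionError("need >= 2 samples")
    if panel_size < 2:
        raise ArgumentError("panel_size must be >= 2")
    current = quantities.copy()
    initial = stability_m(current)
    stages = []
    exclusion = []
    while current.shape[0] > panel_size:
        m = stability_m(current)
        stages.append((list(current.index), m))
        # worst gene; ties broken by label order
        worst = m.sort_index().sort_values(kind="mergesort", ascending=False).index[0]
        exclusion.append(worst)
        current = current.drop(index=worst)
    stages.append((list(current.index), stability_m(current)))
    return StabilityRanking(
        m_values=initial,
        exclusion_order=exclusion,
        panel=list(current.index),
        stages=stages,
    )


def relative_quantities(
    cq_wide: pd.DataFrame, efficiencies: dict | float
) -> pd.DataFrame:
    """E^(delta Cq) against the per-gene minimum Cq (conventional input scale
    for the stability statistic)."""
    out = {}
    for gene in cq_wide.index:
        e = efficiencies[gene] if isinstance(efficiencies, dict) else float(efficiencies)
        cq = cq_wide.loc[gene].to_numpy(dtype=float)
        out[gene] = e ** (np.nanmin(cq) - cq)
    return pd.DataFrame(out, index=cq_wide.columns).T


def normalization_factor(panel_quantities: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of the selected reference genes' quantities."""
    if panel_quantities.shape[0] == 0:
        raise ArgumentError("panel is empty")
    vals = panel_quantities.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ArgumentError("quantities must be strictly positive")
    nf = np.exp(np.log(vals).mean(axis=0))
    return pd.Series(nf, index=panel_quantities.columns, name="nf")


def relative_expression(
    target_cq: pd.Series,
    efficiency: float,
    nf: pd.Series,
    calibrator: str = "AS6",
) -> pd.Series:
    """Calibrator-relative normalized expression per sample.

    quantity = E^(-Cq); normalized = quantity / NF; fold = normalized /
    normalized(calibrator).
    """
    if calibrator not in target_cq.index:
        raise ConsistencyError(f"calibrator sample {calibrator!r} missing")
    if efficiency <= 1.0:
        raise ArgumentError("efficiency must be > 1")
    q = efficiency ** (-target_cq.astype(float))
    normalized = q / nf.reindex(target_cq.index)
    fold = normalized / normalized[calibrator]
    fold.name = "fold"
    return fold


def timecourse_fold(
    cq_table: pd.DataFrame,
    target_genes,
    reference_genes=("RCC2", "COP-g"),
    efficiencies: dict | float = 2.0,
) -> pd.DataFrame:
    """Per-specimen expression fold vs t0, normalized to the reference genes.

    Samples are labelled ``<specimen>@<time>`` with a t0 point per specimen;
    specimens without t0 are dropped with a warning.  Returns long format
    (gene, specimen, time, fold) plus cross-specimen mean and standard error
    in ``.attrs["summary"]``.
    """
    summary = summarize_replicates(cq_table)
    summary = summary[summary["sample"].astype(str).str.contains("@")]
    if summary.empty:
        raise PreconditionError("no time-course samples (expected '<specimen>@<time>')")
    parts = summary["sample"].str.split("@", expand=True)
    summary = summary.assign(specimen=parts[0], time=parts[1])

    def eff(gene):
        return efficiencies[gene] if isinstance(efficiencies, dict) else float(efficiencies)

    rows = []
    for specimen, sub in summary.groupby("specimen"):
        times = sorted(sub["time"].unique(), key=lambda t: (len(t), t))
        if "t0" not in set(times):
            warnings.warn(f"specimen {specimen} lacks a t0 sample; dropped")
            continue
        wide = sub.pivot(index="assay", columns="time", values="cq")
        nf = {}
        for t in times:
            qs = [eff(g) ** (-wide.loc[g, t]) for g in reference_genes]
            nf[t] = float(np.exp(np.mean(np.log(qs))))
        for gene in target_genes:
            q0 = eff(gene) ** (-wide.loc[gene, "t0"]) / nf["t0"]
            for t in times:
                q = eff(gene) ** (-wide.loc[gene, t]) / nf[t]
                rows.append((gene, specimen, t, q / q0))
    out = pd.DataFrame(rows, columns=["gene", "specimen", "time", "fold"])
    summary_stats = out.groupby(["gene", "time"])["fold"].agg(
        mean="mean", sem=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
    )
    out.attrs["summary"] = summary_stats
    return out
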