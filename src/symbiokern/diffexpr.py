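"""Per-gene contrast fitting and empirical-Bayes moderated statistics.

Implements the two-group (via a common reference) gene-wise contrast fit, the
scaled-F moment-matching estimate of the variance-prior hyperparameters
(d0, s0^2), the moderated t statistic, the B log posterior odds of
differential expression under the standard two-component normal model, and
the |M| / B call rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .array_preprocess import MAMatrix
from .errors import (
    ArgumentError,
    ConsistencyError,
    DegenerateDataError,
    PreconditionError,
)

M_THRESH_DEFAULT = 0.59
B_THRESH_DEFAULT = 0.0


@dataclass
class ContrastDesign:
    """A two-group contrast through the common reference.

    ``group_a`` and ``group_b`` are lists of sample labels; the contrast is
    mean(A) - mean(B) of reference-normalized profiles.  ``group_b`` may be
    empty for one-group designs (e.g. direct tissue hybridizations), in which
    case the contrast is mean(A).
    """

    name: str
    group_a: list
    group_b: list

    def __post_init__(self) -> None:
        if not self.group_a:
            raise ArgumentError("contrast needs at least one sample in group_a")
        overlap = set(self.group_a) & set(self.group_b)
        if overlap:
            raise ArgumentError(f"samples on both sides of contrast: {sorted(overlap)}")


def _sample_summaries(wide: pd.DataFrame, arrays_of: dict) -> dict:
    """Per-sample gene-wise mean, finite-array count and residual SS."""
    out = {}
    for sample, arrays in arrays_of.items():
        x = wide[arrays].to_numpy(dtype=float)
        finite = np.isfinite(x)
        n = finite.sum(axis=1)
        total = np.where(finite, x, 0.0).sum(axis=1)
        mean = np.divide(total, n, out=np.full(len(wide), np.nan), where=n > 0)
        dev = np.where(finite, x - mean[:, None], 0.0)
        ss = np.where(np.isfinite(dev), dev, 0.0)
        ss = (dev**2).sum(axis=1)
        out[sample] = (mean, n, ss)
    return out


def fit_gene_contrast(ma: MAMatrix, design: ContrastDesign) -> pd.DataFrame:
    """Gene-wise contrast fit on the per-sample linear model.

    Each sample (specimen profile) gets its own coefficient estimated from
    its arrays (normally the dye-swap pair); the contrast is the difference
    of the two group means of sample coefficients (or the group-A mean for a
    one-group design).  The residual variance s^2 pools within-sample
    replication only, with df = sum over contrast samples of (n_arrays - 1),
    so that biological spread between samples never enters the residual.
    ``se_unscaled`` is the contrast's standard-error scale c (se = c * s).
    Arrays with missing M for a gene are dropped gene-wise; a gene with no
    residual degrees of freedom is flagged df=0, not an error.
    """
    dmap = ma.design.set_index("array_id")["test_sample"]
    arrays_of = {}
    for sample in list(design.group_a) + list(design.group_b):
        arrays = [a for a, s in dmap.items() if s == sample]
        if arrays:
            arrays_of[sample] = arrays
    have_a = [s for s in design.group_a if s in arrays_of]
    have_b = [s for s in design.group_b if s in arrays_of]
    if not have_a or (design.group_b and not have_b):
        raise ConsistencyError(f"contrast '{design.name}': no arrays for one group")
    wide = ma.m_wide()
    absent = sorted(
        set(a for arr in arrays_of.values() for a in arr) - set(wide.columns)
    )
    if absent:
        raise ConsistencyError(f"contrast '{design.name}': arrays missing from MA table: {absent}")
    summaries = _sample_summaries(wide, arrays_of)

    def group_stats(samples):
        means = np.stack([summaries[s][0] for s in samples], axis=1)
        counts = np.stack([summaries[s][1] for s in samples], axis=1)
        present = counts > 0
        k = present.sum(axis=1)
        gmean = np.divide(
            np.where(present, means, 0.0).sum(axis=1), k,
            out=np.full(len(wide), np.nan), where=k > 0,
        )
        with np.errstate(divide="ignore"):
            inv_n = np.where(present, 1.0 / np.maximum(counts, 1), 0.0).sum(axis=1)
        var_scale = np.divide(inv_n, np.maximum(k, 1) ** 2, out=np.zeros(len(wide)),
                              where=k > 0)
        return gmean, k, var_scale

    mean_a, k_a, var_a = group_stats(have_a)
    if have_b:
        mean_b, k_b, var_b = group_stats(have_b)
        coef = mean_a - mean_b
        usable = (k_a > 0) & (k_b > 0)
        var_scale = var_a + var_b
    else:
        coef = mean_a
        usable = k_a > 0
        var_scale = var_a
    coef = np.where(usable, coef, np.nan)

    all_counts = np.stack([summaries[s][1] for s in arrays_of], axis=1)
    all_ss = np.stack([summaries[s][2] for s in arrays_of], axis=1)
    df = np.maximum(all_counts - 1, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, all_ss.sum(axis=1) / np.maximum(df, 1), np.nan)
    out = pd.DataFrame(
        {
            "coef": coef,
            "s2": s2,
            "df": df.astype(int),
            "se_unscaled": np.sqrt(var_scale),
            "n_arrays": all_counts.sum(axis=1).astype(int),
        },
        index=wide.index,
    )
    out.attrs["contrast"] = design.name
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        raise ArgumentError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def estimate_hyperparameters(fits: pd.DataFrame, min_genes: int = 50) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the inverse-chi-square variance prior.

    Moment matching of log s^2 against its theoretical scaled-F
    distribution: with z = log(s2), e = z - digamma(df/2) + log(df/2),
    E[e] = log(s0^2) - digamma(d0/2) + log(d0/2) and
    Var[e] = trigamma(df/2) + trigamma(d0/2).  d0 = +inf when the empirical
    variance does not exceed the theoretical minimum.
    """
    ok_df = fits["df"].to_numpy() >= 1
    if ok_df.sum() < min_genes:
        raise PreconditionError(
            f"need >= {min_genes} genes with df >= 1, have {int(ok_df.sum())}"
        )
    s2 = fits["s2"].to_numpy(dtype=float)
    df = fits["df"].to_numpy(dtype=float)
    usable = ok_df & np.isfinite(s2) & (s2 > 0)
    if not usable.any():
        raise DegenerateDataError("all residual variances are zero: no variance information")
    s2, df = s2[usable], df[usable]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / max(n - 1, 1)
    evar = evar - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        # no excess spread: all genes share one variance; plain mean is the MLE
        d0 = math.inf
        s02 = float(np.mean(s2))
    return float(d0), float(s02)


def _tmixture(
    tstat: np.ndarray,
    se_unscaled: np.ndarray,
    df: np.ndarray,
    proportion: float,
    v0_lim: tuple[float, float] | None = None,
) -> float:
    """Estimate the prior variance ratio v0 from the top fraction of |t|.

    Each of the top ``ceil(proportion/2 * n)`` |t| values is equated to its
    expected order statistic under the mixture, giving one v0 estimate per
    gene; the mean is returned.
    """
    keep = np.isfinite(tstat)
    tstat, se_unscaled, df = np.abs(tstat[keep]), se_unscaled[keep], df[keep]
    ngenes = tstat.size
    ntarget = int(np.ceil(proportion / 2.0 * ngenes))
    if ntarget < 1 or ngenes == 0:
        return float("nan")
    p = max(ntarget / ngenes, proportion)
    max_df = df.max()
    smaller = df < max_df
    if smaller.any():
        tail = stats.t.logsf(tstat[smaller], df[smaller])
        tstat = tstat.copy()
        tstat[smaller] = stats.t.isf(np.exp(tail), max_df)
        df = np.full_like(df, max_df)
    order = np.argsort(-tstat, kind="mergesort")[:ntarget]
    tt = tstat[order]
    v1 = se_unscaled[order] ** 2
    r = np.arange(1, ntarget + 1, dtype=float)
    p0 = 2.0 * stats.t.sf(tt, max_df)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, max_df)
        v0[pos] = v1[pos] * ((tt[pos] / qtarget) ** 2 - 1.0)
    if v0_lim is not None:
        v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(v0.mean())


def b_statistic(
    tstat: np.ndarray,
    df_total: np.ndarray,
    r: np.ndarray,
    prior_p: float,
) -> np.ndarray:
    """Closed-form log posterior odds of differential expression.

    B = logit(p) - log(r)/2 + (1 + df)/2 * log((t^2 + df) / (t^2/r + df)),
    where r = (c^2 + v0)/c^2 is the posterior/prior variance ratio of the
    coefficient.  The infinite-df limit uses the normal kernel
    t^2 (1 - 1/r) / 2.
    """
    logit = math.log(prior_p / (1.0 - prior_p))
    t2 = np.asarray(tstat, dtype=float) ** 2
    df_total = np.asarray(df_total, dtype=float)
    r = np.asarray(r, dtype=float)
    out = np.empty_like(t2)
    inf_df = ~np.isfinite(df_total)
    inf_t = ~np.isfinite(t2)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        fin = ~inf_df & ~inf_t
        out[fin] = (1.0 + df_total[fin]) / 2.0 * np.log(
            (t2[fin] + df_total[fin]) / (t2[fin] / r[fin] + df_total[fin])
        )
        out[inf_df & ~inf_t] = t2[inf_df & ~inf_t] * (1.0 - 1.0 / r[inf_df & ~inf_t]) / 2.0
    out[inf_t] = np.inf
    return logit - np.log(r) / 2.0 + out


def moderated_stats(
    fits: pd.DataFrame,
    hyper: tuple[float, float],
    prior_p: float = 0.01,
    v0: float | str = "auto",
) -> pd.DataFrame:
    """Moderated t and B for each gene of a contrast fit.

    s~2 = (d0 s0^2 + df s^2) / (d0 + df); t = coef / (s~ c); B as in
    :func:`b_statistic`.  ``v0="auto"`` estimates the prior variance of the
    coefficient from the top ``prior_p`` fraction of |t|.
    """
    if not 0.0 < prior_p < 1.0:
        raise ArgumentError("prior_p must be in (0, 1)")
    d0, s02 = hyper
    if d0 < 0 or s02 < 0:
        raise ArgumentError("hyperparameters must be non-negative")
    coef = fits["coef"].to_numpy(dtype=float)
    s2 = fits["s2"].to_numpy(dtype=float)
    df = fits["df"].to_numpy(dtype=float)
    u = fits["se_unscaled"].to_numpy(dtype=float)
    s2 = np.where(df > 0, s2, 0.0)  # df=0 genes carry no variance info
    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df) if d0 > 0 else s2
        df_total = d0 + df
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(s2_post) * u
        t = np.where(denom > 0, coef / denom, np.where(coef == 0, 0.0, np.inf * np.sign(coef)))
    if v0 == "auto":
        s2p = s02 if s02 > 0 else float(np.nanmedian(s2_post[s2_post > 0])) if (s2_post > 0).any() else 1.0
        lim = (0.1**2 / s2p, 4.0**2 / s2p) if s2p > 0 else None
        v0_est = _tmixture(t, u, df_total, prior_p, v0_lim=lim)
        if not np.isfinite(v0_est) or v0_est <= 0:
            v0_est = float(np.mean(u**2))  # fallback: prior sd comparable to se scale
    else:
        v0_est = float(v0)
        if v0_est <= 0:
            raise ArgumentError("v0 must be positive")
    r = (u**2 + v0_est) / u**2
    b = b_statistic(t, df_total, r, prior_p)
    out = fits.copy()
    out["s2_post"] = s2_post
    out["df_total"] = df_total
    out["t"] = t
    out["B"] = b
    out.attrs.update({"d0": d0, "s02": s02, "v0": v0_est, "prior_p": prior_p})
    return out


def call_de(
    stats_table: pd.DataFrame,
    m_thresh: float = M_THRESH_DEFAULT,
    b_thresh: float = B_THRESH_DEFAULT,
) -> pd.DataFrame:
    """Apply the strict |M| / B call rule.

    up: coef > m_thresh and B > b_thresh; down: coef < -m_thresh and
    B > b_thresh; otherwise none.  Inequalities are strict, matching the
    printed form of the thresholds.
    """
    coef = stats_table["coef"].to_numpy(dtype=float)
    b = stats_table["B"].to_numpy(dtype=float)
    call = np.where(
        (b > b_thresh) & (coef > m_thresh),
        "up",
        np.where((b > b_thresh) & (coef < -m_thresh), "down", "none"),
    )
    out = stats_table.copy()
    out["call"] = call
    out.attrs.update(stats_table.attrs)
    out.attrs.update({"m_thresh": m_thresh, "b_thresh": b_thresh})
    return out


def ebayes_pipeline(
    ma: MAMatrix,
    design: ContrastDesign,
    prior_p: float = 0.01,
    v0: float | str = "auto",
    m_thresh: float = M_THRESH_DEFAULT,
    b_thresh: float = B_THRESH_DEFAULT,
    hyper: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """fit -> hyperparameters -> moderated stats -> calls, with a noiseless
    fallback: if every gene has zero residual variance the prior collapses to
    (d0=inf, s0^2=0) and calls reduce to the |M| rule with B = +inf.
    """
    fits = fit_gene_contrast(ma, design)
    if hyper is None:
        try:
            hyper = estimate_hyperparameters(fits)
        except DegenerateDataError:
            hyper = (math.inf, 0.0)
    stats_table = moderated_stats(fits, hyper, prior_p=prior_p, v0=v0)
    return call_de(stats_table, m_thresh=m_thresh, b_thresh=b_thresh)
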