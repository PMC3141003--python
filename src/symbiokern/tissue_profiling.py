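"""Epidermis/gastroderm assignment from the dual designs and Venn counts.

Tissue preference requires agreement of two independent experiments: the
direct gastroderm-vs-epidermis hybridizations and the "transitive" contrast
obtained by differencing each tissue's profile against the shared reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_preprocess import MAMatrix
from .diffexpr import ContrastDesign, fit_gene_contrast
from .errors import ConsistencyError, PreconditionError

TISSUE_THRESH_DEFAULT = 0.59


def _tissue_samples(ma: MAMatrix) -> tuple[list, list]:
    samples = set(ma.design["test_sample"]) | set(ma.design["ref_sample"])
    g = sorted(s for s in samples if s.startswith("G_"))
    e = sorted(s for s in samples if s.startswith("E_"))
    return g, e


def _subset(ma: MAMatrix, array_ids) -> MAMatrix:
    array_ids = set(array_ids)
    return MAMatrix(
        values=ma.values[ma.values["array_id"].isin(array_ids)],
        design=ma.design[ma.design["array_id"].isin(array_ids)],
    )


def direct_tissue_contrast(ma: MAMatrix) -> pd.DataFrame:
    """Per-specimen dye-swap-corrected mean M for the direct G-vs-E arrays.

    Returns genes x specimens, plus a ``consensus`` column (cross-specimen
    mean).  Positive M means higher in the gastroderm.
    """
    design = ma.design
    direct = design[
        design["test_sample"].str.startswith("G_")
        & design["ref_sample"].str.startswith("E_")
    ]
    if direct.empty:
        raise PreconditionError("no direct gastroderm-vs-epidermis arrays present")
    out = {}
    for g_sample, sub in direct.groupby("test_sample"):
        specimen = g_sample[2:]
        ma_sub = _subset(ma, sub["array_id"])
        fit = fit_gene_contrast(ma_sub, ContrastDesign(f"direct_{specimen}", [g_sample], []))
        out[specimen] = fit["coef"]
    table = pd.DataFrame(out)
    table["consensus"] = table.mean(axis=1)
    return table


def transitive_tissue_contrast(ma: MAMatrix) -> pd.DataFrame:
    """M_trans = M(G vs ref) - M(E vs ref) per specimen, plus consensus.

    Specimens missing one side are dropped from the consensus; genes missing
    either side in a specimen get NaN there.
    """
    g_samples, e_samples = _tissue_samples(ma)
    ref_arrays = ma.design[~ma.design["ref_sample"].str.startswith(("G_", "E_"))]
    have = set(ref_arrays["test_sample"])
    out = {}
    ma_ref = _subset(ma, ref_arrays["array_id"])
    for g_sample in g_samples:
        specimen = g_sample[2:]
        e_sample = f"E_{specimen}"
        if g_sample not in have or e_sample not in have:
            continue
        fit_g = fit_gene_contrast(ma_ref, ContrastDesign(f"gref_{specimen}", [g_sample], []))
        fit_e = fit_gene_contrast(ma_ref, ContrastDesign(f"eref_{specimen}", [e_sample], []))
        out[specimen] = fit_g["coef"] - fit_e["coef"]
    if not out:
        raise PreconditionError("no specimen has both tissue-vs-reference contrasts")
    table = pd.DataFrame(out)
    table["consensus"] = table.mean(axis=1)
    return table


def assign_tissue(
    m_direct: pd.Series,
    m_trans: pd.Series,
    thresh: float = TISSUE_THRESH_DEFAULT,
) -> pd.DataFrame:
    """Intersection rule with strict inequalities.

    Ga iff both contrasts > thresh; Ep iff both < -thresh; anything else
    (including discordant signs) is none.
    """
    if not m_direct.index.equals(m_trans.index):
        m_trans = m_trans.reindex(m_direct.index)
        if m_trans.isna().any():
            raise ConsistencyError("direct and transitive contrasts cover different probes")
    d = m_direct.to_numpy(dtype=float)
    t = m_trans.to_numpy(dtype=float)
    call = np.where(
        (d > thresh) & (t > thresh),
        "Ga",
        np.where((d < -thresh) & (t < -thresh), "Ep", "none"),
    )
    out = pd.DataFrame(
        {"M_direct": d, "M_trans": t, "call": call}, index=m_direct.index
    )
    out.attrs["thresh"] = thresh
    return out


VENN_REGIONS = (
    "Ga_only", "Ep_only", "SY_only", "APO_only",
    "Ga_SY", "Ga_APO", "Ep_SY", "Ep_APO", "none",
)


@dataclass
class VennCounts:
    counts: pd.Series  # disjoint region counts over the cnidarian genes
    n_genes: int

    @property
    def ga_fraction(self) -> float:
        """Gastroderm share among tissue-assigned genes."""
        ga = self.counts[["Ga_only", "Ga_SY", "Ga_APO"]].sum()
        ep = self.counts[["Ep_only", "Ep_SY", "Ep_APO"]].sum()
        total = ga + ep
        return float(ga / total) if total else float("nan")


def venn_cross_classification(
    tissue_calls: pd.DataFrame,
    sy_genes,
    apo_genes,
    annotation: pd.DataFrame,
) -> VennCounts:
    """Disjoint cross-classification of tissue and state calls.

    Only genes of cnidarian origin are counted; the SY and APO sets must be
    disjoint.  Region counts sum to the number of cnidarian genes considered.
    """
    sy_genes, apo_genes = set(sy_genes), set(apo_genes)
    if sy_genes & apo_genes:
        raise ConsistencyError("SY and APO gene sets overlap")
    cnid = set(annotation.loc[annotation["origin"] == "cnidarian", "probe_id"])
    genes = [g for g in tissue_calls.index if g in cnid]
    counts = dict.fromkeys(VENN_REGIONS, 0)
    calls = tissue_calls["call"]
    for g in genes:
        tissue = calls[g]
        state = "SY" if g in sy_genes else "APO" if g in apo_genes else "none"
        if tissue == "none" and state == "none":
            region = "none"
        elif tissue == "none":
            region = f"{state}_only"
        elif state == "none":
            region = f"{tissue}_only"
        else:
            region = f"{tissue}_{state}"
        counts[region] += 1
    series = pd.Series(counts, name="count")
    series.index.name = "region"
    return VennCounts(counts=series, n_genes=len(genes))
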