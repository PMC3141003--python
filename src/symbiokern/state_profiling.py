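"""Batch and per-individual state contrasts, consensus selection, clustering.

The batch contrast pools all symbiotic specimens against all aposymbiotic
specimens (through the shared reference); each individual contrast compares
one specimen with the opposing pooled batch.  Every contrast is oriented
"symbiotic side minus aposymbiotic side", so an "up" call always means
SY-elevated and direction consistency is plain call equality.

The consensus ("Kern") rule keeps batch-called genes of cnidarian origin
that are called, with the batch direction, in at least ``min_support`` of
the individual contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .array_preprocess import MAMatrix
from .diffexpr import (
    B_THRESH_DEFAULT,
    M_THRESH_DEFAULT,
    ContrastDesign,
    ebayes_pipeline,
)
from .errors import ArgumentError, ConsistencyError, PreconditionError

BATCH_CONTRAST = "SYvsAPO"


@dataclass
class StateContrastResult:
    batch: pd.DataFrame  # DE-call table for the batch contrast
    individual: dict  # specimen -> DE-call table (all oriented SY - APO)
    specimens: pd.DataFrame  # sample, state

    @property
    def n_individuals(self) -> int:
        return len(self.specimens)


def run_state_contrasts(
    ma: MAMatrix,
    specimens: pd.DataFrame,
    prior_p: float = 0.01,
    v0: float | str = "auto",
    m_thresh: float = M_THRESH_DEFAULT,
    b_thresh: float = B_THRESH_DEFAULT,
) -> StateContrastResult:
    """One batch contrast plus one contrast per specimen vs the opposing batch."""
    sy = list(specimens.loc[specimens["state"] == "SY", "sample"])
    apo = list(specimens.loc[specimens["state"] == "APO", "sample"])
    if not sy or not apo:
        raise PreconditionError("need at least one specimen per state")
    available = set(ma.design["test_sample"])
    for s in sy + apo:
        if s not in available:
            warnings.warn(f"specimen {s} has no arrays; it contributes no profile")
    kwargs = dict(prior_p=prior_p, v0=v0, m_thresh=m_thresh, b_thresh=b_thresh)
    batch = ebayes_pipeline(ma, ContrastDesign(BATCH_CONTRAST, sy, apo), **kwargs)
    individual = {}
    for s in sy:
        individual[s] = ebayes_pipeline(ma, ContrastDesign(f"{s}_vs_apo", [s], apo), **kwargs)
    for s in apo:
        # oriented SY-minus-APO: the symbiotic batch is group A
        individual[s] = ebayes_pipeline(ma, ContrastDesign(f"sy_vs_{s}", sy, [s]), **kwargs)
    return StateContrastResult(batch=batch, individual=individual, specimens=specimens)


STATE_OF_CALL = {"up": "SY", "down": "APO", "none": "none"}


def support_histogram(
    individual_calls: dict, batch_calls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Count direction-consistent individual calls per batch-called gene.

    Returns (support table, histogram).  The support table is indexed by
    probe with columns batch_call ({SY, APO, none}), batch_M, batch_B and
    n_support; the histogram counts batch-called genes by n_support over
    0..n_individuals.
    """
    probes = batch_calls.index
    for name, table in individual_calls.items():
        if not table.index.equals(probes):
            raise ConsistencyError(f"contrast {name} has a different probe set")
    batch_call = batch_calls["call"].map(STATE_OF_CALL)
    n_support = pd.Series(0, index=probes)
    for table in individual_calls.values():
        n_support += (table["call"].to_numpy() == batch_calls["call"].to_numpy()) & (
            batch_calls["call"].to_numpy() != "none"
        )
    support = pd.DataFrame(
        {
            "batch_call": batch_call,
            "batch_M": batch_calls["coef"],
            "batch_B": batch_calls["B"],
            "n_support": n_support.astype(int),
        }
    )
    n_ind = len(individual_calls)
    called = support["batch_call"] != "none"
    histogram = (
        support.loc[called, "n_support"]
        .value_counts()
        .reindex(range(n_ind + 1), fill_value=0)
        .sort_index()
    )
    histogram.index.name = "n_support"
    return support, histogram


def select_kern(
    support: pd.DataFrame,
    annotation: pd.DataFrame,
    min_support: int = 8,
    n_individuals: int = 11,
) -> pd.DataFrame:
    """Consensus gene-set selection.

    Keeps batch-called genes of cnidarian origin with
    n_support >= min_support; rows sorted SY before APO, then by |batch M|
    descending.  Genes without annotation are excluded with a warning.
    """
    if (support["n_support"] > n_individuals).any():
        raise ConsistencyError("support counts exceed the number of individuals")
    ann = annotation.set_index("probe_id")
    candidates = support[(support["batch_call"] != "none") & (support["n_support"] >= min_support)]
    unannotated = candidates.index.difference(ann.index)
    if len(unannotated):
        warnings.warn(f"{len(unannotated)} called genes lack annotation and were excluded")
        candidates = candidates.drop(unannotated)
    origin = ann.loc[candidates.index, "origin"]
    kern = candidates[origin == "cnidarian"].copy()
    kern["origin"] = "cnidarian"
    kern["direction"] = kern["batch_call"]
    # signed linear fold, the convention of the printed result table
    kern["array_fold"] = np.sign(kern["batch_M"]) * 2.0 ** kern["batch_M"].abs()
    kern["abs_m"] = kern["batch_M"].abs()
    kern = kern.sort_values(
        ["direction", "abs_m"], ascending=[False, False]  # SY before APO
    ).drop(columns=["abs_m"])
    kern.attrs["min_support"] = min_support
    kern.attrs["n_individuals"] = n_individuals
    return kern


# ---------------------------------------------------------------------------
# specimen clustering
# ---------------------------------------------------------------------------

DISTANCES = ("pearson", "uncentered")
LINKAGES = ("complete", "average", "centroid")


def correlation_distance(profiles: pd.DataFrame, distance: str = "pearson") -> pd.DataFrame:
    """1 - correlation between specimen profiles (columns).

    ``uncentered`` is the cosine-style correlation without mean-centering.
    Constant (zero-variance) profiles get correlation 0 with a warning.
    """
    if distance not in DISTANCES:
        raise ArgumentError(f"unknown distance: {distance!r}")
    x = profiles.to_numpy(dtype=float)
    if distance == "pearson":
        x = x - x.mean(axis=0, keepdims=True)
    norms = np.sqrt((x**2).sum(axis=0))
    degenerate = norms == 0
    if degenerate.any():
        bad = list(profiles.columns[degenerate])
        warnings.warn(f"constant profiles, correlations set to 0: {bad}")
    safe = np.where(degenerate, 1.0, norms)
    xn = x / safe
    corr = xn.T @ xn
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(1.0 - corr, index=profiles.columns, columns=profiles.columns)


@dataclass
class Dendrogram:
    labels: list
    merges: list  # (left node, right node, height); nodes < n are leaves
    linkage_matrix: np.ndarray = field(repr=False)

    def newick(self) -> str:
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        names = {i: str(self.labels[i]) for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            names[node] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g})"
            heights[node] = h
        return names[n + len(self.merges) - 1] + ";"

    def leaf_order(self) -> list:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def merge_heights(self) -> list:
        return [h for _, _, h in self.merges]


def _centroid_linkage(profiles: pd.DataFrame, distance: str) -> np.ndarray:
    """Agglomerate by correlation distance between cluster centroid profiles."""
    labels = list(profiles.columns)
    n = len(labels)
    clusters = {i: ([i], profiles.iloc[:, i].to_numpy(dtype=float)) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        keys = sorted(clusters)
        best = None
        for i_pos, i in enumerate(keys):
            for j in keys[i_pos + 1:]:
                d = _profile_distance(clusters[i][1], clusters[j][1], distance)
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        members = clusters[i][0] + clusters[j][0]
        centroid = profiles.iloc[:, members].mean(axis=1).to_numpy()
        z[step] = (i, j, d, len(members))
        clusters[next_id] = (members, centroid)
        sizes[next_id] = len(members)
        del clusters[i], clusters[j]
        next_id += 1
    return z


def _profile_distance(a: np.ndarray, b: np.ndarray, distance: str) -> float:
    if distance == "pearson":
        a = a - a.mean()
        b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - (a @ b) / (na * nb))


def cluster_specimens(
    profiles: pd.DataFrame,
    distance: str = "pearson",
    linkage: str = "average",
) -> Dendrogram:
    """Hierarchical clustering of specimen expression profiles.

    ``profiles`` is genes x specimens.  Ties break deterministically by the
    column order of the input (sort columns by label upstream if needed).
    """
    if linkage not in LINKAGES:
        raise ArgumentError(f"unknown linkage: {linkage!r}")
    if profiles.shape[1] < 3:
        raise PreconditionError("need >= 3 specimens to cluster")
    if profiles.shape[0] < 2:
        raise PreconditionError("need >= 2 genes to cluster")
    if linkage == "centroid":
        z = _centroid_linkage(profiles, distance)
    else:
        dist = correlation_distance(profiles, distance)
        condensed = squareform(dist.to_numpy(), checks=False)
        z = hierarchy.linkage(condensed, method=linkage)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(labels=list(profiles.columns), merges=merges, linkage_matrix=z)


def individual_m_matrix(result: StateContrastResult, restrict_to_called: bool = True) -> pd.DataFrame:
    """Per-individual contrast M-hat matrix (genes x specimens)."""
    cols = {s: t["coef"] for s, t in result.individual.items()}
    mat = pd.DataFrame(cols)
    if restrict_to_called:
        called = result.batch["call"] != "none"
        mat = mat.loc[called[called].index]
    return mat
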