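"""Synthetic data generators with planted ground truth.

Emulates the structure the downstream stages assume: dye-swap pairs of
two-color scans against a common aposymbiotic reference (AS6), heterogeneous
per-individual differential-expression activity, epidermis/gastroderm tissue
contrasts, and qPCR dilution series / copy-ratio / expression tables.

Inter-individual heterogeneity model: each planted gene is "active" in a
given individual with probability ``activity_prob``.  A planted gene is
expressed (by ``effect_log2``) only in active individuals of its own state;
individuals of the opposite state sit at the state baseline regardless of
their activity draw.  Activity draws are recorded for all individuals so
recovery tests can condition on them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_preprocess import ArrayScanSet
from .errors import ArgumentError, ConsistencyError

SY_SPECIMENS = ("Sy1", "Sy2", "Sy3", "Sy4", "Sy5")
APO_SPECIMENS = ("AS1", "AS2", "AS3", "AS4", "AS5", "AS6")
REFERENCE_SPECIMEN = "AS6"

GO_VOCABULARY = (
    "GO:0005509|calcium ion binding",
    "GO:0009536|plastid",
    "GO:0005829|cytosol",
    "GO:0016023|cytoplasmic membrane-bounded vesicle",
    "GO:0006351|transcription",
    "GO:0036211|protein modification process",
    "GO:0007155|cell adhesion",
    "GO:0006629|lipid metabolic process",
    "GO:0006810|transport",
    "GO:0016209|antioxidant activity",
    "GO:0006915|apoptotic process",
    "GO:0004089|carbonate dehydratase activity",
    "GO:0005975|carbohydrate metabolic process",
    "GO:0008233|peptidase activity",
    "GO:0016192|vesicle-mediated transport",
    "GO:0006511|ubiquitin-dependent protein catabolic process",
    "GO:0005856|cytoskeleton",
    "GO:0005615|extracellular space",
    "GO:0016020|membrane",
    "GO:0005634|nucleus",
)

ORIGINS = ("cnidarian", "zooxanthella", "prokaryote")

ANNOTATION_COLUMNS = ["probe_id", "origin", "go_terms"]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Substream derived from one global seed by a fixed offset."""
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    n_cnidarian: int,
    n_zoox: int,
    n_prok: int,
    go_terms_per_gene: int,
    seed: int,
) -> pd.DataFrame:
    """Probe annotation with exact per-origin counts and reproducible GO terms."""
    for name, n in (("n_cnidarian", n_cnidarian), ("n_zoox", n_zoox), ("n_prok", n_prok),
                    ("go_terms_per_gene", go_terms_per_gene)):
        if n < 0:
            raise ArgumentError(f"{name} must be >= 0")
    rng = _rng(seed, 1)
    ids = (
        [f"AvCL{i + 1:05d}" for i in range(n_cnidarian)]
        + [f"Zx{i + 1:05d}" for i in range(n_zoox)]
        + [f"Pk{i + 1:05d}" for i in range(n_prok)]
    )
    origins = (
        ["cnidarian"] * n_cnidarian + ["zooxanthella"] * n_zoox + ["prokaryote"] * n_prok
    )
    n = len(ids)
    order = rng.permutation(n)
    go = []
    vocab = np.array(GO_VOCABULARY)
    for _ in range(n):
        if go_terms_per_gene > 0:
            k = min(go_terms_per_gene, len(vocab))
            terms = rng.choice(vocab, size=k, replace=False)
            go.append(";".join(t.split("|")[0] for t in sorted(terms)))
        else:
            go.append("")
    table = pd.DataFrame(
        {
            "probe_id": np.array(ids)[order],
            "origin": np.array(origins)[order],
            "go_terms": go,
        }
    )
    return table.reset_index(drop=True)


def write_annotation(annotation: pd.DataFrame, path: str) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "origin": str})
    table["go_terms"] = table.get("go_terms", "").fillna("")
    return table


# ---------------------------------------------------------------------------
# state experiment
# ---------------------------------------------------------------------------

@dataclass
class StateSimConfig:
    n_probes: int = 2000
    n_sy_specimens: int = 5
    n_apo_specimens: int = 6
    n_planted_sy: int = 50
    n_planted_apo: int = 50
    effect_log2: float = 1.5
    activity_prob: float = 0.9
    noise_sd: float = 0.3
    dye_bias_amplitude: float = 0.2
    n_print_tips: int = 16
    bg_mean: float = 80.0
    replicate_spots: int = 1
    zoox_low_log2: float = -8.0
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_sy + self.n_planted_apo > self.n_probes:
            raise ArgumentError("planted genes exceed probe count")
        if not 0.0 <= self.activity_prob <= 1.0:
            raise ArgumentError("activity_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ArgumentError("noise_sd must be >= 0")
        if self.n_sy_specimens > len(SY_SPECIMENS) or self.n_apo_specimens > len(APO_SPECIMENS):
            raise ArgumentError("at most 5 symbiotic / 6 aposymbiotic specimens supported")
        if self.replicate_spots < 1:
            raise ArgumentError("replicate_spots must be >= 1")

    @property
    def sy_specimens(self) -> list:
        return list(SY_SPECIMENS[: self.n_sy_specimens])

    @property
    def apo_specimens(self) -> list:
        # the reference specimen is always the last aposymbiotic one
        apo = list(APO_SPECIMENS[: self.n_apo_specimens])
        if REFERENCE_SPECIMEN not in apo:
            apo[-1] = REFERENCE_SPECIMEN
        return apo

    @property
    def specimens(self) -> list:
        return self.sy_specimens + self.apo_specimens


@dataclass
class StateTruth:
    """Planted ground truth for a state experiment."""

    direction: pd.Series  # probe -> {SY, APO, null}
    activity: pd.DataFrame  # planted probes x specimens, bool
    true_log2fc: pd.Series  # realized expected batch contrast, 0 for null genes
    expression: pd.DataFrame = field(repr=False)  # probe x specimen log2 levels

    def planted(self, direction: str | None = None) -> pd.Index:
        mask = self.direction != "null"
        if direction is not None:
            mask = self.direction == direction
        return self.direction.index[mask]

    def n_active(self) -> pd.Series:
        """Number of individuals each planted gene is active in."""
        return self.activity.sum(axis=1)


def specimen_table(cfg: StateSimConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": cfg.specimens,
            "state": ["SY"] * cfg.n_sy_specimens + ["APO"] * cfg.n_apo_specimens,
        }
    )


def _tip_assignment(n_probes: int, n_tips: int) -> np.ndarray:
    return (np.arange(n_probes) * n_tips // max(n_probes, 1)) + 1


def _dye_bias_curve(a: np.ndarray, amplitude: float, coeffs: np.ndarray) -> np.ndarray:
    """Smooth cubic intensity-dependent dye bias (on the raw red/green M scale).

    The argument is clipped so the curve saturates at the intensity extremes,
    as real dye bias does; an unbounded cubic tail would put structure where
    a local smoother has no support.
    """
    z = np.clip((a - 10.0) / 2.0, -1.2, 1.2)
    return amplitude * (coeffs[0] + coeffs[1] * z + coeffs[2] * z**2 + coeffs[3] * z**3)


def _truncated_background(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    return np.clip(rng.normal(mean, mean / 10.0, size), 0.0, None)


def _build_scan_frames(
    arrays: list[dict],
    probes: np.ndarray,
    tips: np.ndarray,
    a_base: np.ndarray,
    expression: pd.DataFrame,
    cfg,
    rng: np.random.Generator,
) -> ArrayScanSet:
    """Shared scan construction: per-array channel intensities from expression.

    ``arrays`` entries: {array_id, cy3_sample, cy5_sample, dye_swap_of}.
    log2 red = base + e(cy5) + (bias + noise)/2; green symmetric, so the raw
    red/green log-ratio is e(cy5) - e(cy3) + bias + noise.  The bias term is
    identical for both members of a dye-swap pair, hence flips sign once M is
    re-oriented downstream.
    """
    n = len(probes)
    bias_coeffs = {}
    bias_rng = _rng(cfg.seed, 11)
    for tip in np.unique(tips):
        bias_coeffs[tip] = bias_rng.normal(0.0, 1.0, 4)
    noise_by_pair: dict[str, np.ndarray] = {}
    rows = []
    for spec in arrays:
        array_id = spec["array_id"]
        e5 = expression[spec["cy5_sample"]].to_numpy()
        e3 = expression[spec["cy3_sample"]].to_numpy()
        bias = np.zeros(n)
        if cfg.dye_bias_amplitude != 0:
            for tip, c in bias_coeffs.items():
                sel = tips == tip
                bias[sel] = _dye_bias_curve(a_base[sel], cfg.dye_bias_amplitude, c)
        k = cfg.replicate_spots
        # replicate spots share signal and bias but have independent noise
        noise = rng.normal(0.0, cfg.noise_sd, n * k) if cfg.noise_sd > 0 else np.zeros(n * k)
        log_red = np.repeat(a_base + e5 + bias / 2.0, k) + noise / 2.0
        log_green = np.repeat(a_base + e3 - bias / 2.0, k) - noise / 2.0
        rep_red = 2.0**log_red
        rep_green = 2.0**log_green
        bg_red = _truncated_background(rng, cfg.bg_mean, n * k)
        bg_green = _truncated_background(rng, cfg.bg_mean, n * k)
        rows.append(
            pd.DataFrame(
                {
                    "array_id": array_id,
                    "probe_id": np.repeat(probes, k),
                    "print_tip_group": np.repeat(tips, k),
                    "fg_red": bg_red + rep_red,
                    "bg_red": bg_red,
                    "fg_green": bg_green + rep_green,
                    "bg_green": bg_green,
                }
            )
        )
    scans = pd.concat(rows, ignore_index=True)
    design = pd.DataFrame(arrays)[["array_id", "cy3_sample", "cy5_sample", "dye_swap_of"]]
    return ArrayScanSet(scans=scans, design=design)


def generate_state_experiment(
    cfg: StateSimConfig, annotation: pd.DataFrame
) -> tuple[ArrayScanSet, pd.DataFrame, StateTruth]:
    """Dye-swap scan pairs for every specimen against the AS6 reference.

    The reference specimen also gets a self-self pair so that the
    aposymbiotic batch is represented by one profile per specimen.  Returns
    (scans, design, truth); the design frame is also embedded in the scan set.
    """
    if len(annotation) != cfg.n_probes:
        raise ConsistencyError(
            f"annotation has {len(annotation)} rows, config expects {cfg.n_probes}"
        )
    probes = annotation["probe_id"].to_numpy()
    origin = annotation["origin"].to_numpy()
    specimens = cfg.specimens
    states = dict(zip(specimen_table(cfg)["sample"], specimen_table(cfg)["state"]))

    rng = _rng(cfg.seed, 2)
    cnidarian_idx = np.flatnonzero(origin == "cnidarian")
    n_planted = cfg.n_planted_sy + cfg.n_planted_apo
    if n_planted > len(cnidarian_idx):
        raise ArgumentError("not enough cnidarian probes to plant effects on")
    chosen = rng.choice(cnidarian_idx, size=n_planted, replace=False)
    direction = pd.Series("null", index=pd.Index(probes, name="probe_id"))
    direction.iloc[chosen[: cfg.n_planted_sy]] = "SY"
    direction.iloc[chosen[cfg.n_planted_sy:]] = "APO"

    planted_probes = probes[np.sort(chosen)]
    activity = pd.DataFrame(
        rng.random((len(planted_probes), len(specimens))) < cfg.activity_prob,
        index=pd.Index(planted_probes, name="probe_id"),
        columns=specimens,
    )

    # expression levels (log2, baseline 0) per probe x specimen
    expression = pd.DataFrame(
        0.0, index=pd.Index(probes, name="probe_id"), columns=specimens
    )
    for p in planted_probes:
        d = direction[p]
        for s in specimens:
            if states[s] == d and bool(activity.loc[p, s]):
                expression.loc[p, s] = cfg.effect_log2
    zoox = origin == "zooxanthella"
    if zoox.any():
        for s in specimens:
            if states[s] == "APO":  # no symbionts: zoox probes near background
                expression.loc[zoox, s] = cfg.zoox_low_log2

    sy_mean = expression[cfg.sy_specimens].mean(axis=1)
    apo_mean = expression[cfg.apo_specimens].mean(axis=1)
    true_fc = (sy_mean - apo_mean).where(direction != "null", 0.0)

    a_base = _rng(cfg.seed, 3).normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_probes)
    tips = _tip_assignment(cfg.n_probes, cfg.n_print_tips)

    arrays = []
    for s in specimens:
        arrays.append(
            {"array_id": f"{s}_vs_ref", "cy3_sample": REFERENCE_SPECIMEN,
             "cy5_sample": s, "dye_swap_of": ""}
        )
        arrays.append(
            {"array_id": f"{s}_vs_ref_sw", "cy3_sample": s,
             "cy5_sample": REFERENCE_SPECIMEN, "dye_swap_of": f"{s}_vs_ref"}
        )
    scan_set = _build_scan_frames(
        arrays, probes, tips, a_base, expression, cfg, _rng(cfg.seed, 4)
    )
    truth = StateTruth(
        direction=direction,
        activity=activity,
        true_log2fc=true_fc,
        expression=expression,
    )
    return scan_set, scan_set.design, truth


# ---------------------------------------------------------------------------
# tissue experiment
# ---------------------------------------------------------------------------

@dataclass
class TissueSimConfig:
    n_probes: int = 2000
    specimens: tuple = ("Sy3", "Sy4", "Sy5")
    n_planted_ga: int = 71
    n_planted_ep: int = 29
    effect_log2: float = 2.0
    noise_sd: float = 0.0
    dye_bias_amplitude: float = 0.0
    n_print_tips: int = 16
    bg_mean: float = 0.0
    replicate_spots: int = 1
    zoox_low_log2: float = -8.0
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_ga + self.n_planted_ep > self.n_probes:
            raise ArgumentError("planted genes exceed probe count")
        if self.noise_sd < 0:
            raise ArgumentError("noise_sd must be >= 0")
        if len(self.specimens) < 1:
            raise ArgumentError("need at least one specimen")
        if self.replicate_spots < 1:
            raise ArgumentError("replicate_spots must be >= 1")


@dataclass
class TissueTruth:
    call: pd.Series  # probe -> {Ga, Ep, none}
    tissue_log2fc: pd.Series  # gastroderm minus epidermis

    def assignable(self, thresh: float = 0.59) -> pd.Series:
        """Whether the planted effect clears a strict threshold."""
        return self.tissue_log2fc.abs() > thresh


def generate_tissue_experiment(
    cfg: TissueSimConfig, annotation: pd.DataFrame
) -> tuple[ArrayScanSet, pd.DataFrame, TissueTruth]:
    """Both tissue designs: direct G-vs-E pairs and G/E-vs-reference pairs."""
    if len(annotation) != cfg.n_probes:
        raise ConsistencyError(
            f"annotation has {len(annotation)} rows, config expects {cfg.n_probes}"
        )
    probes = annotation["probe_id"].to_numpy()
    origin = annotation["origin"].to_numpy()
    rng = _rng(cfg.seed, 5)
    cnidarian_idx = np.flatnonzero(origin == "cnidarian")
    n_planted = cfg.n_planted_ga + cfg.n_planted_ep
    if n_planted > len(cnidarian_idx):
        raise ArgumentError("not enough cnidarian probes to plant tissue effects on")
    chosen = rng.choice(cnidarian_idx, size=n_planted, replace=False)
    call = pd.Series("none", index=pd.Index(probes, name="probe_id"))
    call.iloc[chosen[: cfg.n_planted_ga]] = "Ga"
    call.iloc[chosen[cfg.n_planted_ga:]] = "Ep"
    fc = pd.Series(0.0, index=call.index)
    fc[call == "Ga"] = cfg.effect_log2
    fc[call == "Ep"] = -cfg.effect_log2

    samples = [f"G_{s}" for s in cfg.specimens] + [f"E_{s}" for s in cfg.specimens]
    samples.append(REFERENCE_SPECIMEN)
    expression = pd.DataFrame(0.0, index=call.index, columns=samples)
    for s in cfg.specimens:
        expression[f"G_{s}"] = fc / 2.0
        expression[f"E_{s}"] = -fc / 2.0
    zoox = origin == "zooxanthella"
    if zoox.any():
        for col in samples:
            if not col.startswith("G_"):  # zoox only in gastroderm fractions
                expression.loc[zoox, col] = cfg.zoox_low_log2

    a_base = _rng(cfg.seed, 6).normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_probes)
    tips = _tip_assignment(cfg.n_probes, cfg.n_print_tips)
    arrays = []
    for s in cfg.specimens:
        g, e = f"G_{s}", f"E_{s}"
        arrays += [
            {"array_id": f"{s}_GvsE", "cy3_sample": e, "cy5_sample": g, "dye_swap_of": ""},
            {"array_id": f"{s}_GvsE_sw", "cy3_sample": g, "cy5_sample": e,
             "dye_swap_of": f"{s}_GvsE"},
            {"array_id": f"{s}_Gvsref", "cy3_sample": REFERENCE_SPECIMEN,
             "cy5_sample": g, "dye_swap_of": ""},
            {"array_id": f"{s}_Gvsref_sw", "cy3_sample": g,
             "cy5_sample": REFERENCE_SPECIMEN, "dye_swap_of": f"{s}_Gvsref"},
            {"array_id": f"{s}_Evsref", "cy3_sample": REFERENCE_SPECIMEN,
             "cy5_sample": e, "dye_swap_of": ""},
            {"array_id": f"{s}_Evsref_sw", "cy3_sample": e,
             "cy5_sample": REFERENCE_SPECIMEN, "dye_swap_of": f"{s}_Evsref"},
        ]
    scan_set = _build_scan_frames(
        arrays, probes, tips, a_base, expression, cfg, _rng(cfg.seed, 7)
    )
    return scan_set, scan_set.design, TissueTruth(call=call, tissue_log2fc=fc)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ["sample", "assay", "role", "log10_copies", "replicate", "cq"]

DEFAULT_STATE_RATIOS = {
    "Sy1": 1.0, "Sy2": 0.9, "Sy3": 1.1, "Sy4": 0.8, "Sy5": 1.2,
    "AS1": 2e-2, "AS2": 1e-2, "AS3": 5e-3, "AS4": 8.2e-2, "AS5": 1e-3,
    "AS6": 1e-4,
}


@dataclass
class QpcrSimConfig:
    symbiont_loci: tuple = ("EF2", "SPS", "APX")
    host_loci: tuple = ("COP-g", "RCC2", "NPC1")
    planted_ratio: dict = field(default_factory=lambda: dict(DEFAULT_STATE_RATIOS))
    planted_efficiency: float | dict = 1.9
    cq_noise_sd: float = 0.0
    dilution_points: int = 6
    n_replicates: int = 3
    host_copies: float = 1e5
    locus_copy_factor: dict = field(default_factory=dict)
    genomic_intercept: float = 38.0
    # expression panel
    include_expression: bool = False
    reference_genes: tuple = ("RPLP0", "RCC2", "COP-g", "ACTB", "TUBA", "GAPDH")
    unstable_gene: str = "GAPDH"
    unstable_sd_log2: float = 1.0
    target_folds: dict = field(default_factory=dict)  # gene -> {sample: fold vs calibrator}
    expression_calibrator: str = "AS6"
    sample_loading: dict = field(default_factory=dict)
    expression_intercept: float = 30.0
    # heat-stress time course
    timecourse_folds: dict = field(default_factory=dict)  # gene -> {t24: f, t48: f}
    timecourse_specimens: tuple = ("Sy3", "Sy4", "Sy5")
    timecourse_references: tuple = ("RCC2", "COP-g")
    seed: int = 0

    def __post_init__(self) -> None:
        for spec, r in self.planted_ratio.items():
            if r < 0:
                raise ArgumentError(f"planted ratio for {spec} must be >= 0")
        for locus in self.all_assays():
            e = self.efficiency(locus)
            if e <= 1.0:
                raise ArgumentError(f"efficiency for {locus} must be > 1")
        if self.dilution_points < 3:
            raise ArgumentError("need >= 3 dilution points")

    def all_assays(self) -> list:
        assays = list(self.symbiont_loci) + list(self.host_loci)
        if self.include_expression:
            assays += [g for g in self.reference_genes if g not in assays]
            assays += [g for g in self.target_folds if g not in assays]
        assays += [g for g in self.timecourse_folds if g not in assays]
        assays += [g for g in self.timecourse_references if g not in assays]
        return assays

    def efficiency(self, assay: str) -> float:
        if isinstance(self.planted_efficiency, dict):
            return float(self.planted_efficiency.get(assay, 1.9))
        return float(self.planted_efficiency)


@dataclass
class QpcrTruth:
    efficiencies: dict
    ratio: pd.Series  # specimen -> symbiont:host nuclei ratio (absolute)
    ratio_rel: pd.Series  # relative to the calibrator specimen
    loading: pd.Series | None = None
    target_folds: pd.DataFrame | None = None
    timecourse_folds: pd.DataFrame | None = None


def _cq(quantity: np.ndarray, efficiency: float, intercept: float) -> np.ndarray:
    """Cq = intercept + slope * log10(q) with slope = -1/log10(E)."""
    q = np.asarray(quantity, dtype=float)
    slope = -1.0 / np.log10(efficiency)
    with np.errstate(divide="ignore"):
        out = np.where(q > 0, intercept + slope * np.log10(np.where(q > 0, q, 1.0)), np.nan)
    return out


def generate_qpcr_dataset(
    cfg: QpcrSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, QpcrTruth]:
    """Dilution series, unknown-sample Cq values and planted truth.

    Returns (dilution_series, cq_table, truth).  ``dilution_series`` is the
    ``role == "standard"`` slice of the full long-format ``cq_table``
    (sample, assay, role, log10_copies, replicate, cq).
    """
    rng = _rng(cfg.seed, 8)
    rows = []

    def add_rows(sample, assay, role, quantity, intercept, log10_copies=np.nan):
        e = cfg.efficiency(assay)
        base = _cq(np.array([quantity]), e, intercept)[0]
        for rep in range(1, cfg.n_replicates + 1):
            noise = rng.normal(0.0, cfg.cq_noise_sd) if cfg.cq_noise_sd > 0 else 0.0
            cq = base + noise if np.isfinite(base) else np.nan
            rows.append((sample, assay, role, log10_copies, rep, cq))

    genomic = list(cfg.symbiont_loci) + list(cfg.host_loci)
    for assay in cfg.all_assays():
        intercept = cfg.genomic_intercept if assay in genomic else cfg.expression_intercept
        for p in range(cfg.dilution_points, 0, -1):
            add_rows(f"std_{assay}", assay, "standard", 10.0**p, intercept, log10_copies=p)

    specimens = list(cfg.planted_ratio)
    for s in specimens:
        for locus in cfg.host_loci:
            q = cfg.host_copies * cfg.locus_copy_factor.get(locus, 1.0)
            add_rows(s, locus, "unknown", q, cfg.genomic_intercept)
        for locus in cfg.symbiont_loci:
            q = cfg.planted_ratio[s] * cfg.host_copies * cfg.locus_copy_factor.get(locus, 1.0)
            add_rows(s, locus, "unknown", q, cfg.genomic_intercept)

    loading = None
    folds_df = None
    if cfg.include_expression:
        loading_rng = _rng(cfg.seed, 9)
        loading = pd.Series(
            {
                s: cfg.sample_loading.get(s, float(2.0 ** loading_rng.normal(0.0, 0.3)))
                for s in specimens
            }
        )
        for s in specimens:
            for g in cfg.reference_genes:
                q = loading[s]
                if g == cfg.unstable_gene and cfg.unstable_sd_log2 > 0:
                    q = q * float(2.0 ** loading_rng.normal(0.0, cfg.unstable_sd_log2))
                add_rows(s, g, "reference", q, cfg.expression_intercept)
        if cfg.target_folds:
            folds_df = pd.DataFrame(cfg.target_folds).reindex(specimens)
            for g, per_sample in cfg.target_folds.items():
                for s in specimens:
                    fold = per_sample.get(s, 1.0)
                    add_rows(s, g, "target", fold * loading[s], cfg.expression_intercept)

    tc_df = None
    if cfg.timecourse_folds:
        tc_rows = {}
        tc_rng = _rng(cfg.seed, 10)
        for spec in cfg.timecourse_specimens:
            for tp in ("t0", "t24", "t48"):
                sample = f"{spec}@{tp}"
                load = float(2.0 ** tc_rng.normal(0.0, 0.3))
                for g in cfg.timecourse_references:
                    add_rows(sample, g, "reference", load, cfg.expression_intercept)
                for g, per_time in cfg.timecourse_folds.items():
                    fold = per_time.get(tp, 1.0)
                    add_rows(sample, g, "target", fold * load, cfg.expression_intercept)
                    tc_rows[(g, tp)] = fold
        tc_df = pd.Series(tc_rows).unstack()
        tc_df.index.name = "gene"

    cq_table = pd.DataFrame(rows, columns=QPCR_COLUMNS)
    dilution = cq_table[cq_table["role"] == "standard"].reset_index(drop=True)
    ratio = pd.Series({s: float(cfg.planted_ratio[s]) for s in specimens})
    calibrator = specimens[0]
    rel = ratio / ratio[calibrator] if ratio[calibrator] > 0 else ratio
    truth = QpcrTruth(
        efficiencies={a: cfg.efficiency(a) for a in cfg.all_assays()},
        ratio=ratio,
        ratio_rel=rel,
        loading=loading,
        target_folds=folds_df,
        timecourse_folds=tc_df,
    )
    return dilution, cq_table, truth


def write_cq_table(cq_table: pd.DataFrame, path: str) -> None:
    cq_table[QPCR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cq_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ConsistencyError(f"qPCR table missing columns: {missing}")
    return table


def write_state_truth(truth: StateTruth, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    pd.DataFrame(
        {"direction": truth.direction, "true_log2fc": truth.true_log2fc}
    ).to_csv(os.path.join(out_dir, "state_truth.tsv"), sep="\t")
    truth.activity.astype(int).to_csv(os.path.join(out_dir, "state_activity.tsv"), sep="\t")


def write_tissue_truth(truth: TissueTruth, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    pd.DataFrame(
        {"call": truth.call, "tissue_log2fc": truth.tissue_log2fc}
    ).to_csv(os.path.join(out_dir, "tissue_truth.tsv"), sep="\t")
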