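"""Spectral-count quantification of affinity-purified adhesion complexes.

Label-free quantification by normalized spectral counts (NSC): the unweighted
spectral count of a protein in one MS run, divided by the total number of
spectra observed in that run and by the protein's molecular weight. Technical
replicates are summed within each biological isolation and results are
reported as the mean NSC over biological replicates, separately for complexes
isolated with the activating and the inhibiting antibody ("active" and
"inactive" conditions). Fold enrichment is the active/inactive NSC ratio;
proteins detected in only one condition carry a "unique" sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UNIQUE_ACTIVE",
    "UNIQUE_INACTIVE",
    "NSC_SCALE",
    "compute_nsc",
    "aggregate_replicates",
    "filter_min_count",
    "fold_enrichment",
    "differential_flags",
    "venn_summary",
    "summarize_tips",
    "round_half_up",
]

#: Sentinel fold values for proteins detected in a single activation state.
UNIQUE_ACTIVE = "UNIQUE_ACTIVE"
UNIQUE_INACTIVE = "UNIQUE_INACTIVE"

#: Readability multiplier applied to NSC values. Ratios, clustering and all
#: downstream statistics are invariant to this constant.
NSC_SCALE = 1e6

CONDITIONS = ("active", "inactive")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def _check_design(design: pd.DataFrame) -> None:
    required = {"sample_id", "condition", "bio_rep", "tech_rep", "total_spectra"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    bad = set(design["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions in design: {sorted(bad)}")
    if design.duplicated(["condition", "bio_rep", "tech_rep"]).any():
        raise ValueError("duplicate (condition, bio_rep, tech_rep) in design")
    if (design["total_spectra"] <= 0).any():
        bad_ids = design.loc[design["total_spectra"] <= 0, "sample_id"].tolist()
        raise ValueError(f"non-positive total_spectra for samples: {bad_ids}")


def compute_nsc(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    meta: pd.DataFrame,
    scale: float = NSC_SCALE,
) -> pd.DataFrame:
    """Normalized spectral counts per protein and sample.

    NSC[i, s] = SpC[i, s] / (T_s * M_i) * scale, where T_s is the total
    number of spectra observed in sample s and M_i the molecular weight of
    protein i in kDa.

    Parameters
    ----------
    counts
        Proteins (index) x sample_ids (columns), non-negative integers.
    design
        Sample design table with ``sample_id`` and ``total_spectra`` columns.
    meta
        Protein metadata indexed by accession with an ``mw_kda`` column.
    """
    _check_design(design)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative spectral counts")
    totals = design.set_index("sample_id")["total_spectra"]
    missing_s = [s for s in counts.columns if s not in totals.index]
    if missing_s:
        raise ValueError(f"samples missing from design: {missing_s}")
    mw = meta["mw_kda"] if "mw_kda" in meta.columns else meta.squeeze()
    missing_p = counts.index.difference(mw.index)
    if len(missing_p):
        raise ValueError(f"proteins missing molecular weight: {list(missing_p)}")
    mw = mw.loc[counts.index]
    if (mw <= 0).any():
        raise ValueError(f"non-positive molecular weight: {list(mw.index[mw <= 0])}")
    nsc = counts.div(totals.loc[counts.columns], axis=1).div(mw, axis=0) * scale
    return nsc


def aggregate_replicates(nsc: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Sum technical replicates within each biological isolation, then average
    biological replicates, per condition.

    Returns a proteins x conditions table of mean NSC.
    """
    _check_design(design)
    d = design.set_index("sample_id")
    cols = {}
    for cond in CONDITIONS:
        samples = d.index[d["condition"] == cond]
        samples = [s for s in samples if s in nsc.columns]
        if not samples:
            raise ValueError(f"no samples for condition {cond!r}")
        sub = nsc[samples]
        bio = sub.T.groupby(d.loc[samples, "bio_rep"]).sum().T
        cols[cond] = bio.mean(axis=1)
    return pd.DataFrame(cols)


def per_replicate_profiles(nsc: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, biological replicate) summed-NSC profile matrix.

    These are the feature columns used for hierarchical clustering: one column
    per biological isolation of each activation state, technical replicates
    summed.
    """
    _check_design(design)
    d = design.set_index("sample_id")
    key = d.loc[nsc.columns, "condition"] + "." + d.loc[nsc.columns, "bio_rep"].astype(str)
    prof = nsc.T.groupby(key).sum().T
    return prof[sorted(prof.columns)]


def filter_min_count(counts: pd.DataFrame, min_total: int = 4) -> pd.Index:
    """Proteins whose summed spectral count across all samples reaches the
    detection floor (default 4)."""
    return counts.index[counts.sum(axis=1) >= min_total]


def fold_enrichment(
    condition_means: pd.DataFrame,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Fold enrichment (active/inactive) with sentinels for single-state proteins.

    ``fold`` is the mean-NSC ratio when both conditions are positive, and the
    sentinel UNIQUE_ACTIVE / UNIQUE_INACTIVE when exactly one is zero. For
    ``log2fc`` zeros are imputed with ``pseudo`` (default: half the smallest
    non-zero mean in the table) so the log fold change is finite for every
    retained protein.
    """
    act = condition_means["active"]
    inact = condition_means["inactive"]
    both_zero = (act == 0) & (inact == 0)
    if both_zero.any():
        raise ValueError(
            f"proteins with zero mean NSC in both conditions: {list(act.index[both_zero])}"
        )
    if pseudo is None:
        positive = condition_means.to_numpy()[condition_means.to_numpy() > 0]
        pseudo = positive.min() / 2.0
    fold: list[object] = []
    for a, b in zip(act, inact):
        if b == 0:
            fold.append(UNIQUE_ACTIVE)
        elif a == 0:
            fold.append(UNIQUE_INACTIVE)
        else:
            fold.append(a / b)
    log2fc = np.log2(np.maximum(act, pseudo) / np.maximum(inact, pseudo))
    return pd.DataFrame(
        {
            "mean_nsc_active": act,
            "mean_nsc_inactive": inact,
            "fold": fold,
            "log2fc": log2fc,
        },
        index=condition_means.index,
    )


def differential_flags(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Count-based differential abundance flag at a 5% false discovery rate.

    A likelihood-ratio (G) test per protein on spectral counts summed per
    condition, against the null that the protein's counts split between
    conditions in proportion to the conditions' total spectra, followed by
    Benjamini-Hochberg correction across proteins.

    Spectral counts are over-dispersed relative to the Poisson sampling the
    plain G-test assumes, so the G statistics are calibrated by a
    genomic-control factor: the ratio of the genome-wide median G to the
    median of the chi-square(1) reference, floored at 1. The median is robust
    to a minority of truly differential proteins, so calibration restores the
    null error rate without sacrificing power.

    Returns a DataFrame with ``pvalue``, ``qvalue`` and boolean ``significant``.
    """
    _check_design(design)
    d = design.set_index("sample_id")
    lib = {c: d.loc[d["condition"] == c, "total_spectra"].sum() for c in CONDITIONS}
    obs = {}
    for c in CONDITIONS:
        samples = [s for s in counts.columns if d.loc[s, "condition"] == c]
        obs[c] = counts[samples].sum(axis=1).to_numpy(dtype=float)
    o_a, o_i = obs["active"], obs["inactive"]
    n = o_a + o_i
    frac_a = lib["active"] / (lib["active"] + lib["inactive"])
    e_a = n * frac_a
    e_i = n * (1.0 - frac_a)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * (
            np.where(o_a > 0, o_a * np.log(o_a / e_a), 0.0)
            + np.where(o_i > 0, o_i * np.log(o_i / e_i), 0.0)
        )
    g = np.maximum(g, 0.0)
    chi2_median = stats.chi2.ppf(0.5, df=1)
    inflation = max(float(np.median(g[n > 0])) / chi2_median, 1.0) if (n > 0).any() else 1.0
    pvals = stats.chi2.sf(g / inflation, df=1)
    pvals[n == 0] = 1.0
    qvals = stats.false_discovery_control(pvals, method="bh")
    return pd.DataFrame(
        {"pvalue": pvals, "qvalue": qvals, "significant": qvals < alpha},
        index=counts.index,
    )


@dataclass(frozen=True)
class VennSummary:
    n_active_only: int
    n_inactive_only: int
    n_shared: int
    n_total: int
    pct_active_only: int
    pct_inactive_only: int
    pct_shared: int


def venn_summary(active: set, inactive: set) -> VennSummary:
    """Partition of identified proteins by activation state of detection.

    Percentages are of the union, rounded to the nearest integer (halves away
    from zero).
    """
    active, inactive = set(active), set(inactive)
    shared = active & inactive
    union = active | inactive
    n = len(union)
    n_a, n_i, n_s = len(active - inactive), len(inactive - active), len(shared)
    pct = lambda k: round_half_up(100.0 * k / n) if n else 0
    return VennSummary(n_a, n_i, n_s, n, pct(n_a), pct(n_i), pct(n_s))


@dataclass(frozen=True)
class TipSummary:
    n_identified: int
    n_known: int
    pct_of_known: int
    pct_above_threshold: int


def summarize_tips(
    folds: "pd.Series | dict",
    n_known: int,
    threshold: float = 2.0,
) -> TipSummary:
    """Summary of microtubule plus-end tracking protein (+TIP) recruitment.

    Parameters
    ----------
    folds
        Fold enrichment (active/inactive) of each identified +TIP; the
        UNIQUE_ACTIVE sentinel counts as exceeding any finite threshold.
    n_known
        Size of the reference registry of known +TIPs.
    threshold
        Enrichment cut-off; "more than" is strict (fold > threshold).
    """
    if n_known <= 0:
        raise ValueError("empty +TIP registry")
    folds = pd.Series(folds)
    n_id = len(folds)
    above = sum(
        1
        for f in folds
        if f == UNIQUE_ACTIVE or (not isinstance(f, str) and float(f) > threshold)
    )
    return TipSummary(
        n_identified=n_id,
        n_known=n_known,
        pct_of_known=round_half_up(100.0 * n_id / n_known),
        pct_above_threshold=round_half_up(100.0 * above / n_id) if n_id else 0,
    )
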