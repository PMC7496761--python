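"""Model evaluation, maxSSS thresholding, binary transformation and ensemble consensus.

The evaluation backbone of the pipeline:

* AUC via the rank-based Mann–Whitney estimator (ties count one half);
* sensitivity / specificity / TSS (= sensitivity + specificity − 1) at a threshold;
* the maxSSS threshold — the candidate score maximizing training
  sensitivity + specificity, equivalently TSS;
* the replicate exclusion rule (TSS < 0.7 **or** sensitivity = 0);
* binary transformation of continuous suitability and the two-stage consensus:
  replicate binaries are averaged within each model family and re-binarized at
  ≥ 0.5, then the per-family binaries are averaged and re-binarized at ≥ 0.5
  (majority vote with ties counted suitable);
* the species depth mask (skipped for surface phytoplankton).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

#: Replicates scoring below this TSS are excluded from the ensemble.
TSS_EXCLUSION = 0.7


@dataclass
class EvalReport:
    """Evaluation of one fitted replicate on held-out data."""

    auc: float
    sensitivity: float
    specificity: float
    tss: float
    threshold: float
    excluded: bool
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if abs(self.tss - (self.sensitivity + self.specificity - 1.0)) > 1e-12:
            raise ValueError("tss must equal sensitivity + specificity - 1")


def auc(presence_scores: np.ndarray, contrast_scores: np.ndarray) -> float:
    """Probability a random presence outscores a random contrast point (ties = 0.5)."""
    p = np.asarray(presence_scores, dtype=float).ravel()
    c = np.asarray(contrast_scores, dtype=float).ravel()
    if len(p) == 0 or len(c) == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, c]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2.0
    return float(u / (len(p) * len(c)))


def confusion_stats(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """(sensitivity, specificity, TSS) with prediction positive iff score ≥ threshold."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    pred = scores >= threshold
    sens = float(np.mean(pred[labels]))
    spec = float(np.mean(~pred[~labels]))
    return sens, spec, sens + spec - 1.0


def max_sss_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold (from the unique observed scores) maximizing sensitivity + specificity.

    Ties are broken towards the smallest such threshold; the result equals an
    exhaustive scan over all candidates.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    cand = np.unique(scores)
    p_sorted = np.sort(scores[labels])
    c_sorted = np.sort(scores[~labels])
    # sens(t) = P(presence >= t), spec(t) = P(contrast < t)
    sens = 1.0 - np.searchsorted(p_sorted, cand, side="left") / len(p_sorted)
    spec = np.searchsorted(c_sorted, cand, side="left") / len(c_sorted)
    sss = sens + spec
    best = np.flatnonzero(sss >= sss.max() - 1e-12)
    return float(cand[best[0]])


def exclude_replicate(report: EvalReport, rule: str = "or",
                      tss_cutoff: float = TSS_EXCLUSION) -> bool:
    """Exclusion rule: TSS below the cutoff or zero sensitivity.

    ``rule="or"`` (the default reading) excludes on either condition;
    ``rule="and"`` (the stricter conjunctive reading) requires both.
    """
    low_tss = report.tss < tss_cutoff
    zero_sens = report.sensitivity == 0.0
    if rule == "or":
        return low_tss or zero_sens
    if rule == "and":
        return low_tss and zero_sens
    raise ValueError(f"unknown exclusion rule {rule!r}")


def make_report(
    test_presence_scores: np.ndarray,
    test_contrast_scores: np.ndarray,
    threshold: float,
    exclusion_rule: str = "or",
    tss_cutoff: float = TSS_EXCLUSION,
) -> EvalReport:
    """Assemble an EvalReport from held-out scores at a (training-derived) threshold."""
    scores = np.concatenate([test_presence_scores, test_contrast_scores])
    labels = np.concatenate(
        [np.ones(len(test_presence_scores), bool), np.zeros(len(test_contrast_scores), bool)]
    )
    a = auc(test_presence_scores, test_contrast_scores)
    sens, spec, tss = confusion_stats(scores, labels, threshold)
    rep = EvalReport(a, sens, spec, tss, float(threshold), excluded=False)
    rep.excluded = exclude_replicate(rep, exclusion_rule, tss_cutoff)
    if rep.excluded:
        reasons = []
        if rep.tss < tss_cutoff:
            reasons.append(f"tss<{tss_cutoff}")
        if rep.sensitivity == 0.0:
            reasons.append("sensitivity=0")
        rep.exclusion_reason = ",".join(reasons)
    return rep


# ---------------------------------------------------------------------------
# Binary maps and consensus
# ---------------------------------------------------------------------------


def binarize(suitability: np.ndarray, threshold: float, sea_mask: np.ndarray) -> np.ndarray:
    """Suitable (1) iff suitability ≥ threshold, over sea cells; 0 elsewhere."""
    out = np.zeros(suitability.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[sea_mask & (np.nan_to_num(suitability, nan=-np.inf) >= threshold)] = 1
    return out


def consensus(family_binaries: Mapping[str, Sequence[np.ndarray]]) -> np.ndarray:
    """Two-stage majority consensus across replicates, then model families.

    ``family_binaries`` maps family name to the surviving (non-excluded)
    replicate binary maps.  Families with no survivors must already be absent.
    Within each family the replicate binaries are averaged and re-binarized at
    ≥ 0.5; the per-family binaries are then averaged and re-binarized at ≥ 0.5.
    """
    per_family = []
    for family in sorted(family_binaries):
        reps = list(family_binaries[family])
        if not reps:
            continue
        mean = np.mean([np.asarray(r, dtype=float) for r in reps], axis=0)
        per_family.append((mean >= 0.5).astype(np.int8))
    if not per_family:
        raise ValueError("no surviving binary layers to combine")
    overall = np.mean([f.astype(float) for f in per_family], axis=0)
    return (overall >= 0.5).astype(np.int8)


def apply_depth_mask(
    binary: np.ndarray,
    depth: np.ndarray,
    group: str,
    max_depth: float | None,
) -> np.ndarray:
    """Zero suitable cells deeper than the species' maximum depth.

    Phytoplankton (surface organisms) pass through unchanged; every other group
    must provide ``max_depth`` (meters, positive down).
    """
    if group == "phytoplankton":
        return np.asarray(binary, dtype=np.int8).copy()
    if max_depth is None:
        raise ValueError("max_depth required for non-phytoplankton species")
    out = np.asarray(binary, dtype=np.int8).copy()
    with np.errstate(invalid="ignore"):
        out[np.nan_to_num(depth, nan=np.inf) > max_depth] = 0
    return out
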