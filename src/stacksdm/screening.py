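"""Predictor selection: contributions, jackknife, correlation filtering, minimum rule.

The selection protocol applied per species before the final model runs:

1. fit a screening model (the hinge/maxent family) on all candidate predictors
   and estimate each predictor's *relative contribution* as permutation
   importance on training AUC, normalized to sum to 100;
2. drop predictors contributing less than 4%;
3. among the survivors, resolve correlated pairs (|Pearson r| ≥ 0.7, computed
   on a seeded random sample of sea cells) greedily from the highest-|r| pair,
   keeping the member with the higher contribution;
4. if fewer than three predictors survive, restore dropped predictors in
   decreasing contribution order until three remain (three predictors is the
   floor for every model).

A per-predictor jackknife (refit with only / with all-but each predictor,
scored by held-out AUC) is reported alongside, as is a simple shape flag for
each response curve (monotone / unimodal / irregular) — the biological-
plausibility judgment itself is left to the analyst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeding import derive_seed
from .evaluation import auc
from .grid import EnvStack
from .models import ModelSpec, fit, response_curve, sample_background, split_train_test

#: Predictors contributing less than this percentage are dropped.
CONTRIBUTION_THRESHOLD_PCT = 4.0
#: Pairs at or above this |Pearson r| are considered collinear.
CORRELATION_THRESHOLD = 0.7
#: Every model keeps at least this many predictors.
MIN_PREDICTORS = 3


@dataclass
class ScreenReport:
    """Outcome of predictor screening for one species."""

    contributions: dict[str, float]
    correlation: pd.DataFrame
    jackknife: dict[str, tuple[float, float]]
    selected: list[str]
    dropped: dict[str, str]
    response_shape: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.selected) & set(self.dropped):
            raise ValueError("selected and dropped predictors overlap")
        if len(self.selected) < MIN_PREDICTORS:
            raise ValueError(f"fewer than {MIN_PREDICTORS} predictors selected")
        total = sum(self.contributions.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"contributions sum to {total}, expected 100")

    def to_frame(self) -> pd.DataFrame:
        """One row per candidate: contribution, jackknife AUCs, selection status."""
        rows = []
        for name in sorted(self.contributions):
            jk = self.jackknife.get(name, (np.nan, np.nan))
            rows.append({
                "predictor": name,
                "contribution_pct": self.contributions[name],
                "auc_with_only": jk[0],
                "auc_without": jk[1],
                "selected": name in self.selected,
                "drop_reason": self.dropped.get(name, ""),
                "response_shape": self.response_shape.get(name, ""),
            })
        return pd.DataFrame(rows)


def correlation_matrix(
    stack: EnvStack,
    predictors: Sequence[str] | None = None,
    sample_cells: np.ndarray | None = None,
    n_sample: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise Pearson r between predictors over (sampled) sea cells.

    Zero-variance predictors get r = 0 against everything (with a warning);
    the diagonal is always 1.
    """
    names = sorted(predictors) if predictors is not None else stack.names
    if len(names) < 2:
        raise ValueError("need at least 2 predictors")
    if sample_cells is None:
        sea = stack.sea_cells()
        if len(sea) > n_sample:
            rng = np.random.default_rng(seed)
            sea = sea[np.sort(rng.choice(len(sea), size=n_sample, replace=False))]
        sample_cells = sea
    if len(sample_cells) < 3:
        raise ValueError("need at least 3 sample cells")
    X = stack.values_at(sample_cells, names)
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance predictor(s): {[n for n, d in zip(names, degenerate) if d]}; "
            "their correlations are set to 0",
            stacklevel=2,
        )
    Z = np.where(degenerate, 0.0, (X - X.mean(axis=0)) / np.where(degenerate, 1.0, sd))
    R = Z.T @ Z / len(X)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    return pd.DataFrame(R, index=names, columns=names)


def contribution_scores(
    model,
    presences: np.ndarray,
    background: np.ndarray,
    stack: EnvStack,
    predictors: Sequence[str],
    seed: int = 0,
    n_permutations: int = 4,
) -> dict[str, float]:
    """Permutation importance on training AUC, normalized to percentages.

    Each predictor's values over the evaluation cells are shuffled
    ``n_permutations`` times; the mean drop in AUC (floored at zero) is the
    raw importance.  All-zero importances degrade to uniform scores with a
    warning.  ``model`` is any object with ``predict_proba``.
    """
    rng = np.random.default_rng(seed)
    cells = np.vstack([presences, background])
    labels = np.concatenate([np.ones(len(presences)), np.zeros(len(background))]).astype(bool)
    X = stack.values_at(cells, predictors)
    base_scores = model.predict_proba(X)[:, 1]
    base_auc = auc(base_scores[labels], base_scores[~labels])
    raw = np.zeros(len(predictors))
    for j in range(len(predictors)):
        drops = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            s = model.predict_proba(Xp)[:, 1]
            drops.append(base_auc - auc(s[labels], s[~labels]))
        raw[j] = max(0.0, float(np.mean(drops)))
    if raw.sum() == 0:
        warnings.warn("all permutation importances are zero; returning uniform scores",
                      stacklevel=2)
        raw[:] = 1.0
    pct = 100.0 * raw / raw.sum()
    return {name: float(p) for name, p in zip(predictors, pct)}


def jackknife_test(
    presences: np.ndarray,
    background: np.ndarray,
    stack: EnvStack,
    predictors: Sequence[str],
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-predictor (with-only AUC, without AUC) from hinge-model refits.

    Each refit is scored on its held-out split.  A refit that fails on a
    degenerate predictor is recorded as NaN, not fatal.
    """
    if len(predictors) < 2:
        raise ValueError("jackknife needs at least 2 predictors")
    spec = spec or ModelSpec("maxent_hinge", seed=seed)
    out: dict[str, tuple[float, float]] = {}

    def _test_auc(pred_subset: Sequence[str]) -> float:
        rep = fit(spec, presences, background, stack, pred_subset,
                  seed=derive_seed(seed, *pred_subset))
        return rep.report.auc

    for name in predictors:
        try:
            with_only = _test_auc([name])
        except Exception:
            with_only = float("nan")
        others = [p for p in predictors if p != name]
        try:
            without = _test_auc(others)
        except Exception:
            without = float("nan")
        out[name] = (with_only, without)
    return out


def _shape_flag(values: np.ndarray, suit: np.ndarray) -> str:
    """Crude response-curve shape label: monotone, unimodal or irregular."""
    s = np.convolve(suit, np.ones(9) / 9, mode="valid")  # light smoothing
    d = np.diff(s)
    signs = np.sign(d[np.abs(d) > 1e-6 * max(s.max(), 1e-12)])
    if len(signs) == 0:
        return "flat"
    changes = int(np.sum(signs[1:] != signs[:-1]))
    if changes == 0:
        return "monotone"
    if changes == 1 and signs[0] > 0:
        return "unimodal"
    return "irregular"


def apply_selection_rules(
    contributions: dict[str, float],
    corr: pd.DataFrame,
    contribution_threshold: float = CONTRIBUTION_THRESHOLD_PCT,
    correlation_threshold: float = CORRELATION_THRESHOLD,
    min_predictors: int = MIN_PREDICTORS,
) -> tuple[list[str], dict[str, str]]:
    """Pure rule core of the screening protocol.

    1. drop contributions below the threshold;
    2. resolve collinear pairs greedily from the highest |r|, keeping the
       higher-contribution member (ties by name);
    3. if fewer than ``min_predictors`` survive, restore dropped predictors in
       decreasing contribution order — preferring ones that do not reintroduce
       a collinear pair, falling back to collinear ones only if unavoidable
       (the minimum-predictor floor outranks the correlation rule).

    Returns (selected sorted by decreasing contribution, {dropped: reason}).
    """
    candidates = sorted(contributions)
    dropped: dict[str, str] = {}
    surviving = [c for c in candidates if contributions[c] >= contribution_threshold]
    for c in candidates:
        if c not in surviving:
            dropped[c] = "low_contribution"

    def _sort_key(name: str):
        return (contributions[name], name)

    while True:
        flagged = [
            (abs(float(corr.loc[a, b])), a, b)
            for i, a in enumerate(surviving)
            for b in surviving[i + 1:]
            if abs(float(corr.loc[a, b])) >= correlation_threshold
        ]
        if not flagged:
            break
        _, a, b = max(flagged, key=lambda t: (t[0], t[1], t[2]))  # highest |r| first
        loser = min((a, b), key=_sort_key)
        keeper = b if loser == a else a
        surviving.remove(loser)
        dropped[loser] = f"correlated_with:{keeper}"

    if len(surviving) < min_predictors:
        restorable = sorted(dropped, key=lambda n: (-contributions[n], n))

        def _clean(name: str) -> bool:
            return all(
                abs(float(corr.loc[name, s])) < correlation_threshold for s in surviving
            )

        for allow_collinear in (False, True):
            for name in restorable:
                if len(surviving) >= min_predictors:
                    break
                if name in surviving:
                    continue
                if allow_collinear or _clean(name):
                    surviving.append(name)
                    del dropped[name]

    selected = sorted(surviving, key=lambda n: (-contributions[n], n))
    return selected, dropped


def select_predictors(
    candidates: Sequence[str],
    presences: np.ndarray,
    stack: EnvStack,
    seed: int = 0,
    background: np.ndarray | None = None,
    n_background: int = 10_000,
    contribution_threshold: float = CONTRIBUTION_THRESHOLD_PCT,
    correlation_threshold: float = CORRELATION_THRESHOLD,
    min_predictors: int = MIN_PREDICTORS,
    with_jackknife: bool = True,
) -> ScreenReport:
    """Run the full screening protocol for one species.

    Deterministic given seed and inputs; candidate insertion order never
    changes the outcome (candidates are canonicalized by name, rule ties are
    broken by contribution then name).
    """
    candidates = sorted(set(candidates))
    if len(candidates) < min_predictors:
        raise ValueError(
            f"need at least {min_predictors} candidate predictors, got {len(candidates)}"
        )
    if background is None:
        n_bg = min(n_background, int(stack.sea_mask.sum()))
        background = sample_background(stack, n_bg, derive_seed(seed, "screen_bg"))

    spec = ModelSpec("maxent_hinge", seed=derive_seed(seed, "screen_fit"))
    screen_rep = fit(spec, presences, background, stack, candidates,
                     seed=spec.seed, species_id="screen")
    contributions = contribution_scores(
        screen_rep.estimator,
        screen_rep.train_presences, screen_rep.train_contrast,
        stack, candidates, seed=derive_seed(seed, "perm"),
    )
    shapes = {}
    for name in candidates:
        v, s = response_curve(screen_rep, stack, name, n_points=100)
        shapes[name] = _shape_flag(v, s)

    jack = (
        jackknife_test(presences, background, stack, candidates,
                       seed=derive_seed(seed, "jack"))
        if with_jackknife else {}
    )

    corr = correlation_matrix(stack, candidates, seed=derive_seed(seed, "corr"))
    selected, dropped = apply_selection_rules(
        contributions, corr, contribution_threshold, correlation_threshold, min_predictors
    )
    return ScreenReport(
        contributions=contributions,
        correlation=corr,
        jackknife=jack,
        selected=selected,
        dropped=dropped,
        response_shape=shapes,
    )
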