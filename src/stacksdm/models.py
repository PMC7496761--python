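"""Habitat-suitability model families, background/pseudo-absence sampling and replicate runs.

Five model families are available, mirroring the usual presence-background /
presence-absence ensemble:

``maxent_hinge``
    The in-house core: L1-penalized logistic discrimination of presence cells
    against *background* cells on hinge features (the standard equivalence for
    maximum-entropy presence-background fitting).  Hinge features are forward
    and reverse ramps anchored at training-decile knots, plus a rescaled linear
    term, all in [0, 1].
``linear_logistic``
    Logistic regression with quadratic terms (GLM analogue).
``additive_spline``
    Cubic B-spline basis per predictor + logistic link (GAM analogue).
``bagged_trees``
    Random forest (100 trees, √p features per split).
``neural_1layer``
    Single-hidden-layer perceptron (8 units, early stopping).

All non-maxent families contrast presences against *pseudo-absences* (random
sea cells excluding presence cells); maxent uses plain background (presence
cells not excluded).  Each species × family is run as five replicates with
independent 70/30 train/test splits; each replicate carries its own held-out
evaluation and its own training-maxSSS binarization threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler

from ._seeding import derive_seed
from .evaluation import EvalReport, make_report, max_sss_threshold
from .grid import EnvStack, Layer

FAMILIES: tuple[str, ...] = (
    "maxent_hinge",
    "linear_logistic",
    "additive_spline",
    "bagged_trees",
    "neural_1layer",
)

#: Families contrasting presences with pseudo-absences rather than background.
PSEUDO_ABSENCE_FAMILIES = frozenset(FAMILIES) - {"maxent_hinge"}


@dataclass
class ModelSpec:
    """Configuration of one model family run."""

    family: str
    hyperparams: dict = field(default_factory=dict)
    n_background: int = 10_000
    n_replicates: int = 5
    train_fraction: float = 0.7
    seed: int = 0
    exclusion_rule: str = "or"  # "or" | "and": how TSS and sensitivity combine
    tss_cutoff: float = 0.7

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# Cell sampling and splitting
# ---------------------------------------------------------------------------


def _check_n(stack: EnvStack, n: int) -> np.ndarray:
    sea = stack.sea_cells()
    if n > len(sea):
        raise ValueError(f"requested {n} cells but stack has only {len(sea)} sea cells")
    return sea


def sample_background(stack: EnvStack, n: int = 10_000, seed: int = 0) -> np.ndarray:
    """Uniform random sea cells without replacement; presence cells NOT excluded."""
    sea = _check_n(stack, n)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sea), size=n, replace=False)
    return sea[np.sort(idx)]


def sample_pseudo_absences(
    stack: EnvStack, presences: np.ndarray, n: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Uniform random sea cells without replacement, excluding presence cells."""
    sea = stack.sea_cells()
    presences = np.asarray(presences, dtype=int).reshape(-1, 2)
    flat_sea = sea[:, 0] * stack.grid.n_cols + sea[:, 1]
    flat_pres = presences[:, 0] * stack.grid.n_cols + presences[:, 1]
    eligible = sea[~np.isin(flat_sea, flat_pres)]
    if n > len(eligible):
        raise ValueError(
            f"requested {n} pseudo-absences but only {len(eligible)} non-presence sea cells"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return eligible[np.sort(idx)]


def split_train_test(
    cells: np.ndarray, fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive split with |train| = round(fraction · n)."""
    cells = np.asarray(cells)
    n = len(cells)
    if n < 2:
        raise ValueError("need at least 2 cells to split")
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"split would leave an empty side (n={n}, fraction={fraction})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return cells[np.sort(perm[:n_train])], cells[np.sort(perm[n_train:])]


# ---------------------------------------------------------------------------
# Hinge features
# ---------------------------------------------------------------------------


class HingeBasis:
    """Per-predictor hinge feature expansion anchored on training deciles.

    For predictor values in training range [lo, hi] and knots t: features are
    the rescaled linear term (x−lo)/(hi−lo), forward hinges
    clip((x−t)/(hi−t), 0, 1) and reverse hinges clip((t−x)/(t−lo), 0, 1) —
    all in [0, 1].  Predictors with a degenerate training range (hi = lo)
    contribute a constant zero column and are flagged.
    """

    def __init__(self, n_knots: int = 9):
        self.n_knots = n_knots
        self.lo_: np.ndarray | None = None
        self.hi_: np.ndarray | None = None
        self.knots_: list[np.ndarray] = []
        self.degenerate_: list[int] = []

    def fit(self, X: np.ndarray) -> "HingeBasis":
        X = np.asarray(X, dtype=float)
        self.lo_ = X.min(axis=0)
        self.hi_ = X.max(axis=0)
        qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
        self.knots_ = []
        self.degenerate_ = []
        for j in range(X.shape[1]):
            if self.hi_[j] <= self.lo_[j]:
                self.degenerate_.append(j)
                self.knots_.append(np.empty(0))
            else:
                self.knots_.append(np.unique(np.quantile(X[:, j], qs)))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.lo_ is None:
            raise RuntimeError("basis not fitted")
        X = np.asarray(X, dtype=float)
        cols = []
        for j in range(X.shape[1]):
            lo, hi = self.lo_[j], self.hi_[j]
            if j in self.degenerate_:
                cols.append(np.zeros((len(X), 1)))
                continue
            x = X[:, j]
            cols.append(np.clip((x - lo) / (hi - lo), 0, 1)[:, None])
            for t in self.knots_[j]:
                if hi > t:
                    cols.append(np.clip((x - t) / (hi - t), 0, 1)[:, None])
                if t > lo:
                    cols.append(np.clip((t - x) / (t - lo), 0, 1)[:, None])
        return np.hstack(cols)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def hinge_features(x: np.ndarray, knots: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Hinge expansion of a single predictor (linear + forward + reverse hinges)."""
    x = np.asarray(x, dtype=float)
    if hi <= lo:
        return np.zeros((len(x), 1))
    cols = [np.clip((x - lo) / (hi - lo), 0, 1)]
    for t in np.asarray(knots, dtype=float):
        if hi > t:
            cols.append(np.clip((x - t) / (hi - t), 0, 1))
        if t > lo:
            cols.append(np.clip((t - x) / (t - lo), 0, 1))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


class _MaxentHinge:
    """L1-penalized logistic presence-vs-background model on hinge features."""

    def __init__(self, n_knots: int = 9, lam_scale: float = 0.02, tol: float = 1e-5):
        self.n_knots = n_knots
        self.lam_scale = lam_scale
        self.tol = tol

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_MaxentHinge":
        self.basis_ = HingeBasis(self.n_knots).fit(X)
        F = self.basis_.transform(X)
        n_presence = int(y.sum())
        lam = self.lam_scale * np.sqrt(F.shape[1] / max(n_presence, 1))
        # sklearn minimizes ||w||_1 + C * sum(loss): per-sample penalty lam => C = 1/(lam n)
        C = 1.0 / (lam * len(X))
        self.clf_ = LogisticRegression(
            l1_ratio=1, C=C, solver="liblinear", tol=self.tol,
            class_weight="balanced", max_iter=2000, random_state=0,
        ).fit(F, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.clf_.predict_proba(self.basis_.transform(X))


def _build_estimator(family: str, hp: dict, seed: int):
    if family == "maxent_hinge":
        return _MaxentHinge(
            n_knots=hp.get("n_knots", 9),
            lam_scale=hp.get("lam_scale", 0.05),
            tol=hp.get("tol", 1e-5),
        )
    if family == "linear_logistic":
        return Pipeline([
            ("scale", StandardScaler()),
            ("quad", PolynomialFeatures(degree=hp.get("degree", 2), include_bias=False)),
            ("clf", LogisticRegression(max_iter=1000, class_weight="balanced",
                                       C=hp.get("C", 1.0))),
        ])
    if family == "additive_spline":
        return Pipeline([
            ("spline", SplineTransformer(n_knots=hp.get("n_knots", 6),
                                         degree=hp.get("degree", 3))),
            ("clf", LogisticRegression(max_iter=1000, class_weight="balanced",
                                       C=hp.get("C", 1.0))),
        ])
    if family == "bagged_trees":
        # oob_score=True: the maxSSS threshold for trees is computed from
        # out-of-bag scores, since refit training scores are degenerate 0/1.
        # no class_weight: maxSSS thresholding is prevalence-insensitive, and
        # balanced weights corrupt the OOB aggregation in current scikit-learn
        return RandomForestClassifier(
            n_estimators=hp.get("n_trees", 100),
            max_features=hp.get("max_features", "sqrt"),
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
    if family == "neural_1layer":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", MLPClassifier(
                hidden_layer_sizes=(hp.get("hidden_units", 8),),
                max_iter=hp.get("epochs", 500),
                early_stopping=True,
                n_iter_no_change=20,
                random_state=seed,
            )),
        ])
    raise ValueError(f"unknown family {family!r}")


def _row_major_sort(cells: np.ndarray, n_cols: int) -> np.ndarray:
    cells = np.asarray(cells, dtype=int).reshape(-1, 2)
    order = np.argsort(cells[:, 0] * n_cols + cells[:, 1], kind="stable")
    return cells[order]


@dataclass
class FittedReplicate:
    """One fitted replicate: model, split, threshold and held-out evaluation.

    Suitability surfaces for any scenario stack are produced on demand with
    :meth:`predict_layer`; :meth:`binary_map` applies the replicate's own
    training-maxSSS threshold (the present-fitted threshold is reused for
    future scenarios — fitted models are projected, not re-thresholded).
    """

    spec: ModelSpec
    species_id: str
    replicate_id: int
    predictors: tuple[str, ...]
    estimator: object
    train_presences: np.ndarray
    test_presences: np.ndarray
    train_contrast: np.ndarray
    test_contrast: np.ndarray
    threshold: float
    report: EvalReport

    def predict_cells(self, stack: EnvStack, cells: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] at the given (row, col) cells."""
        X = stack.values_at(cells, self.predictors)
        return self.estimator.predict_proba(X)[:, 1]

    def predict_layer(self, stack: EnvStack) -> Layer:
        """Suitability over all sea cells; NaN on land."""
        sea = stack.sea_cells()
        vals = np.full(stack.grid.shape, np.nan)
        vals[sea[:, 0], sea[:, 1]] = self.predict_cells(stack, sea)
        return Layer(stack.grid, np.where(stack.sea_mask, vals, np.nan), ~stack.sea_mask)

    def binary_map(self, stack: EnvStack) -> np.ndarray:
        from .evaluation import binarize

        sea = stack.sea_cells()
        vals = np.zeros(stack.grid.shape)
        vals[sea[:, 0], sea[:, 1]] = self.predict_cells(stack, sea)
        return binarize(np.where(stack.sea_mask, vals, np.nan), self.threshold, stack.sea_mask)


def fit(
    spec: ModelSpec,
    presences: np.ndarray,
    contrast_cells: np.ndarray,
    stack: EnvStack,
    predictors: Sequence[str],
    seed: int | None = None,
    species_id: str = "species",
    replicate_id: int = 0,
) -> FittedReplicate:
    """Fit one replicate: 70/30 splits, training fit, training-maxSSS threshold,
    held-out evaluation.

    ``contrast_cells`` is the family's contrast sample — background for
    ``maxent_hinge``, pseudo-absences for the presence/absence families.  Cell
    ordering is canonicalized internally, so results are invariant to the order
    in which contrast cells are supplied.
    """
    presences = np.asarray(presences, dtype=int).reshape(-1, 2)
    if len(presences) < 10:
        raise ValueError(f"{species_id}: need >= 10 presence cells, got {len(presences)}")
    seed = spec.seed if seed is None else seed
    n_cols = stack.grid.n_cols
    presences = _row_major_sort(presences, n_cols)
    contrast_cells = _row_major_sort(contrast_cells, n_cols)

    p_train, p_test = split_train_test(presences, spec.train_fraction, derive_seed(seed, "p"))
    c_train, c_test = split_train_test(contrast_cells, spec.train_fraction, derive_seed(seed, "c"))

    Xp_train = stack.values_at(p_train, predictors)
    Xc_train = stack.values_at(c_train, predictors)
    if spec.family == "neural_1layer" and len(p_train) < len(c_train):
        # the net supports neither class nor sample weights, and its
        # accuracy-based early stopping stalls at the majority plateau under
        # heavy imbalance — oversample presences to parity for training only
        ratio = len(c_train) // len(p_train)
        Xp_fit = np.repeat(Xp_train, ratio, axis=0)
    else:
        Xp_fit = Xp_train
    X = np.vstack([Xp_fit, Xc_train])
    y = np.concatenate([np.ones(len(Xp_fit)), np.zeros(len(c_train))])
    est = _build_estimator(spec.family, spec.hyperparams, derive_seed(seed, "est"))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        est.fit(X, y)

    rep = FittedReplicate(
        spec=spec,
        species_id=species_id,
        replicate_id=replicate_id,
        predictors=tuple(predictors),
        estimator=est,
        train_presences=p_train,
        test_presences=p_test,
        train_contrast=c_train,
        test_contrast=c_test,
        threshold=np.nan,
        report=None,  # type: ignore[arg-type]
    )
    # threshold on TRAINING data, evaluation on TEST data; bagged trees use
    # out-of-bag training scores because their refit scores are degenerate 0/1
    train_labels = np.concatenate([np.ones(len(p_train), bool), np.zeros(len(c_train), bool)])
    if hasattr(est, "oob_decision_function_"):
        train_scores = est.oob_decision_function_[:, 1]
        ok = np.isfinite(train_scores)
        train_scores, train_labels = train_scores[ok], train_labels[ok]
    else:
        train_scores = np.concatenate([
            rep.predict_cells(stack, p_train), rep.predict_cells(stack, c_train)
        ])
    rep.threshold = max_sss_threshold(train_scores, train_labels)
    rep.report = make_report(
        rep.predict_cells(stack, p_test),
        rep.predict_cells(stack, c_test),
        rep.threshold,
        exclusion_rule=spec.exclusion_rule,
        tss_cutoff=spec.tss_cutoff,
    )
    return rep


def run_replicates(
    spec: ModelSpec,
    presences: np.ndarray,
    stack: EnvStack,
    predictors: Sequence[str],
    species_id: str = "species",
) -> tuple[list[FittedReplicate], list[tuple[int, str]]]:
    """Run ``spec.n_replicates`` independent replicates for one species × family.

    Each replicate draws its own contrast sample and its own 70/30 splits from
    a seed derived stably from (master seed, species, family, replicate).
    Failed replicates are recorded and skipped, not fatal; the caller must flag
    the species if no replicate survives.
    """
    fitted: list[FittedReplicate] = []
    failures: list[tuple[int, str]] = []
    for r in range(spec.n_replicates):
        rep_seed = derive_seed(spec.seed, species_id, spec.family, r)
        try:
            if spec.family in PSEUDO_ABSENCE_FAMILIES:
                contrast = sample_pseudo_absences(
                    stack, presences, spec.n_background, derive_seed(rep_seed, "contrast")
                )
            else:
                contrast = sample_background(
                    stack, spec.n_background, derive_seed(rep_seed, "contrast")
                )
            fitted.append(
                fit(spec, presences, contrast, stack, predictors,
                    seed=rep_seed, species_id=species_id, replicate_id=r)
            )
        except Exception as exc:  # noqa: BLE001 — replicate failures are data, not bugs
            failures.append((r, f"{type(exc).__name__}: {exc}"))
    return fitted, failures


def response_curve(
    rep: FittedReplicate,
    stack: EnvStack,
    predictor: str,
    n_points: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal response: vary one predictor over its training range, hold the
    others at training-presence medians.  Returns (values, suitability)."""
    if predictor not in rep.predictors:
        raise KeyError(f"{predictor!r} not among fitted predictors {rep.predictors}")
    j = rep.predictors.index(predictor)
    Xp = stack.values_at(rep.train_presences, rep.predictors)
    med = np.median(Xp, axis=0)
    Xc = stack.values_at(rep.train_contrast, rep.predictors)
    lo = min(Xp[:, j].min(), Xc[:, j].min())
    hi = max(Xp[:, j].max(), Xc[:, j].max())
    grid_vals = np.linspace(lo, hi, n_points)
    X = np.tile(med, (n_points, 1))
    X[:, j] = grid_vals
    return grid_vals, rep.estimator.predict_proba(X)[:, 1]
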