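"""From-scratch OPLS-DA for two-class marker panels.

Orthogonal projections to latent structures discriminant analysis (OPLS-DA)
splits the variation of a standardized marker matrix X into a single
component predictive of the class response y and ``k_ortho`` components
orthogonal to it.  With y the centered ±1 class dummy, one NIPALS-style
round computes

    w  ∝ Xᵀy            (predictive weight, unit norm)
    t  = X w            (predictive score)
    p  = Xᵀt / tᵀt      (loading)
    w_o ∝ p − (wᵀp) w   (orthogonal weight)
    t_o = X w_o,  p_o = Xᵀ t_o / t_oᵀ t_o
    X  ← X − t_o p_oᵀ   (deflation)

after which the final predictive component is fit on the deflated matrix.
The per-marker coefficients b satisfy t = X b on the original standardized
matrix: these are the published "constants" (α, β, γ for a three-marker
panel) of the predictive-value equation, and t is the predictive value with
its natural cutoff at 0.

Model quality is the explained variation R²Y on the fitting data and the
predictive ability Q² from stratified 7-fold cross-validation in which the
standardization is refit inside each training fold (no leakage); their
significance comes from a 100-permutation test that reruns the whole
pipeline under shuffled class labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import IntensityMatrix, SampleMetadata, ValidationError

__all__ = [
    "StandardizedMatrix",
    "OplsdaModel",
    "PermutationResult",
    "standardize",
    "encode_labels",
    "fit_oplsda",
    "r2y_score",
    "q2_cv",
    "permutation_test",
    "fit_marker_model",
]

_EPS = 1e-12


@dataclass
class StandardizedMatrix:
    """Column-wise z-scored matrix with the fitting-cohort stats retained."""

    values: np.ndarray
    column_ids: list[str]
    means: np.ndarray
    sds: np.ndarray

    def transform(self, raw: np.ndarray, column_ids: Sequence[str]) -> np.ndarray:
        """Standardize new samples with the stored stats (never refit)."""
        if list(column_ids) != self.column_ids:
            raise ValidationError("column mismatch with fitting cohort stats")
        raw = np.asarray(raw, dtype=float)
        return (raw - self.means) / self.sds


def standardize(
    raw: np.ndarray,
    column_ids: Sequence[str],
    fit_stats: StandardizedMatrix | None = None,
) -> StandardizedMatrix:
    """Z-score columns; with ``fit_stats`` given, apply its stats instead.

    Standardization puts markers whose absolute intensities differ by orders
    of magnitude on one scale before the latent-variable fit.  A
    zero-variance column cannot be scaled and is an error naming the
    metabolite.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValidationError("expected a 2-D matrix")
    if np.isnan(raw).any():
        raise ValidationError("standardize requires complete data")
    if fit_stats is not None:
        values = fit_stats.transform(raw, column_ids)
        return StandardizedMatrix(values, list(column_ids), fit_stats.means, fit_stats.sds)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds <= _EPS)
    if dead.size:
        names = [list(column_ids)[j] for j in dead]
        raise ValidationError(f"zero-variance columns cannot be standardized: {names}")
    return StandardizedMatrix((raw - means) / sds, list(column_ids), means, sds)


def encode_labels(groups: Sequence[str]) -> np.ndarray:
    """Centered ±1 dummy: case → +1, control → −1, then mean-centered."""
    y = np.array([1.0 if g == "case" else -1.0 for g in groups])
    if np.unique(y).size < 2:
        raise ValidationError("both classes must be present")
    return y - y.mean()


@dataclass
class OplsdaModel:
    marker_ids: list[str]
    weights: np.ndarray  # predictive weight w, unit norm
    loadings: np.ndarray  # predictive loading p
    ortho_weights: np.ndarray  # (k, p)
    ortho_loadings: np.ndarray  # (k, p)
    response_loading: float  # q > 0 by sign convention
    coefficients: np.ndarray  # b with t = X b on the original X
    scores: np.ndarray  # predictive scores t of the fitting cohort
    ortho_scores: np.ndarray  # (k, n)
    r2y: float
    k_ortho: int  # orthogonal components actually extracted
    stats: StandardizedMatrix | None = None  # standardization of the fit
    q2: float | None = None
    cv_folds: int | None = None
    seed: int | None = None
    permutation: "PermutationResult | None" = None

    def predict_scores(self, X_std: np.ndarray) -> np.ndarray:
        """Predictive scores for already-standardized rows."""
        return np.asarray(X_std, dtype=float) @ self.coefficients


@dataclass
class PermutationResult:
    observed_r2y: float
    observed_q2: float
    permuted: list[tuple[float, float]]  # (r2y, q2) per permutation
    p_q2: float


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-magnitude entry positive."""
    j = int(np.argmax(np.abs(v)))
    return -v if v[j] < 0 else v


def fit_oplsda(
    X: StandardizedMatrix | np.ndarray,
    y: np.ndarray,
    k_ortho: int = 1,
    marker_ids: Sequence[str] | None = None,
) -> OplsdaModel:
    """Fit one predictive plus up to ``k_ortho`` orthogonal components.

    With ``k_ortho=0`` this reduces exactly to single-component PLS1.  The
    sign indeterminacy of the latent vectors is resolved by forcing the
    response loading q positive, so case scores come out positive.  If the
    data hold fewer orthogonal directions than requested (loading already
    collinear with w), extraction stops early and ``model.k_ortho`` records
    the count actually used.
    """
    if isinstance(X, StandardizedMatrix):
        stats_obj = X
        Xv = X.values.copy()
        ids = list(X.column_ids)
    else:
        stats_obj = None
        Xv = np.asarray(X, dtype=float).copy()
        ids = list(marker_ids) if marker_ids is not None else [
            f"m{j}" for j in range(Xv.shape[1])
        ]
    y = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if y.shape != (n,):
        raise ValidationError("y length must match the number of rows")
    if np.allclose(y, y[0]):
        raise ValidationError("degenerate response: only one class present")
    if k_ortho < 0 or n <= k_ortho + 1:
        raise ValidationError("need n > k_ortho + 1 samples")

    X0 = Xv.copy()
    ortho_w: list[np.ndarray] = []
    ortho_p: list[np.ndarray] = []
    ortho_t: list[np.ndarray] = []
    for _ in range(k_ortho):
        w = Xv.T @ y
        nw = np.linalg.norm(w)
        if nw <= _EPS:
            break
        w /= nw
        t = Xv @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        pl = Xv.T @ t / tt
        wo = pl - float(w @ pl) * w
        if np.linalg.norm(wo) <= 1e-10 * max(np.linalg.norm(pl), 1.0):
            break  # no orthogonal variation left
        wo = _fix_sign(wo / np.linalg.norm(wo))
        to = Xv @ wo
        toto = float(to @ to)
        if toto <= _EPS:
            break
        po = Xv.T @ to / toto
        Xv = Xv - np.outer(to, po)
        ortho_w.append(wo)
        ortho_p.append(po)
        ortho_t.append(to)

    w = Xv.T @ y
    nw = np.linalg.norm(w)
    if nw <= _EPS:
        raise ValidationError("response is uncorrelated with every column")
    w /= nw
    t = Xv @ w
    tt = float(t @ t)
    if tt <= _EPS:
        raise ValidationError("degenerate predictive component")
    q = float(y @ t) / tt
    if q < 0:  # sign convention: case class scores positive
        w, t, q = -w, -t, -q
    pl = Xv.T @ t / tt

    # Coefficients on the original standardized matrix: t = X0 b.
    B = np.eye(p)
    for wo, po in zip(ortho_w, ortho_p):
        B = B @ (np.eye(p) - np.outer(wo, po))
    b = B @ w

    y_hat = t * q
    ss_tot = float(y @ y)
    r2y = 1.0 - float((y - y_hat) @ (y - y_hat)) / ss_tot

    return OplsdaModel(
        marker_ids=ids,
        weights=w,
        loadings=pl,
        ortho_weights=np.array(ortho_w).reshape(len(ortho_w), p),
        ortho_loadings=np.array(ortho_p).reshape(len(ortho_p), p),
        response_loading=q,
        coefficients=b,
        scores=t,
        ortho_scores=np.array(ortho_t).reshape(len(ortho_t), n),
        r2y=r2y,
        k_ortho=len(ortho_w),
        stats=stats_obj,
    )


def r2y_score(model: OplsdaModel, X_std: np.ndarray, y: np.ndarray) -> float:
    """Explained variation 1 − SS_res/SS_tot of ŷ = t·q on given data."""
    y = np.asarray(y, dtype=float)
    y_hat = model.predict_scores(X_std) * model.response_loading
    return 1.0 - float((y - y_hat) @ (y - y_hat)) / float(y @ y)


def _fold_assignment(
    groups: Sequence[str], sample_ids: Sequence[str], folds: int, seed: int
) -> np.ndarray:
    """Class-stratified fold labels; seeded shuffle of lexicographically
    sorted sample ids, dealt round-robin, for run-to-run reproducibility."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(groups), dtype=int)
    for cls in ("case", "control"):
        idx = [i for i in range(len(groups)) if groups[i] == cls]
        idx.sort(key=lambda i: sample_ids[i])
        idx = [idx[k] for k in rng.permutation(len(idx))]
        for pos, i in enumerate(idx):
            assignment[i] = pos % folds
    return assignment


def q2_cv(
    raw: np.ndarray,
    groups: Sequence[str],
    sample_ids: Sequence[str],
    marker_ids: Sequence[str],
    k_ortho: int = 1,
    folds: int = 7,
    seed: int = 0,
) -> float:
    """Cross-validated predictive ability Q² = 1 − PRESS/SS_tot.

    Standardization and the OPLS-DA fit are both redone inside every
    training fold; held-out samples are transformed with the training
    fold's stats and predicted with its model.  Folds are stratified by
    class, so each training fold keeps both classes.
    """
    raw = np.asarray(raw, dtype=float)
    if folds < 2:
        raise ValidationError("need at least 2 folds")
    groups = list(groups)
    assignment = _fold_assignment(groups, sample_ids, folds, seed)

    y_pm = np.array([1.0 if g == "case" else -1.0 for g in groups])
    ss_tot = float(np.sum((y_pm - y_pm.mean()) ** 2))
    press = 0.0
    for f in range(folds):
        test = assignment == f
        train = ~test
        if not test.any():
            continue
        train_groups = [g for g, tr in zip(groups, train) if tr]
        if len(set(train_groups)) < 2:
            raise ValidationError(f"fold {f}: training data lost a class")
        stats_f = standardize(raw[train], marker_ids)
        y_train = y_pm[train]
        y_center = y_train.mean()
        model = fit_oplsda(stats_f, y_train - y_center, k_ortho=k_ortho)
        X_test = stats_f.transform(raw[test], marker_ids)
        y_hat = model.predict_scores(X_test) * model.response_loading
        resid = (y_pm[test] - y_center) - y_hat
        press += float(resid @ resid)
    return 1.0 - press / ss_tot


def permutation_test(
    raw: np.ndarray,
    groups: Sequence[str],
    sample_ids: Sequence[str],
    marker_ids: Sequence[str],
    k_ortho: int = 1,
    folds: int = 7,
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Permutation null for R²Y and Q² with the +1-smoothed p-value.

    Class labels are shuffled uniformly; the whole pipeline (standardize,
    fit, stratified CV) is recomputed for every permutation.  The p-value
    for Q² is (1 + #{permuted Q² ≥ observed Q²}) / (n_perm + 1), so it can
    never be exactly zero; its floor at n_perm=100 is 1/101.
    """
    if n_perm < 1:
        raise ValidationError("need at least one permutation")
    raw = np.asarray(raw, dtype=float)
    groups = list(groups)
    rng = np.random.default_rng(seed)

    def _pipeline(perm_groups: list[str], cv_seed: int) -> tuple[float, float]:
        stats_full = standardize(raw, marker_ids)
        y = encode_labels(perm_groups)
        model = fit_oplsda(stats_full, y, k_ortho=k_ortho)
        q2 = q2_cv(raw, perm_groups, sample_ids, marker_ids, k_ortho, folds, cv_seed)
        return model.r2y, q2

    obs_r2y, obs_q2 = _pipeline(groups, seed)
    permuted: list[tuple[float, float]] = []
    for _ in range(n_perm):
        perm = [groups[i] for i in rng.permutation(len(groups))]
        cv_seed = int(rng.integers(0, 2**31 - 1))
        try:
            permuted.append(_pipeline(perm, cv_seed))
        except ValidationError:
            # a pathological shuffle (e.g. a fold losing a class at tiny n)
            permuted.append((float("nan"), float("-inf")))
    n_ge = sum(1 for _, q in permuted if q >= obs_q2)
    p_q2 = (1 + n_ge) / (n_perm + 1)
    return PermutationResult(obs_r2y, obs_q2, permuted, p_q2)


def fit_marker_model(
    matrix: IntensityMatrix,
    metadata: Sequence[SampleMetadata],
    marker_ids: Sequence[str],
    k_ortho: int = 1,
    folds: int = 7,
    n_perm: int = 0,
    seed: int = 0,
) -> OplsdaModel:
    """Standardize the marker columns, fit OPLS-DA, attach Q² (and the
    permutation test when ``n_perm`` > 0).

    Only pretreatment samples (one per subject) enter the fit; the returned
    model carries the frozen standardization stats for scoring new samples.
    """
    from .screening import pretreatment_split  # local import avoids a cycle

    if not matrix.normalized:
        raise ValidationError("fit requires an osmolality-normalized matrix")
    cases, controls = pretreatment_split(matrix, metadata)
    sample_ids = cases + controls
    sub = matrix.subset(sample_ids=sample_ids, metabolite_ids=marker_ids)
    groups = ["case"] * len(cases) + ["control"] * len(controls)

    stats_obj = standardize(sub.values, marker_ids)
    y = encode_labels(groups)
    model = fit_oplsda(stats_obj, y, k_ortho=k_ortho)
    model.q2 = q2_cv(sub.values, groups, sample_ids, marker_ids, k_ortho, folds, seed)
    model.cv_folds = folds
    model.seed = seed
    if n_perm > 0:
        model.permutation = permutation_test(
            sub.values, groups, sample_ids, marker_ids, k_ortho, folds, n_perm, seed
        )
    return model
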