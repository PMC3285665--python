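"""Stepwise linear discriminant analysis of fold-change profiles.

This module implements the classical stepwise-discriminant machinery used
to pick a minimal probe panel that separates the 9 tissue-of-origin classes
and to score new profiles:

* **Wilks' lambda** — Lambda = det(W) / det(T), with W the pooled
  within-class scatter and T the total scatter on the candidate feature
  subset.  Small Lambda means strong separation.
* **Partial F** — the F-to-enter/F-to-remove statistic
  ``F = ((n - g - q + 1) / (g - 1)) * (Lambda_before / Lambda_after - 1)``
  with df (g - 1, n - g - q + 1), where q is the subset size after the
  addition; the first variable's F-to-enter reduces to the one-way ANOVA F.
* **Forward stepwise selection** with alpha-to-enter and alpha-to-remove
  (both 0.150 by default), deterministic tie-breaking, and degrees-of-
  freedom and conditioning guards.
* **Classification score functions** — per class k,
  ``c_k(x) = mu_k' S^-1 x - 1/2 mu_k' S^-1 mu_k + ln pi_k`` with
  S = W / (n - g); the predicted class maximizes c_k.
* **Jackknifed (leave-one-out) classification** — each sample is classified
  by score functions refitted without it (feature set held fixed), yielding
  the true-by-predicted classification matrix and % correct.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("phenoscreen")

_LAMBDA_FLOOR = 1e-12      # clamp for numerically-zero Lambda inside stepwise
DEFAULT_COND_LIMIT = 1e10  # refuse entries that make cond(W) exceed this


# ---------------------------------------------------------------------------
# Wilks' lambda and the partial F test
# ---------------------------------------------------------------------------

def _scatter(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc


def _group_split(X: np.ndarray, y: np.ndarray):
    classes = np.unique(y)
    return classes, [X[y == c] for c in classes]


def within_total_scatter(X, y, subset: Sequence[int] | None = None):
    """Pooled within-class scatter W and total scatter T on a feature subset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("feature subset must be non-empty")
        X = X[:, list(subset)]
    classes, groups = _group_split(X, y)
    if X.shape[0] <= len(classes):
        raise ValueError("need more samples than classes")
    W = sum(_scatter(G) for G in groups)
    T = _scatter(X)
    return np.atleast_2d(W), np.atleast_2d(T)


def wilks_lambda(X, y, subset: Sequence[int] | None = None) -> float:
    """Wilks' Lambda = det(W)/det(T) on the selected features, in [0, 1].

    Zero within-class scatter gives Lambda = 0 exactly; a singular total
    scatter (no information at all in the subset) is an error.
    """
    W, T = within_total_scatter(X, y, subset)
    det_t = float(np.linalg.det(T))
    if not np.isfinite(det_t) or det_t <= 0.0:
        raise ValueError("degenerate feature subset: singular total scatter")
    det_w = float(np.linalg.det(W))
    return float(np.clip(det_w / det_t, 0.0, 1.0))


def partial_F(lambda_before: float, lambda_after: float, n: int, g: int,
              q: int) -> tuple[float, float]:
    """F statistic and upper-tail p for the change in Wilks' Lambda when one
    variable is added (q = subset size after the addition).

    ``F = ((n - g - q + 1)/(g - 1)) * (lambda_before/lambda_after - 1)``
    on (g - 1, n - g - q + 1) degrees of freedom.
    """
    if not (0.0 < lambda_after <= lambda_before * (1 + 1e-12) and
            lambda_before <= 1.0 + 1e-12):
        raise ValueError("need 0 < lambda_after <= lambda_before <= 1")
    if g < 2:
        raise ValueError("need at least two classes")
    df2 = n - g - q + 1
    if df2 <= 0:
        raise ValueError("insufficient residual degrees of freedom")
    ratio = max(lambda_before / lambda_after - 1.0, 0.0)
    F = df2 / (g - 1) * ratio
    p = float(stats.f.sf(F, g - 1, df2))
    return float(F), p


# ---------------------------------------------------------------------------
# forward stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseStep:
    feature: int
    action: str                # "enter" | "remove"
    wilks: float
    F: float
    p: float


@dataclass
class StepwiseResult:
    selected: list[int]
    steps: list[StepwiseStep]
    alpha_enter: float
    alpha_remove: float

    def trace_frame(self, feature_names: Sequence[str] | None = None
                    ) -> pd.DataFrame:
        rows = [{"feature": (feature_names[s.feature] if feature_names
                             else s.feature),
                 "action": s.action, "wilks_lambda": s.wilks,
                 "F": s.F, "p": s.p} for s in self.steps]
        return pd.DataFrame(rows,
                            columns=["feature", "action", "wilks_lambda",
                                     "F", "p"])


def _safe_partial_F(lam_before: float, lam_after: float, n: int, g: int,
                    q: int) -> tuple[float, float]:
    lb = float(np.clip(lam_before, _LAMBDA_FLOOR, 1.0))
    la = float(np.clip(lam_after, _LAMBDA_FLOOR, lb))
    return partial_F(lb, la, n, g, q)


def forward_stepwise_select(X, y, alpha_enter: float = 0.150,
                            alpha_remove: float = 0.150,
                            max_features: int | None = None,
                            cond_limit: float = DEFAULT_COND_LIMIT
                            ) -> StepwiseResult:
    """Forward stepwise variable selection on Wilks' Lambda.

    At each round the candidate with the smallest p-to-enter is entered if
    its p < ``alpha_enter``; then included variables whose p-to-remove
    exceeds ``alpha_remove`` are removed (worst first).  Iteration stops
    when neither action fires, ``max_features`` is reached, or the residual
    degrees of freedom are exhausted (never more than n - g - 1 features).
    Ties break on smallest p, then largest F, then lowest feature index.
    Candidates whose entry would make the within-scatter condition number
    exceed ``cond_limit`` (near-collinear additions) are skipped.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p_all = X.shape
    g = len(np.unique(y))
    if n <= g + 1:
        raise ValueError("need n > g + 1 samples for stepwise selection")
    if not (0 < alpha_enter < 1 and 0 < alpha_remove < 1):
        raise ValueError("alphas must lie in (0, 1)")
    df_cap = n - g - 1
    cap = df_cap if max_features is None else min(max_features, df_cap)

    included: list[int] = []
    lam_cur = 1.0
    steps: list[StepwiseStep] = []

    for _ in range(4 * p_all + 8):         # cycle guard
        acted = False
        # --- entry ---
        if len(included) < cap:
            q_new = len(included) + 1
            best = None                    # (p, -F, index, lam)
            for j in range(p_all):
                if j in included:
                    continue
                subset = included + [j]
                try:
                    lam_j = wilks_lambda(X, y, subset)
                    W, _ = within_total_scatter(X, y, subset)
                    if np.linalg.cond(W) > cond_limit:
                        continue
                    F, pv = _safe_partial_F(lam_cur, min(lam_j, lam_cur),
                                            n, g, q_new)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                key = (pv, -F, j)
                if best is None or key < best[0]:
                    best = (key, lam_j, F, pv)
            if best is not None and best[3] < alpha_enter:
                j = best[0][2]
                included.append(j)
                lam_cur = min(best[1], lam_cur)
                steps.append(StepwiseStep(j, "enter", best[1], best[2],
                                          best[3]))
                acted = True
        # --- removal ---
        while len(included) > 1:
            q = len(included)
            worst = None                   # (-p, F, -index)
            for f in included:
                rest = [k for k in included if k != f]
                try:
                    lam_rest = wilks_lambda(X, y, rest)
                    F, pv = _safe_partial_F(lam_rest, min(lam_cur, lam_rest),
                                            n, g, q)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                key = (-pv, F, f)
                if worst is None or key < worst[0]:
                    worst = (key, f, lam_rest, F, pv)
            if worst is not None and worst[4] > alpha_remove:
                _, f, lam_rest, F, pv = worst
                included.remove(f)
                lam_cur = lam_rest
                steps.append(StepwiseStep(f, "remove", lam_rest, F, pv))
                acted = True
            else:
                break
        if not acted:
            break

    if not included:
        logger.info("stepwise selection entered no feature "
                    "(no candidate passed alpha-to-enter)")
    return StepwiseResult(included, steps, alpha_enter, alpha_remove)


# ---------------------------------------------------------------------------
# LDA classification functions
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Linear classification score functions on a fixed feature set."""

    classes: list
    feature_names: list[str]
    means: np.ndarray              # g x q
    pooled_cov: np.ndarray         # q x q, S = W / (n - g)
    coefs: np.ndarray              # g x q, rows S^-1 mu_k
    consts: np.ndarray             # g, -(1/2) mu_k' S^-1 mu_k + ln pi_k
    priors: np.ndarray             # g, sums to 1

    def scores(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != len(self.feature_names):
            raise ValueError("dimension mismatch with the model's features")
        return x @ self.coefs.T + self.consts

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classes": [str(c) for c in self.classes],
            "features": list(self.feature_names),
            "priors": self.priors.tolist(),
            "score_functions": {
                str(c): {"coefficients": self.coefs[i].tolist(),
                         "constant": float(self.consts[i])}
                for i, c in enumerate(self.classes)},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _resolve_priors(priors, classes, y) -> np.ndarray:
    g = len(classes)
    if priors is None or priors == "equal":
        pr = np.full(g, 1.0 / g)
    elif priors == "proportional":
        counts = np.array([(y == c).sum() for c in classes], dtype=float)
        pr = counts / counts.sum()
    else:
        pr = np.array([priors[c] for c in classes], dtype=float)
        pr = pr / pr.sum()
    if np.any(pr <= 0):
        raise ValueError("priors must be positive")
    return pr


def fit_lda(X, y, features: Sequence[int] | None = None,
            priors="equal",
            feature_names: Sequence[str] | None = None,
            ridge: float = 0.0) -> LDAModel:
    """Fit per-class linear classification functions on a feature subset.

    ``ridge`` (off by default) adds ``ridge * trace(S)/q`` to the diagonal
    of the pooled covariance for near-singular problems.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cols = list(features) if features is not None else list(range(X.shape[1]))
    Xs = X[:, cols]
    classes = list(np.unique(y))
    n, q = Xs.shape
    g = len(classes)
    if n - g < q:
        raise ValueError("need n - g >= number of features for a stable fit")
    means = np.vstack([Xs[y == c].mean(axis=0) for c in classes])
    W = sum(_scatter(Xs[y == c]) for c in classes)
    S = np.atleast_2d(W) / (n - g)
    if ridge > 0:
        S = S + ridge * np.trace(S) / q * np.eye(q)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise ValueError("singular pooled covariance: use fewer features or "
                         "the ridge flag") from None
    Sinv = np.linalg.inv(L.T) @ np.linalg.inv(L)
    pr = _resolve_priors(priors, classes, y)
    coefs = means @ Sinv
    consts = -0.5 * np.einsum("ij,ij->i", coefs, means) + np.log(pr)
    names = ([feature_names[c] for c in cols] if feature_names is not None
             else [str(c) for c in cols])
    return LDAModel(classes, names, means, S, coefs, consts, pr)


def classify(model: LDAModel, x) -> tuple[object, list[tuple[object, float]]]:
    """Predicted class and all class scores sorted descending.

    Exact score ties are broken by class label order (first label wins).
    """
    s = model.scores(np.asarray(x, dtype=float))
    order = sorted(range(len(model.classes)), key=lambda i: (-s[i], i))
    ranked = [(model.classes[i], float(s[i])) for i in order]
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        logger.info("score tie between %s and %s broken by label order",
                    ranked[0][0], ranked[1][0])
    return ranked[0][0], ranked


# ---------------------------------------------------------------------------
# jackknifed cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ClassificationMatrix:
    """True-origin x predicted-origin counts with % correct summaries."""

    counts: pd.DataFrame           # index true, columns predicted
    per_class_pct: pd.Series
    overall_pct: float

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         classes: Sequence | None = None
                         ) -> "ClassificationMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        cl = list(classes) if classes is not None else \
            sorted(set(y_true) | set(y_pred))
        counts = pd.DataFrame(0, index=cl, columns=cl, dtype=int)
        for t, p in zip(y_true, y_pred):
            counts.loc[t, p] += 1
        row_sums = counts.sum(axis=1)
        diag = pd.Series(np.diag(counts), index=cl)
        per_class = 100.0 * diag / row_sums.replace(0, np.nan)
        overall = 100.0 * diag.sum() / len(y_true)
        return cls(counts, per_class, float(overall))


def jackknife_classification(X, y, features: Sequence[int] | None = None,
                             priors="equal",
                             feature_names: Sequence[str] | None = None,
                             ridge: float = 0.0) -> ClassificationMatrix:
    """Leave-one-out classification matrix with per-sample refits.

    Each sample is scored by classification functions refitted on the other
    n - 1 samples; the feature set is held fixed (variable selection is not
    rerun inside the loop).  When a class has a single member, the refit
    proceeds with that class absent and the held-out sample is necessarily
    misclassified (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = list(np.unique(y))
    preds = []
    singletons_seen = set()
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if (y[mask] == y[i]).sum() == 0 and y[i] not in singletons_seen:
            singletons_seen.add(y[i])
            logger.info("class %r has a single member; its sample is "
                        "necessarily misclassified in the jackknife", y[i])
        model = fit_lda(X[mask], y[mask], features, priors, feature_names,
                        ridge)
        xs = X[i, list(features)] if features is not None else X[i]
        pred, _ = classify(model, xs)
        preds.append(pred)
    return ClassificationMatrix.from_predictions(y, preds, classes)


def resubstitution_classification(X, y, features=None, priors="equal",
                                  ridge: float = 0.0) -> ClassificationMatrix:
    """Classify the training samples with the model fitted on all of them."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    model = fit_lda(X, y, features, priors, ridge=ridge)
    cols = list(features) if features is not None else list(range(X.shape[1]))
    preds = [classify(model, X[i, cols])[0] for i in range(len(y))]
    return ClassificationMatrix.from_predictions(y, preds, list(np.unique(y)))


# ---------------------------------------------------------------------------
# score plot and family comparison
# ---------------------------------------------------------------------------

def score_plot(model: LDAModel, X, y, ids: Sequence[str] | None = None
               ) -> pd.DataFrame:
    """Top-two classification scores per sample (highest vs second-highest).

    Well-classified panels show each sample's highest score well above its
    runner-up; the returned frame carries both scores plus the true and
    predicted labels for plotting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rows = []
    for i in range(len(y)):
        pred, ranked = classify(model, X[i])
        rows.append({
            "line_id": ids[i] if ids is not None else str(i),
            "true_origin": y[i], "predicted_origin": pred,
            "score_highest": ranked[0][1],
            "score_second": ranked[1][1] if len(ranked) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def subset_comparison(feature_values: pd.DataFrame, y,
                      families: Mapping[str, str],
                      alpha_enter: float = 0.150,
                      alpha_remove: float = 0.150,
                      max_features: int | None = None,
                      priors="equal") -> pd.DataFrame:
    """Stepwise selection + jackknife separately per scaffold family and on
    the combined pool — the family-complementarity comparison.

    ``families`` maps every feature column to its family label; a missing
    column is an error.  Returns one row per pool with the pool size,
    number of selected features and jackknifed % correct.
    """
    missing = [c for c in feature_values.columns if c not in families]
    if missing:
        raise ValueError(f"family label missing for features: {missing[:5]}")
    fams = sorted({families[c] for c in feature_values.columns})
    pools = {f: [c for c in feature_values.columns if families[c] == f]
             for f in fams}
    pools["combined"] = list(feature_values.columns)
    y = np.asarray(y)

    rows = []
    for name in fams + ["combined"]:
        cols = pools[name]
        if not cols:
            raise ValueError(f"empty feature pool {name!r}")
        Xp = feature_values[cols].to_numpy(dtype=float)
        sel = forward_stepwise_select(Xp, y, alpha_enter, alpha_remove,
                                      max_features)
        if sel.selected:
            cm = jackknife_classification(Xp, y, sel.selected, priors,
                                          feature_names=cols)
            pct = cm.overall_pct
        else:
            pct = np.nan
        rows.append({"pool": name, "pool_size": len(cols),
                     "n_selected": len(sel.selected),
                     "selected": ";".join(cols[j] for j in sel.selected),
                     "jackknife_pct_correct": pct})
    return pd.DataFrame(rows)
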