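"""Variable screening and AICc-based model selection.

The search space is every admissible subset (default sizes 2-6) of the
screened variables crossed with a grid of regularization multipliers
(default {0.5, 1, 2, 3, 4}).  Candidates are scored by the small-sample
corrected Akaike information criterion computed for presence-only
models: the likelihood standardizes raw scores to sum to 1 over every
non-nodata cell of the study region, and k counts nonzero coefficients.
Akaike weights give each candidate's relative support; discrimination is
summarized by a held-out (70/30) AUC and a 10-fold cross-validated AUC.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import maxent_engine as me
from .grid_io import LayerStack

log = logging.getLogger(__name__)

DEFAULT_BETA_GRID = (0.5, 1.0, 2.0, 3.0, 4.0)
DEFAULT_SUBSET_SIZES = (2, 6)


class UndefinedScoreError(ValueError):
    """AICc undefined (n <= k + 1)."""


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def correlation_screen(
    background_values: pd.DataFrame,
    threshold: float = 0.8,
    gains: dict[str, float] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one variable of each highly collinear pair.

    Pearson |r| is computed on the background table.  Pairs at or above
    the threshold are resolved greedily, highest |r| first, dropping the
    member with the lower isolated gain (``gains``; ties and missing
    gains fall back to column order).  Constant variables are dropped
    with a warning.  Returns (retained variables, dropped pairs with r).
    """
    cols = list(background_values.columns)
    X = background_values.to_numpy(dtype=float)
    keep = []
    for i, c in enumerate(cols):
        if np.std(X[:, i]) == 0:
            warnings.warn(f"constant variable {c!r} dropped before screening",
                          stacklevel=2)
        else:
            keep.append(c)
    if len(keep) < 2:
        return keep, []
    sub = background_values[keep].to_numpy(dtype=float)
    r = np.corrcoef(sub, rowvar=False)
    pairs = [
        (abs(r[i, j]), keep[i], keep[j], r[i, j])
        for i, j in itertools.combinations(range(len(keep)), 2)
        if abs(r[i, j]) >= threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    gains = gains or {}
    retained = set(keep)
    dropped_pairs = []
    for _, a, b, rij in pairs:
        if a not in retained or b not in retained:
            continue
        ga, gb = gains.get(a, 0.0), gains.get(b, 0.0)
        loser = b if gb < ga else a if ga < gb else (
            b if keep.index(a) < keep.index(b) else a
        )
        retained.discard(loser)
        dropped_pairs.append((a, b, float(rij)))
    return [c for c in keep if c in retained], dropped_pairs


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def aicc(log_likelihood: float, k: int, n: int) -> float:
    """AICc = 2k - 2 lnL + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise UndefinedScoreError(
            f"AICc undefined for n={n}, k={k} (need n > k+1)"
        )
    return 2.0 * k - 2.0 * log_likelihood + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_scores) -> np.ndarray:
    """w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    a = np.asarray(aicc_scores, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AICc scores")
    w = np.zeros_like(a)
    d = a[finite] - a[finite].min()
    e = np.exp(-d / 2.0)
    w[finite] = e / e.sum()
    return w


def auc(scores_presence, scores_background) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    p = np.asarray(scores_presence, dtype=float)
    b = np.asarray(scores_background, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("both score lists must be non-empty")
    combined = np.concatenate([p, b])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(len(combined))
    ranks[order] = np.arange(1, len(combined) + 1)
    # midranks for ties
    sorted_vals = combined[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = 0.5 * (i + 1 + j + 1)
        i = j + 1
    rank_sum = ranks[: len(p)].sum()
    u = rank_sum - len(p) * (len(p) + 1) / 2.0
    return float(u / (len(p) * len(b)))


def landscape_log_likelihood(model: me.MaxentModel, stack: LayerStack,
                             presence_values) -> float:
    """Sum over presences of log raw scores renormalized over the landscape.

    Raw scores are standardized to sum to 1 across all non-nodata cells
    of the study region (not just the background sample), the convention
    that makes presence-only AICc scores comparable across models.
    """
    mask = stack.common_mask()
    rows, cols = np.nonzero(~mask)
    X_land = stack.value_table(rows, cols, model.feature_set.variables)
    # raw scores share the training log Z, which cancels in the
    # landscape-standardized likelihood
    log_r_land = np.log(model.raw(X_land))
    log_r_pres = np.log(model.raw(presence_values))
    log_total = logsumexp(log_r_land)
    return float(np.sum(log_r_pres - log_total))


# ---------------------------------------------------------------------------
# candidate evaluation
# ---------------------------------------------------------------------------

@dataclass
class CandidateModel:
    variables: tuple[str, ...]
    beta: float
    model: me.MaxentModel = field(repr=False, default=None)
    log_likelihood: float = np.nan
    k: int = 0
    aicc: float = np.inf
    delta_aicc: float = np.nan
    w_aicc: float = np.nan
    auc_test: float = np.nan
    auc_cv_mean: float = np.nan
    auc_cv_sd: float = np.nan
    excluded: str | None = None   # reason AICc was undefined, if any


def _split_indices(n: int, train_fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return perm[:n_train], perm[n_train:]


def cross_validated_auc(
    presence_values: pd.DataFrame,
    background: me.BackgroundSample,
    features: me.FeatureSet,
    beta: float,
    n_folds: int = 10,
    seed: int = 0,
    precision: str = "high",
) -> tuple[float, float]:
    """Mean and sd of AUC over k folds partitioning the presences.

    Background is shared across folds.  Folds with fewer than 2 training
    presences are skipped with a warning.
    """
    n = len(presence_values)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    bg_vals = background.values[features.variables]
    aucs = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        if len(train_idx) < 2 or len(test_idx) < 1:
            warnings.warn(f"fold {f} skipped: too few presences", stacklevel=2)
            continue
        model, _ = me.fit_maxent(
            presence_values.iloc[train_idx], bg_vals, features, beta=beta,
            precision=precision,
        )
        s_pres = model.raw(presence_values.iloc[test_idx])
        s_bg = model.raw(bg_vals)
        aucs.append(auc(s_pres, s_bg))
    if not aucs:
        return np.nan, np.nan
    return float(np.mean(aucs)), float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0


def evaluate_candidate(
    stack: LayerStack,
    presence_values: pd.DataFrame,
    background: me.BackgroundSample,
    variables,
    beta: float,
    seed: int = 0,
    classes: tuple[str, ...] = me.DEFAULT_CLASSES,
    hinge_knots: int = 50,
    train_fraction: float = 0.7,
    n_folds: int = 10,
    compute_cv: bool = True,
    compute_test: bool = True,
    precision: str = "high",
    features: me.FeatureSet | None = None,
    x0: np.ndarray | None = None,
) -> CandidateModel:
    """Fit and score one (variable subset, beta) candidate.

    The test AUC comes from a 70/30 presence split; the CV AUC from
    ``n_folds`` folds; the AICc from a fit on *all* presences with raw
    scores renormalized over the landscape.  Deterministic under
    ``seed``.
    """
    variables = tuple(variables)
    if features is None:
        features = me.build_features(
            None, list(variables), classes=classes, hinge_knots=hinge_knots,
            background=background.values,
        )
    pres = presence_values[features.variables]
    bg_vals = background.values[features.variables]

    # full-data fit for AICc
    model, report = me.fit_maxent(pres, bg_vals, features, beta=beta,
                                  precision=precision, x0=x0)
    k = model.k_nonzero()
    lnl = landscape_log_likelihood(model, stack, pres)
    cand = CandidateModel(
        variables=variables, beta=beta, model=model,
        log_likelihood=lnl, k=k,
    )
    n = len(pres)
    try:
        cand.aicc = aicc(lnl, k, n)
    except UndefinedScoreError as exc:
        cand.excluded = str(exc)
        log.warning("candidate %s beta=%s excluded: %s", variables, beta, exc)

    if compute_test:
        rng = np.random.default_rng(seed)
        train_idx, test_idx = _split_indices(n, train_fraction, rng)
        if len(train_idx) >= 2 and len(test_idx) >= 1:
            m_train, _ = me.fit_maxent(pres.iloc[train_idx], bg_vals, features,
                                       beta=beta, precision=precision)
            cand.auc_test = auc(m_train.raw(pres.iloc[test_idx]), m_train.raw(bg_vals))
    if compute_cv:
        cand.auc_cv_mean, cand.auc_cv_sd = cross_validated_auc(
            pres, background, features, beta, n_folds=n_folds, seed=seed + 1,
            precision=precision,
        )
    return cand


def enumerate_subsets(variables, sizes=DEFAULT_SUBSET_SIZES):
    """All subsets of the given inclusive size range, in stable order."""
    lo, hi = sizes
    hi = min(hi, len(variables))
    out = []
    for size in range(lo, hi + 1):
        out.extend(itertools.combinations(variables, size))
    return out


def select_best(
    candidates: list[CandidateModel], delta_report_cutoff: float = 4.0
) -> tuple[pd.DataFrame, CandidateModel]:
    """Rank candidates by AICc and report those near the top.

    Akaike weights are normalized over *all* valid candidates, not just
    the reported rows.  Ties break by smaller k, then smaller beta, then
    lexicographic variable names.
    """
    valid = [c for c in candidates if np.isfinite(c.aicc)]
    if not valid:
        raise ValueError("no candidate has a defined AICc score")
    weights = akaike_weights([c.aicc for c in valid])
    best_score = min(c.aicc for c in valid)
    for c, w in zip(valid, weights):
        c.w_aicc = float(w)
        c.delta_aicc = c.aicc - best_score
    ranked = sorted(valid, key=lambda c: (c.aicc, c.k, c.beta, c.variables))
    rows = [
        {
            "variables": ", ".join(c.variables),
            "lnL": c.log_likelihood,
            "k": c.k,
            "AICc": c.aicc,
            "dAICc": c.delta_aicc,
            "wAICc": c.w_aicc,
            "AUC_test": c.auc_test,
            "AUC_cv_mean": c.auc_cv_mean,
            "AUC_cv_sd": c.auc_cv_sd,
            "beta": c.beta,
        }
        for c in ranked
        if c.delta_aicc <= delta_report_cutoff
    ]
    return pd.DataFrame(rows), ranked[0]


def search_candidates(
    stack: LayerStack,
    presence_values: pd.DataFrame,
    background: me.BackgroundSample,
    variables,
    beta_grid=DEFAULT_BETA_GRID,
    subset_sizes=DEFAULT_SUBSET_SIZES,
    seed: int = 0,
    classes: tuple[str, ...] = me.DEFAULT_CLASSES,
    hinge_knots: int = 50,
    cv_for_all: bool = False,
    delta_report_cutoff: float = 4.0,
    precision: str = "search",
) -> tuple[pd.DataFrame, CandidateModel, list[CandidateModel]]:
    """Exhaustive subset x beta-grid search scored by AICc.

    Every candidate is evaluated exactly once (the count is logged).
    When ``cv_for_all`` is off, the held-out test AUC and 10-fold CV AUC
    are computed only for models within the report cutoff of the best
    AICc, mirroring tables that report AUC for top models only.
    """
    subsets = enumerate_subsets(list(variables), subset_sizes)
    n_candidates = len(subsets) * len(beta_grid)
    log.info("evaluating %d candidates (%d subsets x %d betas)",
             n_candidates, len(subsets), len(beta_grid))
    candidates = []
    for subset in subsets:
        features = me.build_features(
            None, list(subset), classes=classes, hinge_knots=hinge_knots,
            background=background.values,
        )
        x0 = None
        for beta in sorted(beta_grid):
            cand = evaluate_candidate(
                stack, presence_values, background, subset, beta,
                seed=seed, classes=classes, hinge_knots=hinge_knots,
                compute_cv=cv_for_all, compute_test=cv_for_all,
                precision=precision, features=features, x0=x0,
            )
            x0 = cand.model.lambdas   # warm start the next beta
            candidates.append(cand)
    table, best = select_best(candidates, delta_report_cutoff)
    if not cv_for_all:
        for c in candidates:
            if np.isfinite(c.delta_aicc) and c.delta_aicc <= delta_report_cutoff:
                top = evaluate_candidate(
                    stack, presence_values, background, c.variables, c.beta,
                    seed=seed, classes=classes, hinge_knots=hinge_knots,
                    compute_cv=True, compute_test=True, precision=precision,
                )
                c.auc_test = top.auc_test
                c.auc_cv_mean, c.auc_cv_sd = top.auc_cv_mean, top.auc_cv_sd
        table, best = select_best(candidates, delta_report_cutoff)
    return table, best, candidates
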