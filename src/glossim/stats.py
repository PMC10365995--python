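"""Perceptual statistics for material categorization and gloss rating data.

The chain mirrors how multiple-alternative forced-choice (n-AFC) material
experiments are analysed: free-naming terms are reduced to a consensus
category set; confidence-weighted choices are summed into stimulus × category
*profiles*; an exploratory factor analysis of the profiles reveals latent
material dimensions (with weighted-least-squares "Bartlett" factor scores,
and one extra dimension formed by stimuli with extreme *negative* scores);
leave-one-condition-out (LOCO) linear discriminant analysis tests whether
objective image features predict the material dimension; ordinary least
squares relates the three gloss cues to mean gloss ratings; and
representational similarity analysis (RSA) compares perceptual and
feature-based stimulus dissimilarities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import FactorAnalysis
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "reduce_terms",
    "build_profiles",
    "max_factors",
    "FactorSolution",
    "fit_factor_model",
    "varimax",
    "fit_gloss_regression",
    "RegressionResult",
    "ClassificationResult",
    "lda_loco",
    "select_top_loading",
    "intersubject_agreement",
    "fisher_z",
    "rsa",
    "compare_mediation_models",
    "factor_congruence",
]

UNASSIGNED = -1


def reduce_terms(term_usage: pd.DataFrame, min_users: int = 5,
                 merges: dict[str, list[str]] | None = None) -> list[str]:
    """Reduce free-naming terms to those used by enough participants.

    ``term_usage`` is a participants × terms table of counts (or a boolean
    usage table).  Terms used by at least ``min_users`` distinct participants
    are retained; a merge map (new name → constituent terms, the analyst's
    grouping of visually or semantically similar terms) is then applied, a
    merged term being retained if any constituent survived the cut-off.
    """
    if term_usage.shape[0] == 0 or term_usage.shape[1] == 0:
        raise ValueError("term usage table is empty")
    users = (term_usage > 0).sum(axis=0)
    retained = [t for t in term_usage.columns if users[t] >= min_users]
    if not merges:
        return retained
    merged_members = {t for members in merges.values() for t in members}
    out = [t for t in retained if t not in merged_members]
    for new, members in merges.items():
        if any(m in retained for m in members):
            out.append(new)
    return out


def build_profiles(responses: pd.DataFrame,
                   stimuli: list | None = None,
                   categories: list[str] | None = None) -> pd.DataFrame:
    """Sum confidence ratings into a stimuli × categories profile matrix.

    Cell (s, c) is the summed confidence over all responses that chose
    category ``c`` for stimulus ``s``; stimuli or categories without
    responses give zero rows/columns when the full label sets are supplied.
    """
    required = {"stimulus", "category", "confidence"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"response table lacks columns {sorted(missing)}")
    if categories is not None:
        unknown = set(responses["category"]) - set(categories)
        if unknown:
            raise ValueError(f"unknown category labels: {sorted(unknown)}")
    mat = responses.pivot_table(index="stimulus", columns="category",
                                values="confidence", aggfunc="sum", fill_value=0)
    if stimuli is not None:
        mat = mat.reindex(index=stimuli, fill_value=0)
    if categories is not None:
        mat = mat.reindex(columns=categories, fill_value=0)
    return mat.astype(float)


def max_factors(p: int) -> int:
    """Largest factor count supported by the degrees of freedom of a
    p-variable correlation matrix: the largest m with
    ``((p - m)**2 - (p + m)) / 2 >= 0`` (18 categories → 12 factors)."""
    if p < 2:
        raise ValueError(f"need at least 2 variables, got {p}")
    m = 0
    while m + 1 <= p and ((p - (m + 1)) ** 2 - (p + m + 1)) / 2 >= 0:
        m += 1
    return m


def varimax(loadings: np.ndarray, max_iter: int = 100,
            tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal, no Kaiser norm)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, m = L.shape
    R = np.eye(m)
    var_old = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (LR**3 - LR @ np.diag((LR**2).sum(axis=0)) / p))
        R = u @ vt
        var = s.sum()
        if var_old != 0 and var - var_old < tol:
            break
        var_old = var
    return L @ R


@dataclass
class FactorSolution:
    """Loadings, Bartlett scores and variance bookkeeping of one EFA fit."""

    loadings: pd.DataFrame            # categories × factors
    scores: pd.DataFrame              # stimuli × factors (Bartlett WLS)
    uniquenesses: pd.Series
    shared_variance: pd.Series        # fraction of common variance per factor
    cumulative_shared_variance: pd.Series
    total_variance: pd.Series         # fraction of total variance per factor
    assignments: pd.Series            # stimulus → dimension index (see below)
    negative_factor: int | None       # factor whose negative pole forms dim m
    n_dimensions: int
    flags: list[str] = field(default_factory=list)


def fit_factor_model(profiles: pd.DataFrame, m: int, rotation: str | None = None,
                     min_negative: int = 5, random_state: int = 0) -> FactorSolution:
    """Maximum-likelihood exploratory factor analysis of a profile matrix.

    Stimuli are observations and categories variables; columns are
    standardized internally so the model is fit to the category correlation
    structure.  Factor scores use the weighted-least-squares (Bartlett)
    estimator.  Each stimulus is assigned to the dimension of its most
    extreme score; stimuli whose extreme score is *negative* form one extra
    dimension on the factor where such stimuli are most numerous (at least
    ``min_negative`` of them), and are otherwise flagged unassigned (-1).
    """
    n, p = profiles.shape
    if m < 1 or m > max_factors(p):
        raise ValueError(
            f"m must be in [1, max_factors({p}) = {max_factors(p)}], got {m}")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = list(profiles.columns[sd == 0])
        raise ValueError(
            f"categories with zero variance make the correlation matrix "
            f"singular: {dead}; drop them or collect more responses")
    Z = (X - X.mean(axis=0)) / sd
    fa = FactorAnalysis(n_components=m, random_state=random_state,
                        svd_method="lapack")
    fa.fit(Z)
    L = fa.components_.T                      # p × m
    psi = fa.noise_variance_
    flags: list[str] = []
    if np.any(psi < 1e-3):
        flags.append("heywood_case")

    # Order factors by explained common variance; fix sign so the largest
    # loading of each factor is positive (sign is arbitrary in EFA).
    ssl = (L**2).sum(axis=0)
    order = np.argsort(ssl)[::-1]
    L = L[:, order]
    sign = np.sign(L[np.abs(L).argmax(axis=0), np.arange(m)])
    sign[sign == 0] = 1.0
    L = L * sign
    if rotation == "varimax":
        L = varimax(L)
        ssl = (L**2).sum(axis=0)
        order = np.argsort(ssl)[::-1]
        L = L[:, order]
    elif rotation not in (None, "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    ssl = (L**2).sum(axis=0)

    # Bartlett (WLS) factor scores: F = Z Psi^-1 L (L' Psi^-1 L)^-1.
    psi_inv = 1.0 / np.maximum(psi, 1e-8)
    A = (L * psi_inv[:, None])                # Psi^-1 L
    M = L.T @ A
    scores = Z @ A @ np.linalg.pinv(M)

    fnames = [f"factor{i + 1}" for i in range(m)]
    loadings = pd.DataFrame(L, index=profiles.columns, columns=fnames)
    scores_df = pd.DataFrame(scores, index=profiles.index, columns=fnames)
    shared = pd.Series(ssl / ssl.sum(), index=fnames)
    total = pd.Series(ssl / p, index=fnames)

    # Dimension assignment: argmax |score|, negative pole rule.
    extreme = np.abs(scores).argmax(axis=1)
    extreme_val = scores[np.arange(n), extreme]
    neg = extreme_val < 0
    assignments = extreme.copy()
    negative_factor: int | None = None
    if neg.any():
        counts = np.bincount(extreme[neg], minlength=m)
        cand = int(counts.argmax())
        if counts[cand] >= min_negative:
            negative_factor = cand
            assignments = np.where(neg & (extreme == cand), m, assignments)
            stray = neg & (extreme != cand)
        else:
            stray = neg
        if stray.any():
            assignments = np.where(stray, UNASSIGNED, assignments)
            flags.append(f"{int(stray.sum())}_stimuli_unassigned")
    n_dims = m + (1 if negative_factor is not None else 0)
    return FactorSolution(
        loadings=loadings,
        scores=scores_df,
        uniquenesses=pd.Series(psi, index=profiles.columns),
        shared_variance=shared,
        cumulative_shared_variance=shared.cumsum(),
        total_variance=total,
        assignments=pd.Series(assignments, index=profiles.index),
        negative_factor=negative_factor,
        n_dimensions=n_dims,
        flags=flags,
    )


def factor_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Mean Tucker congruence of optimally matched factors (sign- and
    permutation-invariant); used to compare a fitted loading matrix with the
    generating one."""
    from scipy.optimize import linear_sum_assignment

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = a / np.linalg.norm(a, axis=0, keepdims=True)
    nb = b / np.linalg.norm(b, axis=0, keepdims=True)
    C = np.abs(na.T @ nb)
    ri, ci = linear_sum_assignment(-C)
    return float(C[ri, ci].mean())


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    r_squared: float
    adj_r_squared: float
    f_value: float
    df_model: int
    df_resid: int
    n: int
    p_value: float


def _ols(y: np.ndarray, X: pd.DataFrame) -> RegressionResult:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return RegressionResult(
        params=model.params, bse=model.bse,
        r_squared=float(model.rsquared), adj_r_squared=float(model.rsquared_adj),
        f_value=float(model.fvalue), df_model=int(model.df_model),
        df_resid=int(model.df_resid), n=int(model.nobs),
        p_value=float(model.f_pvalue),
    )


def fit_gloss_regression(features: pd.DataFrame,
                         mean_ratings: pd.Series | np.ndarray) -> RegressionResult:
    """OLS predicting mean gloss ratings from the three gloss cues
    (coverage, sharpness, contrast); with n stimuli the residual degrees of
    freedom are n − 4 (three cues plus intercept)."""
    cols = ["coverage", "sharpness", "contrast"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    X = features[cols]
    y = np.asarray(mean_ratings, dtype=float)
    if len(X) != len(y):
        raise ValueError("features and ratings have different lengths")
    if len(X) <= 4:
        raise ValueError(f"need more than 4 stimuli, got {len(X)}")
    return _ols(y, X)


@dataclass
class ClassificationResult:
    confusion: pd.DataFrame          # true × predicted, aggregated over folds
    per_class_accuracy: pd.Series
    overall_accuracy: float
    fold_accuracy: pd.Series         # held-out condition → accuracy
    flags: list[str] = field(default_factory=list)


def lda_loco(features: pd.DataFrame | np.ndarray, labels,
             condition_ids, shrinkage: float = 0.0) -> ClassificationResult:
    """Pooled-covariance LDA with leave-one-condition-out cross-validation.

    One fold per unique condition id (e.g. shape × light field): the
    classifier is trained on all other conditions and tested on the held-out
    one.  All classes share the pooled within-class covariance (optionally
    shrunk towards the identity by ``shrinkage``; the least-squares solver
    falls back to a pseudo-inverse when the pooled covariance is singular).
    Test items whose class is absent from a training fold are flagged and
    excluded from that fold's accuracy denominator.  Prediction ties resolve
    to the earliest class in sorted label order.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    cond = np.asarray(condition_ids)
    if not (len(X) == len(y) == len(cond)):
        raise ValueError("features, labels and condition ids must align")
    classes = np.unique(y)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    fold_acc = {}
    flags: list[str] = []
    for held in np.unique(cond):
        tr, te = cond != held, cond == held
        train_classes = np.unique(y[tr])
        if len(train_classes) < 2:
            raise ValueError(
                f"training fold (holding out {held!r}) has fewer than 2 classes")
        known = np.isin(y[te], train_classes)
        if not known.all():
            flags.append(
                f"fold {held!r}: {int((~known).sum())} test items with classes "
                f"absent from training excluded")
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        clf.fit(X[tr], y[tr])
        Xte, yte = X[te][known], y[te][known]
        pred = clf.predict(Xte)
        for t, p_ in zip(yte, pred):
            conf.loc[t, p_] += 1
        fold_acc[held] = float((pred == yte).mean()) if len(yte) else float("nan")
    total = conf.to_numpy().sum()
    overall = float(np.trace(conf.to_numpy())) / total if total else float("nan")
    row_sums = conf.sum(axis=1)
    per_class = pd.Series(np.diag(conf), index=classes) / row_sums.replace(0, np.nan)
    return ClassificationResult(
        confusion=conf, per_class_accuracy=per_class, overall_accuracy=overall,
        fold_accuracy=pd.Series(fold_acc), flags=flags,
    )


def select_top_loading(scores: pd.DataFrame, k: int = 36,
                       assignments: pd.Series | None = None
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Top-k stimuli per material dimension by absolute factor score.

    Each stimulus first belongs to exactly one dimension (its argmax
    absolute score, or the supplied assignment), so no stimulus appears in
    two dimensions; within a dimension, members are ranked by |score| and
    the top k kept.  Dimensions with fewer than k members are flagged.
    Returns a table ``stimulus, dimension, score`` and the flag list.
    """
    S = scores.to_numpy(dtype=float)
    if assignments is None:
        dims = np.abs(S).argmax(axis=1)
    else:
        dims = np.asarray(assignments.reindex(scores.index))
    mag = np.abs(S).max(axis=1)
    df = pd.DataFrame({"stimulus": scores.index, "dimension": dims, "score": mag})
    df = df[df["dimension"] != UNASSIGNED]
    flags = []
    out = []
    for dim, grp in df.groupby("dimension"):
        if len(grp) < k:
            flags.append(f"dimension {dim}: only {len(grp)} members (< k={k})")
        out.append(grp.nlargest(min(k, len(grp)), "score"))
    result = pd.concat(out, ignore_index=True) if out else df
    return result, flags


def intersubject_agreement(ratings: pd.DataFrame | np.ndarray
                           ) -> tuple[float, float, list[str]]:
    """Agreement between raters of the same stimuli.

    ``ratings`` is participants × stimuli.  Returns the median pairwise
    Pearson r, the average leave-one-out R² (each participant predicted by
    the mean of the others; R² is the squared correlation with that mean),
    and flags for constant raters whose pairs were skipped.
    """
    R = np.asarray(ratings, dtype=float)
    n_raters = R.shape[0]
    if n_raters < 2:
        raise ValueError("need at least 2 participants")
    flags = []
    const = R.std(axis=1) == 0
    for i in np.flatnonzero(const):
        flags.append(f"participant {i} has constant ratings; pairs skipped")
    rs = []
    for i in range(n_raters):
        for j in range(i + 1, n_raters):
            if const[i] or const[j]:
                continue
            rs.append(sps.pearsonr(R[i], R[j])[0])
    if not rs:
        raise ValueError("no valid rater pairs")
    loo = []
    for i in range(n_raters):
        if const[i]:
            continue
        others = np.delete(R, i, axis=0).mean(axis=0)
        if others.std() == 0:
            continue
        loo.append(sps.pearsonr(R[i], others)[0] ** 2)
    return float(np.median(rs)), float(np.mean(loo)), flags


def fisher_z(r: float) -> float:
    """Fisher z-transform, ``atanh(r)``; requires |r| < 1."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    return math.atanh(r)


def rsa(category_profiles: pd.DataFrame, features: pd.DataFrame,
        rank: bool = True, profile_metric: str = "correlation") -> float:
    """Representational similarity between perceived material and features.

    Stimulus dissimilarities are computed from category profiles
    (correlation distance between profile rows by default;
    ``profile_metric`` accepts any ``scipy.spatial.distance`` metric) and
    from the feature table (Euclidean distance on column-standardized
    cues); the lower triangles are compared with a Spearman (default) or
    Pearson correlation.
    """
    if len(category_profiles) < 3:
        raise ValueError("need at least 3 stimuli")
    if len(category_profiles) != len(features):
        raise ValueError("profiles and features must cover the same stimuli")
    P = category_profiles.to_numpy(dtype=float)
    F = features.to_numpy(dtype=float)
    sd = F.std(axis=0, ddof=1)
    Fz = (F - F.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    d_percept = pdist(P, metric=profile_metric)
    d_feature = pdist(Fz, metric="euclidean")
    if rank:
        return float(sps.spearmanr(d_percept, d_feature)[0])
    return float(sps.pearsonr(d_percept, d_feature)[0])


def compare_mediation_models(features: pd.DataFrame, gloss: pd.Series | np.ndarray,
                             material_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-dimension comparison: material score from gloss vs from the cues.

    For every material dimension, fits (i) score ~ gloss level and
    (ii) score ~ the three gloss cues, and tabulates R² and adjusted R² of
    both together with the adjusted-R² winner.  If the features mediate
    material perception directly, model (ii) should win wherever gloss is an
    imperfect summary of the cues.
    """
    gloss = np.asarray(gloss, dtype=float)
    rows = []
    for dim in material_scores.columns:
        y = material_scores[dim].to_numpy(dtype=float)
        if y.std() == 0:
            raise ValueError(f"material scores for {dim!r} are constant")
        via_gloss = _ols(y, pd.DataFrame({"gloss": gloss}))
        direct = fit_gloss_regression(features, y)
        rows.append({
            "dimension": dim,
            "r2_gloss": via_gloss.r_squared,
            "adj_r2_gloss": via_gloss.adj_r_squared,
            "r2_cues": direct.r_squared,
            "adj_r2_cues": direct.adj_r_squared,
            "winner": "cues" if direct.adj_r_squared > via_gloss.adj_r_squared
                      else "gloss",
        })
    return pd.DataFrame(rows).set_index("dimension")
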