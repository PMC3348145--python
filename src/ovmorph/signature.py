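"""Response-signature discovery and the weighted-voting classifier.

Discovery ranks candidate features (genes or morphometric features) by the
signal-to-noise ratio between the chemosensitive and chemoresistant classes,

    SNR = (mu_sensitive - mu_resistant) / (sigma_sensitive + sigma_resistant),

so a positive SNR favours the sensitive class.  Significance comes from a
two-sided Welch t-test; morphometric features are gated at Benjamini-
Hochberg FDR <= 2%, genes at p < 0.05 combined with a geometric-mean
fold-change cutoff tuned on training accuracy.

The classifier is a Golub-style weighted vote.  Each signature feature f
casts the vote w_f * (x_f - b_f) with weight w_f = SNR_f and decision
boundary b_f the midpoint of the two class means; the sample score is the
vote average, S = (1/N) * sum_f w_f (x_f - b_f).  Scores above a cutoff
(0 by default; ROC/Youden-calibrated in practice) predict sensitive.

Expression values are assumed log2-scale throughout, so the geometric-mean
fold change resistant/sensitive is 2**(mean_resistant - mean_sensitive).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

SENSITIVE = "sensitive"
RESISTANT = "resistant"


class DegenerateFeatureError(ValueError):
    """Both classes have zero spread: SNR undefined."""


@dataclass
class SignatureEntry:
    """One signature feature: weight, class means, boundary, statistics."""

    feature_id: str
    w: float
    mu_sensitive: float
    mu_resistant: float
    b: float
    fold_change: float
    p_value: float
    q_value: float


@dataclass
class PredictiveModel:
    entries: list[SignatureEntry]
    score_cutoff: float = 0.0
    normalized: bool = True

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("model needs at least one entry")

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def to_json(self, path) -> None:
        payload = {
            "score_cutoff": self.score_cutoff,
            "normalized": self.normalized,
            "entries": [asdict(e) for e in self.entries],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PredictiveModel":
        with open(path) as fh:
            payload = json.load(fh)
        entries = [SignatureEntry(**e) for e in payload["entries"]]
        return cls(entries, payload["score_cutoff"], payload.get("normalized", True))


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def snr(values_a: np.ndarray, values_b: np.ndarray, ddof: int = 1) -> float:
    """Signal-to-noise ratio (mu_a - mu_b)/(sigma_a + sigma_b).

    Class a is conventionally the sensitive class.  Antisymmetric under class
    swap.  Requires >= 2 values per class; zero combined spread raises
    :class:`DegenerateFeatureError`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 non-missing values")
    denom = a.std(ddof=ddof) + b.std(ddof=ddof)
    if denom == 0:
        raise DegenerateFeatureError("zero spread in both classes")
    return float((a.mean() - b.mean()) / denom)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def jarque_bera(values) -> tuple[float, float]:
    """Jarque-Bera normality test: JB = n/6 (skew^2 + (kurt-3)^2/4), chi2(2) p."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 8:
        raise ValueError("Jarque-Bera needs n >= 8")
    if np.ptp(v) == 0:
        raise ValueError("constant vector")
    res = stats.jarque_bera(v)
    return float(res.statistic), float(res.pvalue)


def _split_classes(matrix: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Columns of ``matrix`` (features x samples) split into (sensitive, resistant)."""
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    sens = matrix.loc[:, (labels == SENSITIVE).values].to_numpy(dtype=float)
    res = matrix.loc[:, (labels == RESISTANT).values].to_numpy(dtype=float)
    if sens.shape[1] == 0 or res.shape[1] == 0:
        raise ValueError("both classes must be non-empty")
    return sens, res


def _nan_class_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise (mean, sample variance, count) ignoring NaN."""
    n = np.sum(~np.isnan(x), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        warnings.filterwarnings("ignore", message="Degrees of freedom")
        mean = np.nanmean(x, axis=1)
        var = np.nanvar(x, axis=1, ddof=1)
    return mean, var, n


def welch_t_p(x_a: np.ndarray, x_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Welch t-test per row, NaNs excluded pairwise.

    Rows with fewer than two valid values in a class, or zero pooled spread,
    yield NaN p-values (they can never be selected).
    """
    m1, v1, n1 = _nan_class_stats(x_a)
    m2, v2, n2 = _nan_class_stats(x_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * special.stdtr(df, -np.abs(t))
    bad = (n1 < 2) | (n2 < 2) | (se2 == 0) | ~np.isfinite(t)
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)
    return t, p


def _entries_from_stats(
    ids, mu_s, mu_r, sd_s, sd_r, p, q, fold_change=None
) -> list[SignatureEntry]:
    entries = []
    for i, fid in enumerate(ids):
        denom = sd_s[i] + sd_r[i]
        w = (mu_s[i] - mu_r[i]) / denom if denom > 0 else float("nan")
        fc = float(fold_change[i]) if fold_change is not None else float("nan")
        entries.append(
            SignatureEntry(
                feature_id=str(fid),
                w=float(w),
                mu_sensitive=float(mu_s[i]),
                mu_resistant=float(mu_r[i]),
                b=float((mu_s[i] + mu_r[i]) / 2.0),
                fold_change=fc,
                p_value=float(p[i]),
                q_value=float(q[i]) if q is not None else float("nan"),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# screening and selection
# ---------------------------------------------------------------------------

def prescreen_genes(
    matrix: pd.DataFrame,
    min_variation_quantile: float = 0.25,
    min_median_quantile: float = 0.25,
) -> pd.DataFrame:
    """Drop genes with trivial variation or low median expression.

    Retains genes whose across-sample SD exceeds the ``min_variation_quantile``
    quantile of all gene SDs *and* whose median exceeds the
    ``min_median_quantile`` quantile of all gene medians.
    """
    for q in (min_variation_quantile, min_median_quantile):
        if not 0 <= q <= 1:
            raise ValueError("quantiles must lie in [0, 1]")
    sds = matrix.std(axis=1, ddof=1)
    meds = matrix.median(axis=1)
    # a zero quantile imposes no constraint (identity), rather than dropping minima
    keep_sd = (
        sds > sds.quantile(min_variation_quantile)
        if min_variation_quantile > 0
        else pd.Series(True, index=matrix.index)
    )
    keep_med = (
        meds > meds.quantile(min_median_quantile)
        if min_median_quantile > 0
        else pd.Series(True, index=matrix.index)
    )
    keep = keep_sd & keep_med
    out = matrix.loc[keep]
    if out.empty:
        raise ValueError("prescreen removed every gene: thresholds too aggressive")
    return out


def select_morph_features(
    features: pd.DataFrame,
    labels: pd.Series,
    fdr_max: float = 0.02,
) -> list[SignatureEntry]:
    """Response-associated morphometric features at BH FDR <= ``fdr_max``.

    ``features`` is samples x features (normalized).  Each feature gets a
    Welch t-test; q-values are BH-adjusted over all testable features;
    features with q <= fdr_max are returned ordered by SNR descending, so the
    sensitive-favouring (positive-SNR) features head the list.  Missing
    values are excluded pairwise.
    """
    fx = features.T  # features x samples
    sens, res = _split_classes(fx, labels)
    _, p = welch_t_p(sens, res)
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        q[valid] = bh_adjust(p[valid])
    mu_s, var_s, _ = _nan_class_stats(sens)
    mu_r, var_r, _ = _nan_class_stats(res)
    sel = valid & (q <= fdr_max)
    entries = _entries_from_stats(
        fx.index[sel],
        mu_s[sel], mu_r[sel], np.sqrt(var_s[sel]), np.sqrt(var_r[sel]),
        p[sel], q[sel],
    )
    entries.sort(key=lambda e: -e.w)
    return entries


def select_genes(
    matrix: pd.DataFrame,
    labels: pd.Series,
    fold_change_cutoff: float = 1.5,
    p_max: float = 0.05,
) -> list[SignatureEntry]:
    """Differentially expressed genes by joint fold-change and t-test rule.

    Retains genes with |log2 geometric-mean fold change| >=
    log2(``fold_change_cutoff``) and Welch p < ``p_max``.  ``matrix`` is
    genes x samples, log2 scale, ideally prescreened.  Entries are ordered by
    SNR descending.
    """
    if fold_change_cutoff < 1.0:
        raise ValueError("fold_change_cutoff must be >= 1")
    sens, res = _split_classes(matrix, labels)
    _, p = welch_t_p(sens, res)
    mu_s, var_s, _ = _nan_class_stats(sens)
    mu_r, var_r, _ = _nan_class_stats(res)
    log2fc = mu_r - mu_s  # resistant over sensitive, log2
    valid = ~np.isnan(p)
    sel = valid & (np.abs(log2fc) >= math.log2(fold_change_cutoff)) & (p < p_max)
    entries = _entries_from_stats(
        matrix.index[sel],
        mu_s[sel], mu_r[sel], np.sqrt(var_s[sel]), np.sqrt(var_r[sel]),
        p[sel], None, fold_change=2.0 ** log2fc[sel],
    )
    entries.sort(key=lambda e: -e.w)
    return entries


# ---------------------------------------------------------------------------
# weighted voting
# ---------------------------------------------------------------------------

def fit_weighted_voting(
    matrix: pd.DataFrame,
    labels: pd.Series,
    entries: list[SignatureEntry],
    score_cutoff: float = 0.0,
    normalized: bool = True,
) -> PredictiveModel:
    """Fit per-feature weights and boundaries on the training data.

    Recomputes, for each entry's feature, w_f = SNR and b_f = midpoint of the
    class means on ``matrix``/``labels``; degenerate features (zero pooled
    spread) are excluded with a warning.  ``normalized`` selects the 1/N vote
    average (the default) versus the raw vote sum.
    """
    if not entries:
        raise ValueError("entries must be non-empty")
    ids = [e.feature_id for e in entries]
    sub = matrix.loc[ids]
    sens, res = _split_classes(sub, labels)
    mu_s, var_s, _ = _nan_class_stats(sens)
    mu_r, var_r, _ = _nan_class_stats(res)
    sd_sum = np.sqrt(var_s) + np.sqrt(var_r)
    fitted = []
    for i, e in enumerate(entries):
        if not sd_sum[i] > 0:
            warnings.warn(f"dropping degenerate feature {e.feature_id}", stacklevel=2)
            continue
        fitted.append(
            SignatureEntry(
                feature_id=e.feature_id,
                w=float((mu_s[i] - mu_r[i]) / sd_sum[i]),
                mu_sensitive=float(mu_s[i]),
                mu_resistant=float(mu_r[i]),
                b=float((mu_s[i] + mu_r[i]) / 2.0),
                fold_change=e.fold_change,
                p_value=e.p_value,
                q_value=e.q_value,
            )
        )
    return PredictiveModel(fitted, score_cutoff=score_cutoff, normalized=normalized)


def predict_score(model: PredictiveModel, x: pd.Series) -> float:
    """Weighted-voting score S = (1/N) sum_f w_f (x_f - b_f) for one sample.

    Features absent from ``x`` are dropped from the sum with renormalization
    (warned); no overlap at all is an error.
    """
    votes = []
    for e in model.entries:
        if e.feature_id in x.index and not math.isnan(x[e.feature_id]):
            votes.append(e.w * (x[e.feature_id] - e.b))
    if not votes:
        raise ValueError("sample shares no features with the model")
    if len(votes) < len(model.entries):
        warnings.warn(
            f"{len(model.entries) - len(votes)} model features missing; "
            "score renormalized over the rest",
            stacklevel=2,
        )
    total = float(np.sum(votes))
    return total / len(votes) if model.normalized else total


def predict_scores(model: PredictiveModel, matrix: pd.DataFrame) -> pd.Series:
    """Scores for every sample (column) of a features x samples matrix."""
    ids = [e.feature_id for e in model.entries if e.feature_id in matrix.index]
    if not ids:
        raise ValueError("matrix shares no features with the model")
    if len(ids) < len(model.entries):
        warnings.warn(
            f"{len(model.entries) - len(ids)} model features missing; "
            "scores renormalized over the rest",
            stacklevel=2,
        )
    by_id = {e.feature_id: e for e in model.entries}
    w = np.array([by_id[i].w for i in ids])
    b = np.array([by_id[i].b for i in ids])
    sub = matrix.loc[ids].to_numpy(dtype=float)
    total = w @ (sub - b[:, None])
    scores = total / len(ids) if model.normalized else total
    return pd.Series(scores, index=matrix.columns, name="score")


def classify(model: PredictiveModel, scores: pd.Series) -> pd.Series:
    """Score > cutoff => sensitive, else resistant."""
    return pd.Series(
        np.where(scores.values > model.score_cutoff, SENSITIVE, RESISTANT),
        index=scores.index,
        name="predicted",
    )


def training_accuracy(
    matrix: pd.DataFrame, labels: pd.Series, model: PredictiveModel
) -> float:
    """Resubstitution accuracy of the model on its own training samples."""
    pred = classify(model, predict_scores(model, matrix))
    return float((pred.values == labels.reindex(pred.index).values).mean())


def tune_fold_change_cutoff(
    matrix: pd.DataFrame,
    labels: pd.Series,
    candidate_cutoffs: list[float],
    p_max: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Pick the fold-change cutoff maximizing training-set accuracy.

    For every candidate: select genes, fit the weighted vote, score the
    training samples at cutoff 0.  A candidate that selects zero genes scores
    the majority-class rate and is flagged.  Ties go to the smallest cutoff.
    Returns the best cutoff and the full accuracy curve.
    """
    if not candidate_cutoffs:
        raise ValueError("need at least one candidate cutoff")
    majority = max(labels.value_counts(normalize=True))
    rows = []
    for c in candidate_cutoffs:
        entries = select_genes(matrix, labels, fold_change_cutoff=c, p_max=p_max)
        if not entries:
            rows.append({"cutoff": c, "n_genes": 0, "accuracy": majority,
                         "empty_selection": True})
            continue
        model = fit_weighted_voting(matrix, labels, entries)
        rows.append({
            "cutoff": c,
            "n_genes": len(entries),
            "accuracy": training_accuracy(matrix, labels, model),
            "empty_selection": False,
        })
    curve = pd.DataFrame(rows)
    best_acc = curve["accuracy"].max()
    best = float(curve.loc[curve["accuracy"] == best_acc, "cutoff"].min())
    return best, curve


def loo_accuracy(
    matrix: pd.DataFrame,
    labels: pd.Series,
    fold_change_cutoff: float = 1.5,
    p_max: float = 0.05,
    score_cutoff: float = 0.0,
) -> float:
    """Leave-one-out accuracy with selection and fitting redone per fold."""
    correct = 0
    for sid in matrix.columns:
        rest = matrix.drop(columns=[sid])
        rest_labels = labels.drop(index=sid)
        entries = select_genes(rest, rest_labels, fold_change_cutoff, p_max)
        if not entries:
            pred = rest_labels.value_counts().idxmax()
        else:
            model = fit_weighted_voting(rest, rest_labels, entries,
                                        score_cutoff=score_cutoff)
            pred = SENSITIVE if predict_score(model, matrix[sid]) > score_cutoff else RESISTANT
        correct += pred == labels[sid]
    return correct / len(matrix.columns)


# ---------------------------------------------------------------------------
# ROC and stratification
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    points: pd.DataFrame  # columns fpr, tpr, cutoff
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    degenerate: bool = False


def roc_and_cutoff(
    scores: pd.Series,
    labels: pd.Series,
    positive_class: str = SENSITIVE,
    cutoff: float | None = None,
) -> RocResult:
    """ROC curve, trapezoid AUC, and an operating cutoff.

    With ``cutoff=None`` the cutoff maximizing Youden's J (sensitivity +
    specificity - 1) is chosen among midpoints between adjacent distinct
    scores; a user-supplied cutoff (e.g. the study's -0.16) is honoured
    instead.  Classification rule: score > cutoff => positive class.
    Constant scores give AUC 0.5 and a degenerate flag.
    """
    labels = labels.reindex(scores.index)
    y = (labels.values == positive_class).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    s = scores.to_numpy(dtype=float)

    uniq = np.unique(s)
    if len(uniq) == 1:
        return RocResult(
            points=pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0],
                                 "cutoff": [np.inf, -np.inf]}),
            auc=0.5, cutoff=float("nan"), sensitivity=float("nan"),
            specificity=float("nan"), degenerate=True,
        )
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    pos, neg = (y == 1), (y == 0)
    tpr = np.array([(s[pos] > c).mean() for c in candidates])
    fpr = np.array([(s[neg] > c).mean() for c in candidates])
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "cutoff": candidates})
    auc = float(roc_auc_score(y, s))
    if cutoff is None:
        j = tpr - fpr
        cutoff = float(candidates[int(np.argmax(j))])
    sens = float((s[pos] > cutoff).mean())
    spec = float((s[neg] <= cutoff).mean())
    return RocResult(points, auc, float(cutoff), sens, spec)


def split_by_quantile(scores: pd.Series, top_fraction: float) -> pd.Series:
    """Label the round(top_fraction * n) highest scores "high-score".

    Ties are broken by stable sample order.  Matches the study's 171/73 split
    of 244 samples at a 70.1% top fraction.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    n = len(scores)
    n_high = int(math.floor(top_fraction * n + 0.5))
    order = np.lexsort((np.arange(n), -scores.to_numpy(dtype=float)))
    groups = np.empty(n, dtype=object)
    groups[order[:n_high]] = "high-score"
    groups[order[n_high:]] = "low-score"
    return pd.Series(groups, index=scores.index, name="score_group")


def operating_point_accuracy(
    sensitivity: float, specificity: float, n_positive: int, n_negative: int
) -> float:
    """Overall accuracy implied by an operating point and the class sizes:
    (sens * n_pos + spec * n_neg) / (n_pos + n_neg)."""
    return (sensitivity * n_positive + specificity * n_negative) / (
        n_positive + n_negative
    )
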