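"""Response metrics, Ward clustering with branch-length heterogeneity, and
marker-response association statistics.

Responses are per-lesion percent changes from baseline classified with
RECIST-style thresholds applied to single lesions (PR at <= -30%, PD at
>= +20%, CR at complete disappearance, SD otherwise).  Intrapatient response
heterogeneity is flagged when the maximum pairwise difference in percent
change between a patient's lesions meets 10/20/50-point thresholds.

Heterogeneity of a feature block is quantified on a Ward dendrogram
(ward.D2 convention: merge costs on squared dissimilarities, heights on the
dissimilarity scale): the *average branch length* of a group of samples is
the mean cophenetic distance over all pairs in the group — short branches
mean the group clusters tightly, i.e. low heterogeneity.  Genomic blocks
(which contain zeros) use Euclidean distance; continuous immune blocks use
Pearson correlation distance ``1 - r``.

Marker-response association respects the within-patient correlation
structure: the binary response indicator is permuted only within each
patient, which realizes the exchangeability assumption of a random-intercept
ANOVA without its distributional assumptions.  A patient-blocked mixed
linear model backend is available as an alternative.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ResponseRecord",
    "Dendrogram",
    "AssociationResult",
    "recist_class",
    "response_metrics",
    "cluster_samples",
    "average_branch_length",
    "branch_length_wilcoxon",
    "marker_response_association",
    "fisher_median_dichotomy",
    "rf_importance",
    "correlate",
    "variable_heatmap_prep",
    "bh_adjust",
]


@dataclass(frozen=True)
class ResponseRecord:
    lesion_id: str
    patient_id: str
    baseline_size: float
    followup_size: float
    percent_change: float
    recist_class: str


def recist_class(percent_change: float) -> str:
    """Single-lesion response class from percent change (CR/PR/SD/PD)."""
    if percent_change <= -100.0 + 1e-9:
        return "CR"
    if percent_change >= 20.0:
        return "PD"
    if percent_change <= -30.0:
        return "PR"
    return "SD"


def response_metrics(
    sizes: pd.DataFrame,
    thresholds: Sequence[float] = (10.0, 20.0, 50.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lesion response records and per-patient heterogeneity flags.

    ``sizes`` needs columns patient_id, lesion_id, baseline_size,
    followup_size; every patient must contribute >= 2 lesions.  Returns
    (per-lesion table, per-patient table).  Best = most negative percent
    change, worst = most positive; ties broken by lesion_id.
    """
    required = {"patient_id", "lesion_id", "baseline_size", "followup_size"}
    missing = required - set(sizes.columns)
    if missing:
        raise ValueError(f"sizes table missing columns {sorted(missing)}")
    if (sizes["baseline_size"] <= 0).any():
        raise ValueError("baseline sizes must be positive")

    lesion_rows = []
    for _, row in sizes.iterrows():
        pct = 100.0 * (row["followup_size"] - row["baseline_size"]) / row["baseline_size"]
        lesion_rows.append(
            {
                "patient_id": row["patient_id"],
                "lesion_id": row["lesion_id"],
                "baseline_size": row["baseline_size"],
                "followup_size": row["followup_size"],
                "percent_change": pct,
                "recist_class": recist_class(pct),
            }
        )
    lesion_df = pd.DataFrame(lesion_rows)

    patient_rows = []
    for pid, grp in lesion_df.groupby("patient_id", sort=True):
        if len(grp) < 2:
            raise ValueError(f"patient {pid} has fewer than 2 lesions")
        pct = grp["percent_change"]
        max_diff = float(pct.max() - pct.min())
        ordered = grp.sort_values(["percent_change", "lesion_id"], kind="mergesort")
        best = ordered.iloc[0]
        worst = ordered.sort_values(
            ["percent_change", "lesion_id"], ascending=[False, True], kind="mergesort"
        ).iloc[0]
        row = {
            "patient_id": pid,
            "n_lesions": len(grp),
            "max_pairwise_diff": max_diff,
            "best_lesion": best["lesion_id"],
            "worst_lesion": worst["lesion_id"],
            "mixed_recist": len(set(grp["recist_class"])) > 1,
        }
        for t in thresholds:
            row[f"heterogeneous_ge_{t:g}"] = max_diff >= t
        patient_rows.append(row)
    return lesion_df, pd.DataFrame(patient_rows)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape inconsistent with label count")

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (height of lowest common merge)."""
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=list(self.labels), columns=list(self.labels))


def _pearson_distance(X: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    sd = X.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(
            f"zero-variance sample(s) under correlation distance: {[labels[i] for i in bad]}"
        )
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return squareform((d + d.T) / 2.0, checks=False)


def cluster_samples(features: pd.DataFrame, block: str = "genomic") -> Dendrogram:
    """Ward (ward.D2) dendrogram of samples (rows of ``features``).

    ``block="genomic"`` and ``"combined"`` use Euclidean distance (genomic
    variables contain zeros, where correlations misbehave); ``"immune"`` uses
    Pearson correlation distance 1 - r.
    """
    if len(features) < 2:
        raise ValueError("clustering requires at least 2 samples")
    X = features.to_numpy(dtype=float)
    labels = [str(i) for i in features.index]
    if block in ("genomic", "combined"):
        from scipy.spatial.distance import pdist

        condensed = pdist(X, metric="euclidean")
    elif block == "immune":
        condensed = _pearson_distance(X, labels)
    else:
        raise ValueError("block must be one of {'genomic', 'immune', 'combined'}")
    Z = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(linkage=Z, labels=tuple(labels))


def average_branch_length(
    dendrogram: Dendrogram,
    group: Sequence[str],
    mode: str = "mean_cophenetic",
) -> float:
    """Average branch length needed to cluster a group of leaves together.

    ``mean_cophenetic`` (default): mean pairwise cophenetic distance within
    the group.  ``spanning_height``: height of the lowest merge containing the
    whole group (the alternative reading of "branch length required to
    cluster").
    """
    group = [str(g) for g in group]
    if len(group) < 2:
        raise ValueError("group must contain at least 2 leaves")
    missing = set(group) - set(dendrogram.labels)
    if missing:
        raise ValueError(f"leaves not in dendrogram: {sorted(missing)}")
    coph = dendrogram.cophenetic_matrix()
    pairs = list(itertools.combinations(group, 2))
    dists = [coph.loc[a, b] for a, b in pairs]
    if mode == "mean_cophenetic":
        return float(np.mean(dists))
    if mode == "spanning_height":
        return float(np.max(dists))
    raise ValueError("mode must be 'mean_cophenetic' or 'spanning_height'")


def branch_length_wilcoxon(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of branch lengths (exact for
    small tie-free samples). Returns (U statistic, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AssociationResult:
    marker: str
    effect: float  # difference in marker means between indicator classes
    p_value: float
    q_value: float


def _within_patient_permutations(
    patient_ids: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) index array; each row permutes positions within patients."""
    n = len(patient_ids)
    base = np.arange(n)
    blocks = [np.where(patient_ids == pid)[0] for pid in pd.unique(patient_ids)]
    perms = np.tile(base, (n_perm, 1))
    for idx in blocks:
        if len(idx) < 2:
            continue
        # vectorized within-block shuffles: argsort of iid uniforms
        order = np.argsort(rng.random((n_perm, len(idx))), axis=1)
        perms[:, idx] = idx[order]
    return perms


def marker_response_association(
    features: pd.DataFrame,
    indicator: Sequence[int],
    patient_ids: Sequence[str],
    n_perm: int = 10000,
    seed: int | None = 0,
    backend: str = "permutation",
) -> list[AssociationResult]:
    """Association between each marker and a binary within-patient response
    indicator, with Benjamini-Hochberg adjustment across markers.

    The default backend permutes the indicator within each patient (the
    exchangeability structure a random-intercept ANOVA models) and reports
    ``p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm)`` for the difference of
    marker means between classes.  Patients whose lesions all share one
    indicator value carry no contrast and are excluded with a warning.
    ``backend="mixedlm"`` instead fits a patient-random-intercept linear
    model per marker (Wald p on the indicator coefficient).
    """
    y = np.asarray(indicator, dtype=float)
    pids = np.asarray([str(p) for p in patient_ids])
    if len(features) != len(y) or len(y) != len(pids):
        raise ValueError("features, indicator and patient_ids lengths differ")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("indicator must be binary 0/1")

    keep = np.ones(len(y), dtype=bool)
    for pid in pd.unique(pids):
        idx = pids == pid
        if len(np.unique(y[idx])) < 2:
            warnings.warn(
                f"patient {pid} has a constant response indicator; excluded",
                stacklevel=2,
            )
            keep &= ~idx
    X = features.loc[keep]
    y = y[keep]
    pids = pids[keep]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("indicator is constant after exclusions")

    if backend == "mixedlm":
        return _mixedlm_association(X, y, pids)
    if backend != "permutation":
        raise ValueError("backend must be 'permutation' or 'mixedlm'")

    rng = np.random.default_rng(seed)
    perms = _within_patient_permutations(pids, n_perm, rng)
    y_perm = y[perms]  # (n_perm, n); within-patient class counts preserved
    n1 = y.sum()
    n0 = len(y) - n1

    results_p, effects = [], []
    markers = list(X.columns)
    vals = X.to_numpy(dtype=float)
    for m, name in enumerate(markers):
        x = vals[:, m]
        t_obs = x[y == 1].mean() - x[y == 0].mean()
        s1 = y_perm @ x
        t_perm = s1 / n1 - (x.sum() - s1) / n0
        hits = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
        results_p.append((1 + hits) / (1 + n_perm))
        effects.append(float(t_obs))
    q = bh_adjust(results_p)
    return [
        AssociationResult(marker=name, effect=eff, p_value=float(p), q_value=float(qv))
        for name, eff, p, qv in zip(markers, effects, results_p, q)
    ]


def _mixedlm_association(
    X: pd.DataFrame, y: np.ndarray, pids: np.ndarray
) -> list[AssociationResult]:
    import statsmodels.api as sm

    pvals, effects = [], []
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                endog=x, exog=sm.add_constant(y), groups=pids
            ).fit(reml=True)
        effects.append(float(model.params[1]))
        pvals.append(float(model.pvalues[1]))
    q = bh_adjust(pvals)
    return [
        AssociationResult(marker=n, effect=e, p_value=p, q_value=float(qv))
        for n, e, p, qv in zip(X.columns, effects, pvals, q)
    ]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def fisher_median_dichotomy(
    values: Sequence[float], responder: Sequence[bool]
) -> tuple[float, float, np.ndarray]:
    """Dichotomize a marker at its median and test against responder status.

    Values equal to the median go to the low group.  Returns (odds ratio,
    two-sided exact p, 2x2 table [[low&non, low&resp], [high&non, high&resp]]).
    """
    v = np.asarray(values, dtype=float)
    flag = np.asarray(responder, dtype=bool)
    if len(v) != len(flag):
        raise ValueError("values and responder flags differ in length")
    if len(v) < 4:
        raise ValueError("need at least 4 samples")
    if np.all(v == v[0]):
        raise ValueError("all marker values identical: degenerate median split")
    med = np.median(v)
    high = v > med
    if high.all() or (~high).all():
        raise ValueError("median split degenerate (one group empty)")
    table = np.array(
        [
            [int(np.sum(~high & ~flag)), int(np.sum(~high & flag))],
            [int(np.sum(high & ~flag)), int(np.sum(high & flag))],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def rf_importance(
    features: pd.DataFrame,
    labels: Sequence,
    n_trees: int = 1000,
    node_size: int = 1,
    seed: int | None = 0,
) -> tuple[pd.Series, float]:
    """Random-forest Gini importance and out-of-bag error.

    1000 trees, node size 1, mtry = sqrt(p), Gini splitting; importance is
    the mean decrease in node impurity over trees, OOB error the
    misclassification rate of out-of-bag votes.
    """
    from sklearn.ensemble import RandomForestClassifier

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if len(features) < 10:
        raise ValueError("need at least 10 samples for a stable forest")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        min_samples_leaf=node_size,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n OOB coverage warnings
        clf.fit(features.to_numpy(dtype=float), y)
    importance = pd.Series(clf.feature_importances_, index=features.columns)
    return importance, float(1.0 - clf.oob_score_)


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    n_perm: int = 10000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided permutation p-value."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv) or len(xv) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        xr, yr = xv, yv
    elif method == "spearman":
        xr, yr = stats.rankdata(xv), stats.rankdata(yv)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        ac, bc = a - a.mean(), b - b.mean()
        return float((ac * bc).sum() / np.sqrt((ac**2).sum() * (bc**2).sum()))

    r_obs = corr(xr, yr)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(corr(xr, rng.permutation(yr))) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm)


def variable_heatmap_prep(
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, Dendrogram]:
    """Row-z-scored variable matrix plus a Ward/Spearman variable dendrogram.

    ``features`` is samples x variables; the returned matrix is variables x
    samples with each variable row scaled to mean 0, sd 1.  Variables are
    clustered with Ward (ward.D2) on 1 - Spearman correlation distance.
    """
    if features.shape[1] < 2 or features.shape[0] < 3:
        raise ValueError("need >= 2 variables and >= 3 samples")
    mat = features.to_numpy(dtype=float).T  # variables x samples
    names = [str(c) for c in features.columns]
    sds = mat.std(axis=1, ddof=0)
    bad = np.where(sds == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance variable(s): {[names[i] for i in bad]}")
    z = (mat - mat.mean(axis=1, keepdims=True)) / sds[:, None]
    zdf = pd.DataFrame(z, index=names, columns=[str(i) for i in features.index])

    ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    rho = np.corrcoef(ranks)
    d = np.clip(1.0 - rho, 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform((d + d.T) / 2.0, checks=False), method="ward")
    return zdf, Dendrogram(linkage=Z, labels=tuple(names))
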