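"""Six-method comparison harness, group pattern maps, and paired statistics.

The six methods cross three feature selectors — sparse PLS z-score (SP),
plain PLS z-score (P), GLM t-test (G) — with two classifiers: the PLS argmax
classifier (PLSR) and a one-vs-one voting ensemble of binary linear SVMs
(SVM).  For each simulated subject, run 1 trains the selector and the
classifier; run 2 is scored.  Accuracies are compared across methods with
Wilcoxon signed-rank tests, and group-level voxel patterns come from
one-sample t maps thresholded at the voxel level with a cluster-size cut.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from . import decoding
from .pls import PLSRegressor, dummy_code, select_n_components
from .sparse import SparsePLSRegressor, tune_lambda
from .simulator import REST, SimulatedStudy, build_regressors

__all__ = [
    "MethodSpec",
    "METHODS",
    "OneVsOneVotingClassifier",
    "one_vs_one_vote",
    "fit_selector",
    "run_subject",
    "group_pattern_map",
    "compare_methods",
    "run_experiment",
    "ExperimentResult",
]

SELECTORS = ("splsr_z", "plsr_z", "glm_t")
CLASSIFIERS = ("plsr_argmax", "svm_vote")

_NAME = {
    ("splsr_z", "plsr_argmax"): "SP_PLSR",
    ("plsr_z", "plsr_argmax"): "P_PLSR",
    ("glm_t", "plsr_argmax"): "G_PLSR",
    ("splsr_z", "svm_vote"): "SP_SVM",
    ("plsr_z", "svm_vote"): "P_SVM",
    ("glm_t", "svm_vote"): "G_SVM",
}


@dataclass(frozen=True)
class MethodSpec:
    """A (selector, classifier) pair; the name is determined by the pair."""

    selector: str
    classifier: str

    def __post_init__(self):
        if (self.selector, self.classifier) not in _NAME:
            raise ValueError(
                f"unknown method ({self.selector}, {self.classifier})"
            )

    @property
    def name(self) -> str:
        return _NAME[(self.selector, self.classifier)]


METHODS = [MethodSpec(s, c) for s in SELECTORS for c in CLASSIFIERS]


def one_vs_one_vote(pair_predictions: dict, classes) -> np.ndarray:
    """Majority vote over all q(q-1)/2 pairwise decisions.

    Parameters
    ----------
    pair_predictions : dict mapping (class_a, class_b) -> (n,) array of
        predicted labels (each entry one of the pair).
    classes : ordered class labels.

    Vote ties go to the smallest class index (by position in ``classes``).
    """
    classes = list(classes)
    expected = set(itertools.combinations(range(len(classes)), 2))
    got = {
        (classes.index(a), classes.index(b)) for a, b in pair_predictions.keys()
    }
    got = {tuple(sorted(p)) for p in got}
    if got != expected:
        raise ValueError(
            f"missing pairwise decisions: {sorted(expected - got)}"
        )
    n = len(next(iter(pair_predictions.values())))
    votes = np.zeros((n, len(classes)), dtype=int)
    for (_, _), preds in pair_predictions.items():
        for ci, c in enumerate(classes):
            votes[:, ci] += np.asarray(preds) == c
    return np.asarray(classes)[np.argmax(votes, axis=1)]  # first max = lowest index


class OneVsOneVotingClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-one ensemble of binary linear SVMs with simple vote aggregation.

    Each of the q(q-1)/2 binary problems gets its own linear-kernel SVM whose
    regularization constant ``C`` is chosen by stratified cross-validation on
    the training pair.  Final labels come from :func:`one_vs_one_vote`.
    """

    def __init__(self, c_grid=(0.01, 0.1, 1.0, 10.0, 100.0), cv: int = 5,
                 random_state: int = 0):
        self.c_grid = c_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.estimators_ = {}
        for a, b in itertools.combinations(self.classes_, 2):
            sel = (y == a) | (y == b)
            Xp, yp = X[sel], y[sel]
            folds = min(self.cv, int(np.bincount((yp == b).astype(int)).min()))
            svm = SVC(kernel="linear")
            if folds >= 2 and len(self.c_grid) > 1:
                gs = GridSearchCV(
                    svm,
                    {"C": list(self.c_grid)},
                    cv=StratifiedKFold(
                        n_splits=folds, shuffle=True,
                        random_state=self.random_state,
                    ),
                )
                gs.fit(Xp, yp)
                self.estimators_[(a, b)] = gs.best_estimator_
            else:
                self.estimators_[(a, b)] = svm.set_params(C=1.0).fit(Xp, yp)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pair_preds = {
            pair: est.predict(X) for pair, est in self.estimators_.items()
        }
        return one_vs_one_vote(pair_preds, self.classes_)


def fit_selector(
    selector: str,
    train_norm,
    train_labels: np.ndarray,
    regressors: np.ndarray,
    seed: int = 0,
    z_threshold: float = decoding.Z_THRESHOLD,
    glm_alpha: float = decoding.GLM_ALPHA,
    lambda_grid=None,
    cv_folds: int = 5,
):
    """Fit one feature selector on the (normalized) training run only.

    PLS-based selectors fit on the task volumes (rest excluded); the GLM fits
    on the full run against the HRF-convolved task regressors.

    Returns
    -------
    mask : FeatureMask
    info : dict with the fitted hyper-parameters (K, lambda).
    """
    X = train_norm.values if hasattr(train_norm, "values") else np.asarray(train_norm)
    task = train_labels != REST
    Xt, yt = X[task], train_labels[task]
    q = int(yt.max())
    info: dict = {}
    if selector in ("plsr_z", "splsr_z"):
        k, _ = select_n_components(Xt, yt, folds=cv_folds, seed=seed)
        info["n_components"] = k
        Y = dummy_code(yt, q)
        if selector == "splsr_z":
            lam, _ = tune_lambda(
                Xt, yt, n_components=k, lambda_grid=lambda_grid,
                folds=cv_folds, seed=seed,
            )
            info["lambda"] = lam
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                model = SparsePLSRegressor(n_components=k, alpha=lam).fit(Xt, Y)
        else:
            model = PLSRegressor(n_components=k).fit(Xt, Y)
        mask = decoding.select_features_z(
            model.coef_, threshold=z_threshold, selector_name=selector
        )
        info["coef"] = model.coef_
    elif selector == "glm_t":
        t, df = decoding.glm_t_maps(X, regressors)
        mask = decoding.select_features_glm(t, df, alpha=glm_alpha)
        info["t_maps"] = t
        info["df"] = df
    else:
        raise ValueError(f"unknown selector {selector!r}")
    return mask, info


def _train_classifier(classifier, Xtr_masked, ytr, seed):
    if classifier == "plsr_argmax":
        return decoding.PLSTaskClassifier(
            n_components="cv", random_state=seed
        ).fit(Xtr_masked, ytr)
    if classifier == "svm_vote":
        return OneVsOneVotingClassifier(random_state=seed).fit(Xtr_masked, ytr)
    raise ValueError(f"unknown classifier {classifier!r}")


def run_subject(
    train_run,
    test_run,
    train_labels,
    test_labels,
    method: MethodSpec,
    regressors_train: np.ndarray,
    tasks=None,
    seed: int = 0,
    mask=None,
    **selector_kw,
) -> decoding.DecodingResult:
    """Train on run 1, score on run 2 for one method; no test-set leakage.

    ``tasks`` restricts to a subset (two-/three-class problems); ``mask`` can
    inject a precomputed FeatureMask (selector then skipped).
    """
    train_norm = (
        train_run
        if isinstance(train_run, decoding.NormalizedRun)
        else decoding.normalize_run(train_run)
    )
    test_norm = (
        test_run
        if isinstance(test_run, decoding.NormalizedRun)
        else decoding.normalize_run(test_run)
    )
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)

    info = {}
    if mask is None:
        mask, info = fit_selector(
            method.selector, train_norm, train_labels, regressors_train,
            seed=seed, **selector_kw,
        )
    if tasks is None:
        tasks = sorted(set(train_labels.tolist()) - {REST})
    tr_sel = np.isin(train_labels, tasks)
    te_sel = np.isin(test_labels, tasks)
    Xtr = mask.apply(train_norm.values[tr_sel])
    Xte = mask.apply(test_norm.values[te_sel])
    clf = _train_classifier(method.classifier, Xtr, train_labels[tr_sel], seed)
    pred = clf.predict(Xte)
    return decoding.score(
        pred,
        test_labels[te_sel],
        method=method.name,
        tasks=tuple(tasks),
        n_features=mask.size,
        **{k: v for k, v in info.items() if np.isscalar(v)},
    )


def group_pattern_map(
    subject_maps: np.ndarray,
    voxel_p: float = 0.001,
    min_cluster: int = 25,
    connectivity: int = 8,
):
    """One-sample t map across subjects with cluster-size thresholding.

    Voxels with one-sided p < ``voxel_p`` (positive effect) are kept, then
    connected components with size strictly greater than ``min_cluster``
    survive (8-neighbour connectivity in 2-D by default).

    Returns a dict with keys ``t`` (per-voxel t map), ``mask`` (surviving
    voxels), ``n_clusters``.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("expected (n_subjects, H, W) maps")
    if maps.shape[0] < 2:
        raise ValueError("need at least two subjects")
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    p = stats.t.sf(t, df=n - 1)
    supra = p < voxel_p
    structure = (
        np.ones((3, 3), dtype=bool)
        if connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, n_comp = ndimage.label(supra, structure=structure)
    keep = np.zeros_like(supra)
    kept = 0
    for comp in range(1, n_comp + 1):
        sel = labels == comp
        if sel.sum() > min_cluster:  # strictly greater: a 25-voxel cluster dies
            keep |= sel
            kept += 1
    return {"t": t, "mask": keep, "n_clusters": kept}


def compare_methods(table: pd.DataFrame, pairs, alpha: float = 0.05) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank comparisons of per-subject accuracies.

    ``table`` needs columns subject, method, accuracy (plus optional cnr /
    subset columns, which must already be filtered to one cell).  Zeros are
    dropped (classic Wilcoxon); tests are two-sided.
    """
    rows = []
    for a, b in pairs:
        ta = table[table["method"] == a].sort_values("subject")
        tb = table[table["method"] == b].sort_values("subject")
        if len(ta) != len(tb) or not np.array_equal(
            ta["subject"].to_numpy(), tb["subject"].to_numpy()
        ):
            raise ValueError(f"unequal pairing for ({a}, {b})")
        if len(ta) < 2:
            raise ValueError("need at least two paired subjects")
        diff = ta["accuracy"].to_numpy() - tb["accuracy"].to_numpy()
        if np.all(diff == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(diff, zero_method="wilcox", mode="auto")
        rows.append(
            {
                "method_a": a,
                "method_b": b,
                "n": len(ta),
                "median_diff": float(np.median(diff)),
                "statistic": float(stat),
                "p_value": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def selector_recovery(mask, layout) -> dict:
    """Score a feature mask against the simulator's ground-truth ROIs.

    Returns the per-task Jaccard index of the task-j selected voxels against
    the task-j ROI (shared ROI excluded), its mean over tasks, and the hit
    rate inside the shared ROI (fraction of shared-ROI voxels selected for at
    least one task).
    """
    jaccards = []
    for j in range(1, layout.n_tasks + 1):
        roi = set(layout.flat_task_indices(j).tolist())
        sel = set(mask.per_task_sources.get(j, np.array([], dtype=int)).tolist())
        inter = len(roi & sel)
        union = len(roi | sel)
        jaccards.append(inter / union if union else 0.0)
    shared = layout.flat_shared_indices()
    hit = np.isin(shared, mask.voxel_indices).mean()
    return {
        "jaccard_mean": float(np.mean(jaccards)),
        "jaccard_min": float(np.min(jaccards)),
        "shared_hit_rate": float(hit),
    }


@dataclass
class ExperimentResult:
    """Factorial accuracy table plus the configuration that produced it."""

    table: pd.DataFrame
    config: dict
    selector_table: pd.DataFrame | None = None

    def mean_table(self) -> pd.DataFrame:
        return (
            self.table.groupby(["method", "cnr"])["accuracy"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def run_experiment(
    study: SimulatedStudy,
    methods=None,
    tasks=None,
    seed: int = 0,
    progress: bool = False,
) -> ExperimentResult:
    """Full factorial: every subject x CNR x method, train run 1 / test run 2.

    Selector masks are fitted once per (subject, CNR) and shared by the two
    classifiers that use the same selector.  Failed cells (no features
    selected) are recorded with accuracy NaN rather than crashing.
    """
    methods = list(methods) if methods is not None else list(METHODS)
    rows = []
    selector_rows = []
    for ci, cnr in enumerate(study.cnr_levels):
        for subject in range(study.n_subjects):
            cell_seed = abs(hash((seed, ci, subject))) % (2**31)
            ds = study.dataset(cnr, subject)
            (train, ytr), (test, yte) = ds.runs
            train_norm = decoding.normalize_run(train)
            test_norm = decoding.normalize_run(test)
            regs = build_regressors(ds.paradigms[0])
            masks = {}
            for sel in sorted({m.selector for m in methods}):
                srow = {"cnr": cnr, "subject": subject, "selector": sel}
                try:
                    masks[sel], info = fit_selector(
                        sel, train_norm, ytr, regs, seed=cell_seed
                    )
                    srow.update(
                        n_features=masks[sel].size,
                        **{k: v for k, v in info.items() if np.isscalar(v)},
                    )
                    srow.update(selector_recovery(masks[sel], study.layout))
                except decoding.NoFeaturesError:
                    masks[sel] = None
                    srow.update(n_features=0, error="no_features")
                selector_rows.append(srow)
            for method in methods:
                row = {
                    "cnr": cnr,
                    "subject": subject,
                    "method": method.name,
                    "selector": method.selector,
                    "classifier": method.classifier,
                    "subset": "all" if tasks is None else "+".join(map(str, tasks)),
                }
                if masks[method.selector] is None:
                    row.update(accuracy=np.nan, n_features=0, error="no_features")
                else:
                    res = run_subject(
                        train_norm, test_norm, ytr, yte, method, regs,
                        tasks=tasks, seed=cell_seed, mask=masks[method.selector],
                    )
                    row.update(
                        accuracy=res.accuracy,
                        n_correct=res.n_correct,
                        n_total=res.n_total,
                        n_features=masks[method.selector].size,
                    )
                rows.append(row)
            if progress:  # pragma: no cover
                print(f"cnr={cnr} subject={subject} done", flush=True)
    table = pd.DataFrame(rows)
    config = {
        "cnr_levels": list(study.cnr_levels),
        "n_subjects": study.n_subjects,
        "shape": list(study.shape),
        "sigma": study.sigma,
        "seed": seed,
        "study_seed": study.seed,
        "methods": [m.name for m in methods],
    }
    return ExperimentResult(
        table=table, config=config, selector_table=pd.DataFrame(selector_rows)
    )
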