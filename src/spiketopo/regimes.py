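"""Regime-labelled feature datasets and SVM classification.

Each simulation contributes one sample: the 4 Betti-curve features per
dissimilarity measure, plus two baseline descriptors (mean network
activity per neuron per step, and the temporal variance of the
population rate).  Samples are labelled by the control parameter:
super-critical for g < g_c, critical at g = g_c, sub-critical for
g > g_c.

Three classification tasks are evaluated with an RBF-kernel,
L2-regularized SVM (regularization strength selected by stratified
10-fold cross-validation on the training portion):

1. super-critical vs sub-critical (critical samples discarded);
2. all three regimes;
3. critical vs non-critical (super and sub merged).

"Mean accuracy" is the mean test accuracy over repeated stratified
80/20 train/test splits (20 by default), with fresh hyperparameter
selection in every repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.model_selection import GridSearchCV, StratifiedKFold, StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dissimilarity import compute_dissimilarity
from .homology import features_from_matrix
from .network import NetworkParams, simulate
from .synthetic import ExperimentConfig
from .trains import raster_to_trains

__all__ = [
    "LABELS", "C_GRID", "RegimeSample", "ClassificationResult",
    "simulate_sample", "build_dataset", "train_eval", "feature_trend_report",
    "feature_columns",
]

LABELS = ("super_critical", "critical", "sub_critical")
C_GRID = (1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
TASKS = {1: "super vs sub", 2: "three regimes", 3: "critical vs non-critical"}


def regime_label(g: float, g_critical: float = 1.5, tol: float = 1e-9) -> str:
    if abs(g - g_critical) <= tol:
        return "critical"
    return "super_critical" if g < g_critical else "sub_critical"


@dataclass
class RegimeSample:
    g: float
    label: str
    topo: dict[str, float]          # "{measure}_f{k}" -> value
    baseline: dict[str, float]      # mean_activity, activity_variance
    sim_seed: int

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"g": self.g, "label": self.label,
                                       "sim_seed": self.sim_seed}
        row.update(self.baseline)
        row.update(self.topo)
        return row


@dataclass
class ClassificationResult:
    task: int
    feature_set: tuple[str, ...]
    per_split: np.ndarray
    chosen_C: list[float] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_split))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.per_split, ddof=1)) if self.per_split.size > 1 else 0.0

    @property
    def n_repeats(self) -> int:
        return int(self.per_split.size)

    def summary(self) -> str:
        feats = ", ".join(self.feature_set)
        return (f"task {self.task} ({TASKS[self.task]}) | features: {feats} | "
                f"mean accuracy {100 * self.mean_accuracy:.2f}% "
                f"(sd {100 * self.std_accuracy:.2f}%, {self.n_repeats} splits)")


def feature_columns(measures, features=(1, 2, 3, 4)) -> list[str]:
    return [f"{m}_f{k}" for m in measures for k in features]


def simulate_sample(g: float, config: ExperimentConfig, sim_index: int) -> RegimeSample:
    """Run one simulation and reduce it to its feature vector.

    All randomness (simulation, vertex subsampling) flows from
    (master_seed, sim_index) through a single SeedSequence.
    """
    ss = np.random.SeedSequence([config.master_seed, sim_index])
    sim_ss, cap_ss = ss.spawn(2)
    params = NetworkParams(N=config.N, p=config.p, q=config.q, J=config.J,
                           g=g, Gamma=config.Gamma, mu=config.mu,
                           theta=config.theta, I_ext=config.I_ext,
                           seed=sim_index)
    raster = simulate(params, T_total=config.T_total,
                      T_transient=config.T_transient,
                      rng=np.random.default_rng(sim_ss))
    rate = raster.activity() / config.N
    baseline = {"mean_activity": float(rate.mean()),
                "activity_variance": float(rate.var())}
    topo: dict[str, float] = {}
    if config.measures:
        trains = raster_to_trains(raster)
        cap_rng = np.random.default_rng(cap_ss)
        for measure in config.measures:
            Dm = compute_dissimilarity(trains, measure, bin_ms=config.bin_ms,
                                       vertex_cap=config.vertex_cap,
                                       rng=np.random.default_rng(cap_rng.integers(2**31)))
            feats = features_from_matrix(Dm, eps_max=config.eps_max)
            for key, val in feats.as_dict().items():
                topo[f"{measure}_{key}"] = val
    return RegimeSample(g=g, label=regime_label(g, config.g_critical),
                        topo=topo, baseline=baseline, sim_seed=sim_index)


def build_dataset(config: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """One row per simulation over the g grid plus the critical replicates."""
    rows = []
    plan = config.simulation_plan()
    for sim_index, (g, _rep) in enumerate(plan):
        sample = simulate_sample(g, config, sim_index)
        rows.append(sample.as_row())
        if progress and (sim_index + 1) % 25 == 0:
            print(f"  simulated {sim_index + 1}/{len(plan)}", flush=True)
    return pd.DataFrame(rows)


def _task_subset(df: pd.DataFrame, task: int) -> tuple[pd.DataFrame, np.ndarray]:
    if task == 1:
        sub = df[df["label"] != "critical"]
        y = sub["label"].to_numpy()
    elif task == 2:
        sub = df
        y = sub["label"].to_numpy()
    elif task == 3:
        sub = df
        y = np.where(sub["label"] == "critical", "critical", "non_critical")
    else:
        raise ValueError("task must be 1, 2 or 3")
    if len(np.unique(y)) < 2:
        raise ValueError("task is degenerate: fewer than 2 classes present")
    return sub, y


def _median_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """Median heuristic for the RBF width on (standardized) training data."""
    if X.shape[0] > 500:
        X = X[rng.choice(X.shape[0], 500, replace=False)]
    med = np.median(pdist(X, metric="sqeuclidean"))
    return 1.0 / med if med > 0 else 1.0 / max(X.shape[1], 1)


def train_eval(df: pd.DataFrame, task: int, feature_set, repeats: int = 20,
               seed: int = 0, C_grid=C_GRID) -> ClassificationResult:
    """Repeated stratified 80/20 evaluation of the RBF SVM.

    Standardization statistics and the CV-selected regularization strength
    come from the training portion only.
    """
    feature_set = tuple(feature_set)
    sub, y = _task_subset(df, task)
    X = sub.loc[:, list(feature_set)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    splitter = StratifiedShuffleSplit(n_splits=repeats, test_size=0.2,
                                      random_state=seed)
    accs, chosen = [], []
    for split_i, (tr, te) in enumerate(splitter.split(X, y)):
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        gamma = _median_gamma(Xtr, rng)
        # 10-fold CV, clamped when a training class is rarer than the folds
        # (micro runs); below 2 usable folds the grid search is skipped.
        min_count = min(np.unique(y[tr], return_counts=True)[1])
        n_folds = min(10, int(min_count))
        if n_folds >= 2:
            cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                 random_state=seed + split_i)
            model = GridSearchCV(SVC(kernel="rbf", gamma=gamma),
                                 {"C": list(C_grid)}, cv=cv, n_jobs=1)
            model.fit(Xtr, y[tr])
            chosen.append(float(model.best_params_["C"]))
        else:
            model = SVC(kernel="rbf", gamma=gamma, C=1.0).fit(Xtr, y[tr])
            chosen.append(1.0)
        accs.append(float(model.score(Xte, y[te])))
    return ClassificationResult(task=task, feature_set=feature_set,
                                per_split=np.asarray(accs), chosen_C=chosen)


def feature_trend_report(df: pd.DataFrame, feature_cols=None) -> pd.DataFrame:
    """Replicate mean and standard deviation of every feature at every g.

    Long format: one row per (g, feature) with columns g, feature, mean, sd,
    n — the table behind the feature-vs-g panels.
    """
    if feature_cols is None:
        feature_cols = [c for c in df.columns
                        if c not in ("g", "label", "sim_seed")]
    counts = df.groupby("g").size()
    if counts.min() < 2:
        raise ValueError("need >= 2 replicates per g for a trend report")
    rows = []
    grouped = df.groupby("g")
    for col in feature_cols:
        agg = grouped[col].agg(["mean", "std", "size"])
        for g, rec in agg.iterrows():
            rows.append({"g": float(g), "feature": col, "mean": rec["mean"],
                         "sd": rec["std"], "n": int(rec["size"])})
    return pd.DataFrame(rows).sort_values(["feature", "g"], ignore_index=True)
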