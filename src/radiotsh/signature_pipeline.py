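"""Radiogenomic signature modelling: collinearity pruning, genetic-algorithm
feature selection under cross-validation, random-forest classification of the
TSH group, ROC analysis, and prognostic validation of the imaging signature.

The imaging "TSH score" of a patient is the random forest's predicted
probability of the poor-survival class; thresholding it (default 0.5)
assigns the predicted group, whose prognostic value is then tested with
log-rank, adjusted Cox and likelihood-ratio statistics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from radiotsh import tsh_stats

POS_LABEL = "poor"  # higher score = poorer predicted survival


def prune_collinear(table: pd.DataFrame, r_max: float = 0.8) -> pd.DataFrame:
    """Greedy removal of collinear feature columns.

    While any pair has \\|Pearson r\\| > ``r_max``, the member of the worst
    pair with the larger mean absolute correlation to all other features is
    dropped (ties broken lexicographically by name).  The result contains
    no pair exceeding the threshold.
    """
    if table.shape[1] < 2:
        return table.copy()
    cols = list(table.columns)
    corr = table.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    corr = corr.fillna(0.0)
    dropped: list[str] = []
    while True:
        sub = corr.loc[cols, cols]
        worst = sub.to_numpy().max()
        if worst <= r_max:
            break
        a_idx, b_idx = np.unravel_index(sub.to_numpy().argmax(), sub.shape)
        a, b = cols[a_idx], cols[b_idx]
        mean_a, mean_b = sub[a].mean(), sub[b].mean()
        if mean_a > mean_b:
            victim = a
        elif mean_b > mean_a:
            victim = b
        else:
            victim = max(a, b)
        cols.remove(victim)
        dropped.append(victim)
        if len(cols) < 2:
            break
    return table[cols].copy()


def roc_auc(scores, labels, pos_label: str = POS_LABEL):
    """AUC by the trapezoidal rule over all thresholds, plus the ROC curve.

    Returns (auc, fpr, tpr, thresholds).  The AUC equals the normalized
    Mann-Whitney U statistic (concordant-pair fraction, ties counted 1/2).
    """
    y = np.asarray(pd.Series(labels) == pos_label, dtype=int)
    if y.min() == y.max():
        raise ValueError("need both classes to compute a ROC curve")
    fpr, tpr, thresholds = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr, thresholds


def sensitivity_specificity(scores, labels, threshold: float, pos_label: str = POS_LABEL):
    """Sensitivity and specificity of ``score >= threshold`` for the positive class."""
    y = np.asarray(pd.Series(labels) == pos_label, dtype=bool)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    sens = float((pred & y).sum() / y.sum())
    spec = float((~pred & ~y).sum() / (~y).sum())
    return sens, spec


def youden_threshold(scores, labels, pos_label: str = POS_LABEL) -> float:
    """Score threshold maximizing sensitivity + specificity - 1."""
    _, fpr, tpr, thr = roc_auc(scores, labels, pos_label)
    return float(thr[np.argmax(tpr - fpr)])


@dataclass
class GAConfig:
    """Genetic-algorithm feature-selection settings.

    The published workflow ran a population of 100 for 100 generations
    under tenfold cross-validation; smaller settings are appropriate for
    simulation studies.
    """

    population_size: int = 100
    generations: int = 100
    cv_folds: int = 10
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # defaults to 1 / n_features
    tournament_size: int = 3
    elitism: int = 1
    n_estimators: int = 100  # trees per random-forest fitness evaluation
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.population_size, self.generations, self.cv_folds) <= 0:
            raise ValueError("population_size, generations and cv_folds must be > 0")


@dataclass
class SignatureModel:
    """A trained radiogenomic signature: feature subset + classifier."""

    features: list[str]
    classifier: RandomForestClassifier
    threshold: float = 0.5
    seed: int = 0
    config_hash: str = ""

    def predict_score(self, table: pd.DataFrame) -> pd.Series:
        """Imaging TSH score: predicted probability of the poor class."""
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise KeyError(f"feature table lacks {missing[:5]}")
        proba = self.classifier.predict_proba(table[self.features].to_numpy(dtype=float))
        pos = list(self.classifier.classes_).index(POS_LABEL)
        return pd.Series(proba[:, pos], index=table.index, name="tsh_score")


def _check_labels(labels: pd.Series) -> pd.Series:
    labels = pd.Series(labels)
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ValueError(f"need exactly two classes, got {list(counts.index)}")
    return labels


def _cv_auc(
    x: np.ndarray, y: np.ndarray, cv_folds: int, n_estimators: int, seed: int
) -> float:
    """Mean out-of-fold AUC of a random forest over stratified folds."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(x, y):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        clf.fit(x[tr], y[tr])
        pos = list(clf.classes_).index(1)
        s = clf.predict_proba(x[te])[:, pos]
        fpr, tpr, _ = roc_curve(y[te], s)
        aucs.append(float(np.trapezoid(tpr, fpr)))
    return float(np.mean(aucs))


def ga_select(
    table: pd.DataFrame, labels: pd.Series, config: GAConfig
) -> tuple[list[str], list[float]]:
    """Binary-mask genetic algorithm maximizing mean cross-validated AUC.

    Tournament selection, uniform crossover, per-bit flip mutation and
    single-individual elitism; fitness values are cached per chromosome so
    the elite is never re-evaluated.  Returns the best feature subset and
    the elite-fitness trajectory (non-decreasing by construction).
    """
    labels = _check_labels(labels)
    x_all = table.to_numpy(dtype=float)
    y = (labels == POS_LABEL).to_numpy(dtype=int)
    n_feat = x_all.shape[1]
    min_class = min(np.bincount(y))
    if min_class < config.cv_folds:
        raise ValueError(
            f"smallest class ({min_class}) cannot fill {config.cv_folds} folds"
        )
    rng = np.random.default_rng(config.seed)
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_feat

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            if not mask.any():
                cache[key] = 0.0
            else:
                cache[key] = _cv_auc(
                    x_all[:, mask], y, config.cv_folds, config.n_estimators, config.seed
                )
        return cache[key]

    pop = rng.random((config.population_size, n_feat)) < 0.5
    for chrom in pop:  # guarantee non-empty chromosomes
        if not chrom.any():
            chrom[rng.integers(n_feat)] = True

    fits = np.array([fitness(c) for c in pop])
    trajectory = [float(fits.max())]
    for _ in range(config.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[: config.elitism]]
        while len(new_pop) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size, config.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(n_feat) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                flip = rng.random(n_feat) < mut_rate
                child ^= flip
                if not child.any():
                    child[rng.integers(n_feat)] = True
                if len(new_pop) < config.population_size:
                    new_pop.append(child)
        pop = np.array(new_pop)
        fits = np.array([fitness(c) for c in pop])
        trajectory.append(float(fits.max()))

    best = pop[int(np.argmax(fits))]
    return [c for c, keep in zip(table.columns, best) if keep], trajectory


def train_classifier(
    table: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    *,
    features: list[str] | None = None,
    n_estimators: int = 300,
    threshold: float = 0.5,
) -> SignatureModel:
    """Fit the random-forest signature classifier on the selected features."""
    labels = _check_labels(labels)
    features = list(features) if features is not None else list(table.columns)
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(table[features].to_numpy(dtype=float), labels.to_numpy())
    cfg = hashlib.sha256(
        ("|".join(features) + f"|{seed}|{n_estimators}").encode()
    ).hexdigest()[:12]
    return SignatureModel(features, clf, threshold, seed, cfg)


@dataclass
class TumorOnlyModelResult:
    model: SignatureModel
    cv_auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    sensitivity: float
    specificity: float
    oof_scores: pd.Series = field(repr=False, default=None)


def _oof_scores(
    table: pd.DataFrame, y: np.ndarray, features: list[str], cv_folds: int, seed: int,
    n_estimators: int = 300,
) -> np.ndarray:
    x = table[features].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    for tr, te in skf.split(x, y):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        clf.fit(x[tr], y[tr])
        pos = list(clf.classes_).index(1)
        oof[te] = clf.predict_proba(x[te])[:, pos]
    return oof


def tumor_only_tsh_model(
    abundances: pd.DataFrame,
    tsh_groups: pd.Series,
    seed: int = 0,
    *,
    cv_folds: int = 10,
    min_gain: float = 1e-3,
) -> TumorOnlyModelResult:
    """Predict the TSH group from tumor-derived cell abundances alone.

    Greedy forward selection over the ten abundance features maximizes the
    mean cross-validated AUC of a random forest; selection stops when no
    candidate improves the AUC by at least ``min_gain``.  Sensitivity and
    specificity are reported at the Youden-optimal threshold of the
    out-of-fold scores.
    """
    groups = _check_labels(tsh_groups).reindex(abundances.index)
    y = (groups == POS_LABEL).to_numpy(dtype=int)
    selected: list[str] = []
    best_auc = 0.0
    remaining = list(abundances.columns)
    x_all = abundances.to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(abundances.columns)}
    while remaining:
        scores = {}
        for cand in remaining:
            mask = [col_idx[c] for c in selected + [cand]]
            scores[cand] = _cv_auc(x_all[:, mask], y, cv_folds, 100, seed)
        cand = max(sorted(scores), key=scores.get)
        if scores[cand] < best_auc + min_gain:
            break
        best_auc = scores[cand]
        selected.append(cand)
        remaining.remove(cand)
    if not selected:
        selected = [max(sorted(scores), key=scores.get)]
        best_auc = scores[selected[0]]

    oof = _oof_scores(abundances, y, selected, cv_folds, seed)
    auc, fpr, tpr, _ = roc_auc(oof, groups)
    thr = youden_threshold(oof, groups)
    sens, spec = sensitivity_specificity(oof, groups, thr)
    model = train_classifier(abundances, groups, seed, features=selected)
    return TumorOnlyModelResult(
        model, auc, fpr, tpr, sens, spec, pd.Series(oof, index=abundances.index)
    )


_RECEPTOR_CODES = {"positive": 1.0, "negative": 0.0, "missing": 0.5}


def _encode_clinical(survival: pd.DataFrame, covariates) -> pd.DataFrame:
    out = survival[["time", "event"]].copy()
    for cov in covariates:
        col = survival[cov]
        if col.dtype == object:
            out[cov] = col.map(_RECEPTOR_CODES).fillna(0.5)
        else:
            out[cov] = col.astype(float)
    return out


@dataclass
class PrognosisReport:
    km_curves: dict[str, pd.DataFrame]
    logrank_statistic: float
    logrank_p: float
    cox_table: pd.DataFrame
    signature_hr: float
    lr_statistic: float
    lr_p: float
    groups: pd.Series


def validate_prognosis(
    model: SignatureModel,
    features: pd.DataFrame,
    survival: pd.DataFrame,
    threshold: float | None = None,
    covariates=("age", "her2", "er", "pr", "tumor_size_mm"),
    horizon_years: float = tsh_stats.CENSOR_HORIZON_YEARS,
) -> PrognosisReport:
    """Prognostic validation of an imaging signature against follow-up data.

    Patients are split at the score threshold (default: the model's own,
    0.5), compared by Kaplan-Meier / log-rank, and the signature group is
    tested in a Cox model adjusted for the clinical covariates; a
    likelihood-ratio test compares the adjusted model against the
    clinical-covariates-only model.
    """
    threshold = model.threshold if threshold is None else threshold
    common = features.index.intersection(survival.index)
    if len(common) == 0:
        raise ValueError("no shared patient ids between features and survival")
    scores = model.predict_score(features.loc[common])
    groups = pd.Series(
        np.where(scores >= threshold, "poor", "good"), index=common, name="group"
    )
    records = tsh_stats.censor_at(survival.loc[common], horizon_years)

    curves = tsh_stats.km_curve(records, groups)
    lr_stat, lr_p_logrank = tsh_stats.logrank_test(records, groups)

    clin = _encode_clinical(records, covariates)
    clin["signature_poor"] = (groups == "poor").astype(float)
    full_table, ll_full = tsh_stats.cox_fit(clin, [*covariates, "signature_poor"])
    _, ll_null = tsh_stats.cox_fit(clin.drop(columns="signature_poor"), list(covariates))
    stat, p = tsh_stats.lr_test(ll_null, ll_full, 1)

    return PrognosisReport(
        km_curves=curves,
        logrank_statistic=lr_stat,
        logrank_p=lr_p_logrank,
        cox_table=full_table,
        signature_hr=float(full_table.loc["signature_poor", "hr"]),
        lr_statistic=stat,
        lr_p=p,
        groups=groups,
    )
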