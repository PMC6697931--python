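"""Query-independent document classifiers.

Three supervised tasks drive the ranking layer:

* ``cancer``  — is the document about cancer at all?
* ``clinical`` — does it carry clinically relevant information
  (drug-variant associations, trials, treatment reports) rather than
  basic science?
* ``ctype``   — which cancer type is discussed (melanoma, head and neck,
  colorectal, or a catch-all "general cancer")?

Training data is a silver standard: positives come from a curated
variant-interpretation resource (every record is clinically relevant by
construction; the few records with a non-cancer disease annotation
become cancer-negatives), negatives are abstracts sampled from the
literature after excluding anything containing a cancer-related term.

Features are word n-gram tf-idf vectors with chi-square feature
selection; learners are a linear-kernel SVM and a random forest, tuned
by seeded randomized search under 5-fold cross-validation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from scipy.stats import loguniform
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.preprocessing import normalize as l2_normalize
from sklearn.svm import LinearSVC

from .corpus_io import Document

TASKS = ("cancer", "clinical", "ctype")
LEARNERS = ("linear_svm", "random_forest")
CANCER_TYPES = ("melanoma", "head_and_neck", "colorectal", "general_cancer")
CTYPE_NONE = "none"

_NAMED_TYPES = {
    "melanoma": "melanoma",
    "head_and_neck": "head_and_neck",
    "head_and_neck_cancer": "head_and_neck",
    "colorectal": "colorectal",
    "colorectal_cancer": "colorectal",
}


def map_cancer_type(raw: str | None) -> str:
    """Map a free-text cancer-type annotation onto the four type classes.

    The three named types are kept; every other cancer type is folded
    into ``general_cancer``.
    """
    if raw is None or not raw.strip():
        return "general_cancer"
    key = re.sub(r"[\s\-]+", "_", raw.strip().lower())
    return _NAMED_TYPES.get(key, "general_cancer")


@dataclass
class DocLabels:
    cancer: bool
    clinical: bool
    ctype: str  # one of CANCER_TYPES or CTYPE_NONE

    def __post_init__(self) -> None:
        if self.ctype != CTYPE_NONE and not self.cancer:
            raise ValueError("ctype label requires cancer=+")


@dataclass
class PositiveRecord:
    """A curated clinically-relevant record: document + disease annotation."""

    doc: Document
    disease: str = ""
    cancer_type: str | None = None
    is_cancer: bool = True


@dataclass
class LabeledCorpus:
    documents: list[Document]
    labels: list[DocLabels]

    def __post_init__(self) -> None:
        if len(self.documents) != len(self.labels):
            raise ValueError("documents and labels must align")

    def __len__(self) -> int:
        return len(self.documents)

    def texts(self) -> list[str]:
        return [d.text for d in self.documents]

    def task_labels(self, task: str) -> list:
        if task == "cancer":
            return [lab.cancer for lab in self.labels]
        if task == "clinical":
            return [lab.clinical for lab in self.labels]
        if task == "ctype":
            return [lab.ctype for lab in self.labels]
        raise ValueError(f"unknown task {task!r}")

    def subset(self, idx: Sequence[int]) -> "LabeledCorpus":
        return LabeledCorpus([self.documents[i] for i in idx], [self.labels[i] for i in idx])


# ---------------------------------------------------------------------------
# Training-corpus construction
# ---------------------------------------------------------------------------

def _term_regex(terms: Iterable[str]) -> re.Pattern:
    alts = sorted({t.strip() for t in terms if t.strip()}, key=len, reverse=True)
    if not alts:
        raise ValueError("empty cancer term list")
    body = "|".join(re.escape(t) for t in alts)
    return re.compile(rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])", re.IGNORECASE)


def build_training_corpus(
    positives: Sequence[PositiveRecord],
    negative_pool: Sequence[Document],
    cancer_term_list: Iterable[str],
    n_negatives: int,
    seed: int,
) -> LabeledCorpus:
    """Assemble the silver-standard training corpus.

    Positives are all labeled clinical=+; those flagged as non-cancer get
    cancer=- and no cancer type, the rest cancer=+ with their type mapped
    through :func:`map_cancer_type`.  Negatives are a seeded uniform
    sample of pool documents whose title+abstract contain no term from
    ``cancer_term_list`` (case-insensitive, token-boundary match); they
    are labeled cancer=-, clinical=-, ctype=none.
    """
    pat = _term_regex(cancer_term_list)
    eligible = [d for d in negative_pool if not pat.search(d.text)]
    if len(eligible) < n_negatives:
        raise ValueError(
            f"negative pool too small after term filtering: "
            f"{len(eligible)} available, {n_negatives} requested"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=n_negatives, replace=False)

    documents: list[Document] = []
    labels: list[DocLabels] = []
    for rec in positives:
        documents.append(rec.doc)
        if rec.is_cancer:
            labels.append(DocLabels(cancer=True, clinical=True, ctype=map_cancer_type(rec.cancer_type)))
        else:
            labels.append(DocLabels(cancer=False, clinical=True, ctype=CTYPE_NONE))
    for i in sorted(picked.tolist()):
        documents.append(eligible[i])
        labels.append(DocLabels(cancer=False, clinical=False, ctype=CTYPE_NONE))
    return LabeledCorpus(documents, labels)


def split_train_test(
    corpus: LabeledCorpus, train_fraction: float = 0.85, seed: int = 0
) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Seeded stratified split, stratifying on the joint label triple.

    Per-stratum sizes are within one document of the exact fraction, and
    every stratum keeps at least one document on each side (hence strata
    with fewer than two documents, or degenerate fractions, are errors).
    """
    if not len(corpus):
        raise ValueError("empty corpus")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    strata: dict[tuple, list[int]] = {}
    for i, lab in enumerate(corpus.labels):
        strata.setdefault((lab.cancer, lab.clinical, lab.ctype), []).append(i)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for key in sorted(strata):
        idx = strata[key]
        if len(idx) < 2:
            raise ValueError(f"stratum {key} has {len(idx)} document(s); need >= 2")
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[p] for p in perm[:n_train])
        test_idx.extend(idx[p] for p in perm[n_train:])
    return corpus.subset(sorted(train_idx)), corpus.subset(sorted(test_idx))


# ---------------------------------------------------------------------------
# Features: tf-idf + chi-square selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    """Word n-gram tf-idf configuration.

    tf-idf uses the smoothed idf ``ln((1+N)/(1+df)) + 1`` with L2
    normalization; chi-square statistics are computed per feature from
    the document-occurrence contingency table against the task label,
    and the top ``max_features_chi2`` features are kept.
    """

    ngram_range: tuple[int, int] = (1, 2)
    max_features_chi2: int = 20_000
    min_doc_freq: int = 2
    lowercase: bool = True
    token_pattern: str = r"(?u)\b\w\w+\b"

    def __post_init__(self) -> None:
        lo, hi = self.ngram_range
        if not (1 <= lo <= hi <= 3):
            raise ValueError(f"ngram_range must satisfy 1<=min<=max<=3, got {self.ngram_range}")
        if self.max_features_chi2 < 1:
            raise ValueError("max_features_chi2 must be >= 1")


def chi2_occurrence(present: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Chi-square statistic per feature from a present/absent x class table.

    ``present`` is an (n_docs, n_features) boolean/0-1 array.  For each
    feature, a 2 x C contingency table (rows: document contains / does
    not contain the term; columns: classes) is evaluated without
    continuity correction.  Features present in no or all documents get
    statistic 0.
    """
    present = np.asarray(present, dtype=np.float64)
    classes, y_idx = np.unique(y, return_inverse=True)
    n_docs, n_feat = present.shape
    counts = np.zeros((n_feat, len(classes)))
    for c in range(len(classes)):
        counts[:, c] = present[y_idx == c].sum(axis=0)
    n_per_class = np.bincount(y_idx, minlength=len(classes)).astype(np.float64)
    f_tot = counts.sum(axis=1)  # docs containing each feature
    with np.errstate(divide="ignore", invalid="ignore"):
        e_present = np.outer(f_tot, n_per_class) / n_docs
        e_absent = np.outer(n_docs - f_tot, n_per_class) / n_docs
        o_absent = n_per_class[None, :] - counts
        chi = np.where(e_present > 0, (counts - e_present) ** 2 / e_present, 0.0).sum(axis=1)
        chi += np.where(e_absent > 0, (o_absent - e_absent) ** 2 / e_absent, 0.0).sum(axis=1)
    chi[(f_tot == 0) | (f_tot == n_docs)] = 0.0
    return chi


@dataclass
class FittedFeatures:
    """Fitted vocabulary + idf weights + chi-square-selected feature mask."""

    vectorizer: TfidfVectorizer
    mask: np.ndarray  # sorted indices of kept features
    chi2_scores: np.ndarray

    @property
    def feature_names(self) -> list[str]:
        return [self.vectorizer.get_feature_names_out()[i] for i in self.mask]

    def transform(self, texts: Sequence[str]):
        X = self.vectorizer.transform(texts)[:, self.mask]
        return l2_normalize(X, norm="l2", copy=False)


def fit_features(texts: Sequence[str], cfg: FeatureConfig, y: Sequence) -> FittedFeatures:
    """Fit tf-idf vocabulary on ``texts`` and select top-K chi-square features.

    K is capped at the vocabulary size; ties in the chi-square statistic
    break by feature index for determinism.  Transformed vectors are
    re-normalized to unit L2 norm after selection.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes to fit features")
    vec = TfidfVectorizer(
        ngram_range=cfg.ngram_range,
        min_df=cfg.min_doc_freq,
        lowercase=cfg.lowercase,
        token_pattern=cfg.token_pattern,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    try:
        X = vec.fit_transform(texts)
    except ValueError as exc:
        raise ValueError(f"empty vocabulary after min_doc_freq filtering: {exc}") from None
    present = (X > 0).toarray()
    chi = chi2_occurrence(present, y)
    k = min(cfg.max_features_chi2, X.shape[1])
    order = np.argsort(-chi, kind="stable")  # ties by ascending feature index
    mask = np.sort(order[:k])
    return FittedFeatures(vectorizer=vec, mask=mask, chi2_scores=chi)


# ---------------------------------------------------------------------------
# Task models
# ---------------------------------------------------------------------------

_SVM_SPACE = {"C": loguniform(1e-3, 1e3)}
_RF_SPACE = {
    "n_estimators": [100, 200, 300, 400, 500],
    "max_depth": [None, 10, 20],
    "min_samples_leaf": [1, 2, 5],
}

MODEL_FORMAT_TAG = "clinrank-taskmodel-v1"


@dataclass
class TaskModel:
    """A fitted classifier for one task plus its feature pipeline.

    The raw score is the signed decision value for the linear SVM and
    the positive-class vote fraction for the random forest; the raw
    range observed on the training corpus is kept as a fallback for
    normalizing scores of documents streamed outside an indexed corpus
    (corpus-wide min-max normalization lives in the ranking layer).
    """

    task: str
    learner: str
    features: FittedFeatures
    estimator: object
    raw_min: float
    raw_max: float
    best_params: dict = field(default_factory=dict)
    best_cv_score: float = float("nan")

    def raw_scores(self, texts: Sequence[str]) -> np.ndarray:
        """Raw (unnormalized) scores; binary tasks only."""
        X = self.features.transform(texts)
        if self.learner == "linear_svm":
            return np.asarray(self.estimator.decision_function(X), dtype=float)
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(True)
        return proba[:, pos]

    def predict_labels(self, texts: Sequence[str]) -> np.ndarray:
        X = self.features.transform(texts)
        return self.estimator.predict(X)

    def type_predictions(self, texts: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(label, margin) per text for the multi-class cancer-type task.

        Margin is the gap between the best and second-best class score.
        """
        X = self.features.transform(texts)
        if self.learner == "linear_svm":
            scores = np.atleast_2d(self.estimator.decision_function(X))
        else:
            scores = self.estimator.predict_proba(X)
        top = np.argsort(-scores, axis=1)
        labels = self.estimator.classes_[top[:, 0]]
        if scores.shape[1] == 1:
            margins = np.abs(scores[:, 0])
        else:
            margins = scores[np.arange(len(scores)), top[:, 0]] - scores[
                np.arange(len(scores)), top[:, 1]
            ]
        return labels, margins

    def normalize_fallback(self, raw: np.ndarray) -> np.ndarray:
        """Min-max normalize against the training-corpus range, clipped."""
        if self.raw_max == self.raw_min:
            return np.ones_like(np.asarray(raw, dtype=float))
        return np.clip((raw - self.raw_min) / (self.raw_max - self.raw_min), 0.0, 1.0)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": MODEL_FORMAT_TAG,
            "task": self.task,
            "learner": self.learner,
            "raw_min": self.raw_min,
            "raw_max": self.raw_max,
            "best_params": {k: _jsonable(v) for k, v in self.best_params.items()},
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        joblib.dump({"features": self.features, "estimator": self.estimator}, directory / "model.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "TaskModel":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        if meta.get("format") != MODEL_FORMAT_TAG:
            raise ValueError(f"unsupported model format {meta.get('format')!r}")
        blob = joblib.load(directory / "model.joblib")
        return cls(
            task=meta["task"],
            learner=meta["learner"],
            features=blob["features"],
            estimator=blob["estimator"],
            raw_min=meta["raw_min"],
            raw_max=meta["raw_max"],
            best_params=meta["best_params"],
        )


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


def train_task_model(
    task: str,
    learner: str,
    train: LabeledCorpus,
    cfg: FeatureConfig | None = None,
    search_budget: int = 10,
    seed: int = 0,
) -> TaskModel:
    """Fit a task model with seeded randomized hyper-parameter search.

    ``search_budget`` configurations are drawn and scored by macro F1
    over 5 stratified folds; the best is refit on the full training set.
    The cancer-type task uses only documents with a cancer-type label
    and is one-vs-rest for the linear learner.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if learner not in LEARNERS:
        raise ValueError(f"unknown learner {learner!r}")
    cfg = cfg or FeatureConfig()

    if task == "ctype":
        keep = [i for i, lab in enumerate(train.labels) if lab.ctype != CTYPE_NONE]
        train = train.subset(keep)
    texts = train.texts()
    y = np.asarray(train.task_labels(task))
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"task {task}: need >= 2 classes, got {classes.tolist()}")
    tiny = [(c, int(n)) for c, n in zip(classes, counts) if n < 5]
    if tiny:
        raise ValueError(f"task {task}: classes with <5 examples (5-fold CV): {tiny}")

    feats = fit_features(texts, cfg, y)
    X = feats.transform(texts)

    if learner == "linear_svm":
        base = LinearSVC(random_state=seed)
        space = _SVM_SPACE
    else:
        base = RandomForestClassifier(random_state=seed, n_jobs=1)
        space = _RF_SPACE
    search = RandomizedSearchCV(
        base,
        space,
        n_iter=search_budget,
        scoring="f1_macro",
        cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
        random_state=seed,
        refit=True,
        n_jobs=1,
    )
    search.fit(X, y)
    est = search.best_estimator_

    model = TaskModel(
        task=task,
        learner=learner,
        features=feats,
        estimator=est,
        raw_min=0.0,
        raw_max=0.0,
        best_params=dict(search.best_params_),
        best_cv_score=float(search.best_score_),
    )
    if task == "ctype":
        _, margins = model.type_predictions(texts)
        raw = margins
    else:
        raw = model.raw_scores(texts)
    model.raw_min = float(np.min(raw))
    model.raw_max = float(np.max(raw))
    return model


def predict_scores(models: dict[str, TaskModel], doc: Document) -> dict:
    """Score one document with the fitted task models.

    Returns raw cancer/clinical scores plus the predicted cancer type
    and its margin (``None`` when no ctype model is supplied).
    """
    out: dict = {}
    out["cancer_raw"] = float(models["cancer"].raw_scores([doc.text])[0])
    out["clinical_raw"] = float(models["clinical"].raw_scores([doc.text])[0])
    if "ctype" in models:
        labels, margins = models["ctype"].type_predictions([doc.text])
        out["ctype_label"] = str(labels[0])
        out["ctype_margin"] = float(margins[0])
    else:
        out["ctype_label"] = None
        out["ctype_margin"] = None
    return out


def evaluate_classifier(model: TaskModel, test: LabeledCorpus) -> dict:
    """Per-class and macro precision/recall/F1 on a labeled test set.

    Classes absent from the test set are reported as ``None`` and
    excluded from the macro average (an unweighted mean over present
    classes).
    """
    if model.task == "ctype":
        keep = [i for i, lab in enumerate(test.labels) if lab.ctype != CTYPE_NONE]
        test = test.subset(keep)
        y_pred, _ = model.type_predictions(test.texts())
    else:
        y_pred = model.predict_labels(test.texts())
    y_true = np.asarray(test.task_labels(model.task))
    return prf_report(y_true, np.asarray(y_pred), list(model.estimator.classes_))


def prf_report(y_true: np.ndarray, y_pred: np.ndarray, all_classes: list) -> dict:
    """Per-class precision/recall/F1 plus an unweighted macro average.

    Classes in ``all_classes`` that never occur in ``y_true`` are
    reported as ``None`` and excluded from the macro mean.
    """
    present = np.unique(y_true)
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, zero_division=0
    )
    per_class: dict = {}
    present_list = present.tolist()
    for cls in all_classes:
        if cls in present_list:
            i = present_list.index(cls)
            per_class[str(cls)] = {
                "precision": float(p[i]), "recall": float(r[i]), "f1": float(f1[i]),
            }
        else:
            per_class[str(cls)] = {"precision": None, "recall": None, "f1": None}
    macro = {
        "precision": float(np.mean(p)),
        "recall": float(np.mean(r)),
        "f1": float(np.mean(f1)),
    }
    return {"per_class": per_class, "macro": macro}
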