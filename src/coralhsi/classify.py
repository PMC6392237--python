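"""Three-stage spectral classification: standardize -> PLS -> nu-SVM.

Separate pipelines are trained per color morph (white / orange); they share no
fitted state.  Each stage:

* standardization  z_i = (x_i - mu_i) / sigma_i with *train-set* statistics
  (population standard deviation); applied to both X and the continuous
  annotation block Y_h (concentration, mortality);
* PLS two-block regression Y_h ~ B X fitted by NIPALS (scikit-learn's
  ``PLSRegression``), keeping ``n_latent`` components (default 10, selectable
  by 5-fold stratified cross-validation);
* one-vs-one nu-SVM (nu = 0.1, RBF kernel) on the PLS scores against the
  categorical exposure label Y_c.

Metrics follow the precision / recall / F1 definitions with per-class
one-vs-rest counts; report totals are pixel-count-weighted harmonic means.
Per-sample labels come from a majority vote over the sample's pixels, ties
broken toward the more severe category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import NuSVC

from coralhsi.spectral_db import SpectraTable

__all__ = [
    "CATEGORIES",
    "Standardizer",
    "fit_standardizer",
    "PlsModel",
    "fit_pls",
    "select_n_latent",
    "cv_errors",
    "fit_svm",
    "ClassificationReport",
    "evaluate",
    "majority_vote",
    "MorphModel",
    "ClassifierBundle",
    "PipelineResult",
    "train_pipeline",
    "evaluate_reference_group",
    "f1_from_pr",
    "weighted_harmonic_mean",
    "round_half_up",
]

CATEGORIES = ("low", "medium", "high")
_SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (report convention; numpy rounds half-even)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def weighted_harmonic_mean(values, weights) -> float:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(values <= 0):
        raise ValueError("harmonic mean requires positive values")
    return float(weights.sum() / np.sum(weights / values))


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Column-wise (x - mu) / sigma with train statistics; population SD."""

    mean_: np.ndarray
    std_: np.ndarray
    kept_: np.ndarray  # boolean mask of retained (non-constant) columns

    @property
    def n_dropped(self) -> int:
        return int((~self.kept_).sum())

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X[:, self.kept_] - self.mean_[self.kept_]) / self.std_[self.kept_]

    def apply_inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.std_[self.kept_] + self.mean_[self.kept_]


def fit_standardizer(X: np.ndarray) -> Standardizer:
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot standardize an empty training set")
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population SD
    kept = std > 0
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} zero-variance column(s)")
    if not kept.any():
        raise ValueError("all columns have zero variance")
    return Standardizer(mean_=mean, std_=std, kept_=kept)


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------


@dataclass
class PlsModel:
    """Two-block PLS regression Y = B X + E on standardized inputs."""

    pls: PLSRegression
    n_latent: int

    @property
    def B(self) -> np.ndarray:
        return self.pls.coef_

    @property
    def x_loadings(self) -> np.ndarray:
        return self.pls.x_loadings_

    @property
    def x_scores(self) -> np.ndarray:
        return self.pls.x_scores_

    def transform(self, Xz: np.ndarray) -> np.ndarray:
        return self.pls.transform(Xz)

    def predict(self, Xz: np.ndarray) -> np.ndarray:
        return self.pls.predict(Xz)


def fit_pls(Xz: np.ndarray, Yz: np.ndarray, n_latent: int = 10) -> PlsModel:
    """Fit PLS on standardized X and Y_h; errors if n_latent exceeds the rank."""
    Xz = np.asarray(Xz, dtype=float)
    Yz = np.asarray(Yz, dtype=float)
    max_components = min(Xz.shape[0] - 1, Xz.shape[1])
    if not 1 <= n_latent <= max_components:
        raise ValueError(
            f"n_latent={n_latent} outside [1, {max_components}] for X of shape {Xz.shape}"
        )
    pls = PLSRegression(n_components=n_latent, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xz, Yz)
    return PlsModel(pls=pls, n_latent=n_latent)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


def fit_svm(
    scores: np.ndarray, y_c, nu: float = 0.1, gamma: str | float = "scale"
) -> NuSVC:
    """One-vs-one nu-SVM with RBF kernel on PLS scores."""
    y = np.asarray(y_c)
    if np.unique(y).size < 2:
        raise ValueError("nu-SVM needs >= 2 classes in the training set")
    svm = NuSVC(nu=nu, kernel="rbf", gamma=gamma)
    try:
        svm.fit(np.asarray(scores, dtype=float), y)
    except ValueError as exc:
        if "nu" in str(exc).lower():
            raise ValueError(
                f"nu={nu} infeasible for the class sizes "
                f"{dict(zip(*np.unique(y, return_counts=True)))}: {exc}"
            ) from exc
        raise
    return svm


# ---------------------------------------------------------------------------
# Latent-variable selection by stratified CV
# ---------------------------------------------------------------------------


def _subsample_stratified(
    n: int, y: np.ndarray, max_rows: int, seed: int
) -> np.ndarray:
    if max_rows is None or n <= max_rows:
        return np.arange(n)
    idx, _ = train_test_split(
        np.arange(n), train_size=max_rows, stratify=y, random_state=seed
    )
    return np.sort(idx)


def cv_errors(
    X: np.ndarray,
    y_h: np.ndarray,
    y_c,
    candidates=tuple(range(1, 26)),
    k: int = 5,
    seed: int = 0,
    nu: float = 0.1,
    gamma: str | float = "scale",
    max_rows: int | None = None,
) -> dict[int, float]:
    """Mean k-fold misclassification rate of the full pipeline per candidate."""
    X = np.asarray(X, dtype=float)
    y_h = np.asarray(y_h, dtype=float)
    y_c = np.asarray(y_c)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} rows for {k}-fold CV")
    keep = _subsample_stratified(X.shape[0], y_c, max_rows, seed)
    X, y_h, y_c = X[keep], y_h[keep], y_c[keep]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y_c))
    errors: dict[int, float] = {}
    for n_latent in candidates:
        fold_err = []
        for train_idx, val_idx in folds:
            xs = fit_standardizer(X[train_idx])
            ys = fit_standardizer(y_h[train_idx])
            pls = fit_pls(xs.apply(X[train_idx]), ys.apply(y_h[train_idx]), n_latent)
            svm = fit_svm(pls.transform(xs.apply(X[train_idx])), y_c[train_idx], nu, gamma)
            pred = svm.predict(pls.transform(xs.apply(X[val_idx])))
            fold_err.append(np.mean(pred != y_c[val_idx]))
        errors[int(n_latent)] = float(np.mean(fold_err))
    return errors


def select_n_latent(
    X: np.ndarray,
    y_h: np.ndarray,
    y_c,
    candidates=tuple(range(1, 26)),
    k: int = 5,
    seed: int = 0,
    nu: float = 0.1,
    gamma: str | float = "scale",
    max_rows: int | None = None,
) -> int:
    """Candidate with the lowest CV error; ties resolved toward fewer components."""
    errors = cv_errors(X, y_h, y_c, candidates, k, seed, nu, gamma, max_rows)
    best = min(errors, key=lambda n: (errors[n], n))
    return int(best)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class ClassificationReport:
    """Per-class precision / recall / F1 plus pixel-weighted harmonic totals."""

    per_class: pd.DataFrame  # class, pixels, tp/fp/fn fractions, P, R, F1
    totals: dict
    absent_classes: list = field(default_factory=list)

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Report table rounded at serialization time (half-up)."""
        df = self.per_class.copy()
        for col in ("precision", "recall", "f1"):
            df[col] = df[col].map(lambda v: round_half_up(v, decimals))
        total_row = {
            "class": "total",
            "pixels": self.totals["pixels"],
            "precision": round_half_up(self.totals["precision"], decimals),
            "recall": round_half_up(self.totals["recall"], decimals),
            "f1": round_half_up(self.totals["f1"], decimals),
        }
        return pd.concat(
            [df[["class", "pixels", "precision", "recall", "f1"]],
             pd.DataFrame([total_row])],
            ignore_index=True,
        )


def evaluate(
    y_true, y_pred, classes: tuple[str, ...] = CATEGORIES
) -> ClassificationReport:
    """One-vs-rest P/R/F1 per class from predicted vs true labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    extra = set(np.unique(y_pred)) - set(classes)
    if extra:
        raise ValueError(f"predicted labels outside class set: {sorted(extra)}")
    n = y_true.size
    rows, absent = [], []
    for cls in classes:
        tp = int(np.sum((y_pred == cls) & (y_true == cls)))
        fp = int(np.sum((y_pred == cls) & (y_true != cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        pixels = int(np.sum(y_true == cls))
        if pixels == 0:
            absent.append(cls)
            continue
        precision = tp / (tp + fp) if tp + fp else float("nan")
        recall = tp / (tp + fn)
        rows.append(
            {
                "class": cls,
                "pixels": pixels,
                "tp_fraction": tp / n,
                "fp_fraction": fp / n,
                "fn_fraction": fn / n,
                "precision": precision,
                "recall": recall,
                "f1": f1_from_pr(precision, recall) if np.isfinite(precision) else float("nan"),
            }
        )
    if not rows:
        raise ValueError("no class present in the truth labels")
    per_class = pd.DataFrame(rows)
    weights = per_class["pixels"].to_numpy()
    p_tot = weighted_harmonic_mean(per_class["precision"], weights)
    r_tot = weighted_harmonic_mean(per_class["recall"], weights)
    totals = {
        "pixels": int(weights.sum()),
        "precision": p_tot,
        "recall": r_tot,
        "f1": f1_from_pr(p_tot, r_tot),
        "accuracy": float(np.mean(y_true == y_pred)),
    }
    return ClassificationReport(per_class=per_class, totals=totals, absent_classes=absent)


def majority_vote(y_pred, sample_ids) -> pd.DataFrame:
    """Plurality label per sample; ties break toward the more severe category."""
    y_pred = np.asarray(y_pred)
    sample_ids = np.asarray(sample_ids)
    if y_pred.size != sample_ids.size:
        raise ValueError("prediction/sample_id length mismatch")
    if y_pred.size == 0:
        raise ValueError("no predicted pixels to vote over")
    rows = []
    for sid in pd.unique(sample_ids):
        labels, counts = np.unique(y_pred[sample_ids == sid], return_counts=True)
        top = counts.max()
        contenders = [str(l) for l, c in zip(labels, counts) if c == top]
        winner = max(contenders, key=lambda c: _SEVERITY.get(c, -1))
        tie = len(contenders) > 1
        if tie:
            warnings.warn(
                f"sample {sid!r}: vote tie between {contenders}; "
                f"assigned more severe category {winner!r}"
            )
        row = {
            "sample_id": sid,
            "label": winner,
            "n_pixels": int(counts.sum()),
            "tie": tie,
        }
        row.update({f"votes_{l}": int(c) for l, c in zip(labels, counts)})
        rows.append(row)
    df = pd.DataFrame(rows)
    for cls in CATEGORIES:
        col = f"votes_{cls}"
        if col not in df.columns:
            df[col] = 0
        df[col] = df[col].fillna(0).astype(int)
    return df


# ---------------------------------------------------------------------------
# Full per-morph pipeline
# ---------------------------------------------------------------------------


@dataclass
class MorphModel:
    """Fitted stages for one color morph."""

    morph: str
    x_standardizer: Standardizer
    y_standardizer: Standardizer
    pls: PlsModel
    svm: NuSVC
    n_latent: int
    nu: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.pls.transform(self.x_standardizer.apply(X))
        return self.svm.predict(scores)


@dataclass
class ClassifierBundle:
    models: dict[str, MorphModel]
    test_fraction: float
    split_seed: int

    def predict(self, morph: str, X: np.ndarray) -> np.ndarray:
        if morph not in self.models:
            raise KeyError(f"no trained model for morph {morph!r}")
        return self.models[morph].predict(X)


@dataclass
class PipelineResult:
    bundle: ClassifierBundle
    reports: dict[str, ClassificationReport]
    votes: dict[str, pd.DataFrame]
    test_tables: dict[str, SpectraTable]
    vote_accuracy: dict[str, float]


def _train_one_morph(
    table: SpectraTable,
    morph: str,
    n_latent: int,
    nu: float,
    gamma,
    test_fraction: float,
    seed: int,
) -> tuple[MorphModel, ClassificationReport, pd.DataFrame, SpectraTable, float]:
    y_c = table.y_c.to_numpy()
    idx = np.arange(table.n_pixels)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y_c, random_state=seed
    )
    train, test = table.subset(train_idx), table.subset(test_idx)

    xs = fit_standardizer(train.X)
    ys = fit_standardizer(train.y_h.to_numpy(dtype=float))
    pls = fit_pls(xs.apply(train.X), ys.apply(train.y_h.to_numpy(dtype=float)), n_latent)
    svm = fit_svm(pls.transform(xs.apply(train.X)), train.y_c.to_numpy(), nu, gamma)
    model = MorphModel(
        morph=morph,
        x_standardizer=xs,
        y_standardizer=ys,
        pls=pls,
        svm=svm,
        n_latent=n_latent,
        nu=nu,
    )
    pred = model.predict(test.X)
    report = evaluate(test.y_c.to_numpy(), pred)
    votes = majority_vote(pred, test.meta["sample_id"].to_numpy())
    truth_by_sample = (
        test.meta.assign(category=test.y_c.to_numpy())
        .groupby("sample_id")["category"]
        .first()
    )
    correct = votes["label"].to_numpy() == truth_by_sample.loc[votes["sample_id"]].to_numpy()
    return model, report, votes, test, float(np.mean(correct))


def train_pipeline(
    table: SpectraTable,
    n_latent: int = 10,
    nu: float = 0.1,
    gamma: str | float = "scale",
    test_fraction: float = 0.2,
    seed: int = 0,
) -> PipelineResult:
    """Stratified 80/20 split + full pipeline, independently per color morph."""
    if table.y_h is None or table.y_c is None:
        raise ValueError("table must be annotated (Y_h and Y_c) before training")
    models, reports, votes, tests, acc = {}, {}, {}, {}, {}
    for morph, sub in table.split_by_morph().items():
        (
            models[morph],
            reports[morph],
            votes[morph],
            tests[morph],
            acc[morph],
        ) = _train_one_morph(sub, morph, n_latent, nu, gamma, test_fraction, seed)
    bundle = ClassifierBundle(models=models, test_fraction=test_fraction, split_seed=seed)
    return PipelineResult(
        bundle=bundle, reports=reports, votes=votes, test_tables=tests, vote_accuracy=acc
    )


def evaluate_reference_group(
    bundle: ClassifierBundle, reference: SpectraTable
) -> dict[str, dict]:
    """Score held-out healthy corals; "low" is the correct class throughout."""
    if reference.n_pixels == 0:
        raise ValueError("reference set has no pixels")
    out: dict[str, dict] = {}
    for morph, sub in reference.split_by_morph().items():
        if morph not in bundle.models:
            raise KeyError(f"no trained model for morph {morph!r}")
        pred = bundle.predict(morph, sub.X)
        truth = np.full(pred.shape, "low", dtype=object)
        report = evaluate(truth, pred)
        votes = majority_vote(pred, sub.meta["sample_id"].to_numpy())
        out[morph] = {
            "report": report,
            "votes": votes,
            "fraction_samples_low": float(np.mean(votes["label"] == "low")),
        }
    return out
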