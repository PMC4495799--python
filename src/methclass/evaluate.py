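"""Accuracy evaluation: confusion matrices, Cohen's kappa, repeated CV.

Kappa relates observed agreement to the agreement expected by chance from
the table marginals, kappa = (p_o - p_e) / (1 - p_e), with the large-sample
standard error se = sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)) for the
confidence interval. Cross-validation is stratified by class, repeated
with fresh fold assignments, and re-runs probe selection and mtry tuning
inside every training fold so the reported accuracy carries no selection
leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold

from .errors import InputError
from .io import BetaMatrix, LabelMap
from .probe_selection import SignaturePanel, build_panel, rank_all_classes

logger = logging.getLogger(__name__)

#: Pseudo-label for samples whose winning vote fraction misses the threshold.
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Truth × predicted counts; inconclusive calls in a separate column.

    Rows are true classes, columns predicted classes in the same order.
    ``inconclusive[k]`` counts class-k samples whose call was withheld;
    they are excluded from the square table (and hence from kappa).
    """

    classes: list[str]
    counts: np.ndarray
    inconclusive: np.ndarray

    @property
    def n(self) -> int:
        """Samples in the square table (conclusive calls only)."""
        return int(self.counts.sum())

    @property
    def n_inconclusive(self) -> int:
        return int(self.inconclusive.sum())


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its large-sample confidence interval."""

    kappa: float
    se: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class ValidationReport:
    """Pooled accuracy over OOB or repeated cross-validation."""

    scheme: str
    folds: int
    repeats: int
    confusion: ConfusionMatrix
    error_rate: float
    kappa: KappaResult
    per_fold: list[tuple[int, int, float]]
    n_inconclusive: int = 0


def confusion(true, pred, classes: list[str] | None = None) -> ConfusionMatrix:
    """Tabulate truth vs prediction.

    ``pred`` entries may include ``"inconclusive"``, which is tallied in
    the separate column. Class order defaults to the sorted classes of the
    truth vector.
    """
    true = np.asarray(true, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if true.shape != pred.shape:
        raise InputError(f"length mismatch: {true.shape} vs {pred.shape}")
    if classes is None:
        classes = sorted(set(true))
    idx = {c: k for k, c in enumerate(classes)}
    unknown = set(true) - set(classes)
    if unknown:
        raise InputError(f"true labels outside class set: {sorted(unknown)}")
    unknown = set(pred) - set(classes) - {INCONCLUSIVE}
    if unknown:
        raise InputError(f"predicted labels outside class set: {sorted(unknown)}")
    K = len(classes)
    counts = np.zeros((K, K), dtype=np.int64)
    inconclusive = np.zeros(K, dtype=np.int64)
    for t, p in zip(true, pred):
        if p == INCONCLUSIVE:
            inconclusive[idx[t]] += 1
        else:
            counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(classes=list(classes), counts=counts, inconclusive=inconclusive)


def cohen_kappa(cm: ConfusionMatrix, conf_level: float = 0.95) -> KappaResult:
    """Chance-corrected agreement of a square confusion table.

    kappa = (p_o - p_e)/(1 - p_e) with p_o = trace/n and
    p_e = sum_k row_k * col_k / n^2. The CI is kappa ± z * se with the
    large-sample standard error (Fleiss-Cohen-Everitt).
    """
    counts = np.asarray(cm.counts, dtype=float)
    n = counts.sum()
    if n < 1:
        raise InputError("empty confusion matrix")
    p_o = np.trace(counts) / n
    p_e = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0)) / n**2)
    if p_e >= 1.0:
        raise InputError("degenerate table: chance agreement p_e = 1")
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = float(np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2)))
    z = float(norm.ppf(0.5 + conf_level / 2.0))
    return KappaResult(
        kappa=float(kappa),
        se=se,
        ci_low=float(max(-1.0, kappa - z * se)),
        ci_high=float(min(1.0, kappa + z * se)),
        n=int(n),
    )


def repeated_cv(
    m: BetaMatrix,
    labels: LabelMap,
    folds: int = 10,
    repeats: int = 5,
    seed: int = 0,
    n_per_class: int = 100,
    forest_cfg=None,
    tune: bool = True,
    leaky: bool = False,
    strict_inconclusive: bool = False,
) -> ValidationReport:
    """Stratified k-fold CV, repeated with fresh fold assignments.

    Probe selection (and mtry tuning when ``tune``) run inside each
    training fold; ``leaky=True`` instead selects once on the full data
    before splitting, for quantifying the selection bias. Repeat r uses
    fold seed ``seed + r``. Inconclusive calls are excluded from the
    pooled kappa and, unless ``strict_inconclusive``, from the error rate.
    """
    from . import forest as _forest

    cfg = forest_cfg if forest_cfg is not None else _forest.ForestConfig(seed=seed)
    y = labels.labels_for(m.sample_ids)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise InputError(
            f"cannot stratify: class {classes[np.argmin(counts)]!r} has a single sample"
        )
    if counts.min() < folds:
        logger.warning(
            "smallest class has %d samples; reducing folds from %d to %d",
            counts.min(), folds, counts.min(),
        )
        folds = int(counts.min())
    sample_ids = np.array(m.sample_ids, dtype=object)

    full_panel: SignaturePanel | None = None
    if leaky:
        full_panel = build_panel(rank_all_classes(m, labels), n_per_class)

    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    per_fold: list[tuple[int, int, float]] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(seed + r) % 2**31)
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            m_tr = m.subset_samples(sample_ids[tr].tolist())
            m_te = m.subset_samples(sample_ids[te].tolist())
            if leaky:
                panel = full_panel
            else:
                panel = build_panel(rank_all_classes(m_tr, labels), n_per_class)
            fold_cfg = cfg
            if tune and cfg.mtry is None:
                mtry = _forest.tune_mtry(m_tr, labels, cfg, panel)
                fold_cfg = _forest._with_mtry(cfg, mtry)
            clf = _forest.train(m_tr, labels, fold_cfg, panel)
            preds = _forest.predict(clf, m_te)
            t_fold = [labels[p.sample_id] for p in preds]
            p_fold = [p.call for p in preds]
            pooled_true.extend(t_fold)
            pooled_pred.extend(p_fold)
            cm_f = confusion(t_fold, p_fold, classes=list(classes))
            denom = cm_f.n + (cm_f.n_inconclusive if strict_inconclusive else 0)
            err_f = 1.0 - np.trace(cm_f.counts) / denom if denom else 0.0
            per_fold.append((r, f, float(err_f)))

    cm = confusion(pooled_true, pooled_pred, classes=list(classes))
    kappa = cohen_kappa(cm)
    denom = cm.n + (cm.n_inconclusive if strict_inconclusive else 0)
    error = 1.0 - float(np.trace(cm.counts)) / denom
    logger.info(
        "repeated CV (%dx%d): error %.4f, kappa %.4f, %d inconclusive",
        folds, repeats, error, kappa.kappa, cm.n_inconclusive,
    )
    return ValidationReport(
        scheme="repeated_cv",
        folds=folds,
        repeats=repeats,
        confusion=cm,
        error_rate=error,
        kappa=kappa,
        per_fold=per_fold,
        n_inconclusive=cm.n_inconclusive,
    )


def auc_summary(panel: SignaturePanel, floor: float = 0.9) -> dict[str, dict]:
    """Per-class min/median/max AUC of the selected probes.

    Flags any class whose selected-probe minimum falls below ``floor``
    (the published panels report all selected sites above 0.9).
    """
    out: dict[str, dict] = {}
    for cls, scores in panel.per_class.items():
        aucs = np.array([s.auc for s in scores])
        below = bool(aucs.min() < floor)
        if below:
            logger.warning(
                "class %s: selected-probe minimum AUC %.3f below %.2f floor",
                cls, aucs.min(), floor,
            )
        out[cls] = {
            "n": int(aucs.size),
            "min": float(aucs.min()),
            "median": float(np.median(aucs)),
            "max": float(aucs.max()),
            "below_floor": below,
        }
    return out
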