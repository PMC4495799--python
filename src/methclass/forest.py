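"""Random-forest training, mtry tuning, and vote-fraction classification.

The forest (default 900 trees, each grown on a bootstrap resample with a
random predictor subset per split) is backed by scikit-learn, but class
probabilities are reported as exact hard-vote fractions — the number of
trees voting for a class divided by the number of trees — and out-of-bag
(OOB) statistics are computed only from trees whose bootstrap excluded the
sample, recovered from per-tree bootstrap membership. A sample is assigned
its majority class when the winning vote fraction reaches the call
threshold, and ``"inconclusive"`` otherwise (the mixed-profile case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import evaluate
from .errors import InputError
from .io import FORMAT_VERSION, BetaMatrix, LabelMap
from .probe_selection import SignaturePanel

logger = logging.getLogger(__name__)

INCONCLUSIVE = evaluate.INCONCLUSIVE


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    call_threshold is the minimum winning vote fraction for a confident
    call; below it a sample is reported inconclusive. The default 0.40
    sits between published confident calls at 0.49 and withheld calls at
    0.32 and is user-overridable.
    """

    n_trees: int = 900
    mtry: int | None = None
    mtry_grid: tuple[int, ...] | None = None
    seed: int = 0
    call_threshold: float = 0.40

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InputError(f"n_trees must be >= 1, got {self.n_trees}")
        if not 0.0 < self.call_threshold <= 1.0:
            raise InputError(
                f"call_threshold must be in (0, 1], got {self.call_threshold}"
            )


@dataclass(frozen=True)
class OOBReport:
    """Out-of-bag confusion matrix, error rate and kappa."""

    confusion: "evaluate.ConfusionMatrix"
    error_rate: float
    kappa: "evaluate.KappaResult"
    n_excluded: int = 0  # samples in-bag for every tree (rare)


@dataclass(frozen=True)
class TrainedClassifier:
    """A fitted forest plus everything needed to classify new samples."""

    sk_model: RandomForestClassifier
    probe_ids: list[str]
    classes: list[str]
    mtry: int
    n_trees: int
    seed: int
    call_threshold: float
    oob: OOBReport
    panel: SignaturePanel | None = None
    format_version: str = FORMAT_VERSION


@dataclass(frozen=True)
class ClassProbabilities:
    """Per-class vote-fraction probabilities and the thresholded call."""

    sample_id: str
    probs: dict[str, float]
    vote_counts: dict[str, int]
    call: str


def default_mtry_grid(n_probes: int) -> tuple[int, ...]:
    """Grid bracketing the conventional sqrt(p) default."""
    r = int(np.sqrt(n_probes))
    cand = {r // 2, r, 2 * r, n_probes // 10, n_probes // 3}
    return tuple(sorted(min(max(c, 1), n_probes) for c in cand))


def _design(m: BetaMatrix, panel: SignaturePanel | None) -> tuple[np.ndarray, list[str]]:
    """Samples × probes design matrix, restricted to panel probes if given."""
    if panel is not None:
        m = m.subset_probes(panel.merged_probes)
    X = m.values.T
    if np.isnan(X).any():
        raise InputError("matrix contains missing values; impute before training")
    return X, m.probe_ids


def _tree_votes(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """(n_trees, n_samples) array of per-tree hard votes as class indices."""
    return np.stack([t.predict(X).astype(np.intp) for t in model.estimators_])


def _inbag_matrix(model: RandomForestClassifier, n_samples: int) -> np.ndarray:
    inbag = np.zeros((len(model.estimators_), n_samples), dtype=bool)
    for t, idx in enumerate(model.estimators_samples_):
        inbag[t, idx] = True
    return inbag


def train(
    m: BetaMatrix,
    labels: LabelMap,
    cfg: ForestConfig = ForestConfig(),
    panel: SignaturePanel | None = None,
) -> TrainedClassifier:
    """Fit the forest and compute OOB accuracy statistics.

    ``m`` must contain every panel probe (when a panel is given) and no
    missing values; every class needs at least two samples. Training is
    bit-for-bit reproducible from ``cfg.seed``.
    """
    X, probe_ids = _design(m, panel)
    y = labels.labels_for(m.sample_ids)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("training requires >= 2 classes")
    thin = classes[counts < 2]
    if thin.size:
        raise InputError(f"classes with < 2 samples: {thin.tolist()}")
    p = X.shape[1]
    mtry = cfg.mtry if cfg.mtry is not None else max(1, int(np.sqrt(p)))
    if not 1 <= mtry <= p:
        raise InputError(f"mtry={mtry} outside [1, {p}]")
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=mtry,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(X, y)

    votes = _tree_votes(model, X)
    inbag = _inbag_matrix(model, X.shape[0])
    n_classes = len(model.classes_)
    oob_counts = np.zeros((X.shape[0], n_classes), dtype=np.int64)
    for t in range(votes.shape[0]):
        oob = ~inbag[t]
        np.add.at(oob_counts, (np.flatnonzero(oob), votes[t, oob]), 1)
    has_oob = oob_counts.sum(axis=1) > 0
    n_excluded = int((~has_oob).sum())
    if n_excluded:
        logger.warning("%d samples were in-bag for every tree; excluded from OOB", n_excluded)
    oob_pred = model.classes_[np.argmax(oob_counts[has_oob], axis=1)]
    cm = evaluate.confusion(y[has_oob], oob_pred, classes=list(model.classes_))
    kappa = evaluate.cohen_kappa(cm)
    n_eval = int(has_oob.sum())
    error = 1.0 - float(np.trace(cm.counts)) / n_eval
    logger.info("OOB error %.4f, kappa %.4f (mtry=%d)", error, kappa.kappa, mtry)
    return TrainedClassifier(
        sk_model=model,
        probe_ids=probe_ids,
        classes=list(model.classes_),
        mtry=mtry,
        n_trees=cfg.n_trees,
        seed=cfg.seed,
        call_threshold=cfg.call_threshold,
        oob=OOBReport(confusion=cm, error_rate=error, kappa=kappa, n_excluded=n_excluded),
        panel=panel,
    )


def tune_mtry(
    m: BetaMatrix,
    labels: LabelMap,
    cfg: ForestConfig = ForestConfig(),
    panel: SignaturePanel | None = None,
) -> int:
    """Grid-search the number of predictors per split by OOB kappa.

    Returns the grid value with the highest OOB kappa (ties go to the
    smallest mtry); the full grid-vs-kappa table is logged.
    """
    X, _ = _design(m, panel)
    p = X.shape[1]
    grid = cfg.mtry_grid if cfg.mtry_grid is not None else default_mtry_grid(p)
    if not grid:
        raise InputError("mtry grid is empty")
    bad = [g for g in grid if not 1 <= g <= p]
    if bad:
        raise InputError(f"mtry grid values outside [1, {p}]: {bad}")
    results: list[tuple[int, float]] = []
    for g in sorted(set(grid)):
        clf = train(m, labels, cfg=_with_mtry(cfg, g), panel=panel)
        results.append((g, clf.oob.kappa.kappa))
    for g, k in results:
        logger.info("mtry grid: mtry=%-6d OOB kappa=%.4f", g, k)
    best = max(results, key=lambda r: (r[1], -r[0]))
    logger.info("chosen mtry=%d (OOB kappa %.4f)", best[0], best[1])
    return best[0]


def _with_mtry(cfg: ForestConfig, mtry: int) -> ForestConfig:
    return ForestConfig(
        n_trees=cfg.n_trees,
        mtry=mtry,
        mtry_grid=cfg.mtry_grid,
        seed=cfg.seed,
        call_threshold=cfg.call_threshold,
    )


def predict(
    c: TrainedClassifier,
    m: BetaMatrix,
    call_threshold: float | None = None,
) -> list[ClassProbabilities]:
    """Classify every sample in ``m`` with vote-fraction probabilities.

    ``m`` must contain every probe the forest was trained on, with no
    missing values among them. Each tree casts one vote, so for every
    sample the per-class probabilities are integer multiples of
    ``1/n_trees`` and the vote counts sum to ``n_trees`` exactly.
    """
    threshold = c.call_threshold if call_threshold is None else call_threshold
    absent = [p for p in c.probe_ids if p not in m.df.index]
    if absent:
        raise InputError(
            f"{len(absent)} panel probes absent from input matrix: {absent[:10]}"
        )
    sub = m.df.loc[c.probe_ids]
    X = sub.to_numpy().T
    if np.isnan(X).any():
        bad = sub.columns[np.isnan(X).any(axis=1)].tolist()
        raise InputError(f"missing values among panel probes for samples: {bad[:10]}")
    votes = _tree_votes(c.sk_model, X)
    n_classes = len(c.classes)
    counts = np.zeros((X.shape[0], n_classes), dtype=np.int64)
    for t in range(votes.shape[0]):
        np.add.at(counts, (np.arange(X.shape[0]), votes[t]), 1)
    out: list[ClassProbabilities] = []
    for s, sid in enumerate(m.sample_ids):
        row = counts[s]
        best = int(np.argmax(row))
        frac = row[best] / c.n_trees
        call = c.classes[best] if frac >= threshold else INCONCLUSIVE
        out.append(
            ClassProbabilities(
                sample_id=sid,
                probs={cls: row[k] / c.n_trees for k, cls in enumerate(c.classes)},
                vote_counts={cls: int(row[k]) for k, cls in enumerate(c.classes)},
                call=call,
            )
        )
    return out
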