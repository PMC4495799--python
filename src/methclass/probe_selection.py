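"""One-vs-rest AUC probe screening and signature-panel assembly.

Each probe is scored per tumor class by the area under the ROC curve of
its beta values for that class against all other classes pooled (the
c-statistic: the probability that a random in-class beta exceeds a random
out-of-class beta, ties counted half). The AUC is computed directly from
rank statistics; because AUC is invariant under any strictly monotone
transform, this equals the AUC of a single-covariate logistic regression
on the same probe at a fraction of the cost. Scores are folded to
``max(a, 1 - a)`` so hypo-methylated markers rank as highly as
hyper-methylated ones, with the direction recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError
from .io import BetaMatrix, LabelMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbeScore:
    """Discriminative power of one probe for one class.

    ``auc`` is the folded one-vs-rest AUC in [0.5, 1]; ``direction`` is
    ``"hyper"`` if the class's betas are the higher group, ``"hypo"``
    otherwise.
    """

    probe_id: str
    class_label: str
    auc: float
    direction: str


@dataclass(frozen=True)
class SignaturePanel:
    """Per-class ranked probe lists plus the merged classifier probe set."""

    per_class: dict[str, list[ProbeScore]]
    merged_probes: list[str]
    n_per_class: int

    @property
    def classes(self) -> list[str]:
        return list(self.per_class.keys())


def probe_auc(values: np.ndarray, is_class: np.ndarray) -> tuple[float, str]:
    """Folded one-vs-rest AUC of a single probe.

    Returns ``(max(a, 1 - a), direction)`` where
    ``a = P(in-class beta > out-class beta) + 0.5 * P(tie)``, computed via
    the Mann-Whitney rank-sum identity. Raises on single-group input or
    missing values.
    """
    values = np.asarray(values, dtype=float)
    is_class = np.asarray(is_class, dtype=bool)
    if values.shape != is_class.shape:
        raise InputError("values and is_class must have equal length")
    n1 = int(is_class.sum())
    n2 = int((~is_class).sum())
    if n1 == 0 or n2 == 0:
        raise InputError("probe_auc requires both groups non-empty")
    if np.isnan(values).any():
        raise InputError("probe_auc requires imputed (non-missing) values")
    ranks = rankdata(values)
    a = (ranks[is_class].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    if a >= 0.5:
        return float(a), "hyper"
    return float(1.0 - a), "hypo"


def rank_probes(m: BetaMatrix, labels: LabelMap, class_label: str) -> list[ProbeScore]:
    """Score every probe for one class and sort by folded AUC.

    Sorting is (auc descending, probe_id ascending) so rankings are
    deterministic across runs and platforms. Requires >= 2 samples in each
    of the two groups.
    """
    y = labels.labels_for(m.sample_ids)
    if class_label not in set(y):
        raise InputError(f"class {class_label!r} absent from labels")
    is_class = y == class_label
    n1 = int(is_class.sum())
    n2 = len(y) - n1
    if n1 < 2 or n2 < 2:
        raise InputError(
            f"class {class_label!r}: need >= 2 samples in-class and out-of-class "
            f"(got {n1} / {n2})"
        )
    X = m.values
    if np.isnan(X).any():
        raise InputError("rank_probes requires an imputed matrix (no missing values)")
    ranks = rankdata(X, axis=1)
    return _scores_from_ranks(ranks, m.probe_ids, is_class, class_label)


def _scores_from_ranks(
    ranks: np.ndarray, probe_ids: list[str], is_class: np.ndarray, class_label: str
) -> list[ProbeScore]:
    n1 = int(is_class.sum())
    n2 = int((~is_class).sum())
    a = (ranks[:, is_class].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    folded = np.maximum(a, 1.0 - a)
    directions = np.where(a >= 0.5, "hyper", "hypo")
    order = sorted(range(len(folded)), key=lambda i: (-folded[i], probe_ids[i]))
    return [
        ProbeScore(probe_ids[i], class_label, float(folded[i]), str(directions[i]))
        for i in order
    ]


def rank_all_classes(m: BetaMatrix, labels: LabelMap) -> dict[str, list[ProbeScore]]:
    """:func:`rank_probes` for every class (samples are ranked only once)."""
    X = m.values
    if np.isnan(X).any():
        raise InputError("rank_probes requires an imputed matrix (no missing values)")
    y = labels.labels_for(m.sample_ids)
    ranks = rankdata(X, axis=1)
    out: dict[str, list[ProbeScore]] = {}
    for cls in labels.classes:
        is_class = y == cls
        n1 = int(is_class.sum())
        n2 = len(y) - n1
        if n1 < 2 or n2 < 2:
            raise InputError(
                f"class {cls!r}: need >= 2 samples in-class and out-of-class "
                f"(got {n1} / {n2})"
            )
        out[cls] = _scores_from_ranks(ranks, m.probe_ids, is_class, cls)
    return out


def build_panel(
    rankings: dict[str, list[ProbeScore]], n_per_class: int = 100
) -> SignaturePanel:
    """Truncate per-class rankings and merge into the classifier probe set.

    ``merged_probes`` is the deduplicated union of all selected probe IDs
    in first-seen order; probes selected by several classes are kept once
    (the overlap count is logged).
    """
    if not rankings:
        raise InputError("rankings are empty")
    if n_per_class < 1:
        raise InputError(f"n_per_class must be >= 1, got {n_per_class}")
    per_class: dict[str, list[ProbeScore]] = {}
    merged: list[str] = []
    seen: set[str] = set()
    n_selected = 0
    for cls, scores in rankings.items():
        if len(scores) < n_per_class:
            logger.warning(
                "class %s: only %d probes available (n_per_class=%d); selecting all",
                cls, len(scores), n_per_class,
            )
        chosen = scores[:n_per_class]
        per_class[cls] = chosen
        n_selected += len(chosen)
        for s in chosen:
            if s.probe_id not in seen:
                seen.add(s.probe_id)
                merged.append(s.probe_id)
    overlap = n_selected - len(merged)
    if overlap:
        logger.info("panel overlap: %d probe selections shared between classes", overlap)
    return SignaturePanel(per_class=per_class, merged_probes=merged, n_per_class=n_per_class)


def write_panel(panel: SignaturePanel, path) -> None:
    """Export a panel as TSV: class_label, rank, probe_id, auc, direction."""
    rows = [
        (cls, rank + 1, s.probe_id, s.auc, s.direction)
        for cls, scores in panel.per_class.items()
        for rank, s in enumerate(scores)
    ]
    pd.DataFrame(
        rows, columns=["class_label", "rank", "probe_id", "auc", "direction"]
    ).to_csv(path, sep="\t", index=False)


def read_panel(path) -> SignaturePanel:
    """Import a panel written by :func:`write_panel`."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "class_label": str})
    required = {"class_label", "rank", "probe_id", "auc", "direction"}
    if not required.issubset(df.columns):
        raise InputError(f"panel file missing columns {sorted(required - set(df.columns))}")
    rankings: dict[str, list[ProbeScore]] = {}
    for cls, grp in df.groupby("class_label", sort=False):
        grp = grp.sort_values("rank")
        rankings[cls] = [
            ProbeScore(r.probe_id, cls, float(r.auc), r.direction)
            for r in grp.itertuples()
        ]
    n_per_class = max(len(v) for v in rankings.values())
    return build_panel(rankings, n_per_class)
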