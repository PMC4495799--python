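"""Synthetic 450K-like cohorts with known ground truth.

Emulates the structure of a merged multi-study methylation cohort: nine
tumor classes, a large probe pool of which a small disjoint set per class
is differentially methylated (hyper- or hypo-methylated markers), sporadic
missing probes, and one deliberately heterogeneous class whose marker
signal is partially diluted — mirroring the observation that glioblastomas
are a more heterogeneous group needing more CpG sites for separation.

Betas are Beta-distributed: background Beta(5, 5) around 0.5, hyper
markers Beta(8, 2) (mean 0.8), hypo markers Beta(2, 8) (mean 0.2), which
keeps every value inside [0, 1] by construction. Heterogeneity h for a
class replaces each in-class marker cell by a background draw
independently with probability h, so a class's effective marker effect
shrinks continuously as h grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import BetaMatrix, LabelMap

#: The nine tumor classes of the default cohort.
DEFAULT_CLASSES = (
    "DIPG",
    "Ependymoma",
    "ETMR",
    "Glioblastoma",
    "MB_Gr3",
    "MB_Gr4",
    "MB_SHH",
    "MB_WNT",
    "Pilocytic_astrocytoma",
)

#: Class given nonzero heterogeneity by default (the GBM-like class).
HETEROGENEOUS_CLASS = "Glioblastoma"


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator parameters.

    ``effect_*`` are Beta-distribution shape pairs; ``heterogeneity`` maps
    class label → dilution probability in [0, 1] (unlisted classes get 0).
    Leaving it ``None`` applies 0.3 to the GBM-like class and 0 elsewhere.
    """

    n_classes: int = 9
    samples_per_class: int | tuple[int, ...] = 20
    n_probes: int = 5000
    markers_per_class: int = 50
    effect_background: tuple[float, float] = (5.0, 5.0)
    effect_hyper: tuple[float, float] = (8.0, 2.0)
    effect_hypo: tuple[float, float] = (2.0, 8.0)
    heterogeneity: dict[str, float] | None = None
    missing_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise InputError("need at least 2 classes")
        if self.markers_per_class * self.n_classes > self.n_probes:
            raise InputError(
                f"{self.markers_per_class} markers x {self.n_classes} classes "
                f"exceed {self.n_probes} probes"
            )
        if not 0.0 <= self.missing_fraction < 1.0:
            raise InputError("missing_fraction must be in [0, 1)")
        for h in (self.heterogeneity or {}).values():
            if not 0.0 <= h <= 1.0:
                raise InputError("heterogeneity values must be in [0, 1]")

    @property
    def class_labels(self) -> list[str]:
        if self.n_classes <= len(DEFAULT_CLASSES):
            return list(DEFAULT_CLASSES[: self.n_classes])
        extra = [f"Class_{k:02d}" for k in range(len(DEFAULT_CLASSES), self.n_classes)]
        return list(DEFAULT_CLASSES) + extra

    @property
    def samples_per_class_list(self) -> list[int]:
        if isinstance(self.samples_per_class, int):
            return [self.samples_per_class] * self.n_classes
        if len(self.samples_per_class) != self.n_classes:
            raise InputError("samples_per_class list length must equal n_classes")
        return list(self.samples_per_class)

    def heterogeneity_for(self, label: str) -> float:
        if self.heterogeneity is not None:
            return float(self.heterogeneity.get(label, 0.0))
        return 0.3 if label == HETEROGENEOUS_CLASS else 0.0


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cohort."""

    labels: dict[str, str]
    markers: dict[str, list[tuple[str, str]]]  # class -> [(probe_id, direction)]

    def marker_ids(self, class_label: str) -> list[str]:
        return [p for p, _ in self.markers[class_label]]


def simulate_cohort(cfg: SimConfig = SimConfig()) -> tuple[BetaMatrix, LabelMap, SimTruth]:
    """Draw a cohort; fully reproducible from ``cfg.seed``.

    Marker sets are disjoint across classes; directions alternate
    hyper/hypo within each class's marker list.
    """
    rng = np.random.default_rng(cfg.seed)
    labels_list = cfg.class_labels
    sizes = cfg.samples_per_class_list
    n_samples = sum(sizes)
    probe_ids = [f"cg{k:08d}" for k in range(cfg.n_probes)]
    sample_ids: list[str] = []
    sample_class: list[str] = []
    for cls, sz in zip(labels_list, sizes):
        for i in range(sz):
            sample_ids.append(f"{cls}_{i + 1:02d}")
            sample_class.append(cls)

    X = rng.beta(*cfg.effect_background, size=(cfg.n_probes, n_samples))

    perm = rng.permutation(cfg.n_probes)
    markers: dict[str, list[tuple[str, str]]] = {}
    col_of_class = {
        cls: np.array([j for j, c in enumerate(sample_class) if c == cls])
        for cls in labels_list
    }
    for c, cls in enumerate(labels_list):
        rows = perm[c * cfg.markers_per_class : (c + 1) * cfg.markers_per_class]
        dirs = ["hyper" if k % 2 == 0 else "hypo" for k in range(len(rows))]
        markers[cls] = [(probe_ids[r], d) for r, d in zip(rows, dirs)]
        cols = col_of_class[cls]
        h = cfg.heterogeneity_for(cls)
        for r, d in zip(rows, dirs):
            shape = cfg.effect_hyper if d == "hyper" else cfg.effect_hypo
            vals = rng.beta(*shape, size=len(cols))
            if h > 0:
                diluted = rng.random(len(cols)) < h
                vals = np.where(diluted, X[r, cols], vals)
            X[r, cols] = vals

    m = BetaMatrix(pd.DataFrame(X, index=probe_ids, columns=sample_ids))
    if cfg.missing_fraction > 0:
        m = inject_missing(m, cfg.missing_fraction, seed=(cfg.seed + 1) % 2**31)
    label_map = LabelMap(dict(zip(sample_ids, sample_class)))
    return m, label_map, SimTruth(labels=dict(label_map.mapping), markers=markers)


def inject_missing(m: BetaMatrix, fraction: float, seed: int = 0) -> BetaMatrix:
    """Mask exactly ``floor(fraction * cells)`` cells, uniformly at random."""
    if not 0.0 <= fraction < 1.0:
        raise InputError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return m
    X = m.values.copy()
    n_cells = X.size
    n_mask = int(np.floor(fraction * n_cells))
    if n_mask == 0:
        return m
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_mask, replace=False)
    X.flat[flat] = np.nan
    return BetaMatrix(pd.DataFrame(X, index=m.probe_ids, columns=m.sample_ids))
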