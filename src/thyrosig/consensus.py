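"""Unanimous fold-change consensus selection of deregulated probes.

A probe enters a class's deregulated list when its log2 tumor/pool ratio
passes the fold threshold *in the same direction in every sample of the
class* — e.g. at 2-fold, every sample's ratio >= +1 (up) or every sample's
ratio <= -1 (down). Comparisons are inclusive ("at least n-fold"). The
requirement of no opposite regulation is implied: unanimous regulation in one
direction excludes any sample crossing the opposite threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import ConfigurationError, DataError

__all__ = [
    "ALL_UP",
    "ALL_DOWN",
    "NOT_CONSISTENT",
    "classify_probe",
    "ConsensusSelector",
    "ConsensusList",
    "consensus_lists",
    "GeneList",
    "collapse_to_genes",
    "collapse_directions",
]

ALL_UP = "ALL_UP"
ALL_DOWN = "ALL_DOWN"
NOT_CONSISTENT = "NOT_CONSISTENT"


def _check_fold(threshold_fold: float) -> float:
    if threshold_fold < 1:
        raise ConfigurationError(
            f"threshold_fold must be >= 1 (linear scale), got {threshold_fold}"
        )
    return math.log2(threshold_fold)


def classify_probe(ratios, threshold_fold: float) -> str:
    """Tri-state consensus call for one probe over one group's samples.

    Returns ALL_UP if every ratio >= +log2(threshold_fold), ALL_DOWN if every
    ratio <= -log2(threshold_fold), else NOT_CONSISTENT.
    """
    t = _check_fold(threshold_fold)
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise DataError("cannot classify a probe from an empty ratio vector")
    if r.min() >= t:
        return ALL_UP
    if r.max() <= -t:
        return ALL_DOWN
    return NOT_CONSISTENT


class ConsensusSelector(SelectorMixin, BaseEstimator):
    """Select probes unanimously regulated across one group's samples.

    sklearn-style feature selector: ``fit`` takes X of shape
    (n_samples, n_probes) holding the log2 ratios of a *single* tumor class;
    the support mask marks probes called ALL_UP or ALL_DOWN at
    ``threshold_fold``.

    Attributes
    ----------
    up_mask_, down_mask_ : ndarray of bool
        Per-probe unanimous up/down calls (mutually exclusive for fold > 1).
    statuses_ : ndarray of str
        Tri-state call per probe.
    min_abs_ratio_ : ndarray of float
        Minimum |log2 ratio| across samples per probe.
    """

    def __init__(self, threshold_fold: float = 2.0):
        self.threshold_fold = threshold_fold

    def fit(self, X, y=None):
        t = _check_fold(self.threshold_fold)
        X = check_array(X, dtype=float, ensure_min_samples=1,
                        ensure_min_features=0)
        self.n_features_in_ = X.shape[1]
        self.up_mask_ = X.min(axis=0) >= t
        self.down_mask_ = X.max(axis=0) <= -t
        self.statuses_ = np.where(
            self.up_mask_, ALL_UP, np.where(self.down_mask_, ALL_DOWN, NOT_CONSISTENT)
        )
        self.min_abs_ratio_ = np.abs(X).min(axis=0)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "up_mask_")
        return self.up_mask_ | self.down_mask_


@dataclass
class ConsensusList:
    """Per-class unanimous up/down probe lists at a fold threshold."""

    group: str
    threshold_fold: float
    up: list[str]
    down: list[str]
    min_abs_ratio: pd.Series = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.up) + len(self.down)

    def direction_of(self) -> dict[str, str]:
        d = {p: "up" for p in self.up}
        d.update({p: "down" for p in self.down})
        return d

    def to_frame(self) -> pd.DataFrame:
        """Layout accepted by :func:`thyrosig.io.write_gene_list`."""
        probes = self.up + self.down
        return pd.DataFrame(
            {
                "probe_id": probes,
                "direction": ["up"] * len(self.up) + ["down"] * len(self.down),
                "min_abs_log2_ratio": [self.min_abs_ratio[p] for p in probes],
            }
        )


def consensus_lists(
    ratios: pd.DataFrame,
    sheet: pd.Series,
    group: str,
    threshold_fold: float = 2.0,
) -> ConsensusList:
    """Build the unanimous deregulated-probe list for one tumor class.

    Probe order within each list follows the input matrix row order.
    """
    if group not in set(sheet.to_numpy()):
        raise ConfigurationError(f"unknown group: {group!r}")
    cols = [s for s in ratios.columns if s in sheet.index and sheet[s] == group]
    if not cols:
        raise ConfigurationError(f"group {group!r} has no samples in the matrix")
    sel = ConsensusSelector(threshold_fold=threshold_fold).fit(
        ratios[cols].to_numpy().T
    )
    probes = np.asarray(ratios.index, dtype=object)
    return ConsensusList(
        group=group,
        threshold_fold=threshold_fold,
        up=list(probes[sel.up_mask_]),
        down=list(probes[sel.down_mask_]),
        min_abs_ratio=pd.Series(sel.min_abs_ratio_, index=ratios.index),
    )


@dataclass
class GeneList:
    """Gene-level collapse of a probe list."""

    direction_by_gene: dict[str, str]
    conflicts: list[str]  # genes whose probes disagree on direction

    @property
    def size(self) -> int:
        return len(self.direction_by_gene)


def collapse_directions(
    direction_by_probe: dict[str, str], annotation: pd.Series | None
) -> GeneList:
    """Collapse probe-level direction calls to gene level.

    A gene inherits the direction when all of its listed probes agree;
    conflicting genes are excluded and reported separately. Probes missing
    from the annotation pass through under their own probe id.
    """
    by_gene: dict[str, set[str]] = {}
    for probe, direction in direction_by_probe.items():
        gene = probe
        if annotation is not None and probe in annotation.index:
            gene = annotation[probe]
        by_gene.setdefault(gene, set()).add(direction)
    out: dict[str, str] = {}
    conflicts: list[str] = []
    for gene, dirs in by_gene.items():
        if len(dirs) == 1:
            out[gene] = next(iter(dirs))
        else:
            conflicts.append(gene)
    return GeneList(direction_by_gene=out, conflicts=sorted(conflicts))


def collapse_to_genes(clist, annotation: pd.Series | None) -> GeneList:
    """Gene-level view of a :class:`ConsensusList` (or any object exposing
    ``direction_of()``)."""
    return collapse_directions(clist.direction_of(), annotation)
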