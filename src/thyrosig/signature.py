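"""Cross-class aggressiveness-signature selection at the 1.5-fold level.

A probe joins the signature when it passes the fold threshold in *every*
sample of one tumor class while *no* sample of the other class reaches the
opposing threshold ("regulated in all of one class, not modulated the other
way in the other"). Four branches cover the up/down x class combinations; a
probe may satisfy several (e.g. down in every ATC and up in every PTC
satisfies both the ATC-down and PTC-up branches) and all are recorded.

Comparisons are inclusive (>=, <=) on the qualifying side and strict (<, >)
on the opposing-group side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .consensus import collapse_directions, GeneList
from .exceptions import ConfigurationError

__all__ = ["BRANCHES", "SignatureSelector", "SignatureResult", "derive_signature"]

BRANCHES = (
    "ATC_UP_PTC_NOTUP",
    "ATC_DOWN_PTC_NOTDOWN",
    "PTC_UP_ATC_NOTUP",
    "PTC_DOWN_ATC_NOTDOWN",
)


class SignatureSelector(SelectorMixin, BaseEstimator):
    """Select probes discriminating two tumor classes by unanimous fold rules.

    sklearn-style feature selector: ``fit(X, y)`` takes X of shape
    (n_samples, n_probes) and y with exactly the two labels ``atc_label`` and
    ``ptc_label``. With t = log2(threshold_fold) the four branch masks are

    * ATC_UP_PTC_NOTUP:      min over ATC >= +t  and  max over PTC < +t
    * ATC_DOWN_PTC_NOTDOWN:  max over ATC <= -t  and  min over PTC > -t
    * PTC_UP_ATC_NOTUP:      min over PTC >= +t  and  max over ATC < +t
    * PTC_DOWN_ATC_NOTDOWN:  max over PTC <= -t  and  min over ATC > -t

    and the support is their union.

    Attributes
    ----------
    branch_masks_ : dict of str -> ndarray of bool
    min_abs_atc_, min_abs_ptc_ : ndarray of float
        Per-probe minimum |log2 ratio| within each class.
    """

    def __init__(
        self,
        threshold_fold: float = 1.5,
        atc_label: str = "ATC",
        ptc_label: str = "PTC",
    ):
        self.threshold_fold = threshold_fold
        self.atc_label = atc_label
        self.ptc_label = ptc_label

    def fit(self, X, y):
        if self.threshold_fold < 1:
            raise ConfigurationError(
                f"threshold_fold must be >= 1, got {self.threshold_fold}"
            )
        t = math.log2(self.threshold_fold)
        X = check_array(X, dtype=float, ensure_min_samples=2)
        y = np.asarray(y)
        a = y == self.atc_label
        p = y == self.ptc_label
        if not a.any() or not p.any():
            raise ConfigurationError(
                f"both groups {self.atc_label!r} and {self.ptc_label!r} "
                "must be non-empty"
            )
        self.n_features_in_ = X.shape[1]
        min_a, max_a = X[a].min(axis=0), X[a].max(axis=0)
        min_p, max_p = X[p].min(axis=0), X[p].max(axis=0)
        self.branch_masks_ = {
            "ATC_UP_PTC_NOTUP": (min_a >= t) & (max_p < t),
            "ATC_DOWN_PTC_NOTDOWN": (max_a <= -t) & (min_p > -t),
            "PTC_UP_ATC_NOTUP": (min_p >= t) & (max_a < t),
            "PTC_DOWN_ATC_NOTDOWN": (max_p <= -t) & (min_a > -t),
        }
        self.min_abs_atc_ = np.abs(X[a]).min(axis=0)
        self.min_abs_ptc_ = np.abs(X[p]).min(axis=0)
        self._min_a, self._max_a, self._min_p, self._max_p = min_a, max_a, min_p, max_p
        self._t = t
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "branch_masks_")
        masks = list(self.branch_masks_.values())
        out = masks[0].copy()
        for m in masks[1:]:
            out |= m
        return out

    def _group_pattern(self, min_g, max_g):
        if min_g >= self._t:
            return "up"
        if max_g <= -self._t:
            return "down"
        return "not_modulated"


@dataclass
class SignatureResult:
    """Probes passing the cross-class discrimination rules.

    ``frame`` is indexed by probe_id with columns ``branches``
    (comma-joined branch names), ``pattern`` (per-class unanimous direction,
    e.g. ``ATC_down/PTC_up``), ``min_abs_atc`` and ``min_abs_ptc``.
    """

    threshold_fold: float
    frame: pd.DataFrame = field(repr=False)

    @property
    def probes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def size(self) -> int:
        return len(self.frame)

    def branches_of(self, probe: str) -> tuple[str, ...]:
        return tuple(self.frame.loc[probe, "branches"].split(","))

    def direction_of(self) -> dict[str, str]:
        """Per-probe pattern, for gene-level collapsing."""
        return dict(self.frame["pattern"])

    def collapse(self, annotation: pd.Series | None) -> GeneList:
        return collapse_directions(self.direction_of(), annotation)

    def to_frame(self) -> pd.DataFrame:
        """Layout accepted by :func:`thyrosig.io.write_gene_list`."""
        return pd.DataFrame(
            {
                "probe_id": self.frame.index,
                "direction": self.frame["pattern"].to_numpy(),
                "min_abs_log2_ratio": np.minimum(
                    self.frame["min_abs_atc"], self.frame["min_abs_ptc"]
                ).to_numpy(),
            }
        )


def derive_signature(
    ratios: pd.DataFrame,
    sheet: pd.Series,
    threshold_fold: float = 1.5,
) -> SignatureResult:
    """Derive the ATC-vs-PTC aggressiveness signature from log2 ratios."""
    cols = [s for s in ratios.columns if s in sheet.index]
    y = sheet.loc[cols].to_numpy()
    sel = SignatureSelector(threshold_fold=threshold_fold).fit(
        ratios[cols].to_numpy().T, y
    )
    support = sel._get_support_mask()
    idx = np.flatnonzero(support)
    branch_strings = []
    patterns = []
    for i in idx:
        hits = [b for b in BRANCHES if sel.branch_masks_[b][i]]
        branch_strings.append(",".join(hits))
        pat_a = sel._group_pattern(sel._min_a[i], sel._max_a[i])
        pat_p = sel._group_pattern(sel._min_p[i], sel._max_p[i])
        patterns.append(f"ATC_{pat_a}/PTC_{pat_p}")
    frame = pd.DataFrame(
        {
            "branches": branch_strings,
            "pattern": patterns,
            "min_abs_atc": sel.min_abs_atc_[idx],
            "min_abs_ptc": sel.min_abs_ptc_[idx],
        },
        index=pd.Index(np.asarray(ratios.index, dtype=object)[idx], name="probe_id"),
    )
    return SignatureResult(threshold_fold=threshold_fold, frame=frame)
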