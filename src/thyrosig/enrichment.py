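"""AU-rich element (ARE) enrichment between probe groups.

AREs are 3'UTR uridylate-rich motifs controlling mRNA stability. Given a
binary ARE annotation, this module compares the proportion of ARE-flagged
probes between two disjoint probe groups (e.g. regulated vs non-regulated,
or up- vs down-regulated) and attaches a two-sided Fisher exact p-value as
the minimal rigorization of "more ARE-containing genes in group A"; raw
proportions are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError

__all__ = ["AREEnrichment", "fisher_exact_2x2", "are_proportions"]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) whose point probability does not exceed the observed table's
    (point-probability method). A table with a zero margin carries no
    information; its p-value is defined as 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise DataError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise DataError("table entries must be non-negative")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


@dataclass
class AREEnrichment:
    """2x2 ARE-by-group table with row proportions and exact p-value.

    ``table`` rows are the two probe groups, columns (ARE, no-ARE).
    ``pct_a``/``pct_b`` are the per-group flagged percentages rounded to one
    decimal.
    """

    table: np.ndarray
    pct_a: float
    pct_b: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "pct_a": self.pct_a,
            "pct_b": self.pct_b,
            "p_value": self.p_value,
        }


def are_proportions(group_a, group_b, are: pd.Series) -> AREEnrichment:
    """ARE-flag proportions of two disjoint probe groups plus exact test.

    Every probe in either group must be present in the annotation;
    unannotated probes are reported by id.
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise DataError("both probe groups must be non-empty")
    overlap = set(a) & set(b)
    if overlap:
        raise DataError(f"probe groups must be disjoint; shared: {sorted(overlap)}")
    unannotated = [p for p in a + b if p not in are.index]
    if unannotated:
        raise DataError(f"probes missing from the ARE table: {unannotated}")
    flags_a = int(are.loc[a].sum())
    flags_b = int(are.loc[b].sum())
    table = np.array(
        [[flags_a, len(a) - flags_a], [flags_b, len(b) - flags_b]], dtype=int
    )
    return AREEnrichment(
        table=table,
        pct_a=round(100.0 * flags_a / len(a), 1),
        pct_b=round(100.0 * flags_b / len(b), 1),
        p_value=fisher_exact_2x2(table),
    )
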