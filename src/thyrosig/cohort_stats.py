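"""Overlap, concordance, mutation-frequency and amplification statistics.

These operations quantify how the two tumor classes relate: how much of the
PTC consensus list is shared with the ATC list (Venn arithmetic), whether two
platforms agree on regulation direction, how often screened genes are
mutated, and how much stronger shared regulations are in ATC than in PTC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusList
from .exceptions import DataError

__all__ = [
    "round_half_away",
    "OverlapSummary",
    "overlap_summary",
    "ConcordanceResult",
    "direction_concordance",
    "MutationSummary",
    "mutation_frequencies",
    "AmplificationResult",
    "amplification_stat",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (so 42.5 -> 43, -1.5 -> -2)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class OverlapSummary:
    """Venn arithmetic between the PTC and ATC consensus lists."""

    ptc_up: int
    ptc_down: int
    atc_up: int
    atc_down: int
    shared_up: int
    shared_down: int
    opposite: int
    pct_ptc_shared: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def overlap_summary(ptc: ConsensusList, atc: ConsensusList) -> OverlapSummary:
    """Count same- and opposite-direction overlaps between the class lists.

    ``pct_ptc_shared`` is the percentage of PTC-deregulated probes regulated
    the same way in all ATC, rounded half away from zero; defined as 0 when
    the PTC lists are empty.
    """
    pu, pdn = set(ptc.up), set(ptc.down)
    au, adn = set(atc.up), set(atc.down)
    shared_up = len(pu & au)
    shared_down = len(pdn & adn)
    opposite = len(pu & adn) + len(pdn & au)
    denom = len(pu) + len(pdn)
    pct = round_half_away(100.0 * (shared_up + shared_down) / denom) if denom else 0
    return OverlapSummary(
        ptc_up=len(pu),
        ptc_down=len(pdn),
        atc_up=len(au),
        atc_down=len(adn),
        shared_up=shared_up,
        shared_down=shared_down,
        opposite=opposite,
        pct_ptc_shared=pct,
    )


@dataclass
class ConcordanceResult:
    """Direction agreement between two per-gene log2 ratio vectors."""

    fraction: float
    n_compared: int
    ties: list[str]  # genes with a zero ratio on either side, excluded


def direction_concordance(a: pd.Series, b: pd.Series) -> ConcordanceResult:
    """Fraction of genes whose log2 ratios agree in sign between platforms.

    Genes with a zero ratio on either side have undefined direction; they are
    excluded from the denominator and reported as ties. Symmetric in (a, b).
    """
    if len(a) == 0 or len(b) == 0:
        raise DataError("direction concordance of an empty gene set is undefined")
    if set(a.index) != set(b.index):
        raise DataError(
            "gene sets differ: " + str(sorted(set(a.index) ^ set(b.index)))
        )
    b = b.reindex(a.index)
    tie_mask = (a == 0) | (b == 0)
    ties = sorted(a.index[tie_mask])
    a_, b_ = a[~tie_mask], b[~tie_mask]
    if len(a_) == 0:
        raise DataError("all genes are ties (zero ratios); concordance undefined")
    frac = float(np.mean(np.sign(a_) == np.sign(b_)))
    return ConcordanceResult(fraction=frac, n_compared=len(a_), ties=ties)


@dataclass
class MutationSummary:
    """Per-gene mutation counts/percentages and co-occurrence."""

    n_samples: int
    counts: dict[str, int]
    percents: dict[str, int]
    co_mutated_samples: dict[str, list[str]]  # sample -> its >=2 mutated genes

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "counts": self.counts,
            "percents": self.percents,
            "co_mutated_samples": self.co_mutated_samples,
        }


def mutation_frequencies(table: pd.DataFrame) -> MutationSummary:
    """Summarize a long-format mutation table (sample_id, gene, status).

    Percentages are 100 * count / n_samples rounded half away from zero.
    Samples carrying two or more mutations are reported for co-occurrence.
    """
    samples = list(dict.fromkeys(table["sample_id"]))
    if not samples:
        raise DataError("mutation table has no samples")
    n = len(samples)
    mutated = table.loc[table["status"] == 1]
    counts = {
        g: int((mutated["gene"] == g).sum())
        for g in dict.fromkeys(table["gene"])
    }
    percents = {g: round_half_away(100.0 * c / n) for g, c in counts.items()}
    per_sample = mutated.groupby("sample_id")["gene"].apply(list)
    co = {
        s: sorted(gs)
        for s, gs in per_sample.items()
        if len(gs) >= 2
    }
    return MutationSummary(
        n_samples=n, counts=counts, percents=percents, co_mutated_samples=co
    )


@dataclass
class AmplificationResult:
    """Strength of shared regulations in ATC relative to PTC.

    Per shared probe: mean |log2 ratio| over ATC divided by mean |log2 ratio|
    over PTC (values > 1 mean stronger regulation in ATC), plus the cohort
    median. Probes with a zero PTC mean are flagged and excluded.
    """

    per_probe: pd.Series = field(repr=False)
    median: float
    excluded: list[str]


def amplification_stat(
    ratios: pd.DataFrame, sheet: pd.Series, shared_probes
) -> AmplificationResult:
    shared_probes = list(shared_probes)
    if not shared_probes:
        raise DataError("shared probe set is empty")
    missing = [p for p in shared_probes if p not in ratios.index]
    if missing:
        raise DataError(f"shared probes missing from the matrix: {missing}")
    groups = sheet.loc[ratios.columns]
    atc_cols = list(ratios.columns[(groups == "ATC").to_numpy()])
    ptc_cols = list(ratios.columns[(groups == "PTC").to_numpy()])
    if not atc_cols or not ptc_cols:
        raise DataError("both ATC and PTC samples are required")
    sub = ratios.loc[shared_probes]
    mean_a = sub[atc_cols].abs().mean(axis=1)
    mean_p = sub[ptc_cols].abs().mean(axis=1)
    zero = mean_p == 0
    per_probe = (mean_a[~zero] / mean_p[~zero]).rename("amplification")
    if len(per_probe) == 0:
        raise DataError("every shared probe has zero PTC mean |ratio|")
    return AmplificationResult(
        per_probe=per_probe,
        median=float(per_probe.median()),
        excluded=list(mean_p.index[zero]),
    )
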