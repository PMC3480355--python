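"""Synthetic ATC/PTC cohort generator with planted regulation classes.

Emulates the statistical structure of a two-class thyroid-carcinoma microarray
cohort expressed as log2 tumor/normal-pool ratios: 11 anaplastic (ATC) and 48
papillary (PTC) tumors against a pooled normal reference. Probes fall into
eight planted classes:

* ``SHARED_UP`` / ``SHARED_DOWN`` — regulated in the same direction in both
  tumor classes, with the ATC effect amplified by a constant factor (the
  "regulations are weaker in PTC" structure).
* ``PTC_ONLY_*`` / ``ATC_ONLY_*`` — consistently regulated (2-fold in every
  sample) only in one class. The other class is *partially* co-regulated: a
  random proper subset of its samples carries the same-direction effect, so
  these probes are modulated in the other class (excluding them from the
  1.5-fold cross-class signature rule) without ever reaching unanimous 2-fold
  regulation there.
* ``SIGNATURE`` — down in every ATC and up in every PTC beyond the 1.5-fold
  threshold plus a guard margin; the planted aggressiveness signature.
* ``NULL`` — no planted effect, pure noise background.

Noise is additive Gaussian on the log2 scale; for planted (non-NULL) probes it
is truncated at ±``margin`` so that planted memberships survive noise exactly
rather than probabilistically. NULL probes receive untruncated noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats as _st

from .exceptions import ConfigurationError

__all__ = [
    "PROBE_CLASSES",
    "SyntheticScenario",
    "GroundTruth",
    "generate_cohort",
    "generate_are_table",
]

PROBE_CLASSES = (
    "SHARED_UP",
    "SHARED_DOWN",
    "PTC_ONLY_UP",
    "PTC_ONLY_DOWN",
    "ATC_ONLY_UP",
    "ATC_ONLY_DOWN",
    "SIGNATURE",
    "NULL",
)

_LOG2_15 = math.log2(1.5)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of a synthetic cohort.

    Defaults are the package's "paper-like" desk-scale scenario: 11 ATC and
    48 PTC samples, 5000 probes standing in for a full array, a 9-probe
    planted signature, and a 2x amplification of shared effects in ATC.

    Parameters
    ----------
    n_atc, n_ptc : int
        Tumor sample counts per class.
    n_pool : int
        Size of the conceptual normal reference pool. The pool is not
        simulated sample-by-sample (ratios are drawn directly against the
        pool mean); kept for metadata realism.
    n_probes : int
        Total probe count; probes not assigned to a planted class are NULL.
    n_shared_up, n_shared_down : int
        Probes regulated concordantly in both classes.
    amplification : float
        Multiplicative factor (on the log2 effect) applied to shared-probe
        effects in ATC relative to PTC. Must be >= 1.
    n_ptc_only_up, n_ptc_only_down, n_atc_only_up, n_atc_only_down : int
        Class-restricted consistently regulated probes.
    n_signature : int
        Probes down >=1.5-fold in every ATC and up >=1.5-fold in every PTC.
    effect_low, effect_high : float
        Bounds (log2 units) of the uniform distribution of per-probe base
        effect magnitudes. ``effect_low`` must be >= log2(1.5) + margin so
        planted signature/modulation calls survive truncated noise.
    noise_sd : float
        Standard deviation (log2 units) of the additive Gaussian noise.
    margin : float
        Guard band (log2 units); noise on planted probes is truncated at
        +/- margin. Must satisfy margin < 1 (= log2 of the 2-fold threshold)
        so partially co-regulated samples never reach unanimous 2-fold.
    cross_talk : float
        Fraction of other-class samples co-regulated for class-restricted
        probes (clamped so that at least one sample is and at least one is
        not co-regulated).
    seed : int
        Root RNG seed; per-component substreams are derived from it.
    """

    n_atc: int = 11
    n_ptc: int = 48
    n_pool: int = 23
    n_probes: int = 5000
    n_shared_up: int = 200
    n_shared_down: int = 200
    amplification: float = 2.0
    n_ptc_only_up: int = 60
    n_ptc_only_down: int = 30
    n_atc_only_up: int = 150
    n_atc_only_down: int = 150
    n_signature: int = 9
    effect_low: float = 1.3
    effect_high: float = 2.5
    noise_sd: float = 0.15
    margin: float = 0.7
    cross_talk: float = 0.3
    seed: int = 42

    def planted_counts(self) -> dict[str, int]:
        return {
            "SHARED_UP": self.n_shared_up,
            "SHARED_DOWN": self.n_shared_down,
            "PTC_ONLY_UP": self.n_ptc_only_up,
            "PTC_ONLY_DOWN": self.n_ptc_only_down,
            "ATC_ONLY_UP": self.n_atc_only_up,
            "ATC_ONLY_DOWN": self.n_atc_only_down,
            "SIGNATURE": self.n_signature,
        }

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the violated invariant."""
        counts = self.planted_counts()
        for name, c in counts.items():
            if c < 0:
                raise ConfigurationError(f"negative probe count for {name}: {c}")
        if self.n_atc < 1 or self.n_ptc < 1:
            raise ConfigurationError("need at least one sample per tumor class")
        if self.n_pool < 1:
            raise ConfigurationError("n_pool must be >= 1")
        total = sum(counts.values())
        if total > self.n_probes:
            raise ConfigurationError(
                f"planted probes ({total}) exceed n_probes ({self.n_probes})"
            )
        if self.amplification < 1:
            raise ConfigurationError(
                f"amplification must be >= 1, got {self.amplification}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.margin < 1:
            raise ConfigurationError(
                "margin must lie in [0, 1) log2 units (below the 2-fold threshold)"
            )
        if self.effect_high < self.effect_low:
            raise ConfigurationError("effect_high must be >= effect_low")
        if self.effect_low < _LOG2_15 + self.margin:
            raise ConfigurationError(
                "effect_low must be >= log2(1.5) + margin "
                f"({_LOG2_15 + self.margin:.4f}) to guarantee planted calls"
            )
        if not 0 <= self.cross_talk <= 1:
            raise ConfigurationError("cross_talk must lie in [0, 1]")
        has_restricted = (
            self.n_ptc_only_up + self.n_ptc_only_down
            + self.n_atc_only_up + self.n_atc_only_down
        ) > 0
        if has_restricted and (self.n_atc < 2 or self.n_ptc < 2):
            raise ConfigurationError(
                "class-restricted probes require >= 2 samples per class "
                "(partial co-regulation needs a proper subset)"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted class labels and effects of a generated cohort.

    Attributes
    ----------
    table : pandas.DataFrame
        Indexed by probe_id, columns ``label``, ``atc_effect``, ``ptc_effect``
        — the *mean* planted effect per sample group in log2 units (for a
        partially co-regulated group this is fraction x effect).
    effects : pandas.DataFrame
        Full planted per-sample effect matrix, probes x samples; the noiseless
        version of the generated ratio matrix.
    """

    table: pd.DataFrame
    effects: pd.DataFrame = field(repr=False)

    def probes(self, *labels: str) -> list[str]:
        """Probe ids carrying any of the given class labels."""
        for lab in labels:
            if lab not in PROBE_CLASSES:
                raise ConfigurationError(f"unknown probe class: {lab}")
        mask = self.table["label"].isin(labels)
        return list(self.table.index[mask])

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def _spawn_rngs(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _truncated_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sd: float, bound: float
) -> np.ndarray:
    """Gaussian noise conditioned on |x| <= bound (exact truncation)."""
    if sd == 0 or bound == 0:
        return np.zeros(shape)
    a, b = -bound / sd, bound / sd
    return _st.truncnorm.rvs(a, b, scale=sd, size=shape, random_state=rng)


def _partial_mask(
    rng: np.random.Generator, n_rows: int, n_cols: int, frac: float
) -> np.ndarray:
    """Boolean mask with exactly k True per row, 1 <= k <= n_cols - 1."""
    k = int(round(frac * n_cols))
    k = min(max(k, 1), n_cols - 1)
    order = np.argsort(rng.random((n_rows, n_cols)), axis=1)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    rows = np.repeat(np.arange(n_rows), k)
    mask[rows, order[:, :k].ravel()] = True
    return mask


def generate_cohort(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Generate a synthetic log2-ratio cohort.

    Returns
    -------
    ratios : pandas.DataFrame
        Probes x tumor samples, log2(tumor / normal-pool) values.
    sheet : pandas.Series
        sample_id -> group label ('ATC' or 'PTC').
    truth : GroundTruth
        Planted labels and effects, for recovery testing.

    Two calls with the same scenario (hence same seed) are bit-identical.
    """
    scenario.validate()
    sc = scenario
    rngs = _spawn_rngs(
        sc.seed, ("effects", "crosstalk", "noise_planted", "noise_null")
    )

    n_digits = max(5, len(str(sc.n_probes)))
    probe_ids = [f"probe_{i:0{n_digits}d}" for i in range(1, sc.n_probes + 1)]
    atc_ids = [f"ATC_{i:02d}" for i in range(1, sc.n_atc + 1)]
    ptc_ids = [f"PTC_{i:02d}" for i in range(1, sc.n_ptc + 1)]
    sample_ids = atc_ids + ptc_ids
    atc_cols = slice(0, sc.n_atc)
    ptc_cols = slice(sc.n_atc, sc.n_atc + sc.n_ptc)

    counts = sc.planted_counts()
    labels = np.array(
        sum(([lab] * counts[lab] for lab in counts), [])
        + ["NULL"] * (sc.n_probes - sum(counts.values())),
        dtype=object,
    )

    n_planted = sum(counts.values())
    base = rngs["effects"].uniform(sc.effect_low, sc.effect_high, size=n_planted)
    effects = np.zeros((sc.n_probes, sc.n_atc + sc.n_ptc))

    row = 0
    for lab, n in counts.items():
        if n == 0:
            continue
        e = base[row : row + n]
        block = effects[row : row + n]
        if lab == "SHARED_UP":
            block[:, atc_cols] = (sc.amplification * e)[:, None]
            block[:, ptc_cols] = e[:, None]
        elif lab == "SHARED_DOWN":
            block[:, atc_cols] = -(sc.amplification * e)[:, None]
            block[:, ptc_cols] = -e[:, None]
        elif lab in ("PTC_ONLY_UP", "PTC_ONLY_DOWN"):
            sign = 1.0 if lab.endswith("UP") else -1.0
            block[:, ptc_cols] = sign * e[:, None]
            mask = _partial_mask(rngs["crosstalk"], n, sc.n_atc, sc.cross_talk)
            block[:, atc_cols] = np.where(mask, sign * e[:, None], 0.0)
        elif lab in ("ATC_ONLY_UP", "ATC_ONLY_DOWN"):
            sign = 1.0 if lab.endswith("UP") else -1.0
            block[:, atc_cols] = sign * e[:, None]
            mask = _partial_mask(rngs["crosstalk"], n, sc.n_ptc, sc.cross_talk)
            block[:, ptc_cols] = np.where(mask, sign * e[:, None], 0.0)
        elif lab == "SIGNATURE":
            block[:, atc_cols] = -e[:, None]
            block[:, ptc_cols] = e[:, None]
        row += n

    planted = labels != "NULL"
    noise = np.zeros_like(effects)
    noise[planted] = _truncated_noise(
        rngs["noise_planted"],
        (int(planted.sum()), effects.shape[1]),
        sc.noise_sd,
        sc.margin,
    )
    n_null = int((~planted).sum())
    if sc.noise_sd > 0 and n_null:
        noise[~planted] = rngs["noise_null"].normal(
            0.0, sc.noise_sd, size=(n_null, effects.shape[1])
        )

    ratios = pd.DataFrame(effects + noise, index=probe_ids, columns=sample_ids)
    sheet = pd.Series(
        ["ATC"] * sc.n_atc + ["PTC"] * sc.n_ptc, index=sample_ids, name="group"
    )

    truth_table = pd.DataFrame(
        {
            "label": labels,
            "atc_effect": effects[:, atc_cols].mean(axis=1),
            "ptc_effect": effects[:, ptc_cols].mean(axis=1),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    truth = GroundTruth(
        table=truth_table,
        effects=pd.DataFrame(effects, index=probe_ids, columns=sample_ids),
    )
    return ratios, sheet, truth


def generate_are_table(
    truth: GroundTruth, p_regulated: float, p_null: float, seed: int
) -> pd.Series:
    """Assign each probe an independent AU-rich-element (ARE) flag.

    Probes in any planted regulation class are flagged with probability
    ``p_regulated``; NULL probes with probability ``p_null``. Returns a
    probe_id -> {0,1} Series emulating an ARED-style annotation table.
    """
    for name, p in (("p_regulated", p_regulated), ("p_null", p_null)):
        if not 0 <= p <= 1:
            raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    is_null = (truth.labels == "NULL").to_numpy()
    p_vec = np.where(is_null, p_null, p_regulated)
    flags = (rng.random(len(p_vec)) < p_vec).astype(int)
    return pd.Series(flags, index=truth.table.index, name="are_flag")
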