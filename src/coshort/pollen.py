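"""Pollen-sample rendering and dichotomous phenotype classification.

Gamete pools from :mod:`coshort.meiosis` are turned into microscopy-like
observations: balanced gametes become stainable grains, unbalanced reduced
gametes become shrivelled unstained grains (with a small probability of a
stainable aneuploid), and grain diameters are drawn per ploidy class.
Unreduced (2n) grains are on average ~15% wider than reduced grains; a
fixed diameter cutoff (default 23 µm) separates the size classes.

Samples are then classified with a dichotomous key into ``unknown`` (too
few stained grains to say anything), ``wild_type`` (stained reduced grains
present), ``co_shortage`` (stained grains are unreduced while unstained
small grains witness the failed reduced meiosis), or ``undetermined``.

The wild-type rule comes in two flavours: the lenient rule accepts a
single small stained grain as evidence of normal reduction, which makes
mutants producing a few stainable aneuploid grains easy to miss (a false
negative).  The strict rule requires small stained grains to exceed 5% of
the stained fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .meiosis import Gamete, UNREDUCED

__all__ = [
    "PollenGrain",
    "PollenSample",
    "ClassifierConfig",
    "render_sample",
    "classify_sample",
    "UNKNOWN",
    "WILD_TYPE_CALL",
    "CO_SHORTAGE_CALL",
    "UNDETERMINED",
]

UNKNOWN = "unknown"
WILD_TYPE_CALL = "wild_type"
CO_SHORTAGE_CALL = "co_shortage"
UNDETERMINED = "undetermined"
LENIENT = "lenient"
STRICT = "strict"


@dataclass(frozen=True)
class ClassifierConfig:
    """Rendering and classification parameters.

    ``diameter_threshold`` (µm) separates small (n) from large (2n)
    grains.  Reduced-grain diameters are normal with mean ``n_mean_um``
    and coefficient of variation ``diameter_cv``; unreduced grains are
    ``size_ratio`` times wider.  ``aneuploid_stainable_prob`` is the
    per-grain probability that an unbalanced reduced gamete still renders
    as a stained small grain (aneuploid cytoplasm that takes the stain).
    """

    min_stained_fraction: float = 0.05
    strict_small_fraction: float = 0.05
    diameter_threshold: float = 23.0
    n_mean_um: float = 22.0
    size_ratio: float = 1.15
    diameter_cv: float = 0.04
    aneuploid_stainable_prob: float = 0.003

    def __post_init__(self) -> None:
        for name in ("min_stained_fraction", "strict_small_fraction", "aneuploid_stainable_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.diameter_threshold <= 0 or self.n_mean_um <= 0 or self.size_ratio <= 0:
            raise ValueError("diameters and ratios must be positive")


@dataclass(frozen=True)
class PollenGrain:
    stained: bool
    diameter: float

    def size_class(self, cfg: ClassifierConfig) -> str:
        return "large_2n" if self.diameter > cfg.diameter_threshold else "small_n"


@dataclass
class PollenSample:
    """A rendered pollen sample with derived grain counts."""

    grains: list[PollenGrain]
    cfg: ClassifierConfig = field(default_factory=ClassifierConfig)

    def _is_large(self, g: PollenGrain) -> bool:
        return g.diameter > self.cfg.diameter_threshold

    @property
    def n_total(self) -> int:
        return len(self.grains)

    @property
    def n_stained(self) -> int:
        return sum(g.stained for g in self.grains)

    @property
    def n_stained_small(self) -> int:
        return sum(g.stained and not self._is_large(g) for g in self.grains)

    @property
    def n_stained_large(self) -> int:
        return sum(g.stained and self._is_large(g) for g in self.grains)

    @property
    def n_unstained(self) -> int:
        return self.n_total - self.n_stained

    @property
    def n_unstained_small(self) -> int:
        return sum((not g.stained) and not self._is_large(g) for g in self.grains)

    @property
    def stained_fraction(self) -> float:
        return self.n_stained / self.n_total if self.n_total else 0.0


def render_sample(
    gametes: Sequence[Gamete],
    cfg: ClassifierConfig | None = None,
    n_grains: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PollenSample:
    """Draw ``n_grains`` pollen grains (with replacement) from a gamete pool.

    Balanced gametes stain; unbalanced reduced gametes are unstained
    except with probability ``cfg.aneuploid_stainable_prob``.  Diameters
    follow the per-ploidy normal distributions, truncated at zero.
    """
    if not gametes:
        raise ValueError("gamete pool is empty")
    cfg = cfg or ClassifierConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    grains: list[PollenGrain] = []
    idx = rng.integers(0, len(gametes), size=n_grains)
    for i in idx:
        g = gametes[int(i)]
        if g.balanced:
            stained = True
        else:
            stained = bool(rng.random() < cfg.aneuploid_stainable_prob)
        mean = cfg.n_mean_um * (cfg.size_ratio if g.ploidy_class == UNREDUCED else 1.0)
        diameter = max(float(rng.normal(mean, cfg.diameter_cv * mean)), 0.0)
        grains.append(PollenGrain(stained=stained, diameter=diameter))
    return PollenSample(grains=grains, cfg=cfg)


def classify_sample(sample: PollenSample, cfg: ClassifierConfig | None = None, mode: str = STRICT) -> str:
    """Apply the dichotomous key to a pollen sample.

    1. Stained fraction below ``min_stained_fraction`` → ``unknown``
       (indistinguishable from other causes of sterility).
    2. Otherwise, small stained grains present (lenient: at least one;
       strict: more than ``strict_small_fraction`` of stained grains) →
       ``wild_type``.
    3. Otherwise, large stained grains alongside small unstained grains →
       ``co_shortage`` (2n pollen rescued by restitution next to the
       shrivelled unbalanced reduced grains).
    4. Anything else → ``undetermined``.
    """
    cfg = cfg or sample.cfg
    if mode not in (LENIENT, STRICT):
        raise ValueError(f"mode must be '{LENIENT}' or '{STRICT}'")
    if sample.n_total < 1:
        raise ValueError("sample has no grains")
    if sample.stained_fraction < cfg.min_stained_fraction:
        return UNKNOWN
    n_st = sample.n_stained
    if mode == LENIENT:
        is_wt = sample.n_stained_small >= 1
    else:
        # "more than 5%" is an exclusive boundary: exactly 5% is not wild type.
        is_wt = n_st > 0 and sample.n_stained_small / n_st > cfg.strict_small_fraction
    if is_wt:
        return WILD_TYPE_CALL
    if sample.n_stained_large >= 1 and sample.n_unstained_small >= 1:
        return CO_SHORTAGE_CALL
    return UNDETERMINED
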