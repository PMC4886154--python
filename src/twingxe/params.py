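"""Parameter containers and published reference values for the 9-item liberalism scale.

The package models three-category ("no"/"?"/"yes") Wilson-Patterson-style attitude
items with a generalized partial credit model (GPCM) whose latent trait is
decomposed, twin-biometrically, into additive-genetic (A), common-environment (C)
and unique-environment (E) components.  The environmental variances are moderated
exp-linearly by the genetic value:

    sigma2_E = exp(beta0 + beta1 * A)      (A x E interaction)
    sigma2_C = exp(gamma0 + gamma1 * A)    (A x C interaction)

`GeneratingParams` bundles everything the synthetic-data generator needs;
`ItemParams` holds one item's GPCM discrimination and two step thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "ItemParams",
    "GeneratingParams",
    "LIBERALISM_9_ITEMS",
    "PAPER_SELECTED_ITEMS",
    "REVERSE_CODED_28",
    "reference_generating_params",
]


@dataclass(frozen=True)
class ItemParams:
    """GPCM parameters of one three-category item.

    Parameters
    ----------
    alpha : float
        Discrimination (slope); must be positive.
    b1 : float
        First step threshold: trait location where the "no" and "?" weights
        are equal.
    b2 : float
        Second step threshold: "?" versus "yes".
    name : str, optional
        Item label.
    """

    alpha: float
    b1: float
    b2: float
    name: str = ""

    def __post_init__(self) -> None:
        import math

        if not (self.alpha > 0):
            raise ValueError(f"discrimination must be positive, got {self.alpha}")
        if not (math.isfinite(self.b1) and math.isfinite(self.b2)):
            raise ValueError("thresholds must be finite")


@dataclass(frozen=True)
class GeneratingParams:
    """Full generating model for a synthetic twin item-response dataset.

    ``sigma2_A`` is the additive-genetic variance of the latent trait;
    ``gamma0``/``gamma1`` are intercept and A x C slope of the log
    common-environment variance, ``beta0``/``beta1`` intercept and A x E slope
    of the log unique-environment variance.
    """

    sigma2_A: float
    gamma0: float
    gamma1: float
    beta0: float
    beta1: float
    items: tuple[ItemParams, ...]
    n_mz: int = 2795
    n_dz: int = 3280
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sigma2_A > 0):
            raise ValueError(f"sigma2_A must be > 0, got {self.sigma2_A}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if len(self.items) < 1:
            raise ValueError("at least one item is required")
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def n_items(self) -> int:
        return len(self.items)

    def with_(self, **kwargs) -> "GeneratingParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: Published GPCM estimates (discrimination, two step thresholds) for the nine
#: liberalism items retained from the 28-item Wilson-Patterson conservatism
#: scale in the Virginia 30K twin-family survey, trait identified as N(0, 1).
#: School prayer is reverse-coded so that high trait = liberal.
LIBERALISM_9_ITEMS: tuple[ItemParams, ...] = (
    ItemParams(0.58, -1.52, -1.47, "X-rated movies"),
    ItemParams(0.60, 0.11, 0.09, "Modern art"),
    ItemParams(1.00, 0.22, 0.80, "Women's liberation"),
    ItemParams(1.01, -0.65, -0.16, "Abortion"),
    ItemParams(1.65, -0.90, -1.95, "Gay rights"),
    ItemParams(1.44, 0.57, -0.67, "Liberals"),
    ItemParams(1.08, -0.91, -0.53, "Living together"),
    ItemParams(0.74, -0.44, 0.23, "Divorce"),
    ItemParams(0.65, -1.86, -2.04, "School prayer (rev. coded)"),
)

#: The nine items retained by the homogeneity-based selection rule (higher
#: absolute loading on the liberalism-conservatism dimension than on the
#: "?"-response dimension) in the Virginia 30K analysis.
PAPER_SELECTED_ITEMS: tuple[str, ...] = (
    "Gay rights",
    "Women's liberation",
    "Living together",
    "Modern art",
    "Divorce",
    "X-rated movies",
    "School prayer (reverse-coded)",
    "Liberalism",
    "Abortion",
)

#: Conservatism-keyed items of the 28-item scale (1-based positions and labels)
#: that are reverse coded so a high sum score means high liberalism.
REVERSE_CODED_28: dict[int, str] = {
    1: "Death penalty",
    9: "Military drill",
    10: "Draft",
    16: "Capitalism",
    17: "Segregation",
    18: "Moral majority",
    20: "Censorship",
    21: "Nuclear power",
    23: "Republicans",
    25: "School prayer",
    28: "Busing",
}

# Biometric posterior means reported for the Virginia 30K liberalism scale,
# used as the default generating truth for parameter-recovery simulations:
# sigma2_A = 0.43, exp(gamma0) = 0.29, exp(beta0) = 0.07, beta1 = -2.81,
# gamma1 = 0.54.
_REF_SIGMA2_A = 0.43
_REF_EXP_GAMMA0 = 0.29
_REF_EXP_BETA0 = 0.07
_REF_BETA1 = -2.81
_REF_GAMMA1 = 0.54


def reference_generating_params(
    n_mz: int = 2795,
    n_dz: int = 3280,
    missing_rate: float = 0.05,
    seed: int = 0,
    items: Sequence[ItemParams] = LIBERALISM_9_ITEMS,
) -> GeneratingParams:
    """Generating parameters at the published biometric posterior means.

    Combines the reported ACE + A x E + A x C estimates for the liberalism
    trait with the published 9-item GPCM parameters, at configurable family
    counts (defaults: the survey's 2795 MZ and 3280 DZ pairs).
    """
    import math

    return GeneratingParams(
        sigma2_A=_REF_SIGMA2_A,
        gamma0=math.log(_REF_EXP_GAMMA0),
        gamma1=_REF_GAMMA1,
        beta0=math.log(_REF_EXP_BETA0),
        beta1=_REF_BETA1,
        items=tuple(items),
        n_mz=n_mz,
        n_dz=n_dz,
        missing_rate=missing_rate,
        seed=seed,
    )
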