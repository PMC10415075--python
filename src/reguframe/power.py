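"""A-priori sample-size lower bound for structural equation models.

Two published components are combined, following Westland (2010):

1. *Effect-detection bound.*  An SEM simultaneously tests all
   m = j (j - 1) / 2 pairwise correlations among its j latent variables, so
   the significance level is Šidák-adjusted to a* = 1 - (1 - a)^(1/m).
   The minimum n to detect an anticipated standardized effect delta at
   adjusted significance a* and power 1 - beta is

       n1 = ceil( ((z_{1-a*/2} + z_{1-beta}) / delta)^2 + 3 ).

2. *Model-structure bound.*  The simulation-fitted curve in the ratio
   r = indicators / latents,

       n2 = ceil( 50 r^2 - 450 r + 1100 ),

   evaluated left of its vertex (r = 4.5) and held at the vertex value
   beyond it, so the bound is non-increasing in r.

The recommended minimum is max(n1, n2).  On alpha = 0.05, power = 0.90,
effect = 0.30 with 11 latent and 41 observed variables this yields
max(238, 118) = 238.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from reguframe.errors import InvalidConfigError


@dataclass(frozen=True)
class PowerInputs:
    """Inputs of the a-priori bound: significance level, target power,
    anticipated standardized effect size, and the model's latent and
    indicator counts."""

    alpha: float = 0.05
    power: float = 0.90
    effect: float = 0.30
    n_latent: int = 11
    n_indicators: int = 41

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise InvalidConfigError("power must lie in (0, 1)")
        if not 0.0 < self.effect < 1.0:
            raise InvalidConfigError("effect size must lie in (0, 1)")
        if self.n_latent < 1 or self.n_indicators < self.n_latent:
            raise InvalidConfigError("need n_indicators >= n_latent >= 1")


def effect_bound(p: PowerInputs) -> int:
    """Minimum n to detect the anticipated effect (component 1)."""
    p.validate()
    m = p.n_latent * (p.n_latent - 1) / 2
    alpha_adj = 1.0 - (1.0 - p.alpha) ** (1.0 / m) if m >= 1 else p.alpha
    z_a = norm.ppf(1.0 - alpha_adj / 2.0)
    z_b = norm.ppf(p.power)
    return math.ceil(((z_a + z_b) / p.effect) ** 2 + 3.0)


def structure_bound(p: PowerInputs) -> int:
    """Minimum n supported by the indicator-to-latent ratio (component 2)."""
    p.validate()
    r = min(p.n_indicators / p.n_latent, 4.5)
    return math.ceil(50.0 * r * r - 450.0 * r + 1100.0)


def westland_sample_size(*args, **kwargs) -> int:
    """Recommended minimum SEM sample size: the larger of the
    effect-detection and model-structure bounds.

    Accepts either a :class:`PowerInputs` or
    ``(alpha, power, effect, n_latent, n_indicators)``.
    """
    if len(args) == 1 and isinstance(args[0], PowerInputs) and not kwargs:
        p = args[0]
    else:
        p = PowerInputs(*args, **kwargs)
    return max(effect_bound(p), structure_bound(p))


def sample_size_report(p: PowerInputs) -> dict[str, int]:
    return {
        "effect_bound": effect_bound(p),
        "structure_bound": structure_bound(p),
        "recommended": westland_sample_size(p),
    }
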