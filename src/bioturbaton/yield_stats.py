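"""Over/underyielding of species mixtures: the D_max statistic.

D_max compares a mixture's performance to the *best-performing* species
monoculture (transgressive overyielding).  Responses are first mapped to a
common performance scale: identity when larger values mean more function,
negation when smaller (more negative) values mean more function — e.g. a
tracer drawdown where negative changes indicate stronger bioirrigation.
With P the performance scale,

    D_max_i = (P_mix_i - max_s mean(P_mono_s)) / max_s mean(P_mono_s)

per mixture replicate i; the estimate is the replicate mean with a
Student-t 95% confidence interval.  D_max > 0 is overyielding (the mixture
outperforms every monoculture), D_max < 0 underyielding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["YieldInput", "DmaxResult", "d_max"]


@dataclass
class YieldInput:
    """Mixture replicates and monoculture means for one response variable."""

    mixture_values: np.ndarray  # one value per mixture replicate
    monoculture_means: dict  # species label -> mean response
    response_direction: str = "higher_is_more"  # or "lower_is_more"
    response_name: str = ""

    def __post_init__(self) -> None:
        self.mixture_values = np.asarray(self.mixture_values, dtype=float)
        if self.mixture_values.size < 2:
            raise ValueError("need at least 2 mixture replicates")
        if not self.monoculture_means:
            raise ValueError("need at least one monoculture")
        if self.response_direction not in ("higher_is_more", "lower_is_more"):
            raise ValueError("response_direction must be higher_is_more or lower_is_more")


@dataclass
class DmaxResult:
    estimate: float
    ci_lo: float
    ci_hi: float
    per_replicate: np.ndarray
    best_monoculture: str
    response_name: str = ""


def d_max(inp: YieldInput, ci_level: float = 0.95) -> DmaxResult:
    """Proportional deviation of mixture performance from the best monoculture."""
    sign = 1.0 if inp.response_direction == "higher_is_more" else -1.0
    p_mix = sign * inp.mixture_values
    p_mono = {s: sign * m for s, m in inp.monoculture_means.items()}
    best_species = max(p_mono, key=p_mono.get)
    best = p_mono[best_species]
    if best == 0:
        raise ZeroDivisionError(
            "best monoculture performance is zero; D_max is undefined"
        )
    # dividing by |best| keeps the sign convention (better than the best
    # monoculture => D_max > 0) even if performances are negative
    d = (p_mix - best) / abs(best)
    n = d.size
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, n - 1))
    return DmaxResult(
        estimate=mean,
        ci_lo=mean - tcrit * se,
        ci_hi=mean + tcrit * se,
        per_replicate=d,
        best_monoculture=best_species,
        response_name=inp.response_name,
    )
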