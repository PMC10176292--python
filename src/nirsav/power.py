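"""Power for repeated-measures within-factor designs (noncentral F).

Follows the convention of the standard power software for "RM ANOVA, within
factors": with standardized effect size f, n participants, m repeated
measurements, mean inter-measure correlation rho and nonsphericity epsilon,

    lambda = f^2 * n * m * eps / (1 - rho)
    df1 = (m - 1) * eps,     df2 = (n - k) * (m - 1) * eps

and power is the upper tail of the noncentral F(df1, df2, lambda) beyond the
central-F critical value at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    f: float
    n: int
    m: int = 6
    rho: float = 0.5
    eps: float = 1.0
    alpha: float = 0.05
    groups: int = 1

    def validate(self) -> None:
        if self.f < 0:
            raise ValueError("f must be >= 0")
        if self.n < 2 or self.m < 2:
            raise ValueError("need n >= 2 and m >= 2")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 < self.eps <= 1:
            raise ValueError("eps must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def rm_within_power(spec: PowerSpec) -> float:
    """Power of the within-factor F test under ``spec``."""
    spec.validate()
    df1 = (spec.m - 1) * spec.eps
    df2 = (spec.n - spec.groups) * (spec.m - 1) * spec.eps
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    lam = spec.f**2 * spec.n * spec.m * spec.eps / (1.0 - spec.rho)
    crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(crit, df1, df2, lam))
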