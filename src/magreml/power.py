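"""GREML power calculation.

The power of the mediation LRT is bounded above by the power to detect a
non-zero SNP heritability of the mediator, which the standard GREML power
formula approximates as follows: the sampling variance of the heritability
estimate is

    var(h2_hat) ~= 2 / (n^2 * var_pi),

with ``var_pi`` the variance of the off-diagonal entries of the GRM
(~2e-5 for common-SNP GRMs in conventionally unrelated samples).  The test
of h2 = 0 then has noncentrality h2^2 / var(h2_hat) against a central
chi-square(1) critical value.
"""

from __future__ import annotations

import dataclasses

import scipy.stats


@dataclasses.dataclass
class PowerQuery:
    """Inputs of the GREML power formula (defaults: var_relatedness 2e-5,
    two-sided alpha 0.05)."""

    n: int
    h2: float
    var_relatedness: float = 2e-5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must lie in [0, 1)")
        if self.var_relatedness <= 0:
            raise ValueError("var_relatedness must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def greml_power(
    n: int,
    h2: float,
    var_relatedness: float = 2e-5,
    alpha: float = 0.05,
) -> float:
    """Power to detect h2 > 0 with GREML at sample size ``n``.

    Returns the upper tail of noncentral chi-square(1, ncp) beyond the
    central chi-square(1) critical value at ``alpha``, with
    ncp = h2^2 * n^2 * var_relatedness / 2.  At h2 = 0 this equals alpha.
    """
    q = PowerQuery(n=n, h2=h2, var_relatedness=var_relatedness, alpha=alpha)
    var_h2 = 2.0 / (q.n**2 * q.var_relatedness)
    ncp = q.h2**2 / var_h2
    crit = scipy.stats.chi2.isf(q.alpha, df=1)
    return float(scipy.stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else q.alpha
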