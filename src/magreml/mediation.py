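"""Mediation estimands from bivariate variance components.

Under the mediation structural model — where the mediator M transmits part
of the additive-genetic component of the outcome Y — the quantities of
interest are simple functions of the six variance components:

    b        = sigma_E_MY / sigma_E_MM                 (effect of M on Y)
    indirect = sigma_G_MM * b^2                        (genetic variance of Y
                                                        mediated by M)
    direct   = sigma_G_YY + sigma_G_MM * b^2
               - 2 * sigma_G_MY * b                    (genetic variance of Y
                                                        not mediated by M)

The remainder  cross = sigma_G_YY - direct - indirect  is the covariance
contribution that arises when the same genetic factor affects Y both
directly and through M; it belongs to neither effect and is reported
separately.  Identification of b from the environmental covariance requires
that all environmental confounders of the M-Y association are controlled
for and that M retains non-zero environmental variance.

Standard errors come from the delta method: analytic Jacobians of the
estimands with respect to the VC vector, applied to the VC sampling
covariance.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .vcmodel import VC_NAMES, VarCompEstimate


class AssumptionError(ValueError):
    """The mediator's environmental variance is (numerically) zero, so the
    effect of M on Y is not identified from the environmental covariance."""


@dataclasses.dataclass
class MediationResult:
    """Point estimates and delta-method SEs of the mediation estimands.

    ``prop_mediated`` is indirect / sigma_G_YY (share of the outcome's
    genetic variance running through the mediator); ``prop_mediated_strict``
    normalizes by indirect + direct instead, leaving the cross term out of
    the denominator as well.  Both are NaN when sigma_G_YY is zero (a
    non-heritable outcome makes the mediation question moot).
    """

    b: float
    indirect: float
    direct: float
    cross_term: float
    prop_mediated: float
    prop_mediated_strict: float
    se_b: float
    se_indirect: float
    se_direct: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("b", self.b, self.se_b),
            ("indirect", self.indirect, self.se_indirect),
            ("direct", self.direct, self.se_direct),
            ("cross_term", self.cross_term, np.nan),
            ("prop_mediated", self.prop_mediated, np.nan),
            ("prop_mediated_strict", self.prop_mediated_strict, np.nan),
        ]
        return pd.DataFrame(rows, columns=["estimand", "estimate", "se"])


def _vc_vector(vc: VarCompEstimate | np.ndarray) -> np.ndarray:
    if isinstance(vc, VarCompEstimate):
        return vc.vc
    v = np.asarray(vc, dtype=float)
    if v.shape != (6,):
        raise ValueError(f"expected 6 VCs in {VC_NAMES} order")
    return v


def estimand_jacobian(vc: VarCompEstimate | np.ndarray, which: str) -> np.ndarray:
    """Analytic gradient of an estimand w.r.t. the six VCs (VC_NAMES order)."""
    gmm, gmy, gyy, emm, emy, eyy = _vc_vector(vc)
    b = emy / emm
    db_demm = -emy / emm**2
    db_demy = 1.0 / emm
    if which == "b":
        return np.array([0.0, 0.0, 0.0, db_demm, db_demy, 0.0])
    if which == "indirect":
        return np.array([
            b * b, 0.0, 0.0,
            gmm * 2.0 * b * db_demm,
            gmm * 2.0 * b * db_demy,
            0.0,
        ])
    if which == "direct":
        dd_db = 2.0 * gmm * b - 2.0 * gmy
        return np.array([b * b, -2.0 * b, 1.0, dd_db * db_demm, dd_db * db_demy, 0.0])
    raise ValueError(f"unknown estimand {which!r}")


def delta_se(vc: VarCompEstimate, which: str) -> float:
    """Delta-method SE of an estimand: sqrt(J' vcov_vc J)."""
    if vc.vcov_vc is None:
        return float("nan")
    J = estimand_jacobian(vc, which)
    var = float(J @ vc.vcov_vc @ J)
    if var < 0:
        warnings.warn(
            f"negative delta-method variance for {which}; clipped to 0",
            RuntimeWarning,
        )
        var = 0.0
    return float(np.sqrt(var))


def mediation_effects(
    vc: VarCompEstimate,
    emm_floor_frac: float = 1e-6,
) -> MediationResult:
    """Map fitted VCs to (b, indirect, direct, cross term, proportions).

    Raises :class:`AssumptionError` when the mediator's environmental
    variance falls below ``emm_floor_frac`` times its total variance.
    """
    gmm, gmy, gyy, emm, emy, eyy = _vc_vector(vc)
    floor = emm_floor_frac * max(gmm + emm, 1e-300)
    if emm <= floor:
        raise AssumptionError(
            "mediator environmental variance is zero (or numerically so); "
            "the mediation model requires M to have non-zero environmental "
            "variance after covariate adjustment"
        )
    b = emy / emm
    indirect = gmm * b * b
    direct = gyy + gmm * b * b - 2.0 * gmy * b
    cross = gyy - direct - indirect
    if gyy > 0:
        prop = indirect / gyy
        tot = indirect + direct
        prop_strict = indirect / tot if tot > 0 else float("nan")
    else:
        prop = prop_strict = float("nan")
    return MediationResult(
        b=float(b),
        indirect=float(indirect),
        direct=float(direct),
        cross_term=float(cross),
        prop_mediated=float(prop),
        prop_mediated_strict=float(prop_strict),
        se_b=delta_se(vc, "b"),
        se_indirect=delta_se(vc, "indirect"),
        se_direct=delta_se(vc, "direct"),
    )
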