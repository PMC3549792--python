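"""Detection-difficulty metrics computed directly from a penetrance model.

Three candidate metrics quantify how hard a model's predictive loci are to
find in case-control data, without running any search algorithm:

* **EDM** (ease of detection measure): a squared-probability-weighted
  penetrance deviation score,

      EDM = (1 / (2 (K (1 - K))^2)) sum_G P(G)^2 (f_G - K)^2,

  algebraically equal to half the squared Euclidean distance between the
  case and control MLG distributions P(G|case) and P(G|control). Higher EDM
  means the predictive loci stand out more from noise.

* **COR** (customized odds ratio): MLGs are split into high and low risk by
  comparing the expected case proportion E_case(G) = P(G) f_G / K with the
  expected control proportion; the odds ratio a*d / (b*c) of the resulting
  expected 2x2 table measures model strength.

* **PTV** (penetrance table variance): the unweighted population variance of
  the 3^n penetrance values; it ignores genotype frequencies entirely.

Control-proportion convention: the default normalizes E_control by (1 - K),
so both class-conditional vectors are probability distributions and the
high-risk rule reduces to f_G >= K. ``literal_control=True`` instead divides
by K, reproducing a published variant in which the high-risk rule reduces to
f_G >= 0.5 and the control vector is not normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateModelError, UndefinedCORError
from .genetics import PenetranceModel, prevalence

__all__ = [
    "ClassConditionalDistribution",
    "RiskClassification",
    "class_conditionals",
    "edm",
    "edm_distance_form",
    "classify_risk",
    "cor",
    "ptv",
]

# Relative tolerance for calling E_case == E_control a tie. Exact-K flat
# models can land a hair on either side after rounding; ties go high risk.
_TIE_RTOL = 1e-12


@dataclass(frozen=True, eq=False)
class ClassConditionalDistribution:
    """MLG distributions among cases and among controls.

    ``p_case[G] = P(G) f_G / K`` and, by default,
    ``p_control[G] = P(G) (1 - f_G) / (1 - K)``; both sum to 1.
    """

    p_case: np.ndarray
    p_control: np.ndarray


@dataclass(frozen=True, eq=False)
class RiskClassification:
    """Per-MLG expected class proportions, risk flags, and the 2x2 table.

    ``a``/``b`` are the expected proportions of cases falling in high/low
    risk MLGs, ``c``/``d`` the same for controls; a + b = 1 and c + d = 1
    (under the normalized control convention).
    """

    e_case: np.ndarray
    e_control: np.ndarray
    high_risk: np.ndarray
    a: float
    b: float
    c: float
    d: float


def _checked_prevalence(model: PenetranceModel) -> float:
    k = prevalence(model)
    # margin absorbs floating rounding for all-0/all-1 penetrance tables
    if k <= 1e-12 or k >= 1.0 - 1e-12:
        raise DegenerateModelError(
            f"metric undefined for prevalence K = {k}: no case/control contrast"
        )
    return k


def class_conditionals(
    model: PenetranceModel, literal_control: bool = False
) -> ClassConditionalDistribution:
    """Probability of each MLG among cases and among controls."""
    k = _checked_prevalence(model)
    p = model.joint_probs
    f = model.penetrances
    p_case = p * f / k
    denom = k if literal_control else 1.0 - k
    p_control = p * (1.0 - f) / denom
    return ClassConditionalDistribution(p_case=p_case, p_control=p_control)


def edm(model: PenetranceModel) -> float:
    """Ease of detection measure from penetrances and genotype probabilities.

    EDM = (1 / (2 (K (1-K))^2)) sum_G P(G)^2 (f_G - K)^2. Because P(G) enters
    squared, rare MLGs contribute proportionally less than they do to
    heritability.
    """
    k = _checked_prevalence(model)
    p = model.joint_probs
    dev = model.penetrances - k
    return float((p * p) @ (dev * dev) / (2.0 * (k * (1.0 - k)) ** 2))


def edm_distance_form(model: PenetranceModel) -> float:
    """EDM as half the squared Euclidean distance between the case and
    control MLG distributions; algebraically equal to :func:`edm`."""
    cc = class_conditionals(model)
    delta = cc.p_case - cc.p_control
    return float(0.5 * delta @ delta)


def classify_risk(
    model: PenetranceModel, literal_control: bool = False
) -> RiskClassification:
    """Split MLGs into high/low risk and collapse to the expected 2x2 table.

    An MLG is high risk when its expected case proportion equals or exceeds
    its expected control proportion (ties count as high risk); a/b/c/d are
    the expected high/low-risk case and control proportions.
    """
    cc = class_conditionals(model, literal_control=literal_control)
    e_case, e_control = cc.p_case, cc.p_control
    scale = np.maximum(np.abs(e_case), np.abs(e_control))
    high = e_case >= e_control - _TIE_RTOL * scale
    a = float(e_case[high].sum())
    b = float(e_case[~high].sum())
    c = float(e_control[high].sum())
    d = float(e_control[~high].sum())
    return RiskClassification(
        e_case=e_case, e_control=e_control, high_risk=high, a=a, b=b, c=c, d=d
    )


def cor(model: PenetranceModel, literal_control: bool = False) -> float:
    """Customized odds ratio a*d / (b*c) of the expected 2x2 risk table.

    Raises :class:`UndefinedCORError` when every MLG falls into one risk
    class (b = 0 or c = 0), e.g. for a flat model; the error carries the
    degenerate table. Whenever defined, COR >= 1, because high-risk MLGs are
    exactly the case-enriched ones.
    """
    rc = classify_risk(model, literal_control=literal_control)
    if rc.b <= 0.0 or rc.c <= 0.0:
        raise UndefinedCORError(
            "odds ratio undefined: all MLGs fall in a single risk class "
            f"(a={rc.a:.6g}, b={rc.b:.6g}, c={rc.c:.6g}, d={rc.d:.6g})",
            table=(rc.a, rc.b, rc.c, rc.d),
        )
    return rc.a * rc.d / (rc.b * rc.c)


def ptv(model: PenetranceModel) -> float:
    """Penetrance table variance: the unweighted population variance of the
    3^n penetrance values (genotype frequencies play no role)."""
    return float(np.var(model.penetrances))
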