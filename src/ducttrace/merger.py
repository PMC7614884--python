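"""Closed-form model of labelling-induced clone merger and multicolor
co-labelling.

At induction, N endbuds experience a total of M independent labelling events
in one reporter color.  With p = M/N the mean labelling probability per
endbud:

* ``P_c = 1 - (1 - 1/N)**M``        probability an endbud is labelled in that
  color (exponential approximation ``1 - exp(-p)``),
* ``P_1 = (M/N) * (1 - 1/N)**(M-1)`` probability of exactly one event
  (approximation ``p * exp(-p)``),
* ``P_merger = 1 - P_1/P_c``        probability a labelled endbud carries two
  or more like-color events and so hosts a merged "clone" (approximation
  ``1 - p/(e**p - 1)``; small-p limit ``p/2``).

With ``k`` distinguishable colors at equal intensity,
``Q_1 = k * P_c * (1-P_c)**(k-1)`` is the probability of labelling in exactly
one color, ``Q_* = 1 - (1-P_c)**k`` of labelling in any color, and the
co-labelling fraction ``C = 1 - Q_1/Q_*`` satisfies ``C ~ 3p/2 = 3 * P_merger``
for 4 colors at small p — which is what lets an observed co-label fraction
estimate the unobservable same-color merger rate as ``P_merger ~ C/3``.

Exact discrete formulas are the default; the exponential approximations are
named variants so both are testable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "MergerParams",
    "MergerResult",
    "label_prob",
    "single_label_prob",
    "merger_prob",
    "colabel_fraction",
    "colabel_fraction_percolor",
    "infer_merger_from_colabel",
    "merger_report",
]

_METHODS = ("exact", "approx", "small_p")


@dataclass(frozen=True)
class MergerParams:
    """Labelling-event parameters: N endbuds at risk, M events in one color,
    and the number of distinguishable labels (4 for the confetti cassette)."""

    N: int
    M: int
    n_colors: int = 4

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.M < 0:
            raise ValueError("M must be >= 0")
        if self.n_colors < 2:
            raise ValueError("n_colors must be >= 2")

    @property
    def p(self) -> float:
        """Mean labelling probability per endbud, M/N."""
        return self.M / self.N


@dataclass(frozen=True)
class MergerResult:
    """All derived labelling/merger quantities for one parameter set."""

    P_c: float
    P_1: float
    P_merger: float
    Q_1: float
    Q_star: float
    C: float
    method: str


def _check_method(method: str) -> None:
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")


def label_prob(params: MergerParams, method: str = "exact") -> float:
    """Probability that an endbud is labelled in the color: exact
    ``1-(1-1/N)**M`` or the ``1-exp(-p)`` approximation."""
    _check_method(method)
    if method == "exact":
        return 1.0 - (1.0 - 1.0 / params.N) ** params.M
    return 1.0 - math.exp(-params.p)


def single_label_prob(params: MergerParams, method: str = "exact") -> float:
    """Probability that an endbud acquired precisely one event of the color:
    exact ``(M/N)(1-1/N)**(M-1)`` or ``p*exp(-p)``."""
    _check_method(method)
    if params.M == 0:
        return 0.0
    if method == "exact":
        return params.p * (1.0 - 1.0 / params.N) ** (params.M - 1)
    return params.p * math.exp(-params.p)


def merger_prob(params: MergerParams, method: str = "exact") -> float:
    """Probability that a labelled endbud is a merger (two or more like-color
    events in the same endbud).

    ``method``: "exact" = ``1 - P_1/P_c`` with the discrete forms;
    "approx" = ``1 - p/(e**p - 1)``; "small_p" = ``p/2``.  M = 1 gives 0
    (one event cannot merge); M = 0 is undefined.
    """
    _check_method(method)
    if params.M == 0:
        raise ValueError("merger probability undefined for M = 0 (no labelling)")
    if method == "small_p":
        return params.p / 2.0
    if method == "approx":
        p = params.p
        return 1.0 - p / math.expm1(p)
    # clamp: the exact ratio can land an ulp below 0 at M = 1
    return max(0.0, 1.0 - single_label_prob(params) / label_prob(params))


def colabel_fraction(params: MergerParams, method: str = "exact") -> float:
    """Probability that a labelled endbud is co-labelled by two or more
    colors, ``C = 1 - Q_1/Q_*`` (equal per-color intensity).

    "approx" evaluates the same forms with the exponential ``P_c``;
    "small_p" returns the 4-color limit ``3p/2`` (generally
    ``(k-1) p / 2`` for k colors).  M = 0 gives C = 0.
    """
    _check_method(method)
    if params.M == 0:
        return 0.0
    if method == "small_p":
        return (params.n_colors - 1) * params.p / 2.0
    pc = label_prob(params, method="exact" if method == "exact" else "approx")
    k = params.n_colors
    q1 = k * pc * (1.0 - pc) ** (k - 1)
    qstar = 1.0 - (1.0 - pc) ** k
    if qstar == 0.0:
        return 0.0
    return 1.0 - q1 / qstar


def colabel_fraction_percolor(Ms: Sequence[int], N: int) -> float:
    """Generalized co-labelling fraction for unequal per-color event counts
    (e.g. the observed 10:11:3:13 clone proportions for CFP:YFP:GFP:RFP).

    ``Q_1 = sum_c P_c * prod_{c'!=c}(1-P_c')``, ``Q_* = 1 - prod_c (1-P_c)``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if any(m < 0 for m in Ms):
        raise ValueError("per-color event counts must be >= 0")
    pcs = [1.0 - (1.0 - 1.0 / N) ** m for m in Ms]
    prod_none = math.prod(1.0 - pc for pc in pcs)
    qstar = 1.0 - prod_none
    if qstar == 0.0:
        return 0.0
    q1 = 0.0
    for i, pc in enumerate(pcs):
        q1 += pc * math.prod(1.0 - pcs[j] for j in range(len(pcs)) if j != i)
    return 1.0 - q1 / qstar


def infer_merger_from_colabel(
    n_colabelled: int, n_total: int
) -> tuple[float, float]:
    """Infer the same-color merger rate from observed co-labelled CAs.

    Returns ``(C_hat, P_merger_hat)`` with ``C_hat = n_colabelled/n_total``
    and ``P_merger_hat = C_hat/3`` — valid in the small-p regime only; a
    warning is raised when ``C_hat > 0.2``.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_colabelled <= n_total:
        raise ValueError("need 0 <= n_colabelled <= n_total")
    c_hat = n_colabelled / n_total
    if c_hat > 0.2:
        warnings.warn(
            f"co-label fraction {c_hat:.2f} > 0.2: the C/3 inference assumes "
            "the small-p regime and may be biased",
            RuntimeWarning,
        )
    return c_hat, c_hat / 3.0


def merger_report(params: MergerParams, method: str = "exact") -> MergerResult:
    """All six labelling/merger quantities for one parameter set."""
    return MergerResult(
        P_c=label_prob(params, method="exact" if method == "exact" else "approx"),
        P_1=single_label_prob(params, method="exact" if method == "exact" else "approx"),
        P_merger=merger_prob(params, method=method) if params.M >= 1 else 0.0,
        Q_1=(
            params.n_colors
            * label_prob(params, "exact" if method == "exact" else "approx")
            * (1 - label_prob(params, "exact" if method == "exact" else "approx"))
            ** (params.n_colors - 1)
        ),
        Q_star=1
        - (1 - label_prob(params, "exact" if method == "exact" else "approx"))
        ** params.n_colors,
        C=colabel_fraction(params, method=method),
        method=method,
    )
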