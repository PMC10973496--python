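"""Posterior summaries: HPDIs, evidence ratios, and contrasts.

Inferences are reported as posterior means with 90% highest posterior
density intervals (the narrowest interval holding the stated mass) and
evidence ratios (ERs): the posterior odds of a directed effect versus
its reverse, equivalent to a one-sided Bayes factor under a symmetric
prior.  Following common reporting practice, ERs are capped in display
as "> 100" once fewer than 1 in 101 draws oppose the direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ER_CAP = 100.0


def hpdi(draws, prob: float = 0.9) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the draws.

    Computed by sliding a window of ceil(prob * n) order statistics and
    taking the shortest; exact for unimodal samples.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("hpdi needs at least two draws")
    if not (0.0 < prob < 1.0):
        raise ValueError("prob must be in (0, 1)")
    m = int(np.ceil(prob * n))
    m = min(max(m, 1), n - 1)
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


@dataclass(frozen=True)
class EvidenceRatio:
    """Posterior odds for a directed effect, with the display convention."""

    value: float  # for/against ratio; inf when no draw opposes
    n_for: int
    n_against: int

    @property
    def capped(self) -> bool:
        n = self.n_for + self.n_against
        return self.n_against < n / 101.0

    def __str__(self) -> str:
        if self.n_against == 0:
            # never report infinity: bounded by the draw count
            return f"> {self.n_for + self.n_against}"
        if self.capped:
            return f"> {ER_CAP:.0f}"
        return f"{self.value:.1f}"


def evidence_ratio(draws, direction: str = ">", null: float = 0.0) -> EvidenceRatio:
    """Evidence ratio for draws lying on the stated side of ``null``."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("evidence_ratio needs at least two draws")
    if direction == ">":
        n_for = int(np.sum(x > null))
    elif direction == "<":
        n_for = int(np.sum(x < null))
    else:
        raise ValueError("direction must be '>' or '<'")
    n_against = x.size - n_for
    value = np.inf if n_against == 0 else n_for / n_against
    return EvidenceRatio(value=value, n_for=n_for, n_against=n_against)


@dataclass(frozen=True)
class ContrastResult:
    """Posterior mean, 90% HPDI and evidence ratio of a derived quantity."""

    mean: float
    hpdi_low: float
    hpdi_high: float
    er: EvidenceRatio
    prob: float = 0.9

    def __str__(self) -> str:
        return (
            f"{self.mean:.3g} [{self.hpdi_low:.3g}, {self.hpdi_high:.3g}], ER = {self.er}"
        )


def contrast(draws, direction: str = ">", null: float = 0.0, prob: float = 0.9) -> ContrastResult:
    """Summarize a draw vector (e.g. a between-condition difference).

    ``draws`` may be the elementwise difference of two posterior draw
    arrays or any per-draw functional.  At least 100 draws required.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("contrast needs at least 100 draws")
    lo, hi = hpdi(x, prob)
    return ContrastResult(
        mean=float(x.mean()),
        hpdi_low=lo,
        hpdi_high=hi,
        er=evidence_ratio(x, direction, null),
        prob=prob,
    )
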