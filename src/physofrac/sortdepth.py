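"""Binomial capture model for choosing the number of events to sort.

When N events are sorted from a community in which a taxon has prevalence p,
the number of captured cells of that taxon is X ~ Binomial(N, p). The design
question is how large N must be so that at least k cells of a taxon as rare
as p are captured with high probability. The tail convention used throughout
is P(X >= k), "capture at least k".
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .exceptions import InvalidArgument


@dataclass(frozen=True)
class CaptureModel:
    """Sorting design: N events, taxon prevalence p, required capture k."""

    N: int
    p: float
    k: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise InvalidArgument(f"prevalence p={self.p} outside [0, 1]")
        if self.N < 0 or self.k < 0:
            raise InvalidArgument("N and k must be non-negative")

    @property
    def capture_probability(self) -> float:
        return capture_probability(self.N, self.p, self.k)

    @property
    def expected_capture(self) -> float:
        return expected_capture(self.N, self.p)


def capture_probability(N: int, p: float, k: int, gate_error: float = 0.0) -> float:
    """P(X >= k) for X ~ Binomial(N, p'), computed via the regularized
    incomplete beta (scipy survival function), stable for large N.

    gate_error optionally discounts prevalence to p' = p * (1 - gate_error)
    so that only truly in-gate cells count as captured.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidArgument(f"prevalence p={p} outside [0, 1]")
    if not 0.0 <= gate_error < 1.0:
        raise InvalidArgument("gate_error must be in [0, 1)")
    if k <= 0:
        return 1.0
    if k > N:
        return 0.0
    p_eff = p * (1.0 - gate_error)
    return float(stats.binom.sf(k - 1, N, p_eff))


def expected_capture(N: int, p: float) -> float:
    """Expected number of captured cells, N * p."""
    if not 0.0 <= p <= 1.0:
        raise InvalidArgument(f"prevalence p={p} outside [0, 1]")
    return float(N) * p


def min_events(p: float, k: int, confidence: float, gate_error: float = 0.0) -> int:
    """Smallest N with P(X >= k) >= confidence.

    capture_probability is nondecreasing in N, so doubling followed by
    bisection finds the exact threshold.
    """
    if not 0.0 < p <= 1.0:
        raise InvalidArgument("p must be in (0, 1] for a solution to exist")
    if not 0.0 < confidence < 1.0:
        raise InvalidArgument("confidence must be in (0, 1)")
    if k <= 0:
        return 0
    hi = max(k, 1)
    while capture_probability(hi, p, k, gate_error) < confidence:
        hi *= 2
        if hi > 10**12:  # pragma: no cover - unreachable for valid inputs
            raise InvalidArgument("no feasible N below 1e12")
    lo = k - 1  # P at lo is < confidence (k-1 events can never yield k)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if capture_probability(mid, p, k, gate_error) >= confidence:
            hi = mid
        else:
            lo = mid
    return hi


def design_table(p: float, k: int, confidences=(0.5, 0.8, 0.9, 0.95, 0.99)):
    """Minimal-N table across confidence levels (used by the CLI)."""
    import pandas as pd

    rows = [{"confidence": c, "min_events": min_events(p, k, c)} for c in confidences]
    return pd.DataFrame(rows)
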