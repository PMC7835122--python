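"""Signal-detection sensitivity (d') from binary confusion counts.

d' = Phi^{-1}(hit rate) - Phi^{-1}(false-alarm rate), where Phi^{-1} is the
standard-normal quantile. A d' of 0 is chance; positive values mean the
classifier separates positives from negatives. Perfect or empty rates give
infinite quantiles, so a correction for extreme rates is applied before the
quantile transform.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["ConfusionCounts", "dprime", "CORRECTIONS"]

CORRECTIONS = ("clamp", "loglinear", "none")


@dataclass(frozen=True)
class ConfusionCounts:
    """Outcome tallies of a binary decision rule against ground truth.

    ``hits + misses`` is the number of true positives scored and
    ``false_alarms + correct_rejections`` the number of true negatives;
    both totals must be at least 1.
    """

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.hits + self.misses < 1:
            raise ValueError("need at least one scored positive (hits + misses >= 1)")
        if self.false_alarms + self.correct_rejections < 1:
            raise ValueError(
                "need at least one scored negative (false_alarms + correct_rejections >= 1)"
            )

    @property
    def n_pos(self) -> int:
        return self.hits + self.misses

    @property
    def n_neg(self) -> int:
        return self.false_alarms + self.correct_rejections


def _corrected_rate(count: int, total: int, correction: str) -> float:
    if correction == "clamp":
        rate = count / total
        lo = 1.0 / (2 * total)
        return min(max(rate, lo), 1.0 - lo)
    if correction == "loglinear":
        return (count + 0.5) / (total + 1.0)
    if correction == "none":
        rate = count / total
        if rate in (0.0, 1.0):
            raise ValueError(
                f"rate {count}/{total} is extreme; an infinite quantile would result — "
                "use correction='clamp' or 'loglinear'"
            )
        return rate
    raise ValueError(f"unknown correction {correction!r}; expected one of {CORRECTIONS}")


def dprime(counts: ConfusionCounts, correction: str = "clamp") -> float:
    """Sensitivity index from confusion counts.

    Parameters
    ----------
    counts
        Hit/miss/false-alarm/correct-rejection tallies.
    correction
        How extreme (0 or 1) rates are handled before the quantile transform:
        ``clamp`` confines each rate to ``[1/(2N), 1 - 1/(2N)]`` for its own
        trial count N; ``loglinear`` uses ``(count + 0.5) / (N + 1)`` for every
        rate; ``none`` raises on an extreme rate.
    """
    hr = _corrected_rate(counts.hits, counts.n_pos, correction)
    far = _corrected_rate(counts.false_alarms, counts.n_neg, correction)
    return float(norm.ppf(hr) - norm.ppf(far))
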