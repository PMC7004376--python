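"""Control-allele selection from case/control/healthy frequency tables.

The screening and selection rules operationalise the study design used in
HLA adverse-drug-reaction association work: an allele is a usable control
only if it is reasonably common in the study control group (frequency over
3%) and shows no enrichment in cases relative to either the study controls
or healthy-population reference frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyRecord",
    "ContingencyTable2x2",
    "screen_candidates",
    "select_controls",
    "odds_ratio",
]


@dataclass
class FrequencyRecord:
    """Per-allele frequencies: cases, study controls, and zero or more
    healthy reference populations (name, proportion)."""

    allele: str
    case_freq: float
    study_control_freq: float
    healthy_freqs: list[tuple[str, float]] = field(default_factory=list)
    case_n: int = 0
    control_n: int = 0

    def __post_init__(self) -> None:
        for label, value in [
            ("case_freq", self.case_freq),
            ("study_control_freq", self.study_control_freq),
        ] + [(f"healthy[{p}]", f) for p, f in self.healthy_freqs]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{self.allele}: {label}={value} outside [0, 1]")
        if self.case_n < 0 or self.control_n < 0:
            raise ValueError(f"{self.allele}: negative cohort size")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier counts: a = carrier cases, b = carrier controls,
    c = non-carrier cases, d = non-carrier controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def screen_candidates(
    table: list[FrequencyRecord], min_control_freq: float = 0.03
) -> list[str]:
    """Alleles with study-control frequency strictly over the threshold
    (default 3%), in input order. Rare alleles are uninformative controls."""
    if not 0.0 <= min_control_freq <= 1.0:
        raise ValueError(f"min_control_freq={min_control_freq} outside [0, 1]")
    return [r.allele for r in table if r.study_control_freq > min_control_freq]


def select_controls(
    table: list[FrequencyRecord],
    tolerance: float = 0.1,
    min_control_freq: float = 0.03,
) -> list[str]:
    """Select non-associated control alleles.

    An allele passes if (i) it survives the frequency screen and (ii) its
    study-control frequency, or any healthy-population frequency, is
    similar to or greater than its case frequency. "Similar to" is a
    relative margin: selected iff
    ``max(study_control_freq, healthy...) >= case_freq * (1 - tolerance)``.
    A record with no healthy frequencies is judged on its study-control
    frequency alone. The result is always a subset of
    :func:`screen_candidates` output.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    screened = set(screen_candidates(table, min_control_freq))
    selected = []
    for rec in table:
        if rec.allele not in screened:
            continue
        best = max(
            [rec.study_control_freq] + [f for _, f in rec.healthy_freqs]
        )
        if best >= rec.case_freq * (1.0 - tolerance):
            selected.append(rec.allele)
    return selected


def odds_ratio(t: ContingencyTable2x2) -> tuple[float, tuple[float, float]]:
    """Odds ratio (a*d)/(b*c) with a Woolf-type 95% CI.

    Any zero cell triggers the Haldane-Anscombe correction (add 0.5 to
    every cell). Two zero cells in the same row or column leave the odds
    ratio undefined and raise.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    zero_pairs = [(a, b), (c, d), (a, c), (b, d)]
    if any(x == 0 and y == 0 for x, y in zero_pairs):
        raise ValueError("odds ratio undefined: two zero cells share a row or column")
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    ci = (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se)))
    return float(or_), ci
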