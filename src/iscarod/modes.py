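"""Binding-mode classification from interaction-energy distributions.

Each docked partner's per-frame interaction energy with the polymer is
Gaussian-like; its mean E classifies the partner into one of three binding
modes with inclusive boundaries toward the extremes:

    strong        E <= -700 kcal/mol
    intermediate  -700 < E < -200 kcal/mol
    weak          E >= -200 kcal/mol

The +-100 kcal/mol tolerance quoted alongside the thresholds is reported
(and can flag borderline means) but plays no part in the hard assignment,
so that every partner receives a unique mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .energetics import InteractionEnergySeries
from .errors import InputError

__all__ = [
    "BindingModeThresholds",
    "BindingModeReport",
    "fit_gaussian",
    "classify",
    "classify_all",
]


@dataclass(frozen=True)
class BindingModeThresholds:
    """Mode boundaries in kcal/mol, with the reported +- tolerance."""

    strong_max: float = -700.0
    weak_min: float = -200.0
    tolerance: float = 100.0

    def __post_init__(self) -> None:
        if not self.strong_max < self.weak_min:
            raise InputError(
                f"strong_max ({self.strong_max}) must be below weak_min ({self.weak_min})"
            )
        if self.tolerance < 0:
            raise InputError("tolerance must be nonnegative")


@dataclass
class BindingModeReport:
    """Per-partner summary: mean/std energy, Gaussian fit and mode label."""

    partner_id: str
    mean_E: float
    std_E: float
    mode: str
    gaussian_fit: tuple[float, float]
    borderline: bool = False


def fit_gaussian(samples: Sequence[float]) -> tuple[float, float]:
    """Gaussian (mu, sigma) of energy samples: sample mean and n-1 std."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise InputError("Gaussian fit requires at least 2 samples")
    return float(np.mean(samples)), float(np.std(samples, ddof=1))


def classify(mean_E: float, thresholds: BindingModeThresholds | None = None) -> str:
    """Binding mode of a mean interaction energy: weak/intermediate/strong.

    Boundaries are inclusive toward the extremes: E <= strong_max is
    strong, E >= weak_min is weak, anything between is intermediate.
    """
    if thresholds is None:
        thresholds = BindingModeThresholds()
    if not math.isfinite(mean_E):
        raise InputError(f"mean energy {mean_E} is not finite")
    if mean_E <= thresholds.strong_max:
        return "strong"
    if mean_E >= thresholds.weak_min:
        return "weak"
    return "intermediate"


def classify_all(
    series: Sequence[InteractionEnergySeries],
    thresholds: BindingModeThresholds | None = None,
) -> list[BindingModeReport]:
    """Classify every partner's energy series; ordered by partner id.

    Each report carries the recomputed mean/std, the Gaussian fit and a
    ``borderline`` flag marking means within the quoted tolerance of a
    mode boundary.
    """
    if not series:
        raise InputError("no interaction-energy series given")
    if thresholds is None:
        thresholds = BindingModeThresholds()
    reports = []
    for s in sorted(series, key=lambda s: s.partner_id):
        mu, sigma = fit_gaussian(s.per_frame_energy)
        mode = classify(mu, thresholds)
        borderline = (
            abs(mu - thresholds.strong_max) <= thresholds.tolerance
            or abs(mu - thresholds.weak_min) <= thresholds.tolerance
        )
        reports.append(
            BindingModeReport(
                partner_id=s.partner_id, mean_E=mu, std_E=sigma, mode=mode,
                gaussian_fit=(mu, sigma), borderline=borderline,
            )
        )
    return reports


def mode_counts(reports: Sequence[BindingModeReport]) -> dict[str, int]:
    """Number of partners per binding mode."""
    counts = {"strong": 0, "intermediate": 0, "weak": 0}
    for report in reports:
        counts[report.mode] += 1
    return counts
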