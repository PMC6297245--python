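"""Test-retest feature reproducibility via Lin's concordance correlation.

A feature measured on repeat scans of the same subjects is considered
reproducible when its concordance correlation coefficient (CCC) across
subjects strictly exceeds a threshold (default 0.9); only reproducible
features enter the downstream selection and modeling stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import AlignmentError, FeatureTable

__all__ = ["CCCReport", "ccc", "filter_reproducible"]


@dataclass
class CCCReport:
    """Per-feature CCC values and the retained (reproducible) feature names."""

    values: dict[str, float]
    retained: list[str]
    threshold: float
    degenerate: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.values),
                "ccc": [self.values[f] for f in self.values],
                "retained": [f in set(self.retained) for f in self.values],
            }
        )


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2) with
    population (1/n) moments, as in Lin's original estimator. Conventions
    for degenerate input: both samples constant and equal -> 1; one sample
    constant (or both constant but unequal) -> 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("samples must be 1D and of equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    vx = x.var()
    vy = y.var()
    if vx == 0 and vy == 0:
        return 1.0 if np.allclose(x.mean(), y.mean()) else 0.0
    if vx == 0 or vy == 0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    value = 2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2)
    return float(np.clip(value, -1.0, 1.0))


def filter_reproducible(
    test_table: FeatureTable,
    retest_table: FeatureTable,
    threshold: float = 0.9,
) -> CCCReport:
    """Per-feature CCC between test and retest scans; retain CCC > threshold.

    The inequality is strict: a feature with CCC exactly at the threshold is
    excluded. Features degenerate in either table (constant across subjects)
    are flagged and given the degenerate-case CCC convention.
    """
    if test_table.patient_ids != retest_table.patient_ids:
        raise AlignmentError("test and retest tables must cover the same patients in order")
    if test_table.feature_names != retest_table.feature_names:
        raise AlignmentError("test and retest tables must share feature names in order")
    values: dict[str, float] = {}
    degenerate: list[str] = []
    for j, name in enumerate(test_table.feature_names):
        x = test_table.values[:, j]
        y = retest_table.values[:, j]
        if x.var() == 0 or y.var() == 0:
            degenerate.append(name)
        values[name] = ccc(x, y)
    retained = [f for f, v in values.items() if v > threshold]
    return CCCReport(values=values, retained=retained, threshold=threshold, degenerate=degenerate)
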