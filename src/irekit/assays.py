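"""Reporter-assay and qPCR arithmetic for in-vitro IRE validation.

Dual-luciferase activation: each well's firefly reading is normalized by its
renilla reading (cancelling transfection efficiency); the activation fold
change of a construct is

    FC = (s_i(H) / s_i(N)) / (s_c(H) / s_c(N))

where s are per-condition means of the relative activities for the test
construct (i) and the empty-vector control (c) under hypoxia (H) and normal
culture (N). qPCR uses the delta-delta-CT method against a reference gene
(Gapdh), reporting 2^(-ddCT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import ttest_ind

__all__ = [
    "LuciferaseMeasurement",
    "QpcrMeasurement",
    "LuciferaseResult",
    "DdctResult",
    "luciferase_activation_fc",
    "ddct_relative_expression",
    "unpaired_ttest",
]

NORMAL = "N"
HYPOXIA = "H"


@dataclass(frozen=True)
class LuciferaseMeasurement:
    construct: str
    condition: str  # "N" or "H"
    firefly: float
    renilla: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.condition not in (NORMAL, HYPOXIA):
            raise ValueError("condition must be 'N' or 'H'")
        if self.renilla <= 0:
            raise ValueError("renilla reading must be positive")

    @property
    def relative_activity(self) -> float:
        return self.firefly / self.renilla


@dataclass(frozen=True)
class QpcrMeasurement:
    gene: str
    condition: str
    ct_target: float
    ct_reference: float
    replicate: int = 0

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_reference):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError("CT values must be finite and positive")


@dataclass
class LuciferaseResult:
    fold_change: float
    sem: float
    replicate_fold_changes: list[float]


def _condition_values(ms: Sequence[LuciferaseMeasurement], cond: str) -> list[float]:
    vals = [m.relative_activity for m in ms if m.condition == cond]
    if not vals:
        raise ValueError(f"missing condition {cond!r}")
    return vals


def luciferase_activation_fc(
    test: Sequence[LuciferaseMeasurement],
    control: Sequence[LuciferaseMeasurement],
) -> LuciferaseResult:
    """Hypoxia activation fold change of a construct over the empty vector.

    The headline FC is computed from per-condition means; per-replicate FCs
    (hypoxia/normal replicates paired by index, normalized by the control
    ratio) feed the SEM and any downstream unpaired t-test.
    """
    ti_h = _condition_values(test, HYPOXIA)
    ti_n = _condition_values(test, NORMAL)
    tc_h = _condition_values(control, HYPOXIA)
    tc_n = _condition_values(control, NORMAL)
    control_ratio = np.mean(tc_h) / np.mean(tc_n)
    fc = (np.mean(ti_h) / np.mean(ti_n)) / control_ratio
    per_rep = [
        (h / n) / control_ratio for h, n in zip(ti_h, ti_n)
    ]
    sem = (
        float(np.std(per_rep, ddof=1) / np.sqrt(len(per_rep)))
        if len(per_rep) > 1
        else 0.0
    )
    return LuciferaseResult(float(fc), sem, per_rep)


@dataclass
class DdctResult:
    condition: str
    relative_expression: float  # mean of per-replicate 2^(-ddCT)
    sem: float
    replicate_values: list[float]


def ddct_relative_expression(
    measurements: Sequence[QpcrMeasurement],
    baseline_condition: str,
) -> dict[str, DdctResult]:
    """Relative expression 2^(-ddCT) per condition against a baseline.

    dCT = CT_target - CT_reference per measurement; ddCT subtracts the mean
    baseline dCT, so the baseline condition averages a relative expression
    of about 1. Adding a constant to both CTs of a replicate cancels.
    """
    if not measurements:
        raise ValueError("no measurements")
    dcts: dict[str, list[float]] = {}
    for m in measurements:
        dcts.setdefault(m.condition, []).append(m.ct_target - m.ct_reference)
    if baseline_condition not in dcts:
        raise ValueError(f"baseline condition {baseline_condition!r} absent")
    base = float(np.mean(dcts[baseline_condition]))
    out = {}
    for cond, vals in dcts.items():
        rel = [2.0 ** (-(v - base)) for v in vals]
        sem = (
            float(np.std(rel, ddof=1) / np.sqrt(len(rel))) if len(rel) > 1 else 0.0
        )
        out[cond] = DdctResult(cond, float(np.mean(rel)), sem, rel)
    return out


def unpaired_ttest(a: Sequence[float], b: Sequence[float], welch: bool = True) -> float:
    """Two-sided unpaired t-test p-value (Welch by default; set welch=False
    for the equal-variance Student form)."""
    return float(ttest_ind(list(a), list(b), equal_var=not welch).pvalue)
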