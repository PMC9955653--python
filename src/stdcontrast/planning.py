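"""Minimal sample sizes for precise standardized-contrast estimation.

Two accuracy-in-parameter-estimation criteria are supported: the expected
width of the two-sided exact interval must not exceed ``omega``
(``Omega <= omega``), or the width must stay within ``omega`` with
assurance probability at least ``1 - gamma`` (``Gamma >= 1 - gamma``).
Search walks the group-size-ratio lattice ``N_i = r_i * n`` for
``n = 1, 2, ...`` by linear ascent — monotonicity of the assurance
criterion in ``N`` is empirical rather than proven, so every returned plan
carries a minimality certificate: the criterion holds at the returned size
and fails at the preceding lattice size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .precision import (
    DesignSpec,
    assurance_approx,
    assurance_exact,
    expected_width_approx,
    expected_width_exact,
)

__all__ = ["PrecisionSpec", "SampleSizePlan", "min_NT_expected_width", "min_NT_assurance"]

N_TOTAL_CAP = 20_000


@dataclass(frozen=True)
class PrecisionSpec:
    """Precision criterion for planning."""

    omega: float  # width bound, standardized units
    assurance: float | None = None  # 1 - gamma, required for the assurance criterion
    method: str = "exact"  # exact | approximate

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.assurance is not None and not 0.0 < self.assurance < 1.0:
            raise ValueError("assurance level must lie in (0, 1)")
        if self.method not in ("exact", "approximate"):
            raise ValueError("method must be 'exact' or 'approximate'")


@dataclass(frozen=True)
class SampleSizePlan:
    """A minimal sample size with its certificate."""

    n_total: int
    group_sizes: np.ndarray
    achieved: float  # Omega or Gamma at n_total
    previous: float | None  # value at the preceding (infeasible) lattice size
    criterion: str  # expected_width | assurance
    method: str
    omega: float
    assurance: float | None = None
    trace: list = field(default_factory=list)  # [(n_total, value), ...]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = [int(v) for v in self.group_sizes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SampleSizePlan":
        d = dict(d)
        d["group_sizes"] = np.asarray(d["group_sizes"], dtype=int)
        d["trace"] = [tuple(t) for t in d["trace"]]
        return cls(**d)


def _lattice_start(design: DesignSpec) -> int:
    """Smallest lattice multiplier giving every N_i >= 2 and nu >= 2."""
    n = 1
    while True:
        sizes = design.ratios * n
        n_total = int(sizes.sum())
        if sizes.min() >= 2 and design.nu(n_total) >= 2:
            return n
        n += 1


def _scan(design: DesignSpec, evaluate, meets, criterion: str, spec: PrecisionSpec) -> SampleSizePlan:
    unit = int(design.ratios.sum())
    n = _lattice_start(design)
    previous = None
    trace = []
    d0 = 2.0 * stats.norm.isf(design.alpha / 2.0)
    while True:
        n_total = unit * n
        if n_total > N_TOTAL_CAP:
            raise RuntimeError(
                f"criterion unattainable within bound: N_T exceeded {N_TOTAL_CAP}"
            )
        # W = V^{1/2} d(T) >= a^{1/2} d(0) pointwise, so sizes whose width
        # floor already exceeds omega are infeasible without quadrature
        floor = math.sqrt(design.a_factor(n_total)) * d0
        if floor >= spec.omega:
            value = floor if criterion == "expected_width" else 0.0
        else:
            value = evaluate(n_total)
        trace.append((n_total, value))
        if meets(value):
            return SampleSizePlan(
                n_total=n_total,
                group_sizes=design.ratios * n,
                achieved=value,
                previous=previous,
                criterion=criterion,
                method=spec.method,
                omega=spec.omega,
                assurance=spec.assurance,
                trace=trace,
            )
        previous = value
        n += 1


def min_NT_expected_width(design: DesignSpec, spec: PrecisionSpec) -> SampleSizePlan:
    """Smallest lattice ``N_T`` with expected width ``Omega <= omega``."""
    fn = expected_width_exact if spec.method == "exact" else expected_width_approx
    return _scan(
        design,
        evaluate=lambda nt: fn(design, nt).value,
        meets=lambda v: v <= spec.omega,  # ties count as feasible
        criterion="expected_width",
        spec=spec,
    )


def min_NT_assurance(design: DesignSpec, spec: PrecisionSpec) -> SampleSizePlan:
    """Smallest lattice ``N_T`` with assurance ``Gamma >= 1 - gamma``."""
    if spec.assurance is None:
        raise ValueError("assurance criterion requires an assurance level")
    fn = assurance_exact if spec.method == "exact" else assurance_approx
    return _scan(
        design,
        evaluate=lambda nt: fn(design, nt, spec.omega).value,
        meets=lambda v: v >= spec.assurance,
        criterion="assurance",
        spec=spec,
    )
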