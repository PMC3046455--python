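"""Risk-factor specifications: continuous codings, category systems, subsets.

The six factors scanned against each SNP are age at menarche, ever having
had a live birth, number of live births (parous women only), age at first
birth (parous women only), and BMI in two age strata (<55 and >=55 years,
a surrogate for menopausal status).  Each factor carries

* a continuous coding (affine transform applied before model entry) —
  interaction and trend models always use the continuous coding;
* an ordered category system used for stratified per-allele OR reports;
* an applicability rule (parous-only, age stratum) that defines the
  analysis subset.

Continuous codings default to the natural unit (years, births, kg/m^2);
``report_per`` records the conventional reporting increment (5 years for
age at first birth, 5 kg/m^2 for BMI) so reports can rescale a fitted
per-unit OR as ``or_per_unit ** report_per`` without refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RiskFactorSpec:
    """Coding, categories and subset rule for one risk factor."""

    name: str
    column: str
    category_edges: tuple[float, ...]
    category_labels: tuple[str, ...]
    offset: float = 0.0
    scale: float = 1.0
    report_per: float = 1.0
    parous_only: bool = False
    age_min: float | None = None   # inclusive lower age bound
    age_max: float | None = None   # exclusive upper age bound

    def __post_init__(self) -> None:
        if len(self.category_labels) != len(self.category_edges) + 1:
            raise ValueError(
                f"{self.name}: need len(edges)+1 labels, got "
                f"{len(self.category_edges)} edges / {len(self.category_labels)} labels"
            )
        if list(self.category_edges) != sorted(self.category_edges):
            raise ValueError(f"{self.name}: category edges must be increasing")

    def coded(self, values):
        """Apply the continuous coding ``(value - offset) * scale``."""
        return (np.asarray(values, dtype=float) - self.offset) * self.scale

    @property
    def n_categories(self) -> int:
        return len(self.category_labels)


def categorize(value: float | None, spec: RiskFactorSpec) -> int | None:
    """Index of the unique category bin containing ``value``.

    Bins are left-closed at their lower edge: a value equal to an edge falls
    in the bin above it (so BMI 25.0 is "25.00-29.99" and 30.0 is ">=30.00").
    Missing values (``None``/NaN) map to ``None``, never an exception.
    """
    if value is None:
        return None
    value = float(value)
    if math.isnan(value):
        return None
    return int(np.digitize(value, spec.category_edges, right=False))


def categorize_array(values, spec: RiskFactorSpec) -> np.ndarray:
    """Vectorised :func:`categorize`; missing values map to -1."""
    values = np.asarray(values, dtype=float)
    idx = np.digitize(values, spec.category_edges, right=False)
    return np.where(np.isnan(values), -1, idx)


MENARCHE = RiskFactorSpec(
    name="menarche",
    column="menarche_age",
    category_edges=(12.0, 13.0, 14.0, 15.0),
    category_labels=("<=11", "12", "13", "14", ">=15"),
)

EVER_BIRTH = RiskFactorSpec(
    name="ever_birth",
    column="parous",
    category_edges=(0.5,),
    category_labels=("nulliparous", "parous"),
)

N_BIRTHS = RiskFactorSpec(
    name="n_births",
    column="n_live_births",
    category_edges=(2.0, 3.0, 4.0),
    category_labels=("1", "2", "3", ">=4"),
    parous_only=True,
)

AGE_FIRST_BIRTH = RiskFactorSpec(
    name="age_first_birth",
    column="age_first_birth",
    category_edges=(20.0, 25.0, 30.0),
    category_labels=("<=19", "20-24", "25-29", ">=30"),
    report_per=5.0,
    parous_only=True,
)

BMI_LT55 = RiskFactorSpec(
    name="bmi_lt55",
    column="bmi",
    category_edges=(25.0, 30.0),
    category_labels=("<=24.99", "25.00-29.99", ">=30.00"),
    report_per=5.0,
    age_max=55.0,
)

BMI_GE55 = RiskFactorSpec(
    name="bmi_ge55",
    column="bmi",
    category_edges=(25.0, 30.0),
    category_labels=("<=24.99", "25.00-29.99", ">=30.00"),
    report_per=5.0,
    age_min=55.0,
)

#: the scan's factor family, in reporting order
DEFAULT_FACTORS: dict[str, RiskFactorSpec] = {
    spec.name: spec
    for spec in (MENARCHE, EVER_BIRTH, N_BIRTHS, AGE_FIRST_BIRTH, BMI_LT55, BMI_GE55)
}


def get_factor(name: str) -> RiskFactorSpec:
    try:
        return DEFAULT_FACTORS[name]
    except KeyError:
        raise KeyError(
            f"unknown risk factor {name!r}; known: {sorted(DEFAULT_FACTORS)}"
        ) from None
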