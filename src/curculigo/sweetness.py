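"""Sucrose-equivalence arithmetic and 2^-ddCt relative quantification.

Neoculin is several hundred times sweeter than sucrose on the percentage
sucrose-equivalent scale, so fruit sweetness can be estimated from the
protein content per gram of fresh pulp. For a relative species whose
neoculin transcripts are expressed at a fraction of the reference species'
level, the content and sucrose equivalent are scaled down by that
expression ratio. qPCR fold changes use the standard 2^-ddCt method against
a reference gene and calibrator sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, log10
from typing import Sequence

#: Fold sweetness of neoculin relative to sucrose (percentage sucrose
#: equivalent scale).
DEFAULT_SWEETNESS_FACTOR = 550.0

#: Reported neoculin content of fresh fruit pulp, mg per g.
DEFAULT_CONTENT_MG_PER_G = 1.3


@dataclass(frozen=True)
class SweetnessEstimate:
    """Neoculin content and its sucrose equivalent, both mg per g fresh pulp."""

    content_mg_per_g: float
    factor: float

    def __post_init__(self) -> None:
        if self.content_mg_per_g < 0 or self.factor < 0:
            raise ValueError("content and sweetness factor must be non-negative")

    @property
    def sucrose_equivalent_mg_per_g(self) -> float:
        return self.content_mg_per_g * self.factor


def sucrose_equivalent(
    content_mg_per_g: float, factor: float = DEFAULT_SWEETNESS_FACTOR
) -> float:
    """mg sucrose per g pulp equivalent in sweetness to the given content.

    Full precision; display rounding belongs to the report layer.
    """
    if content_mg_per_g < 0:
        raise ValueError("neoculin content cannot be negative")
    return content_mg_per_g * factor


def scale_by_expression_ratio(
    content_mg_per_g: float,
    tpm_ratio: float,
    factor: float = DEFAULT_SWEETNESS_FACTOR,
) -> SweetnessEstimate:
    """Estimate for a species expressing neoculin at 1/``tpm_ratio`` the level.

    E.g. content 1.3 mg/g scaled by ratio 60 gives about 0.022 mg/g
    (22 ug/g) and a sucrose equivalent of about 12 mg/g.
    """
    if tpm_ratio <= 0:
        raise ValueError("expression ratio must be positive")
    return SweetnessEstimate(content_mg_per_g / tpm_ratio, factor)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report-layer display rounding)."""
    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


@dataclass(frozen=True)
class QpcrSample:
    """Ct measurements of the target and reference gene for one condition."""

    ct_target: float
    ct_reference: float
    condition: str = ""

    def __post_init__(self) -> None:
        for value in (self.ct_target, self.ct_reference):
            if not (value > 0 and value == value and value != float("inf")):
                raise ValueError("Ct values must be finite and positive")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def delta_delta_ct(sample: QpcrSample, calibrator: QpcrSample) -> float:
    """Relative expression 2^-[(dCt sample) - (dCt calibrator)]."""
    return 2.0 ** -(sample.delta_ct - calibrator.delta_ct)


def mean_sample(replicates: Sequence[QpcrSample], condition: str = "") -> QpcrSample:
    """Average replicate Ct values into a single sample before ddCt."""
    if not replicates:
        raise ValueError("need at least one replicate")
    return QpcrSample(
        ct_target=sum(r.ct_target for r in replicates) / len(replicates),
        ct_reference=sum(r.ct_reference for r in replicates) / len(replicates),
        condition=condition or replicates[0].condition,
    )


def fold_change_range(
    replicates: Sequence[QpcrSample], calibrator: QpcrSample
) -> tuple[float, float, float]:
    """(mean fold, min fold, max fold) across replicates vs a calibrator.

    The spread is the replicate min/max fold change, not a formal confidence
    interval.
    """
    folds = [delta_delta_ct(rep, calibrator) for rep in replicates]
    mean_fold = delta_delta_ct(mean_sample(list(replicates)), calibrator)
    return mean_fold, min(folds), max(folds)
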