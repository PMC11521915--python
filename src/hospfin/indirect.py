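"""Per-bed global budget for indirect services.

Indirect services — administration, patient registration, governance,
biomedical waste management, laundry and dietetics — scale with hospital
size, so their budget is a flat annual rate per bed. The secondary-care
rate is estimated by pooling observed indirect costs over observed beds
(Σ cost / Σ beds); tertiary facilities carry a higher rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .types import HospitalRecord

__all__ = ["IndirectRateConfig", "estimate_per_bed_rate", "indirect_budget"]

#: Estimated annual indirect cost per bed at a secondary district hospital.
SECONDARY_RATE_INR_PER_BED = 163_969.0
#: The same rate for facilities upgraded to medical colleges (tertiary care).
TERTIARY_RATE_INR_PER_BED = 294_441.0


@dataclass(frozen=True)
class IndirectRateConfig:
    """Per-bed annual indirect-service rates (INR/bed/year)."""

    rate_base: float = SECONDARY_RATE_INR_PER_BED
    rate_medical_college: float = TERTIARY_RATE_INR_PER_BED

    def __post_init__(self) -> None:
        if self.rate_base <= 0 or self.rate_medical_college <= 0:
            raise ValueError("indirect rates must be > 0")


def estimate_per_bed_rate(records: Sequence[HospitalRecord]) -> float:
    """Pooled per-bed indirect rate: Σ indirect_cost / Σ beds.

    Pooling weights each hospital by its bed count, matching an average
    annual cost per bed across the sample (rather than a mean of
    per-hospital ratios).
    """
    total_beds = sum(r.beds for r in records)
    if total_beds <= 0:
        raise ValueError("total beds must be > 0 to estimate a per-bed rate")
    return sum(r.indirect_cost for r in records) / total_beds


def indirect_budget(beds: int, rate: float) -> float:
    """Annual indirect-services budget: beds × rate (exactly linear)."""
    if beds < 0:
        raise ValueError(f"beds must be >= 0, got {beds}")
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    return beds * rate
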