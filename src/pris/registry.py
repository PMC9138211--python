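"""Registry of clinical thresholds used throughout the pipeline.

Every cutoff that enters screening, dominance identification or scoring is
collected here so that a run can audit (and, where clinically defensible,
override) the constants instead of chasing literals through the code.  The
defaults are the values used in routine allergy practice:

======================  =======  =====================================
threshold               default  meaning
======================  =======  =====================================
spt_positive_mm         3.0      SPT wheal diameter (mm) counted positive
ige_positive_kua_l      0.35     specific / component IgE (kUA/L) positive
crd_high_kua_l          3.50     component IgE high-positive cutoff
ratio_high              0.2      s/t ratio for the top scoring band
ratio_mid               0.05     s/t ratio lower edge of the middle band
dominance_wheal_mm      5.0      wheal margin separating dominant allergens
dominance_log10_ige     0.5      log10 sIgE margin ("half a logarithm")
act_controlled          20       ACT score at/above which asthma is controlled
ige_floor_kua_l         0.01     floor applied before taking log10 of sIgE
======================  =======  =====================================
"""

from __future__ import annotations

import dataclasses
import logging

logger = logging.getLogger("pris")


@dataclasses.dataclass(frozen=True)
class Thresholds:
    spt_positive_mm: float = 3.0
    ige_positive_kua_l: float = 0.35
    crd_high_kua_l: float = 3.50
    ratio_high: float = 0.2
    ratio_mid: float = 0.05
    dominance_wheal_mm: float = 5.0
    dominance_log10_ige: float = 0.5
    act_controlled: int = 20
    ige_floor_kua_l: float = 0.01

    def __post_init__(self) -> None:
        from .errors import ValidationError

        if self.dominance_wheal_mm <= 0 or self.dominance_log10_ige <= 0:
            raise ValidationError("dominance margins must be positive")
        if not 5 <= self.act_controlled <= 25:
            raise ValidationError("act_controlled must lie in the ACT range 5-25")
        if not 0 < self.ratio_mid < self.ratio_high:
            raise ValidationError("ratio bands must satisfy 0 < ratio_mid < ratio_high")
        if self.ige_floor_kua_l <= 0:
            raise ValidationError("ige_floor_kua_l must be positive")

    def log(self) -> None:
        """Emit every threshold at INFO level for run auditability."""
        for field in dataclasses.fields(self):
            logger.info("threshold %s = %s", field.name, getattr(self, field.name))


DEFAULT_THRESHOLDS = Thresholds()
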