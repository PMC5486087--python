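"""Panel configuration: marker vocabulary, reference gene and calling rule.

The default panel is a seven-gene circulating-tumor-cell (CTC) signature
(GAPDH, VIL1, CLU, TIMP1, TLN1, LOXL3, ZEB2) measured by RT-qPCR in
EpCAM-immunoisolated blood fractions, normalized to the leukocyte marker
PTPRC (CD45) to control for unspecific cell capture.  A patient sample is
called "high-CTC" when at least ``call_threshold`` markers exceed their
per-marker percentile cutoffs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Timepoint(str, enum.Enum):
    """Blood-draw schedule: before treatment, after cycle 1, before cycle 5."""

    BASELINE = "baseline"
    WEEK4 = "week4"
    WEEK16 = "week16"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


TIMEPOINTS: tuple[str, ...] = tuple(t.value for t in Timepoint)

DEFAULT_MARKERS: tuple[str, ...] = (
    "GAPDH",
    "VIL1",
    "CLU",
    "TIMP1",
    "TLN1",
    "LOXL3",
    "ZEB2",
)

DEFAULT_REFERENCE_GENE = "PTPRC"


@dataclass(frozen=True)
class MarkerPanel:
    """Gene panel plus the constants of the high/low calling rule.

    Parameters
    ----------
    markers
        Ordered marker gene symbols scored against percentile cutoffs.
    reference_gene
        Reference gene used for delta-Cq normalization; must amplify for a
        sample to be usable and must not be a member of ``markers``.
    max_cycles
        Maximum number of PCR cycles; undetermined target Cq values are
        imputed at this floor.
    call_threshold
        Minimum number of concordant marker calls required for a panel-level
        high-CTC (or low-CTC) group assignment.
    cutoff_percentile
        Percentile of the cohort delta-Cq distribution defining each
        marker's high/low cutoff.
    """

    markers: tuple[str, ...] = DEFAULT_MARKERS
    reference_gene: str = DEFAULT_REFERENCE_GENE
    max_cycles: int = 40
    call_threshold: int = 4
    cutoff_percentile: float = 75.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker symbols in panel")
        if self.reference_gene in self.markers:
            raise ValueError(
                f"reference gene {self.reference_gene!r} must not be a panel marker"
            )
        if not 1 <= self.call_threshold <= len(self.markers):
            raise ValueError(
                f"call_threshold must be in [1, {len(self.markers)}], "
                f"got {self.call_threshold}"
            )
        if not 0.0 < self.cutoff_percentile < 100.0:
            raise ValueError("cutoff_percentile must lie strictly between 0 and 100")
        if self.max_cycles <= 0:
            raise ValueError("max_cycles must be positive")

    @property
    def genes(self) -> tuple[str, ...]:
        """All measured genes: markers plus the reference."""
        return self.markers + (self.reference_gene,)

    @property
    def n_markers(self) -> int:
        return len(self.markers)
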