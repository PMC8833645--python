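"""Run-time configuration shared by the detection pipeline and the CLI."""

from __future__ import annotations

import dataclasses
import logging

logger = logging.getLogger("tdscan")


@dataclasses.dataclass
class RunConfig:
    """Tunable constants of the TD detection method.

    Attributes
    ----------
    unique_mapq:
        MAPQ value that marks a uniquely mapped read. STAR writes 255 for
        unique alignments; BWA/HISAT2 users should lower this (e.g. 60).
    min_clip:
        Minimum number of soft-clipped bases a junction read must carry;
        shorter clips can match the virtual junction by chance.
    read_cap:
        Maximum number of reads examined per candidate region. When more
        qualify, the positional first and last ``read_cap / 2`` are kept.
    min_support:
        Minimum number of distinct TD read-pairs required to call a region.
    threshold:
        TD-score cut-off that classifies a sample as BRCA1-type.
    adjust:
        Multiple-testing adjustment for the recurrence table
        (``hochberg`` or ``bh``).
    seed:
        Seed for every stochastic step (simulation, bootstrap).
    """

    unique_mapq: int = 255
    min_clip: int = 10
    read_cap: int = 4000
    min_support: int = 1
    threshold: int = 2
    adjust: str = "hochberg"
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("unique_mapq", "min_clip", "read_cap", "min_support", "threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.read_cap % 2 != 0:
            raise ValueError(f"read_cap must be even, got {self.read_cap}")
        if self.adjust not in ("hochberg", "bh"):
            raise ValueError(f"adjust must be 'hochberg' or 'bh', got {self.adjust!r}")
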