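"""Small shared helpers: genomic region parsing and seeding."""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @classmethod
    def parse(cls, text: str) -> "Region":
        m = re.fullmatch(r"([\w.]+):([\d,]+)-([\d,]+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
        return cls(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))

    def contains(self, chrom: str, pos) -> np.ndarray | bool:
        """Vectorised membership test for 1-based positions."""
        return (np.asarray(chrom) == self.chrom) & (np.asarray(pos) >= self.start) & (
            np.asarray(pos) <= self.end
        )

    def __str__(self) -> str:  # round-trips through parse()
        return f"{self.chrom}:{self.start}-{self.end}"


# Default coordinates of the FADS haplogroup LD block (hg19, 1-based inclusive).
HIGH_COVERAGE_REGION = Region("chr11", 61_543_499, 61_591_907)
LOW_COVERAGE_REGION = Region("chr11", 61_543_499, 61_591_636)
PBS_SCAN_REGION = Region("chr11", 61_540_615, 61_664_170)


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """n independent child seed sequences derived from one master seed."""
    return np.random.SeedSequence(seed).spawn(n)
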