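"""Binned genome coordinate frame shared by every analysis stage.

All coordinates are 0-based half-open (cooler/BED convention). Bins tile each
chromosome without gaps or overlaps; the last bin of a chromosome may be
shorter than ``bin_size``. Global bin ids are consecutive in chromosome order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BinnedGenome:
    """Chromosome sizes plus a fixed bin size, with a global bin index.

    Parameters
    ----------
    chromsizes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Bin width in bp.
    """

    chromsizes: tuple[tuple[str, int], ...]
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if len(self.chromsizes) == 0:
            raise ValueError("at least one chromosome required")
        names = [c for c, _ in self.chromsizes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromsizes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @classmethod
    def from_dict(cls, chromsizes: dict[str, int], bin_size: int) -> "BinnedGenome":
        return cls(tuple(chromsizes.items()), bin_size)

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromsizes]

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromsizes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def chrom_nbins(self, chrom: str) -> int:
        length = self.chrom_length(chrom)
        return -(-length // self.bin_size)  # ceil division

    @property
    def n_bins(self) -> int:
        return sum(self.chrom_nbins(c) for c in self.names)

    def chrom_offset(self, chrom: str) -> int:
        off = 0
        for name, _ in self.chromsizes:
            if name == chrom:
                return off
            off += self.chrom_nbins(name)
        raise KeyError(f"unknown chromosome {chrom!r}")

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the global bin index covering ``chrom``."""
        off = self.chrom_offset(chrom)
        return slice(off, off + self.chrom_nbins(chrom))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin id containing position ``pos`` (0-based)."""
        length = self.chrom_length(chrom)
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom!r} [0, {length})")
        return self.chrom_offset(chrom) + pos // self.bin_size

    @property
    def bins(self) -> pd.DataFrame:
        """Bin table (chrom, start, end) indexed by global bin id."""
        rows = []
        for chrom, length in self.chromsizes:
            starts = np.arange(0, length, self.bin_size)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        table = pd.concat(rows, ignore_index=True)
        table.index.name = "bin_id"
        return table
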