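"""Per-bin signal tracks (ChIP-seq-like marks, DNA-methylation contexts)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import BinnedGenome


@dataclass
class SignalTrack:
    """A named non-negative per-bin signal on a :class:`BinnedGenome`.

    ``normalization`` is ``"raw"`` for as-simulated/as-loaded values and
    ``"scaled"`` once the genome-wide mean has been fixed to 1 so that samples
    are comparable (the pipeline's stand-in for depth normalization).
    """

    name: str
    genome: BinnedGenome
    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.n_bins,):
            raise ValueError(
                f"track {self.name!r}: {self.values.size} values for "
                f"{self.genome.n_bins} bins"
            )
        if np.any(self.values < 0):
            raise ValueError(f"track {self.name!r} has negative values")

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.genome.chrom_slice(chrom)]

    def scaled(self) -> "SignalTrack":
        """Copy rescaled to genome-wide mean 1."""
        mean = float(self.values.mean())
        if mean == 0:
            raise ValueError(f"track {self.name!r} has zero mean; cannot scale")
        return replace(self, values=self.values / mean, normalization="scaled")
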