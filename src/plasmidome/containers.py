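"""Shared in-memory containers for abundance/presence data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AbundanceMatrix:
    """Samples x entities relative abundances with sequencing metadata.

    abundance : DataFrame (samples x entities), per-sample relative abundance
        (mapped reads / sample read depth); nonnegative.
    coverage : DataFrame, same shape, fraction of each entity's length covered
        by at least one read in that sample, in [0, 1].
    read_depth : Series indexed by sample, total reads per sample.
    """

    abundance: pd.DataFrame
    coverage: pd.DataFrame
    read_depth: pd.Series

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.coverage.index) or \
           not self.abundance.columns.equals(self.coverage.columns):
            raise ValueError("abundance and coverage must share index and columns")
        if not self.abundance.index.equals(self.read_depth.index):
            raise ValueError("read_depth index must match samples")
        cov = self.coverage.to_numpy()
        if np.any((cov < 0) | (cov > 1)):
            raise ValueError("coverage fractions must lie in [0, 1]")
        if np.any(self.read_depth.to_numpy() <= 0):
            raise ValueError("read depths must be positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def entity_ids(self) -> pd.Index:
        return self.abundance.columns
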