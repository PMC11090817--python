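"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ENVIRONMENTS = ("animal", "aquatic", "plant", "soil")


@dataclass
class AbundanceMatrix:
    """OTU x sample relative abundances with per-sample environment labels.

    ``matrix``: DataFrame, OTUs as rows, samples as columns, values in
    [0, 1]; every column sums to at most 1.  ``sample_env``: Series mapping
    sample id to one of animal/aquatic/plant/soil (or ``none``).
    """

    matrix: pd.DataFrame
    sample_env: pd.Series

    def __post_init__(self):
        vals = self.matrix.to_numpy()
        if np.any(vals < 0):
            raise ValueError("negative abundance values")
        if np.any(vals.sum(axis=0) > 1.0 + 1e-9):
            raise ValueError("a sample column sums above 1")
        unknown = set(self.sample_env.unique()) - set(ENVIRONMENTS) - {"none"}
        if unknown:
            raise ValueError(f"unknown environment labels: {sorted(unknown)}")
        if list(self.sample_env.index) != list(self.matrix.columns):
            self.sample_env = self.sample_env.reindex(self.matrix.columns)
            if self.sample_env.isna().any():
                raise ValueError("sample_env does not cover all samples")

    @property
    def otus(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)
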