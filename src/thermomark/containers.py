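"""Omics data containers and tab-separated plumbing.

A single container, :class:`OmicsMatrix`, carries both roles used throughout
the pipeline: a metabolome (continuous log-normal abundances) and a
transcriptome (negative-binomial counts).  Features are rows, samples are
columns, and every sample carries (genotype, temperature_C, replicate)
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TEMPERATURES = (25, 30, 35)
GENOTYPES = ("tolerant", "sensitive")

REQUIRED_METADATA = ("genotype", "temperature_C", "replicate")


@dataclass
class OmicsMatrix:
    """Features x samples abundance matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative reals, index = feature ids,
        columns = sample ids.
    metadata
        DataFrame indexed by sample id with columns
        ``genotype``, ``temperature_C``, ``replicate``.
    role
        ``"metabolome"`` (continuous abundances) or
        ``"transcriptome"`` (integral counts).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    role: str = "metabolome"

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite abundance values")
        if (arr < 0).any():
            raise ValueError("negative abundance values")
        if self.role == "transcriptome" and not np.allclose(arr, np.round(arr)):
            raise ValueError("transcriptome counts must be integral")
        # keep metadata aligned to the value columns
        self.metadata = self.metadata.loc[self.values.columns]

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching all metadata conditions.

        A condition value may be a scalar or a collection of admissible values,
        e.g. ``samples_where(genotype="tolerant", temperature_C=(30, 35))``.
        """
        mask = pd.Series(True, index=self.metadata.index)
        for key, val in conditions.items():
            col = self.metadata[key]
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= col.isin(list(val))
            else:
                mask &= col == val
        return list(self.metadata.index[mask])

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        sample_ids = list(sample_ids)
        return OmicsMatrix(
            values=self.values[sample_ids].copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
            role=self.role,
        )

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(
            values=self.values.loc[list(feature_ids)].copy(),
            metadata=self.metadata.copy(),
            role=self.role,
        )


def write_matrix_tsv(matrix: OmicsMatrix, values_path, metadata_path) -> None:
    """Write the abundance table and the sample metadata table as TSV."""
    matrix.values.to_csv(values_path, sep="\t", index_label="feature_id")
    matrix.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_matrix_tsv(values_path, metadata_path, role: str = "metabolome") -> OmicsMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="feature_id")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    return OmicsMatrix(values=values, metadata=metadata, role=role)
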