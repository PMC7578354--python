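"""Expression-matrix container shared by the query and atlas roles.

The matrix stores genes in rows and samples in columns. Expression units
are arbitrary: every downstream comparison ranks each profile first, so
only the within-profile ordering of values matters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

#: Column names expected in atlas sample metadata.
META_COLUMNS = ("region", "stage")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with optional sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
        Values must be non-negative reals (NaN allowed only where a
        measurement is genuinely absent; fully missing rows are rejected).
    sample_meta
        Optional per-sample annotation (index = sample id) with at least a
        ``region`` column and, for stage-resolved atlases, a ``stage``
        column. Required for the atlas role, absent for plain queries.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise InputError("values must be a pandas DataFrame")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample ids: {dups[:5]}")
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise InputError("expression matrix must be non-empty")
        all_missing = v.isna().all(axis=1)
        if all_missing.any():
            bad = v.index[all_missing].tolist()
            raise InputError(f"rows entirely missing: {bad[:5]}")
        with np.errstate(invalid="ignore"):
            if (v.to_numpy(dtype=float) < 0).any():
                raise InputError("expression values must be non-negative")
        if self.sample_meta is not None:
            m = self.sample_meta
            missing = set(v.columns) - set(m.index)
            if missing:
                raise InputError(
                    f"samples without metadata: {sorted(missing)[:5]}")
            if "region" not in m.columns:
                raise InputError("sample_meta must carry a 'region' column")

    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_meta)
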