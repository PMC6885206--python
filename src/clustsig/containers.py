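"""In-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "SurvivalTable", "align_samples"]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    ``values`` has gene identifiers as the index and sample identifiers as
    columns.  ``batch`` optionally labels each sample with its cohort or
    platform.  ``metadata`` carries free-form provenance (platform, log
    base, survival clock definition) that travels with the matrix.
    """

    values: pd.DataFrame
    batch: pd.Series | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        idx = self.values.index
        cols = self.values.columns
        dup_g = idx[idx.duplicated()].unique().tolist()
        if dup_g:
            raise ValueError(f"duplicate gene ids: {dup_g}")
        dup_s = cols[cols.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression matrix contains non-finite values")
        if self.batch is not None:
            self.batch = pd.Series(self.batch)
            missing = [s for s in cols if s not in self.batch.index]
            if missing:
                raise ValueError(f"samples without batch label: {missing[:5]}")
            self.batch = self.batch.loc[cols]

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(
            self.values.loc[list(genes)], batch=self.batch, metadata=dict(self.metadata)
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        sub = self.values[list(samples)]
        batch = self.batch.loc[list(samples)] if self.batch is not None else None
        return ExpressionMatrix(sub, batch=batch, metadata=dict(self.metadata))


@dataclass
class SurvivalTable:
    """Right-censored follow-up per sample.

    ``data`` is indexed by sample id with columns ``time`` (non-negative
    follow-up in the unit declared in metadata), ``event`` (1 = death from
    any cause, 0 = censored) and any number of named covariate columns.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"survival table lacks required column {col!r}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if (df["time"] < 0).any():
            raise ValueError("negative follow-up times")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def covariate_names(self) -> list:
        return [c for c in self.data.columns if c not in ("time", "event")]

    def covariates(self, names=None) -> pd.DataFrame:
        return self.data[list(names) if names is not None else self.covariate_names]

    def subset(self, samples) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)], metadata=dict(self.metadata))


def align_samples(expr: ExpressionMatrix, surv: SurvivalTable, logger=None):
    """Inner-join expression and survival on sample id, preserving the
    expression column order.  Dropped samples are reported, never silent."""
    shared = [s for s in expr.sample_ids if s in set(surv.sample_ids)]
    if not shared:
        raise ValueError("expression and survival tables share no sample ids")
    dropped_expr = sorted(set(expr.sample_ids) - set(shared))
    dropped_surv = sorted(set(surv.sample_ids) - set(shared))
    if (dropped_expr or dropped_surv) and logger is not None:
        logger.warning(
            "sample alignment dropped %d expression / %d survival samples: %s",
            len(dropped_expr),
            len(dropped_surv),
            (dropped_expr + dropped_surv)[:10],
        )
    return expr.subset_samples(shared), surv.subset(shared)
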