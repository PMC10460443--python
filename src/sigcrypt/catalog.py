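"""In-memory containers: mutation catalogs, signature sets, exposure matrices.

All three wrap a pandas DataFrame and are written/read in the COSMIC matrix
dialect: tab-separated, first column channel labels, header row of sample or
signature IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schemas import ChannelSchema, SchemaError, get_schema

__all__ = ["MutationCatalog", "SignatureSet", "ExposureMatrix"]


def _infer_schema(labels) -> ChannelSchema:
    for name in ("SBS96", "SBS7", "ID83", "ID16"):
        schema = get_schema(name)
        if set(labels) == set(schema.labels):
            return schema
    raise SchemaError(
        f"channel labels do not match any known schema (n={len(labels)})"
    )


@dataclass
class MutationCatalog:
    """A channels x samples matrix of non-negative mutation counts.

    Parameters
    ----------
    df
        DataFrame indexed by channel label with one column per sample.
    schema
        The channel schema; rows are reindexed to the schema order.
    group_of
        Optional mapping ``sample_id -> group label`` (e.g. HFD / SD).
    """

    df: pd.DataFrame
    schema: ChannelSchema
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.schema.labels) - set(self.df.index)
        if missing or len(self.df.index) != len(self.schema):
            extra = set(self.df.index) - set(self.schema.labels)
            raise SchemaError(
                f"catalog rows do not match schema {self.schema.name}: "
                f"{len(missing)} missing, {len(extra)} extraneous"
            )
        self.df = self.df.reindex(list(self.schema.labels))
        values = self.df.to_numpy()
        if (values < 0).any():
            raise ValueError("mutation counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("mutation counts must be integers")
        self.df = self.df.astype(np.int64)

    # -- basic views ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def totals(self) -> pd.Series:
        """Mutations per sample (column sums)."""
        return self.df.sum(axis=0)

    def samples_in_group(self, group: str) -> list[str]:
        ids = [s for s in self.sample_ids if self.group_of.get(s) == group]
        if not ids:
            raise KeyError(f"no samples in group {group!r}")
        return ids

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            g = self.group_of.get(s)
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)

    def subset(self, sample_ids: list[str]) -> "MutationCatalog":
        return MutationCatalog(
            self.df[sample_ids].copy(),
            self.schema,
            {s: g for s, g in self.group_of.items() if s in sample_ids},
        )

    def pooled(self, by_group: bool = True) -> "MutationCatalog":
        """Sum counts per group into one column per group."""
        if not by_group or not self.group_of:
            pooled = self.df.sum(axis=1).to_frame("pooled")
            return MutationCatalog(pooled, self.schema)
        cols = {
            g: self.df[self.samples_in_group(g)].sum(axis=1)
            for g in self.groups
        }
        return MutationCatalog(
            pd.DataFrame(cols), self.schema, {g: g for g in cols}
        )

    # -- IO -------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "MutationType"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        schema: ChannelSchema | str | None = None,
        group_of: dict[str, str] | None = None,
    ) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if schema is None:
            schema = _infer_schema(df.index)
        elif isinstance(schema, str):
            schema = get_schema(schema)
        return cls(df, schema, group_of or {})


@dataclass
class SignatureSet:
    """A channels x signatures column-stochastic matrix.

    Each column is one mutational signature: a probability distribution over
    the schema's channels. Columns are renormalized to sum to one on
    construction; an all-zero column is an error.
    """

    df: pd.DataFrame
    schema: ChannelSchema

    def __post_init__(self) -> None:
        if set(self.df.index) != set(self.schema.labels):
            raise SchemaError(
                f"signature rows do not match schema {self.schema.name}"
            )
        self.df = self.df.reindex(list(self.schema.labels)).astype(float)
        values = self.df.to_numpy()
        if (values < 0).any():
            raise ValueError("signature entries must be non-negative")
        sums = values.sum(axis=0)
        if (sums <= 0).any():
            bad = [c for c, s in zip(self.df.columns, sums) if s <= 0]
            raise ValueError(f"all-zero signature column(s): {bad}")
        self.df = self.df / sums

    @property
    def signature_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.df.to_numpy()

    def __len__(self) -> int:
        return self.df.shape[1]

    def subset(self, signature_ids: list[str]) -> "SignatureSet":
        return SignatureSet(self.df[list(signature_ids)].copy(), self.schema)

    def drop(self, signature_id: str) -> "SignatureSet":
        return SignatureSet(self.df.drop(columns=[signature_id]), self.schema)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "MutationType"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, schema: ChannelSchema | str | None = None
    ) -> "SignatureSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if schema is None:
            schema = _infer_schema(df.index)
        elif isinstance(schema, str):
            schema = get_schema(schema)
        return cls(df, schema)


@dataclass
class ExposureMatrix:
    """A signatures x samples matrix of attributed mutation counts."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.df.to_numpy() < -1e-9).any():
            raise ValueError("exposures must be non-negative")
        self.df = self.df.clip(lower=0.0).astype(float)

    @property
    def signature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.df.to_numpy()

    def relative(self) -> pd.DataFrame:
        """Per-sample relative exposures (columns sum to one)."""
        totals = self.df.sum(axis=0)
        return self.df / totals.replace(0, np.nan)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "Signature"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExposureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))
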