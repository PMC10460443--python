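"""Mutation channel schemas.

Four channel systems are supported:

* ``SBS96`` — single-base substitutions in pyrimidine-centered trinucleotide
  context, ``X[R>A]Y`` with R in {C, T} and X, Y in {A, C, G, T}.  Labels are
  ordered by substitution type (C>A, C>G, C>T, T>A, T>C, T>G), then 5' base,
  then 3' base.
* ``SBS7`` — the six substitution types with C>T split into CpG and non-CpG.
* ``ID83`` — the curated insertion/deletion classification in the
  SigProfiler/COSMIC string dialect (``"1:Del:C:0"`` ... ``"5:Del:M:5"``).
  For deletions the trailing index is the total number of repeat units
  including the deleted copy minus one (0 means the deleted copy stands
  alone, 5 means 6+ units); for insertions it is the number of pre-existing
  copies (0..5+); for microhomology deletions it is the microhomology length
  (1..5+, capped at deletion size - 1).
* ``ID16`` — the main-context collapse of ID83 (size class x Del/Ins x
  C/T/repeat/microhomology), obtained by dropping the trailing index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "ChannelSchema",
    "SchemaError",
    "SUBSTITUTION_TYPES",
    "get_schema",
    "sbs96_labels",
    "sbs7_labels",
    "id83_labels",
    "id16_labels",
    "id83_to_id16",
    "reverse_complement",
]

BASES = "ACGT"
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class SchemaError(ValueError):
    """Raised when a catalog/operation is given the wrong channel schema."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sbs96_labels() -> tuple[str, ...]:
    return tuple(
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTION_TYPES
        for five in BASES
        for three in BASES
    )


def sbs7_labels() -> tuple[str, ...]:
    return ("C>A", "C>G", "C>T other", "C>T at CpG", "T>A", "T>C", "T>G")


def id83_labels() -> tuple[str, ...]:
    labels: list[str] = []
    # 1-bp deletions / insertions at homopolymers, base collapsed to C/T.
    for op in ("Del", "Ins"):
        for base in ("C", "T"):
            labels += [f"1:{op}:{base}:{i}" for i in range(6)]
    # >=2-bp deletions then insertions at repeats, size classes 2,3,4,5+.
    for op in ("Del", "Ins"):
        for size in range(2, 6):
            labels += [f"{size}:{op}:R:{i}" for i in range(6)]
    # Deletions at microhomologies; MH <= deletion length - 1, so sizes
    # 2..4 allow 1..size-1 while the 5+ class allows up to 5.
    for size in range(2, 6):
        top = 5 if size == 5 else size - 1
        labels += [f"{size}:Del:M:{m}" for m in range(1, top + 1)]
    return tuple(labels)


def id16_labels() -> tuple[str, ...]:
    return (
        "1:Del:C", "1:Del:T", "1:Ins:C", "1:Ins:T",
        "2:Del:R", "3:Del:R", "4:Del:R", "5:Del:R",
        "2:Ins:R", "3:Ins:R", "4:Ins:R", "5:Ins:R",
        "2:Del:M", "3:Del:M", "4:Del:M", "5:Del:M",
    )


def id83_to_id16(label: str) -> str:
    """Collapse an ID83 label to its ID16 main-context category."""
    size, op, subtype, _ = label.split(":")
    return f"{size}:{op}:{subtype}"


@dataclass(frozen=True)
class ChannelSchema:
    """An ordered, named set of mutation channels."""

    name: str
    labels: tuple[str, ...] = field(repr=False)

    _EXPECTED = {"SBS96": 96, "SBS7": 7, "ID83": 83, "ID16": 16}

    def __post_init__(self) -> None:
        if self.name not in self._EXPECTED:
            raise SchemaError(f"unknown schema name {self.name!r}")
        n = self._EXPECTED[self.name]
        if len(self.labels) != n or len(set(self.labels)) != n:
            raise SchemaError(
                f"schema {self.name} requires {n} unique labels, "
                f"got {len(self.labels)}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@lru_cache(maxsize=None)
def get_schema(name: str) -> ChannelSchema:
    """Return the canonical schema for ``name`` (SBS96, SBS7, ID83, ID16)."""
    builders = {
        "SBS96": sbs96_labels,
        "SBS7": sbs7_labels,
        "ID83": id83_labels,
        "ID16": id16_labels,
    }
    if name not in builders:
        raise SchemaError(f"unknown schema name {name!r}")
    return ChannelSchema(name=name, labels=builders[name]())
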