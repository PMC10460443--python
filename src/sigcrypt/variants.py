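"""Somatic variant handling: caller consensus, clonality QC, channel
classification, and mutation-catalog construction.

The entry point for a typical run is :func:`read_vcf` for each caller's
PASS set, :func:`intersect_callers` for the consensus, and
:func:`build_catalog` against a reference genome to obtain a
:class:`~sigcrypt.catalog.MutationCatalog` in a chosen channel schema.

Coordinates are 1-based inclusive (VCF convention) throughout.  Indels are
normalized by shared-suffix/prefix trimming and left-alignment before any
cross-caller comparison, so the same event is matched regardless of how a
caller chose to represent it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .schemas import (
    ChannelSchema,
    SchemaError,
    get_schema,
    id83_to_id16,
    reverse_complement,
)

__all__ = [
    "VariantRecord",
    "ReferenceGenome",
    "MalformedInputError",
    "ClassificationError",
    "FlankError",
    "ClonalityResult",
    "read_vcf",
    "normalize_variant",
    "intersect_callers",
    "vaf_clonality_filter",
    "classify_sbs",
    "classify_indel",
    "merge_adjacent_snvs",
    "build_catalog",
    "collapse_to_sbs7",
    "rank_mutated_genes",
]

_VALID = set("ACGT")
_PURINES = set("AG")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class MalformedInputError(ValueError):
    """Inconsistent caller input (e.g. conflicting REF alleles at a locus)."""


class ClassificationError(ValueError):
    """A variant/context pair that cannot be assigned to a channel."""


class FlankError(ClassificationError):
    """Flanking sequence too short for indel context classification."""


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant with provenance.

    ``pos`` is the 1-based position of the first base of ``ref``.  ``vaf``
    is the variant allele fraction in [0, 1] (NaN when unavailable).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float = float("nan")
    sample_id: str = ""
    callers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise MalformedInputError(
                f"{self.chrom}:{self.pos} empty allele string"
            )
        if not (_VALID >= set(self.ref) and _VALID >= set(self.alt)):
            raise MalformedInputError(
                f"{self.chrom}:{self.pos} alleles must be over ACGT: "
                f"{self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise MalformedInputError(
                f"{self.chrom}:{self.pos} ref equals alt ({self.ref})"
            )
        if not np.isnan(self.vaf) and not 0.0 <= self.vaf <= 1.0:
            raise MalformedInputError(
                f"{self.chrom}:{self.pos} VAF {self.vaf} outside [0, 1]"
            )

    @property
    def variant_class(self) -> str:
        nr, na = len(self.ref), len(self.alt)
        if nr == na:
            return {1: "SNV", 2: "DBS"}.get(nr, "MNV")
        return "INS" if nr < na else "DEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def indel_seq(self) -> str:
        """The inserted or deleted sequence (for INS/DEL records)."""
        if self.variant_class == "INS":
            return self.alt[len(self.ref):]
        if self.variant_class == "DEL":
            return self.ref[len(self.alt):]
        raise ValueError(f"{self.key} is not an indel")


class ReferenceGenome:
    """Uniform 1-based access to a reference, from FASTA or dict.

    Wraps either a ``pyfaidx.Fasta`` (path accepted) or a plain mapping of
    contig name to sequence string, as used by the synthetic fixtures.
    """

    def __init__(self, source: str | Path | Mapping[str, str]) -> None:
        if isinstance(source, (str, Path)):
            from pyfaidx import Fasta

            self._fasta = Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._dict: Mapping[str, str] | None = None
        else:
            self._fasta = None
            self._dict = {k: v.upper() for k, v in source.items()}

    def __contains__(self, chrom: str) -> bool:
        if self._dict is not None:
            return chrom in self._dict
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` from ``start`` to ``end``, 1-based inclusive,
        clipped to the contig bounds."""
        if chrom not in self:
            raise KeyError(f"contig {chrom!r} not in reference")
        start = max(start, 1)
        end = min(end, self.length(chrom))
        if end < start:
            return ""
        if self._dict is not None:
            return self._dict[chrom][start - 1:end]
        return str(self._fasta[chrom][start - 1:end]).upper()


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    sample_id: str,
    caller: str,
    pass_only: bool = True,
) -> list[VariantRecord]:
    """Read one caller's VCF into :class:`VariantRecord` objects.

    Only records with FILTER == PASS are kept when ``pass_only``.  VAF is
    taken, in order of preference, from FORMAT/AF, FORMAT/AD
    (alt / (ref + alt)), then INFO/AF; NaN when none is present.
    Multi-allelic records are split into one record per ALT.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    for v in vcf:
        if pass_only and v.FILTER is not None:  # cyvcf2: None means PASS
            continue
        vafs = _extract_vafs(v)
        for i, alt in enumerate(v.ALT):
            if not (_VALID >= set(alt) and _VALID >= set(v.REF)):
                continue  # symbolic / breakend alleles are out of scope
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    vaf=vafs[i] if i < len(vafs) else float("nan"),
                    sample_id=sample_id,
                    callers=frozenset({caller}),
                )
            )
    vcf.close()
    return records


def _extract_vafs(v) -> list[float]:
    try:
        af = v.format("AF")
        if af is not None:
            return [float(x) for x in np.atleast_1d(af[0])]
    except Exception:
        pass
    try:
        ad = v.format("AD")
        if ad is not None:
            counts = np.atleast_1d(ad[0]).astype(float)
            total = counts.sum()
            if total > 0:
                return [c / total for c in counts[1:]]
    except Exception:
        pass
    info_af = v.INFO.get("AF")
    if info_af is not None:
        if isinstance(info_af, (tuple, list)):
            return [float(x) for x in info_af]
        return [float(info_af)]
    return []


# ---------------------------------------------------------------------------
# Normalization and consensus
# ---------------------------------------------------------------------------

def normalize_variant(v: VariantRecord, reference: ReferenceGenome) -> VariantRecord:
    """Trim shared prefix/suffix and left-align indels.

    The canonical parsimonious representation: alleles share no suffix; any
    shared prefix beyond the single VCF anchor base is removed; indels are
    shifted left as far as the reference allows.
    """
    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos <= 1:
                    raise MalformedInputError(
                        f"{v.chrom}:{v.pos} cannot left-extend past contig start"
                    )
                pos -= 1
                b = reference.fetch(v.chrom, pos, pos)
                ref, alt = b + ref, b + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if pos == v.pos and ref == v.ref and alt == v.alt:
        return v
    return replace(v, pos=pos, ref=ref, alt=alt)


def intersect_callers(
    calls_a: list[VariantRecord],
    calls_b: list[VariantRecord],
) -> list[VariantRecord]:
    """Consensus of two callers' PASS sets.

    A variant is retained iff its normalized (chrom, pos, ref, alt) key is
    present in both inputs; the result carries records from ``calls_a``
    (the primary caller, whose VAF is kept) with ``callers`` set to the
    union of provenance labels.  Records at the same (chrom, pos) with
    conflicting REF alleles raise :class:`MalformedInputError`.
    """
    ref_at: dict[tuple[str, int], str] = {}
    for v in list(calls_a) + list(calls_b):
        prev = ref_at.setdefault((v.chrom, v.pos), v.ref)
        if prev != v.ref:
            raise MalformedInputError(
                f"conflicting REF alleles at {v.chrom}:{v.pos}: "
                f"{prev!r} vs {v.ref!r}"
            )
    b_by_key: dict[tuple, VariantRecord] = {v.key: v for v in calls_b}
    out: list[VariantRecord] = []
    for v in calls_a:
        match = b_by_key.get(v.key)
        if match is not None:
            out.append(replace(v, callers=v.callers | match.callers))
    return out


# ---------------------------------------------------------------------------
# Clonality QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClonalityResult:
    """Outcome of the VAF clonality filter for one sample.

    ``status`` is ``"pass"``, ``"fail"``, or ``"indeterminate"`` (too few
    variants with a defined VAF to judge).
    """

    sample_id: str
    status: str
    n: int
    median_vaf: float
    iqr: float
    frac_below_03: float


def vaf_clonality_filter(
    variants_of_sample: Iterable[VariantRecord],
    window: tuple[float, float] = (0.4, 0.6),
    min_variants: int = 50,
) -> ClonalityResult:
    """Clonality QC: pass iff the median VAF falls inside ``window``.

    A clonally expanded single-cell-derived line carries heterozygous
    somatic variants at VAF ~ 0.5; a median far below that indicates a
    polyclonal culture or contamination.
    """
    records = list(variants_of_sample)
    sample_id = records[0].sample_id if records else ""
    vafs = np.array([v.vaf for v in records], dtype=float)
    vafs = vafs[~np.isnan(vafs)]
    if len(vafs) < min_variants:
        return ClonalityResult(
            sample_id, "indeterminate", len(vafs),
            float(np.median(vafs)) if len(vafs) else float("nan"),
            float("nan"), float("nan"),
        )
    med = float(np.median(vafs))
    q1, q3 = np.percentile(vafs, [25, 75])
    status = "pass" if window[0] <= med <= window[1] else "fail"
    return ClonalityResult(
        sample_id, status, len(vafs), med, float(q3 - q1),
        float(np.mean(vafs < 0.3)),
    )


# ---------------------------------------------------------------------------
# Channel classification
# ---------------------------------------------------------------------------

def classify_sbs(v: VariantRecord, context: str) -> str:
    """SBS-96 channel of an SNV given its centered trinucleotide context.

    Channels are pyrimidine-centered: when the reference base is a purine
    the variant and its context are reverse-complemented first, so e.g.
    G>T in context TGT maps to A[C>A]A.
    """
    if v.variant_class != "SNV":
        raise ClassificationError(f"{v.key} is not an SNV")
    context = context.upper()
    if len(context) != 3:
        raise ClassificationError(
            f"{v.key}: context must be a 3-mer, got {context!r}"
        )
    if not _VALID >= set(context):
        raise ClassificationError(
            f"{v.key}: context {context!r} contains non-ACGT characters"
        )
    if context[1] != v.ref:
        raise ClassificationError(
            f"{v.key}: context middle base {context[1]!r} does not match "
            f"ref {v.ref!r}"
        )
    ref, alt = v.ref, v.alt
    if ref in _PURINES:
        context = reverse_complement(context)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def _run_length(flank: str, base: str, from_end: bool) -> int:
    n = 0
    it = reversed(flank) if from_end else iter(flank)
    for ch in it:
        if ch != base:
            break
        n += 1
    return n


def _unit_copies(flank: str, unit: str, from_end: bool) -> int:
    """Contiguous full copies of ``unit`` at the start (or end) of a flank."""
    n = 0
    L = len(unit)
    while (n + 1) * L <= len(flank):
        if from_end:
            end = len(flank) - n * L
            chunk = flank[end - L:end]
        else:
            chunk = flank[n * L:(n + 1) * L]
        if chunk != unit:
            break
        n += 1
    return n


def _shared_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_indel(
    v: VariantRecord,
    flank_left: str,
    flank_right: str,
    allow_short_flanks: bool = False,
) -> str:
    """ID-83 channel of an insertion or deletion.

    ``flank_left`` / ``flank_right`` are reference sequence immediately 5'
    and 3' of the inserted/deleted segment.  The flank must cover at least
    six repeat units (6 x indel length) on each side unless
    ``allow_short_flanks`` marks a contig-boundary truncation, where the
    boundary legitimately terminates any repeat run.

    Categories follow the curated 83-channel convention: 1-bp indels by
    homopolymer length (base collapsed to the pyrimidine strand), longer
    indels by repeat-unit count of the indel sequence in the flanks, and
    deletions without a full flanking copy but with a partial one scored as
    microhomology of the longest shared proper prefix (with the right
    flank) or suffix (with the left flank).  The ID-16 main-context label
    is obtained with :func:`sigcrypt.schemas.id83_to_id16`.
    """
    if v.variant_class not in ("INS", "DEL"):
        raise ClassificationError(f"{v.key} is not an indel")
    seq = v.indel_seq
    L = len(seq)
    flank_left = flank_left.upper()
    flank_right = flank_right.upper()
    needed = 6 * L
    if not allow_short_flanks and (
        len(flank_left) < needed or len(flank_right) < needed
    ):
        raise FlankError(
            f"{v.key}: flanks of >= {needed} bp required for a {L}-bp "
            f"indel (got {len(flank_left)} / {len(flank_right)})"
        )
    is_del = v.variant_class == "DEL"
    op = "Del" if is_del else "Ins"

    if L == 1:
        base = seq
        run = _run_length(flank_left, base, True) + _run_length(
            flank_right, base, False
        )
        if base in _PURINES:
            base = _COMPLEMENT[base]
        if is_del:
            idx = min(run, 5)  # run + deleted copy - 1
        else:
            idx = min(run, 5)  # pre-existing copies
        return f"1:{op}:{base}:{idx}"

    size = min(L, 5)
    copies = _unit_copies(flank_left, seq, True) + _unit_copies(
        flank_right, seq, False
    )
    if is_del:
        units = copies + 1
        if units == 1:
            mh = max(
                _shared_prefix(seq[:-1], flank_right),
                _shared_prefix(seq[::-1][:-1], flank_left[::-1]),
            )
            if mh >= 1:
                return f"{size}:Del:M:{min(mh, 5)}"
        return f"{size}:Del:R:{min(units - 1, 5)}"
    return f"{size}:Ins:R:{min(copies, 5)}"


def merge_adjacent_snvs(
    variants: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Merge per-sample adjacent SNV pairs into DBS records.

    Returns ``(merged_list, dbs_records)`` where ``merged_list`` is the
    input with each adjacent pair replaced by one DBS record (also listed
    separately in ``dbs_records``).  DBS events are counted but not
    signature-analyzed.
    """
    by_sample: dict[str, list[VariantRecord]] = {}
    others: list[VariantRecord] = []
    for v in variants:
        if v.variant_class == "SNV":
            by_sample.setdefault(v.sample_id, []).append(v)
        else:
            others.append(v)
    merged: list[VariantRecord] = []
    dbs: list[VariantRecord] = []
    for sample, snvs in by_sample.items():
        snvs.sort(key=lambda r: (r.chrom, r.pos))
        i = 0
        while i < len(snvs):
            a = snvs[i]
            if (
                i + 1 < len(snvs)
                and snvs[i + 1].chrom == a.chrom
                and snvs[i + 1].pos == a.pos + 1
            ):
                b = snvs[i + 1]
                vaf = float(np.nanmean([a.vaf, b.vaf]))
                rec = VariantRecord(
                    chrom=a.chrom,
                    pos=a.pos,
                    ref=a.ref + b.ref,
                    alt=a.alt + b.alt,
                    vaf=vaf,
                    sample_id=sample,
                    callers=a.callers | b.callers,
                )
                merged.append(rec)
                dbs.append(rec)
                i += 2
            else:
                merged.append(a)
                i += 1
    merged.extend(others)
    merged.sort(key=lambda r: (r.sample_id, r.chrom, r.pos))
    return merged, dbs


# ---------------------------------------------------------------------------
# Catalog construction
# ---------------------------------------------------------------------------

def build_catalog(
    variants: Iterable[VariantRecord],
    reference: ReferenceGenome,
    schema: ChannelSchema | str,
    group_of: dict[str, str] | None = None,
    sample_ids: list[str] | None = None,
) -> MutationCatalog:
    """Classify variants and count them into a channels x samples catalog.

    Variants whose class has no channel under ``schema`` (e.g. a DBS under
    SBS96) are never silently dropped: they are tabulated in the returned
    catalog's ``unclassified`` DataFrame with the reason.  A locus outside
    the reference raises, listing the offending records.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    if schema.name not in ("SBS96", "ID83"):
        raise SchemaError(
            "catalogs are built in SBS96 or ID83; collapse afterwards"
        )
    variants = list(variants)
    missing = [
        v for v in variants
        if v.chrom not in reference
        or v.pos + len(v.ref) - 1 > reference.length(v.chrom)
    ]
    if missing:
        loci = ", ".join(f"{v.chrom}:{v.pos}" for v in missing[:10])
        raise KeyError(
            f"{len(missing)} variant(s) outside the reference: {loci}"
        )

    if sample_ids is None:
        sample_ids = sorted({v.sample_id for v in variants})
    counts = pd.DataFrame(
        0, index=list(schema.labels), columns=sample_ids, dtype=np.int64
    )
    unclassified: list[dict] = []
    for v in variants:
        if v.sample_id not in counts.columns:
            unclassified.append(_unclassified(v, "unknown sample_id"))
            continue
        try:
            label = _classify_for_schema(v, reference, schema)
        except ClassificationError as exc:
            unclassified.append(_unclassified(v, str(exc)))
            continue
        if label is None:
            unclassified.append(
                _unclassified(
                    v, f"class {v.variant_class} outside schema {schema.name}"
                )
            )
            continue
        counts.loc[label, v.sample_id] += 1

    catalog = MutationCatalog(counts, schema, group_of or {})
    catalog.unclassified = pd.DataFrame(
        unclassified,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "variant_class", "reason"],
    )
    return catalog


def _unclassified(v: VariantRecord, reason: str) -> dict:
    return {
        "sample_id": v.sample_id,
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "variant_class": v.variant_class,
        "reason": reason,
    }


def _classify_for_schema(
    v: VariantRecord, reference: ReferenceGenome, schema: ChannelSchema
) -> str | None:
    if schema.name == "SBS96":
        if v.variant_class != "SNV":
            return None
        context = reference.fetch(v.chrom, v.pos - 1, v.pos + 1)
        if len(context) < 3:
            raise ClassificationError(
                f"{v.key}: SNV at contig boundary has no 3-mer context"
            )
        return classify_sbs(v, context)
    # ID83
    if v.variant_class not in ("INS", "DEL"):
        return None
    vn = normalize_variant(v, reference)
    L = len(vn.indel_seq)
    window = 6 * L
    if vn.variant_class == "DEL":
        del_start = vn.pos + len(vn.alt)
        del_end = vn.pos + len(vn.ref) - 1
        left = reference.fetch(vn.chrom, del_start - window, del_start - 1)
        right = reference.fetch(vn.chrom, del_end + 1, del_end + window)
    else:
        ins_after = vn.pos + len(vn.ref) - 1
        left = reference.fetch(vn.chrom, ins_after - window + 1, ins_after)
        right = reference.fetch(vn.chrom, ins_after + 1, ins_after + window)
    return classify_indel(vn, left, right, allow_short_flanks=True)


def collapse_to_sbs7(catalog: MutationCatalog) -> MutationCatalog:
    """Collapse an SBS96 catalog to 7 substitution categories.

    C>T is split by CpG status: a 3' G in pyrimidine orientation marks a
    CpG site (methyl-cytosine deamination, the SBS1 mechanism).  Column
    sums are preserved.
    """
    if catalog.schema.name != "SBS96":
        raise SchemaError(
            f"collapse_to_sbs7 requires an SBS96 catalog, got "
            f"{catalog.schema.name}"
        )
    sbs7 = get_schema("SBS7")
    out = pd.DataFrame(
        0, index=list(sbs7.labels), columns=catalog.sample_ids, dtype=np.int64
    )
    for label in catalog.schema.labels:
        sub = label[2:5]
        if sub == "C>T":
            target = "C>T at CpG" if label[6] == "G" else "C>T other"
        else:
            target = sub
        out.loc[target] += catalog.df.loc[label]
    return MutationCatalog(out, sbs7, dict(catalog.group_of))


# ---------------------------------------------------------------------------
# Coding-mutation gene ranking
# ---------------------------------------------------------------------------

def rank_mutated_genes(
    annotated_variants: pd.DataFrame,
    group_of: Mapping[str, str],
    n: int = 10,
) -> tuple[dict[str, pd.DataFrame], int]:
    """Rank genes by recurrence per group and count the top-n overlap.

    ``annotated_variants`` has columns ``sample_id``, ``gene``,
    ``consequence`` (annotation is produced upstream; any free-form
    consequence labels are accepted).  Genes are ranked by the number of
    mutated samples, then total mutations, ties broken lexicographically.
    Returns ``({group: ranked table}, overlap)`` where ``overlap`` is the
    size of the intersection of the two groups' top-n gene sets.
    """
    import warnings

    required = {"sample_id", "gene", "consequence"}
    if not required <= set(annotated_variants.columns):
        raise ValueError(f"annotated table must have columns {sorted(required)}")
    df = annotated_variants.copy()
    df["group"] = df["sample_id"].map(dict(group_of))
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "sample_id"].unique())
        raise KeyError(f"samples without a group assignment: {missing}")

    tables: dict[str, pd.DataFrame] = {}
    tops: list[set[str]] = []
    for group, sub in df.groupby("group", sort=True):
        agg = (
            sub.groupby("gene")
            .agg(
                n_samples=("sample_id", "nunique"),
                n_mutations=("sample_id", "size"),
            )
            .reset_index()
        )
        agg = agg.sort_values(
            ["n_samples", "n_mutations", "gene"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        if n > len(agg):
            warnings.warn(
                f"requested top {n} but group {group!r} has only "
                f"{len(agg)} mutated genes; returning all"
            )
        tables[group] = agg
        tops.append(set(agg["gene"].head(n)))
    overlap = len(set.intersection(*tops)) if len(tops) >= 2 else len(tops[0]) if tops else 0
    return tables, overlap
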