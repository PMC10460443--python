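"""Synthetic cohorts, catalogs, VAF spectra and on-disk VCF/FASTA fixtures.

The generator emulates the statistical structure of a two-diet clonal
organoid WGS cohort: two groups (HFD / SD) of 5 mice x 4 clones, each
clone carrying Poisson-distributed mutation counts drawn from a small
mixture of mutational signatures, equal between groups under the null
design.  Per-clone totals default to the cohort-scale burden divided by
40 clones (~1200 SNVs, ~170 indels per clone), with gamma-distributed
between-clone variability.  Every simulated artifact returns its
generating parameters so recovery error is always computable.

:func:`write_fixture_vcf_and_fasta` goes one step further down: it embeds
each drawn channel in a synthetic contig whose local sequence realizes
that channel (trinucleotide context for SBS; homopolymer / repeat /
microhomology flanks for indels) and writes a reference FASTA plus two
pseudo-caller VCFs per sample, so the whole VCF -> consensus -> catalog
path can be round-tripped against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ExposureMatrix, MutationCatalog, SignatureSet
from .schemas import ChannelSchema, get_schema

__all__ = [
    "CohortDesign",
    "GeneratingMixture",
    "FixtureSet",
    "make_reference_signatures",
    "simulate_cohort",
    "simulate_vaf",
    "write_fixture_vcf_and_fasta",
]


@dataclass(frozen=True)
class CohortDesign:
    """Two-group cohort layout and per-clone mutation burden."""

    groups: tuple[str, str] = ("HFD", "SD")
    mice_per_group: int = 5
    clones_per_mouse: int = 4
    mutations_per_clone: float = 1200.0  # ~48,742 SNVs over 40 clones; ~170 for indels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.groups[0] == self.groups[1]:
            raise ValueError("group labels must be distinct")
        if min(self.mice_per_group, self.clones_per_mouse) < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.mutations_per_clone <= 0:
            raise ValueError("mutations_per_clone must be positive")

    def sample_ids(self) -> dict[str, str]:
        """Ordered sample -> group mapping."""
        out: dict[str, str] = {}
        for g in self.groups:
            for m in range(1, self.mice_per_group + 1):
                for c in range(1, self.clones_per_mouse + 1):
                    out[f"{g}_m{m}_c{c}"] = g
        return out


@dataclass
class GeneratingMixture:
    """Known signature mixture from which a cohort is simulated.

    ``group_exposure_means`` is signatures x groups with each group column
    summing to one.  ``dispersion`` is the shape of the mean-one gamma
    multiplier applied per clone and signature (larger = tighter).
    """

    signatures: SignatureSet
    group_exposure_means: pd.DataFrame
    dispersion: float = 20.0

    def __post_init__(self) -> None:
        means = self.group_exposure_means
        if list(means.index) != self.signatures.signature_ids:
            raise ValueError("exposure-mean rows must match signature ids")
        if (means.to_numpy() < 0).any():
            raise ValueError("exposure means must be non-negative")
        sums = means.sum(axis=0)
        if not np.allclose(sums, 1.0):
            raise ValueError("each group's exposure means must sum to 1")

    @classmethod
    def null(
        cls,
        signatures: SignatureSet,
        groups: tuple[str, str] = ("HFD", "SD"),
        weights: np.ndarray | None = None,
        dispersion: float = 20.0,
    ) -> "GeneratingMixture":
        """Both groups share one mixture (the study's null structure)."""
        k = len(signatures)
        w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, float)
        w = w / w.sum()
        means = pd.DataFrame(
            {g: w for g in groups}, index=signatures.signature_ids
        )
        return cls(signatures, means, dispersion)

    @classmethod
    def with_differential(
        cls,
        signatures: SignatureSet,
        differential: str,
        fold_change: float,
        groups: tuple[str, str] = ("HFD", "SD"),
        base_weights: np.ndarray | None = None,
        dispersion: float = 20.0,
    ) -> "GeneratingMixture":
        """Alternative design: one signature up-weighted in the first group."""
        null = cls.null(signatures, groups, base_weights, dispersion)
        means = null.group_exposure_means.copy()
        means.loc[differential, groups[0]] *= fold_change
        means[groups[0]] /= means[groups[0]].sum()
        return cls(signatures, means, dispersion)


def make_reference_signatures(
    schema: ChannelSchema | str,
    k: int,
    separation: float = 0.3,
    seed: int = 0,
    concentration: float = 0.08,
    max_tries: int = 200,
) -> SignatureSet:
    """Random well-separated column-stochastic signatures.

    Draws sparse Dirichlet profiles until all pairwise cosines are at most
    ``separation``.  Deterministic under ``seed``; raises if the requested
    separation is infeasible within ``max_tries`` redraws.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < separation < 1:
        raise ValueError("separation must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(schema)
    alpha = np.full(n, concentration)
    for _ in range(max_tries):
        S = rng.dirichlet(alpha, size=k).T  # channels x k
        S = np.maximum(S, 1e-12)
        S = S / S.sum(axis=0)
        norm = S / np.linalg.norm(S, axis=0)
        gram = norm.T @ norm
        off = gram[~np.eye(k, dtype=bool)]
        if k == 1 or off.max() <= separation:
            ids = [f"SYN{schema.name}{i + 1}" for i in range(k)]
            return SignatureSet(
                pd.DataFrame(S, index=list(schema.labels), columns=ids), schema
            )
    raise ValueError(
        f"could not draw {k} signatures with pairwise cosine <= {separation} "
        f"in {max_tries} tries"
    )


def simulate_cohort(
    design: CohortDesign,
    mixture: GeneratingMixture,
    seed: int | None = None,
) -> tuple[MutationCatalog, ExposureMatrix]:
    """Simulate a catalog and its ground-truth exposures.

    Per clone: the expected exposure vector is the group's mean mixture
    scaled to the clone total, each signature jittered by an independent
    mean-one gamma multiplier; channel counts are Poisson around
    S @ e.  Deterministic under the seed (``design.seed`` by default).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    S = mixture.signatures.matrix
    sig_ids = mixture.signatures.signature_ids
    sample_groups = design.sample_ids()
    shape = mixture.dispersion

    exposures = {}
    counts = {}
    for sample, group in sample_groups.items():
        mean_w = mixture.group_exposure_means[group].to_numpy()
        jitter = (
            rng.gamma(shape, 1.0 / shape, size=len(sig_ids))
            if shape > 0
            else np.ones(len(sig_ids))
        )
        e = mean_w * design.mutations_per_clone * jitter
        lam = S @ e
        counts[sample] = rng.poisson(lam)
        exposures[sample] = e
    catalog = MutationCatalog(
        pd.DataFrame(counts, index=list(mixture.signatures.schema.labels)),
        mixture.signatures.schema,
        dict(sample_groups),
    )
    truth = ExposureMatrix(pd.DataFrame(exposures, index=sig_ids))
    return catalog, truth


def simulate_vaf(
    n: int,
    clonal: bool = True,
    seed: int = 0,
    subclonal_fraction: float = 0.65,
) -> np.ndarray:
    """Variant allele fractions of a clonal or contaminated sample.

    Clonal: Beta(50, 50), median ~0.5 (heterozygous variants in a
    single-cell-derived line).  Non-clonal: a mixture with a subclonal
    Beta(12.5, 37.5) mode near 0.25 carrying ``subclonal_fraction`` of
    the mass — enough to pull the sample median clearly below the
    clonality window, so the two cases separate cleanly under the
    default filter (an equal-weight mixture would park the median right
    at the 0.4 boundary).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    clonal_draws = rng.beta(50, 50, size=n)
    if clonal:
        return clonal_draws
    sub = rng.beta(12.5, 37.5, size=n)
    pick = rng.random(n) < 1.0 - subclonal_fraction
    return np.where(pick, clonal_draws, sub)


# ---------------------------------------------------------------------------
# On-disk fixtures: synthetic contig + two pseudo-caller VCFs
# ---------------------------------------------------------------------------

_MH_STEM = "ACGAGC"  # T-free, aperiodic: safe against guard interactions
_REPEAT_UNITS = {2: "AC", 3: "ACG", 4: "ACGA", 5: "ACGAG"}


def _sbs_cassette(label: str) -> tuple[str, int, str, str]:
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    seq = "GG" + five + ref + three + "GG"
    return seq, 3, ref, alt


def _indel_cassette(label: str) -> tuple[str, int, str, str]:
    size_s, op, subtype, idx_s = label.split(":")
    size, idx = int(size_s), int(idx_s)
    if subtype in ("C", "T"):
        b = subtype
        if op == "Del":
            copies = idx + 1
            seq = "AA" + b * copies + "AA"
            return seq, 1, "A" + b, "A"
        seq = "AA" + b * idx + "AA"
        return seq, 1, "A", "A" + b
    if subtype == "R":
        unit = _REPEAT_UNITS[size]
        if op == "Del":
            units = idx + 1
            seq = "TT" + unit * units + "TT"
            return seq, 1, "T" + unit, "T"
        seq = "TT" + unit * idx + "TT"
        return seq, 1, "T", "T" + unit
    # microhomology deletion; label "5:Del:M:5" needs a 6-bp deletion
    length = 6 if (size == 5 and idx == 5) else size
    D = _MH_STEM[:length]
    seq = "TT" + D + D[:idx] + "T" + "TT"
    return seq, 1, "T" + D, "T"


@dataclass
class FixtureSet:
    """Paths and ground truth of one on-disk fixture."""

    fasta: Path
    vcf_a: dict[str, Path]
    vcf_b: dict[str, Path]
    contig: str
    truth_consensus: pd.DataFrame  # channels x samples, variants in BOTH callers
    truth_drawn: pd.DataFrame  # channels x samples, all drawn variants
    group_of: dict[str, str] = field(default_factory=dict)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=low_qual,Description="Failed caller quality model">
##contig=<ID={contig},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
"""


def write_fixture_vcf_and_fasta(
    draws: pd.DataFrame,
    schema: ChannelSchema | str,
    out_dir: str | Path,
    overlap: float = 1.0,
    seed: int = 0,
    group_of: dict[str, str] | None = None,
    contig: str = "chr_syn",
) -> FixtureSet:
    """Materialize channel draws as a toy reference and caller VCF pairs.

    ``draws`` is channels x samples integer counts.  Each mutation is
    embedded in a cassette whose sequence realizes its channel; caller B
    writes indels in a non-parsimonious (anchor-padded) representation so
    the consensus step has to normalize before matching.  With
    probability ``1 - overlap`` a variant is assigned to only one caller
    (choosing A or B evenly), so the consensus retains ~``overlap`` of
    the draws; ``truth_consensus`` records the exact retained counts.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0, 1]")
    draws = draws.reindex(list(schema.labels)).fillna(0).astype(int)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cassette = _sbs_cassette if schema.name == "SBS96" else _indel_cassette

    chunks: list[str] = []
    offset = 0
    per_sample: dict[str, list[tuple[int, str, str, float, str]]] = {
        s: [] for s in draws.columns
    }
    consensus = pd.DataFrame(0, index=draws.index, columns=draws.columns)
    for sample in draws.columns:
        for label, count in draws[sample].items():
            for _ in range(int(count)):
                seq, rel, ref, alt = cassette(label)
                pos = offset + rel + 1  # 1-based
                vaf = float(rng.beta(50, 50))
                u = rng.random()
                if u < overlap:
                    dest = "both"
                    consensus.loc[label, sample] += 1
                elif u < overlap + (1.0 - overlap) / 2.0:
                    dest = "a"
                else:
                    dest = "b"
                per_sample[sample].append((pos, ref, alt, vaf, dest))
                chunks.append(seq)
                offset += len(seq)

    sequence = "".join(chunks) or "ACGT" * 10
    fasta = out_dir / "reference.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i:i + 70] + "\n")

    vcf_a: dict[str, Path] = {}
    vcf_b: dict[str, Path] = {}
    for sample, records in per_sample.items():
        vcf_a[sample] = _write_vcf(
            out_dir / f"{sample}.callerA.vcf", contig, len(sequence),
            [r for r in records if r[4] in ("both", "a")], sequence, pad=False,
        )
        vcf_b[sample] = _write_vcf(
            out_dir / f"{sample}.callerB.vcf", contig, len(sequence),
            [r for r in records if r[4] in ("both", "b")], sequence, pad=True,
        )
    return FixtureSet(
        fasta=fasta,
        vcf_a=vcf_a,
        vcf_b=vcf_b,
        contig=contig,
        truth_consensus=consensus,
        truth_drawn=draws.copy(),
        group_of=dict(group_of or {}),
    )


def _write_vcf(
    path: Path,
    contig: str,
    length: int,
    records: list[tuple[int, str, str, float, str]],
    sequence: str,
    pad: bool,
) -> Path:
    lines = [_VCF_HEADER.format(contig=contig, length=length)]
    for pos, ref, alt, vaf, _ in sorted(records):
        if pad and len(ref) != len(alt) and pos > 1:
            # anchor-padded (non-parsimonious) indel representation
            prev = sequence[pos - 2]
            pos, ref, alt = pos - 1, prev + ref, prev + alt
        depth = 100
        alt_reads = int(round(vaf * depth))
        lines.append(
            f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
            f"GT:AF:AD\t0/1:{vaf:.4f}:{depth - alt_reads},{alt_reads}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)
    return path
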