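"""Core I/O and domain types: variant lists, pileup evidence, exclusions.

Conventions
-----------
* VCF positions are 1-based; BED intervals are 0-based half-open. Every
  ``GenomicLocus`` in this package is 1-based; conversion happens exactly
  once, at the BED boundary (:func:`read_bed_regions`).
* Multi-allelic VCF records are decomposed into one :class:`SnvCall` per
  alternate allele; each allele is filtered independently and surviving
  alleles are re-emitted as separate records.
* A read whose alignment places a deletion or reference skip across a locus
  contributes a GAP observation: GAPs never count as alt support and are
  excluded from depth.
"""

from __future__ import annotations

import sys
import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from intervaltree import IntervalTree

logger = logging.getLogger("raresieve")

NUCLEOTIDES = frozenset("ACGT")

#: Namespace prefix for every INFO key and header line this suite writes.
ANNOTATION_PREFIX = "SIEVE_"
HEADER_PREFIX = "##raresieve_"


class VcfParseError(ValueError):
    """Malformed VCF input; message names the offending line."""


class BedParseError(ValueError):
    """Malformed BED or exclusion-table input; message names the line."""


class ConfigurationError(ValueError):
    """Unusable run configuration (missing index, empty panel, bad file)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicLocus:
    """A 1-based reference position."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")


@dataclass
class SnvCall:
    """One candidate single-nucleotide variant (one alt allele).

    ``passthrough`` preserves the original record's ID/QUAL/FILTER/INFO
    columns verbatim so filtering is lossless; ``annotations`` holds the
    INFO keys added by this suite (prefixed ``SIEVE_``).
    """

    locus: GenomicLocus
    ref_base: str
    alt_base: str
    site_id: str = "."
    qual: str = "."
    passthrough: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_base not in NUCLEOTIDES or self.alt_base not in NUCLEOTIDES:
            raise ValueError(
                f"ref/alt must be single nucleotides, got {self.ref_base!r}/{self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base must differ from alt_base")

    @property
    def identity(self) -> tuple[str, int, str, str]:
        """Exact variant identity: (chrom, pos, ref, alt)."""
        return (self.locus.chrom, self.locus.pos, self.ref_base, self.alt_base)


GAP = "GAP"


@dataclass(frozen=True)
class ReadObservation:
    """One aligned read's contribution to a pileup column."""

    read_name: str
    base_at_locus: str  # A/C/G/T or GAP
    mate_ordinal: str  # "first", "second" or "unpaired"
    read_length: int
    base_quality: int
    mapping_quality: int
    duplicate_flag: bool


@dataclass(frozen=True)
class QualityGates:
    """Observation-level gates applied before evidence counting.

    Defaults are permissive (evidence in *any* read counts) except that
    duplicate-flagged reads are ignored, since duplicate removal is assumed
    upstream and retained flags are defensive.
    """

    min_base_quality: int = 0
    min_mapping_quality: int = 0
    count_duplicates: bool = False


@dataclass(frozen=True)
class MateClassConfig:
    """How reads are split into long-mate vs short-mate classes.

    ``by-length`` (default): reads strictly shorter than ``length_cutoff``
    are short-mate; with ``length_cutoff=None`` the cutoff is the longest
    qualifying read length observed at the locus, so in a 50/35 chemistry
    the 35-base mate is short and on balanced data no read is short.
    ``by-ordinal``: the configured mate of each pair is short.
    Unpaired reads are long-mate in both modes.
    """

    mode: str = "by-length"  # "by-length" | "by-ordinal"
    short_mate_ordinal: str = "second"  # "first" | "second"
    length_cutoff: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("by-length", "by-ordinal"):
            raise ValueError(f"unknown mate-class mode {self.mode!r}")
        if self.short_mate_ordinal not in ("first", "second"):
            raise ValueError("short_mate_ordinal must be 'first' or 'second'")
        if self.length_cutoff is not None and self.length_cutoff < 1:
            raise ValueError("length_cutoff must be >= 1")


def mate_class(
    observation: ReadObservation,
    config: MateClassConfig,
    locus_max_length: int | None = None,
) -> str:
    """Classify one observation as ``"long_mate"`` or ``"short_mate"``.

    ``locus_max_length`` supplies the per-locus cutoff when the by-length
    config leaves ``length_cutoff`` unset.
    """
    if observation.mate_ordinal == "unpaired":
        return "long_mate"
    if config.mode == "by-ordinal":
        return (
            "short_mate"
            if observation.mate_ordinal == config.short_mate_ordinal
            else "long_mate"
        )
    cutoff = config.length_cutoff
    if cutoff is None:
        if locus_max_length is None:
            return "long_mate"
        cutoff = locus_max_length
    return "short_mate" if observation.read_length < cutoff else "long_mate"


@dataclass(frozen=True)
class PileupEvidence:
    """Per-sample, per-locus read support summary."""

    locus: GenomicLocus
    sample_id: str
    depth: int
    alt_count: int
    alt_count_long_mate: int
    alt_count_short_mate: int

    def __post_init__(self) -> None:
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError("alt_count must satisfy 0 <= alt_count <= depth")
        if self.alt_count_long_mate + self.alt_count_short_mate != self.alt_count:
            raise ValueError("mate-class alt counts must sum to alt_count")

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class FilterOutcome:
    """Partition of input variants into kept and binned, with provenance.

    ``kept`` and ``binned`` are disjoint, preserve input order, and jointly
    exhaust the input. ``provenance`` has one entry per input variant in
    input order.
    """

    kept: list[SnvCall]
    binned: list[SnvCall]
    provenance: list[dict]

    def __post_init__(self) -> None:
        if len(self.kept) + len(self.binned) != len(self.provenance):
            raise ValueError("provenance must cover every input variant")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def _vcf_line_fields(record: pysam.VariantRecord) -> list[str]:
    return str(record).rstrip("\n").split("\t")


def read_snv_calls(path: str) -> tuple[list[SnvCall], dict]:
    """Read candidate SNVs from a VCF (plain or bgzipped).

    Multi-allelic records are decomposed into one :class:`SnvCall` per alt
    allele; non-SNV alleles (indels, MNVs, symbolic or missing alleles) are
    skipped and counted. Returns ``(calls, meta)`` where ``meta`` carries the
    original header lines, the skip counter and the record count.
    """
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc

    header_lines = [
        line for line in str(vcf.header).rstrip("\n").split("\n")
        if line.startswith("##")
    ]
    calls: list[SnvCall] = []
    skipped_non_snv = 0
    n_records = 0
    lineno = len(header_lines) + 1  # the #CHROM line
    try:
        for record in vcf:
            lineno += 1
            n_records += 1
            fields = _vcf_line_fields(record)
            if len(fields) < 8:
                raise VcfParseError(f"{path}: line {lineno}: fewer than 8 VCF columns")
            info_str = fields[7]
            passthrough = {
                "id": fields[2],
                "qual": fields[5],
                "filter": fields[6],
                "info": info_str,
            }
            annotations = _annotations_from_info(info_str)
            ref = (record.ref or "").upper()
            alts = record.alts or ()
            if not alts:
                skipped_non_snv += 1
                continue
            for alt in alts:
                alt = (alt or "").upper()
                if len(ref) == 1 and ref in NUCLEOTIDES and len(alt) == 1 \
                        and alt in NUCLEOTIDES and alt != ref:
                    calls.append(
                        SnvCall(
                            locus=GenomicLocus(record.chrom, record.pos),
                            ref_base=ref,
                            alt_base=alt,
                            site_id=fields[2],
                            qual=fields[5],
                            passthrough=dict(passthrough),
                            annotations=dict(annotations),
                        )
                    )
                else:
                    skipped_non_snv += 1
    except VcfParseError:
        raise
    except Exception as exc:  # htslib parse failures surface here
        raise VcfParseError(f"{path}: line {lineno}: malformed VCF record: {exc}") from exc
    finally:
        vcf.close()

    if skipped_non_snv:
        logger.info("%s: skipped %d non-SNV allele(s)", path, skipped_non_snv)
    meta = {
        "header_lines": header_lines,
        "skipped_non_snv": skipped_non_snv,
        "n_records": n_records,
    }
    return calls, meta


def _annotations_from_info(info_str: str) -> dict:
    """Recover this suite's own INFO keys so re-annotation overwrites them."""
    out: dict[str, str] = {}
    if info_str in (".", ""):
        return out
    for item in info_str.split(";"):
        key, _, value = item.partition("=")
        if key.startswith(ANNOTATION_PREFIX):
            out[key] = value
    return out


def _strip_suite_keys(info_str: str) -> str:
    if info_str in (".", ""):
        return "."
    items = [
        item for item in info_str.split(";")
        if not item.partition("=")[0].startswith(ANNOTATION_PREFIX)
    ]
    return ";".join(items) if items else "."


_ANNOTATION_HEADER_DEFS = {
    "SIEVE_BIN": '##INFO=<ID=SIEVE_BIN,Number=1,Type=String,'
                 'Description="Reason this variant was binned by a raresieve filter">',
    "SIEVE_CMP": '##INFO=<ID=SIEVE_CMP,Number=.,Type=String,'
                 'Description="Per-comparator alt/depth counts as sample:alt/depth">',
    "SIEVE_CMP_PCT": '##INFO=<ID=SIEVE_CMP_PCT,Number=1,Type=Float,'
                     'Description="Percent of comparator samples that are variant-like">',
    "SIEVE_PE": '##INFO=<ID=SIEVE_PE,Number=1,Type=String,'
                'Description="Paired-end mate support as long/short alt counts">',
    "SIEVE_FLAG": '##INFO=<ID=SIEVE_FLAG,Number=.,Type=String,'
                  'Description="Audit flags (e.g. no-support-observed)">',
    "SIEVE_FAM": '##INFO=<ID=SIEVE_FAM,Number=.,Type=String,'
                 'Description="Per-relative alt/depth counts as sample:alt/depth">',
    "SIEVE_FAM_N": '##INFO=<ID=SIEVE_FAM_N,Number=1,Type=Integer,'
                   'Description="Number of relatives with read-level evidence">',
}

_MINIMAL_HEADER = ["##fileformat=VCFv4.2"]
_CHROM_LINE = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"


def write_snv_calls(
    variants: Sequence[SnvCall],
    path: str,
    source_header: Sequence[str] | None = None,
    provenance: Mapping[str, str] | None = None,
) -> None:
    """Write SNV calls as a plain-text VCF.

    The original header is reproduced (or a minimal one synthesised),
    augmented with ``##raresieve_*`` provenance lines and INFO definitions
    for every suite annotation key in use. Original ID/QUAL/FILTER/INFO
    columns are carried through verbatim; suite annotations are appended to
    INFO (replacing any previous run's values, so annotation is idempotent).
    """
    header = list(source_header) if source_header else list(_MINIMAL_HEADER)
    if not any(line.startswith("##fileformat") for line in header):
        header.insert(0, "##fileformat=VCFv4.2")
    header = [line for line in header if not line.startswith(HEADER_PREFIX)]

    used_keys = sorted({key for v in variants for key in v.annotations})
    declared = {
        line.split("<ID=", 1)[1].split(",", 1)[0]
        for line in header
        if line.startswith("##INFO=<ID=")
    }
    for key in used_keys:
        if key not in declared and key in _ANNOTATION_HEADER_DEFS:
            header.append(_ANNOTATION_HEADER_DEFS[key])
    for key, value in (provenance or {}).items():
        header.append(f"{HEADER_PREFIX}{key}={value}")

    try:
        with open(path, "w") as out:
            for line in header:
                out.write(line + "\n")
            out.write(_CHROM_LINE + "\n")
            for v in variants:
                base_info = _strip_suite_keys(v.passthrough.get("info", "."))
                extra = ";".join(
                    f"{k}={v.annotations[k]}" for k in sorted(v.annotations)
                )
                if extra:
                    info = extra if base_info == "." else f"{base_info};{extra}"
                else:
                    info = base_info
                out.write(
                    "\t".join(
                        [
                            v.locus.chrom,
                            str(v.locus.pos),
                            v.passthrough.get("id", v.site_id),
                            v.ref_base,
                            v.alt_base,
                            v.passthrough.get("qual", v.qual),
                            v.passthrough.get("filter", "."),
                            info,
                        ]
                    )
                    + "\n"
                )
    except OSError as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Pileup evidence
# ---------------------------------------------------------------------------

def open_alignment(path: str) -> pysam.AlignmentFile:
    """Open an indexed BAM; a missing index is a configuration error."""
    try:
        bam = pysam.AlignmentFile(path, "rb")
    except (OSError, ValueError) as exc:
        raise ConfigurationError(f"cannot open alignment file {path}: {exc}") from exc
    if not bam.has_index():
        bam.close()
        raise ConfigurationError(f"alignment file {path} has no index (.bai)")
    return bam


def collect_read_observations(
    alignments: pysam.AlignmentFile,
    locus: GenomicLocus,
    gates: QualityGates = QualityGates(),
) -> list[ReadObservation]:
    """All qualifying read observations over one locus (GAPs included).

    Secondary, supplementary, unmapped and QC-fail records never qualify;
    duplicates qualify only when the gates say so. A chromosome absent from
    the BAM header yields no observations (with a warning).
    """
    if locus.chrom not in alignments.references:
        logger.warning(
            "%s absent from %s header; treating as zero coverage",
            locus.chrom, alignments.filename.decode(),
        )
        return []
    observations: list[ReadObservation] = []
    for column in alignments.pileup(
        locus.chrom,
        locus.pos - 1,
        locus.pos,
        truncate=True,
        stepper="nofilter",
        ignore_overlaps=False,
        min_base_quality=0,
        max_depth=1_000_000,
    ):
        for pileup_read in column.pileups:
            read = pileup_read.alignment
            if read.is_unmapped or read.is_secondary or read.is_supplementary \
                    or read.is_qcfail:
                continue
            if read.is_duplicate and not gates.count_duplicates:
                continue
            if read.mapping_quality < gates.min_mapping_quality:
                continue
            if pileup_read.is_del or pileup_read.is_refskip:
                base, base_quality = GAP, 0
            else:
                qpos = pileup_read.query_position
                base = read.query_sequence[qpos].upper()
                quals = read.query_qualities
                base_quality = int(quals[qpos]) if quals is not None else 0
                if base_quality < gates.min_base_quality:
                    continue
            if read.is_paired:
                ordinal = "first" if read.is_read1 else "second"
            else:
                ordinal = "unpaired"
            observations.append(
                ReadObservation(
                    read_name=read.query_name,
                    base_at_locus=base,
                    mate_ordinal=ordinal,
                    read_length=read.query_length,
                    base_quality=base_quality,
                    mapping_quality=read.mapping_quality,
                    duplicate_flag=read.is_duplicate,
                )
            )
    return observations


def summarize_observations(
    observations: Iterable[ReadObservation],
    locus: GenomicLocus,
    sample_id: str,
    alt_base: str,
    mate_config: MateClassConfig = MateClassConfig(),
) -> PileupEvidence:
    """Reduce observations at a locus to :class:`PileupEvidence` counts."""
    aligned = [o for o in observations if o.base_at_locus != GAP]
    locus_max = max((o.read_length for o in aligned), default=None)
    alt = [o for o in aligned if o.base_at_locus == alt_base]
    n_short = sum(
        1 for o in alt if mate_class(o, mate_config, locus_max) == "short_mate"
    )
    return PileupEvidence(
        locus=locus,
        sample_id=sample_id,
        depth=len(aligned),
        alt_count=len(alt),
        alt_count_long_mate=len(alt) - n_short,
        alt_count_short_mate=n_short,
    )


def collect_pileup_evidence(
    alignments: pysam.AlignmentFile,
    locus: GenomicLocus,
    alt_base: str,
    gates: QualityGates = QualityGates(),
    mate_config: MateClassConfig = MateClassConfig(),
    sample_id: str | None = None,
) -> PileupEvidence:
    """Count read support for ``alt_base`` at ``locus`` in one BAM."""
    if sample_id is None:
        sample_id = alignments.filename.decode()
    observations = collect_read_observations(alignments, locus, gates)
    return summarize_observations(observations, locus, sample_id, alt_base, mate_config)


# ---------------------------------------------------------------------------
# Exclusion lists and region filters
# ---------------------------------------------------------------------------

@dataclass
class ExclusionSet:
    """Positions to exclude, at (chrom,pos,alt) or (chrom,pos) granularity.

    When the source table supplies alt alleles, matching uses position+allele
    (dbSNP exports vary); position-only rows exclude every allele there.
    """

    pos_alt: set = field(default_factory=set)
    pos_only: set = field(default_factory=set)

    def __contains__(self, variant: SnvCall) -> bool:
        chrom, pos = variant.locus.chrom, variant.locus.pos
        return (chrom, pos) in self.pos_only or \
            (chrom, pos, variant.alt_base) in self.pos_alt

    def __len__(self) -> int:
        return len(self.pos_alt) + len(self.pos_only)


def read_exclusion_table(path: str) -> ExclusionSet:
    """Read a tab-separated chrom/pos[/ref/alt] exclusion table.

    2 columns -> position-only rows; 3 columns -> chrom, pos, alt;
    4 columns -> chrom, pos, ref, alt. Lines starting with '#' are comments.
    """
    excl = ExclusionSet()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                chrom, pos = fields[0], int(fields[1])
            except (IndexError, ValueError) as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: expected 'chrom<TAB>pos[...]': {exc}"
                ) from exc
            if len(fields) == 2:
                excl.pos_only.add((chrom, pos))
            else:
                alt = fields[3] if len(fields) >= 4 else fields[2]
                for allele in alt.split(","):
                    allele = allele.strip().upper()
                    if allele in NUCLEOTIDES:
                        excl.pos_alt.add((chrom, pos, allele))
                    else:
                        excl.pos_only.add((chrom, pos))
    return excl


def read_bed_regions(path: str) -> dict[str, IntervalTree]:
    """Read a BED file into per-chromosome interval trees.

    BED is 0-based half-open; a line ``chr1 100 200`` covers 1-based
    positions 101..200.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: BED needs >= 3 tab-separated columns"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer BED coordinates"
                ) from exc
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def locus_in_regions(locus: GenomicLocus, regions: Mapping[str, IntervalTree]) -> bool:
    tree = regions.get(locus.chrom)
    return bool(tree is not None and tree.overlaps(locus.pos - 1))


def exclude_variants(
    variants: Sequence[SnvCall],
    exclusion: ExclusionSet | None = None,
    regions_keep: Mapping[str, IntervalTree] | None = None,
) -> FilterOutcome:
    """Bin variants listed in ``exclusion`` or outside ``regions_keep``."""
    exclusion = exclusion or ExclusionSet()
    kept: list[SnvCall] = []
    binned: list[SnvCall] = []
    provenance: list[dict] = []
    for variant in variants:
        reason = None
        if variant in exclusion:
            reason = "excluded-position"
        elif regions_keep is not None and not locus_in_regions(variant.locus, regions_keep):
            reason = "outside-target-regions"
        if reason:
            binned_variant = replace(
                variant,
                passthrough=dict(variant.passthrough),
                annotations={**variant.annotations, "SIEVE_BIN": reason},
            )
            binned.append(binned_variant)
        else:
            kept.append(variant)
        provenance.append({"identity": variant.identity, "reason": reason})
    return FilterOutcome(kept=kept, binned=binned, provenance=provenance)


def percent_at_least(count: int, total: int, percent_threshold: float) -> bool:
    """Exact-rational test for ``100*count/total >= percent_threshold``."""
    if total <= 0:
        raise ConfigurationError("percentage threshold needs a non-empty denominator")
    return Fraction(100 * count, total) >= Fraction(str(percent_threshold))
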