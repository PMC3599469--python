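"""Test helpers: an independent pileup oracle and tiny fixture builders.

The oracle counts read support by parsing the *textual* SAM form and walking
CIGAR strings itself, sharing no code with the package's htslib-based pileup
path.
"""

from __future__ import annotations

import re

import pysam

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def sam_pileup_counts(
    bam_path: str,
    chrom: str,
    pos: int,
    alt_base: str,
    min_base_quality: int = 0,
    min_mapping_quality: int = 0,
    count_duplicates: bool = False,
    sam_lines: list[str] | None = None,
) -> tuple[int, int, int, int]:
    """Brute-force (depth, alt, alt_long, alt_short) at 1-based ``pos``.

    Mate split follows the default by-length rule: paired reads strictly
    shorter than the longest qualifying read at the locus are short-mate,
    unpaired reads are long-mate. ``sam_lines`` lets callers fetch the SAM
    text once and reuse it across loci.
    """
    if sam_lines is None:
        sam_lines = pysam.view(bam_path).splitlines()
    observations: list[tuple[str, int, bool]] = []  # (base, read_len, paired)
    for line in sam_lines:
        fields = line.split("\t")
        flag, rname = int(fields[1]), fields[2]
        if rname != chrom:
            continue
        if flag & (0x4 | 0x100 | 0x200 | 0x800):
            continue
        if (flag & 0x400) and not count_duplicates:
            continue
        mapq = int(fields[4])
        if mapq < min_mapping_quality:
            continue
        ref_cursor = int(fields[3])  # 1-based
        query_cursor = 0
        seq, qual = fields[9], fields[10]
        base = None
        base_quality = 0
        for length_str, op in _CIGAR_RE.findall(fields[5]):
            length = int(length_str)
            if op in "M=X":
                if ref_cursor <= pos < ref_cursor + length:
                    offset = query_cursor + (pos - ref_cursor)
                    base = seq[offset].upper()
                    base_quality = 0 if qual == "*" else ord(qual[offset]) - 33
                ref_cursor += length
                query_cursor += length
            elif op in "DN":
                if ref_cursor <= pos < ref_cursor + length:
                    base = "GAP"
                ref_cursor += length
            elif op in "IS":
                query_cursor += length
        if base is None or base == "GAP":
            continue
        if base_quality < min_base_quality:
            continue
        observations.append((base, len(seq), bool(flag & 0x1)))

    depth = len(observations)
    max_len = max((ln for _, ln, _ in observations), default=0)
    alt = [(b, ln, paired) for b, ln, paired in observations if b == alt_base]
    n_short = sum(1 for _, ln, paired in alt if paired and ln < max_len)
    return depth, len(alt), len(alt) - n_short, n_short


def build_bam(
    path: str,
    reads: list[dict],
    chrom: str = "chr1",
    ref_len: int = 2000,
) -> str:
    """Write an indexed coordinate-sorted BAM from simple read specs.

    Each spec: ``start`` (0-based) and ``seq`` required; optional ``name``,
    ``cigar`` (default all-match), ``ordinal`` ("first"/"second"/"unpaired"),
    ``mapq`` (60), ``baseq`` (40), ``dup`` (False).
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": ref_len}]}
    specs = sorted(enumerate(reads), key=lambda item: item[1]["start"])
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for i, spec in specs:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = spec.get("name", f"read{i:04d}")
            seg.reference_id = 0
            seg.reference_start = spec["start"]
            seg.mapping_quality = spec.get("mapq", 60)
            seq = spec["seq"]
            seg.query_sequence = seq
            baseq = spec.get("baseq", 40)
            seg.query_qualities = pysam.qualitystring_to_array(
                chr(baseq + 33) * len(seq)
            )
            seg.cigarstring = spec.get("cigar", f"{len(seq)}M")
            ordinal = spec.get("ordinal", "unpaired")
            flag = 0
            if ordinal != "unpaired":
                flag |= 0x1 | 0x2 | (0x40 if ordinal == "first" else 0x80)
                seg.next_reference_id = 0
                seg.next_reference_start = spec["start"]
            if spec.get("dup"):
                flag |= 0x400
            seg.flag = flag
            out.write(seg)
    pysam.index(path)
    return path


def write_vcf(path: str, rows: list[tuple], extra_header: tuple = ()) -> str:
    """Write a plain-text VCF from (chrom,pos,id,ref,alt,qual,filter,info)."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for line in extra_header:
            out.write(line + "\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in rows:
            out.write("\t".join(str(x) for x in row) + "\n")
    return path


def homopolymer_reads(n: int, start: int, length: int = 30, base: str = "A",
                      alt_at: dict | None = None, **kwargs) -> list[dict]:
    """n identical reads at ``start``; ``alt_at`` maps read index -> (offset, base)."""
    reads = []
    for i in range(n):
        seq = list(base * length)
        if alt_at and i in alt_at:
            offset, alt = alt_at[i]
            seq[offset] = alt
        reads.append({"start": start, "seq": "".join(seq), **kwargs})
    return reads
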