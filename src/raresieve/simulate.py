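"""Seeded synthetic cohorts: reference + BAMs + candidate VCFs + truth.

The generator emulates the signal classes a rare-variant shortlisting
pipeline must separate:

* ``true_rare`` — heterozygous variants private to a single carrier at
  ~50% allele fraction;
* ``shared_family`` — heterozygous variants carried by both members of a
  cousin pair (each cousin's rare variants are shared with probability
  equal to the kinship coefficient, 0.125 by default);
* ``common`` — heterozygous variants planted in more than 30% of samples
  (indistinguishable from recurrent artefacts to a comparator filter, by
  design);
* ``artefact_mapping`` — systematic signals appearing across a range of
  samples at sub-homozygous read fractions (bounded below 0.5: recurrent
  artefact signals are never homozygous-like);
* ``artefact_pe`` — signals confined to the short mate of imbalanced read
  pairs (50/35-base chemistry by default).

Reads are ungapped perfect-match alignments over a random reference so that
pileup semantics, not alignment, are under test; an optional
deletion-bearing read class exercises the pileup GAP rule. All randomness
derives from per-(seed, stream, site, sample) substreams, so adding samples
or sites does not reshuffle earlier ones, and a given seed reproduces the
cohort byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .io import ConfigurationError, GenomicLocus, SnvCall, logger, write_snv_calls

CHROM = "chr1"
_EDGE_MARGIN = 60
_MIN_SITE_COVERAGE = 4
_BASES = np.array(list("ACGT"))

# substream labels
_S_REFERENCE = 0
_S_READS = 1
_S_SITE = 2
_S_PLANT = 3
_S_SHARING = 4
_S_ERRORS = 5


@dataclass
class SitePlan:
    """Site counts and per-class parameter ranges."""

    n_rare_per_cousin: int = 48
    n_true_rare_per_sample: int = 6  # private sites for non-cousin samples
    n_common: int = 10
    n_artefact_mapping: int = 20
    n_artefact_pe: int = 8
    sharing_prob: float = 0.125
    het_alt_fraction: float = 0.5
    common_prevalence: tuple[float, float] = (0.5, 0.9)
    common_alt_fraction: tuple[float, float] = (0.4, 0.6)
    pe_alt_fraction: tuple[float, float] = (0.15, 0.4)


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort."""

    seed: int = 0
    n_samples: int = 10
    n_cousin_pairs: int = 1
    reference_length: int = 8000
    mean_coverage: float = 30.0
    read_length_long: int = 50
    read_length_short: int = 35
    balanced_pairs: bool = False
    base_error_rate: float = 0.0
    fragment_length: int = 160
    deletion_read_fraction: float = 0.0
    deletion_length: int = 3
    site_plan: SitePlan = field(default_factory=SitePlan)
    artefact_prevalence: tuple[float, float] = (0.3, 0.9)
    artefact_alt_fraction: tuple[float, float] = (0.08, 0.4)

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_cousin_pairs < 0:
            raise ConfigurationError("sample/pair counts must be non-negative")
        if 2 * self.n_cousin_pairs > self.n_samples:
            raise ConfigurationError("not enough samples for the cousin pairs")
        if min(self.read_length_long, self.read_length_short) < 20:
            raise ConfigurationError("read lengths must be >= 20 bases")
        if not (0 <= self.base_error_rate <= 1):
            raise ConfigurationError("base_error_rate must be in [0, 1]")
        if self.fragment_length < self.read_length_long + 5:
            raise ConfigurationError("fragment_length too short for the long mate")
        if self.fragment_length >= self.reference_length:
            raise ConfigurationError("fragment_length must fit in the reference")
        for lo, hi in (self.artefact_prevalence, self.artefact_alt_fraction,
                       self.site_plan.common_prevalence,
                       self.site_plan.common_alt_fraction,
                       self.site_plan.pe_alt_fraction):
            if not (0 <= lo <= hi <= 1):
                raise ConfigurationError("parameter ranges must satisfy 0 <= lo <= hi <= 1")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_samples)]

    @property
    def cousin_pairs(self) -> list[tuple[str, str]]:
        return [
            (f"S{2 * i:02d}", f"S{2 * i + 1:02d}")
            for i in range(self.n_cousin_pairs)
        ]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class SimRead:
    """One simulated aligned read (match blocks in reference coordinates)."""

    name: str
    start: int
    query_length: int
    blocks: tuple[tuple[int, int], ...]  # (ref_start, length) match blocks
    is_short: bool
    is_read2: bool
    reverse: bool
    mate_start: int
    tlen: int
    muts: dict = field(default_factory=dict)  # ref_pos -> alt base

    def covers(self, pos0: int) -> bool:
        """True iff an aligned (non-deleted) base covers 0-based ``pos0``."""
        return any(s <= pos0 < s + ln for s, ln in self.blocks)

    @property
    def end(self) -> int:
        s, ln = self.blocks[-1]
        return s + ln

    def cigar(self) -> list[tuple[int, int]]:
        ops: list[tuple[int, int]] = []
        prev_end = None
        for s, ln in self.blocks:
            if prev_end is not None and s > prev_end:
                ops.append((2, s - prev_end))  # D
            ops.append((0, ln))  # M
            prev_end = s + ln
        return ops

    def sequence(self, reference: str) -> str:
        parts = []
        for s, ln in self.blocks:
            seg = list(reference[s:s + ln])
            for pos, base in self.muts.items():
                if s <= pos < s + ln:
                    seg[pos - s] = base
            parts.append("".join(seg))
        return "".join(parts)


@dataclass
class CohortTruth:
    """Ground truth: one row per (site, carrier), plus carrier-free sites.

    Columns: site_index, site_class, chrom, pos (1-based), ref, alt,
    sample_id, n_alt_reads, depth, alt_fraction, mate_restricted.
    """

    table: pd.DataFrame

    def sites(self, site_class: str | None = None) -> pd.DataFrame:
        """Site-level view (one row per site), optionally one class only."""
        df = self.table
        if site_class is not None:
            df = df[df.site_class == site_class]
        return df.drop_duplicates("site_index")[
            ["site_index", "site_class", "chrom", "pos", "ref", "alt"]
        ]

    def carriers(self, site_index: int) -> pd.DataFrame:
        df = self.table
        rows = df[(df.site_index == site_index) & (df.sample_id != ".")]
        return rows

    def carrier_ids(self, site_index: int) -> list[str]:
        return self.carriers(site_index).sample_id.tolist()

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CohortResult:
    """Paths and truth for one simulated cohort."""

    config: SimulationConfig
    reference_path: str
    bam_paths: dict[str, str]
    vcf_paths: dict[str, str]
    truth: CohortTruth
    truth_path: str
    n_relocated_sites: int


def plant_read_support(
    reads: Sequence[SimRead],
    pos: int,
    alt_base: str,
    target_fraction: float,
    rng: np.random.Generator,
    mate_restriction: str | None = None,
    min_alt_reads: int = 0,
    ensure_long_mate: bool = False,
    max_fraction: float | None = None,
) -> tuple[int, int, float]:
    """Mutate reads so the alt fraction at 1-based ``pos`` approximates target.

    The achieved count is the nearest realizable one: round(target x depth),
    half away from zero, capped by the eligible pool (all covering reads, or
    only short mates under ``mate_restriction="short_mate"``) and by
    ``max_fraction`` when given (artefact signals stay sub-homozygous).
    ``ensure_long_mate`` guarantees at least one planted read is a long mate
    when one is available (mate-balanced support for genuine variants).
    Returns ``(n_alt, depth, achieved_fraction)``.
    """
    pos0 = pos - 1
    covering = [r for r in reads if r.covers(pos0)]
    depth = len(covering)
    if depth == 0:
        raise ConfigurationError(f"no coverage at position {pos}; cannot plant")
    if mate_restriction == "short_mate":
        eligible = [r for r in covering if r.is_short]
    elif mate_restriction is None:
        eligible = covering
    else:
        raise ValueError(f"unknown mate restriction {mate_restriction!r}")
    n_alt = int(math.floor(target_fraction * depth + 0.5))
    if max_fraction is not None:
        n_alt = min(n_alt, int(math.floor(max_fraction * depth)))
    n_alt = min(n_alt, len(eligible))
    n_alt = max(n_alt, min(min_alt_reads, len(eligible)))
    if n_alt == 0:
        return 0, depth, 0.0
    order = rng.permutation(len(eligible))
    chosen = [eligible[i] for i in order[:n_alt]]
    if ensure_long_mate and all(r.is_short for r in chosen):
        spare_long = [r for r in eligible if not r.is_short]
        if spare_long:
            chosen[0] = spare_long[0]
    for read in chosen:
        read.muts[pos0] = alt_base
    return n_alt, depth, n_alt / depth


def _make_reads(config: SimulationConfig, sample_index: int) -> list[SimRead]:
    rng = _rng(config.seed, _S_READS, sample_index)
    long_len = config.read_length_long
    short_len = config.read_length_long if config.balanced_pairs \
        else config.read_length_short
    frag = config.fragment_length
    n_frags = int(math.ceil(
        config.reference_length * config.mean_coverage / (long_len + short_len)
    ))
    starts = rng.integers(0, config.reference_length - frag + 1, size=n_frags)
    del_mask = (
        rng.random(n_frags) < config.deletion_read_fraction
        if config.deletion_read_fraction > 0
        else np.zeros(n_frags, dtype=bool)
    )
    sid = f"S{sample_index:02d}"
    reads: list[SimRead] = []
    for i in range(n_frags):
        start = int(starts[i])
        name = f"{sid}_frag{i:06d}"
        short_start = start + frag - short_len
        if del_mask[i]:
            half = long_len // 2
            dlen = config.deletion_length
            blocks = ((start, half), (start + half + dlen, long_len - half))
        else:
            blocks = ((start, long_len),)
        reads.append(SimRead(
            name=name, start=start, query_length=long_len, blocks=blocks,
            is_short=False, is_read2=False, reverse=False,
            mate_start=short_start, tlen=frag,
        ))
        reads.append(SimRead(
            name=name, start=short_start, query_length=short_len,
            blocks=((short_start, short_len),),
            is_short=not config.balanced_pairs, is_read2=True, reverse=True,
            mate_start=start, tlen=-frag,
        ))
    return reads


@dataclass
class _PlannedSite:
    site_index: int
    site_class: str
    pos: int  # 1-based
    ref: str
    alt: str
    carriers: list[str]
    mate_restricted: bool
    alt_fraction_targets: dict  # sample_id -> target fraction


def _choose_alt(ref_base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != ref_base]
    return choices[int(rng.integers(0, 3))]


def _plan_sites(
    config: SimulationConfig,
    reference: str,
    reads_by_sample: dict[str, list[SimRead]],
) -> tuple[list[_PlannedSite], int]:
    """Assign classes, carriers, positions and target fractions to sites."""
    plan = config.site_plan
    samples = config.sample_ids
    cousin_members = {s for pair in config.cousin_pairs for s in pair}

    # carrier blueprints in deterministic order: (class, carriers, restricted)
    blueprints: list[tuple[str, list[str], bool]] = []
    for pair_index, (a, b) in enumerate(config.cousin_pairs):
        rng_pair = _rng(config.seed, _S_SHARING, pair_index)
        n_shared = int(rng_pair.binomial(plan.n_rare_per_cousin, plan.sharing_prob))
        blueprints += [("shared_family", [a, b], False)] * n_shared
        n_private = plan.n_rare_per_cousin - n_shared
        blueprints += [("true_rare", [a], False)] * n_private
        blueprints += [("true_rare", [b], False)] * n_private
    for s in samples:
        if s not in cousin_members:
            blueprints += [("true_rare", [s], False)] * plan.n_true_rare_per_sample
    blueprints += [("common", [], False)] * plan.n_common
    blueprints += [("artefact_mapping", [], False)] * plan.n_artefact_mapping
    if config.balanced_pairs and plan.n_artefact_pe:
        # a balanced chemistry has no short mates to confine an artefact to
        logger.info("balanced chemistry: planting %d artefact_pe sites as "
                    "unrestricted mapping artefacts", plan.n_artefact_pe)
        blueprints += [("artefact_mapping", [], False)] * plan.n_artefact_pe
    else:
        blueprints += [("artefact_pe", [], True)] * plan.n_artefact_pe

    usable = config.reference_length - 2 * _EDGE_MARGIN
    if len(blueprints) > usable:
        raise ConfigurationError(
            f"site plan needs {len(blueprints)} positions but only {usable} usable"
        )

    # per-sample coverage index for feasibility checks
    starts = {
        s: np.array([r.start for r in rs]) for s, rs in reads_by_sample.items()
    }
    ends = {
        s: np.array([r.end for r in rs]) for s, rs in reads_by_sample.items()
    }

    def covering(sample: str, pos0: int) -> list[SimRead]:
        rs = reads_by_sample[sample]
        idx = np.nonzero((starts[sample] <= pos0) & (ends[sample] > pos0))[0]
        return [rs[i] for i in idx if rs[i].covers(pos0)]

    used_positions: set[int] = set()
    sites: list[_PlannedSite] = []
    n_relocated = 0

    for site_index, (site_class, fixed_carriers, restricted) in enumerate(blueprints):
        rng_site = _rng(config.seed, _S_SITE, site_index)

        # class parameters drawn from the site's own stream
        if site_class in ("true_rare", "shared_family"):
            carriers = list(fixed_carriers)
            targets = {s: plan.het_alt_fraction for s in carriers}
        elif site_class == "common":
            lo, hi = plan.common_prevalence
            prevalence = float(rng_site.uniform(lo, hi))
            flo, fhi = plan.common_alt_fraction
            carriers, targets = [], {}
            for s_idx, s in enumerate(samples):
                rng_cell = _rng(config.seed, _S_SITE, site_index, s_idx)
                if rng_cell.random() < prevalence:
                    carriers.append(s)
                    targets[s] = float(rng_cell.uniform(flo, fhi))
            # the prevalence range is a contract: clamp the carrier count to
            # [ceil(lo*n), floor(hi*n)], topping up / trimming in sample order
            n_min = math.ceil(lo * len(samples))
            n_max = max(n_min, math.floor(hi * len(samples)))
            for s in samples:
                if len(carriers) >= n_min:
                    break
                if s not in carriers:
                    carriers.append(s)
                    targets[s] = float(rng_site.uniform(flo, fhi))
            while len(carriers) > n_max:
                targets.pop(carriers.pop())
        else:  # artefact_mapping / artefact_pe
            lo, hi = config.artefact_prevalence
            prevalence = float(rng_site.uniform(lo, hi))
            if site_class == "artefact_pe":
                flo, fhi = plan.pe_alt_fraction
            else:
                flo, fhi = config.artefact_alt_fraction
            carriers, targets = [], {}
            for s_idx, s in enumerate(samples):
                rng_cell = _rng(config.seed, _S_SITE, site_index, s_idx)
                if rng_cell.random() < prevalence:
                    carriers.append(s)
                    targets[s] = float(rng_cell.uniform(flo, fhi))
            if not carriers:
                carriers = [samples[-1]]
                targets = {samples[-1]: float(rng_site.uniform(flo, fhi))}

        # find a position where every carrier has workable coverage
        pos = None
        for attempt in range(300):
            cand0 = int(rng_site.integers(_EDGE_MARGIN,
                                          config.reference_length - _EDGE_MARGIN))
            if cand0 in used_positions:
                continue
            feasible = True
            for s in carriers:
                cov = covering(s, cand0)
                if len(cov) < _MIN_SITE_COVERAGE:
                    feasible = False
                    break
                if restricted and not any(r.is_short for r in cov):
                    feasible = False
                    break
                if not restricted and not any(not r.is_short for r in cov):
                    feasible = False
                    break
            if feasible:
                pos = cand0
                if attempt > 0:
                    n_relocated += 1
                break
        if pos is None:
            raise ConfigurationError(
                f"could not place site {site_index} ({site_class}) after 300 tries"
            )
        used_positions.add(pos)
        ref_base = reference[pos]
        sites.append(_PlannedSite(
            site_index=site_index,
            site_class=site_class,
            pos=pos + 1,
            ref=ref_base,
            alt=_choose_alt(ref_base, rng_site),
            carriers=carriers,
            mate_restricted=restricted,
            alt_fraction_targets=targets,
        ))
    if n_relocated:
        logger.info("relocated %d site position(s) for coverage", n_relocated)
    return sites, n_relocated


def _write_reference(path: Path, reference: str) -> None:
    with open(path, "w") as out:
        out.write(f">{CHROM}\n")
        for i in range(0, len(reference), 70):
            out.write(reference[i:i + 70] + "\n")
    pysam.faidx(str(path))


def _write_bam(path: Path, reads: list[SimRead], reference: str,
               ref_len: int) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": CHROM, "LN": ref_len}],
    }
    ordered = sorted(reads, key=lambda r: (r.start, r.is_read2, r.name))
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for read in ordered:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.name
            seg.reference_id = 0
            seg.reference_start = read.start
            seg.mapping_quality = 60
            seg.cigar = read.cigar()
            seq = read.sequence(reference)
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            flag = 0x1 | 0x2  # paired, proper pair
            flag |= 0x80 if read.is_read2 else 0x40
            if read.reverse:
                flag |= 0x10
            else:
                flag |= 0x20  # mate is reverse
            seg.flag = flag
            seg.next_reference_id = 0
            seg.next_reference_start = read.mate_start
            seg.template_length = read.tlen
            out.write(seg)
    pysam.index(str(path))


_CANDIDATE_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Qualifying read depth">',
    '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alt-supporting read count">',
]


def simulate_cohort(config: SimulationConfig, out_dir: str) -> CohortResult:
    """Generate a complete cohort under ``out_dir``.

    Emits ``reference.fa`` (+ .fai), per-sample coordinate-sorted indexed
    BAMs, per-sample candidate VCFs listing every planted site with at least
    one alt-supporting read in that sample (emulating permissive upstream
    calling), and ``truth.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rng_ref = _rng(config.seed, _S_REFERENCE)
    reference = "".join(
        _BASES[rng_ref.integers(0, 4, size=config.reference_length)]
    )

    samples = config.sample_ids
    reads_by_sample = {
        s: _make_reads(config, i) for i, s in enumerate(samples)
    }

    sites, n_relocated = _plan_sites(config, reference, reads_by_sample)

    # plant alt support; record achieved counts
    truth_rows: list[dict] = []
    planted: dict[tuple[int, str], tuple[int, int]] = {}  # (site, sample) -> (alt, depth)
    for site in sites:
        is_artefact = site.site_class.startswith("artefact")
        if site.site_class == "artefact_pe":
            cap = config.site_plan.pe_alt_fraction[1]
        elif site.site_class == "artefact_mapping":
            cap = config.artefact_alt_fraction[1]
        else:
            cap = None
        for s in site.carriers:
            s_idx = samples.index(s)
            rng_plant = _rng(config.seed, _S_PLANT, site.site_index, s_idx)
            n_alt, depth, achieved = plant_read_support(
                reads_by_sample[s],
                site.pos,
                site.alt,
                site.alt_fraction_targets[s],
                rng_plant,
                mate_restriction="short_mate" if site.mate_restricted else None,
                min_alt_reads=1 if is_artefact else 0,
                ensure_long_mate=not is_artefact,
                max_fraction=cap,
            )
            planted[(site.site_index, s)] = (n_alt, depth)
            truth_rows.append({
                "site_index": site.site_index,
                "site_class": site.site_class,
                "chrom": CHROM,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "sample_id": s,
                "n_alt_reads": n_alt,
                "depth": depth,
                "alt_fraction": achieved,
                "mate_restricted": site.mate_restricted,
            })

    # sequencing errors (default rate 0)
    if config.base_error_rate > 0:
        for s_idx, s in enumerate(samples):
            rng_err = _rng(config.seed, _S_ERRORS, s_idx)
            for read in reads_by_sample[s]:
                n_err = rng_err.binomial(read.query_length, config.base_error_rate)
                for _ in range(int(n_err)):
                    block_i = int(rng_err.integers(0, len(read.blocks)))
                    b_start, b_len = read.blocks[block_i]
                    pos0 = b_start + int(rng_err.integers(0, b_len))
                    current = read.muts.get(pos0, reference[pos0])
                    read.muts[pos0] = _choose_alt(current, rng_err)

    reference_path = out / "reference.fa"
    _write_reference(reference_path, reference)

    bam_paths: dict[str, str] = {}
    vcf_paths: dict[str, str] = {}
    for s in samples:
        bam_path = out / f"{s}.bam"
        _write_bam(bam_path, reads_by_sample[s], reference,
                   config.reference_length)
        bam_paths[s] = str(bam_path)

        calls = []
        for site in sorted(sites, key=lambda x: x.pos):
            n_alt, depth = planted.get((site.site_index, s), (0, 0))
            if n_alt >= 1:
                calls.append(SnvCall(
                    locus=GenomicLocus(CHROM, site.pos),
                    ref_base=site.ref,
                    alt_base=site.alt,
                    passthrough={"id": ".", "qual": ".", "filter": ".",
                                 "info": f"DP={depth};AO={n_alt}"},
                ))
        vcf_path = out / f"{s}.candidates.vcf"
        header = _CANDIDATE_HEADER + [
            f"##contig=<ID={CHROM},length={config.reference_length}>"
        ]
        write_snv_calls(calls, str(vcf_path), source_header=header,
                        provenance={"source": "simulate", "sample": s,
                                    "seed": str(config.seed)})
        vcf_paths[s] = str(vcf_path)

    columns = ["site_index", "site_class", "chrom", "pos", "ref", "alt",
               "sample_id", "n_alt_reads", "depth", "alt_fraction",
               "mate_restricted"]
    truth = CohortTruth(pd.DataFrame(truth_rows, columns=columns))
    truth_path = out / "truth.tsv"
    truth.to_tsv(str(truth_path))

    return CohortResult(
        config=config,
        reference_path=str(reference_path),
        bam_paths=bam_paths,
        vcf_paths=vcf_paths,
        truth=truth,
        truth_path=str(truth_path),
        n_relocated_sites=n_relocated,
    )
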