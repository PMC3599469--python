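"""Assessment procedures: kinship O/E ratio and sensitivity projection.

Two complementary checks of a rare-variant shortlist:

* **Specificity** — first cousins share on average 12.5% of their DNA, so
  among *genuine* rare variants the number shared by a cousin pair should
  be close to the kinship coefficient times their mean variant count. An
  observed/expected ratio well above 1 before filtering indicates recurrent
  artefacts masquerading as shared variants; a ratio near 1 after filtering
  indicates the survivors are mostly genuine.

* **Sensitivity** — for a panel of known genuine SNVs, any sample carrying
  the allele at >= 9% read frequency is a "true carrier" and is excluded;
  if the allele is still apparent in any read of >= 30% of the remaining
  files, the comparator filter would have removed it (a projected false
  negative). The retained fraction projects the filter's sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pysam

from .io import (
    ConfigurationError,
    QualityGates,
    SnvCall,
    collect_pileup_evidence,
    logger,
    open_alignment,
    percent_at_least,
)

DEFAULT_KINSHIP = 0.125  # first cousins share 12.5% of their DNA on average


@dataclass(frozen=True)
class OeSummary:
    """Observed vs expected shared variant counts for one relative pair."""

    n_a: int
    n_b: int
    observed_shared: int
    kinship: float
    expected_shared: float
    oe_ratio: float


def shared_snvs(
    variants_a: Sequence[SnvCall], variants_b: Sequence[SnvCall]
) -> set[tuple[str, int, str, str]]:
    """Variant identities present in both lists.

    Identity is exact (chrom, pos, ref, alt) equality — the same locus with
    different alt alleles is not shared.
    """
    return {v.identity for v in variants_a} & {v.identity for v in variants_b}


def observed_expected(
    n_a: int,
    n_b: int,
    observed_shared: int,
    kinship: float = DEFAULT_KINSHIP,
    aggregate: str = "mean",
) -> OeSummary:
    """O/E summary with expected = kinship x aggregate(n_a, n_b).

    The aggregation of the two counts defaults to their mean; "min"/"max"
    are available for sensitivity analyses.
    """
    if n_a < 0 or n_b < 0 or observed_shared < 0:
        raise ValueError("variant counts must be non-negative")
    if not (0 < kinship <= 1):
        raise ValueError("kinship must be in (0, 1]")
    agg = {
        "mean": (n_a + n_b) / 2,
        "min": min(n_a, n_b),
        "max": max(n_a, n_b),
    }.get(aggregate)
    if agg is None:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    expected = kinship * agg
    if expected == 0:
        raise ConfigurationError("expected shared count is zero; O/E undefined")
    return OeSummary(
        n_a=n_a,
        n_b=n_b,
        observed_shared=observed_shared,
        kinship=kinship,
        expected_shared=expected,
        oe_ratio=observed_shared / expected,
    )


def oe_for_pair(
    variants_a: Sequence[SnvCall],
    variants_b: Sequence[SnvCall],
    kinship: float = DEFAULT_KINSHIP,
    aggregate: str = "mean",
) -> OeSummary:
    """Convenience wrapper: counts + intersection + O/E in one call."""
    return observed_expected(
        len(variants_a),
        len(variants_b),
        len(shared_snvs(variants_a, variants_b)),
        kinship=kinship,
        aggregate=aggregate,
    )


@dataclass
class SnvAssessment:
    """Per-SNV result of the sensitivity projection."""

    identity: tuple[str, int, str, str]
    carrier_ids: list[str]
    n_remaining: int
    n_remaining_with_evidence: int
    evidence_fraction: float
    projected_false_negative: bool


@dataclass
class SensitivityReport:
    """Aggregate sensitivity projection over a known-variant panel."""

    assessments: list[SnvAssessment] = field(default_factory=list)
    skipped: list[tuple[str, int, str, str]] = field(default_factory=list)

    @property
    def n_assessed(self) -> int:
        return len(self.assessments)

    @property
    def n_projected_false_negative(self) -> int:
        return sum(1 for a in self.assessments if a.projected_false_negative)

    @property
    def retained_fraction(self) -> float:
        if not self.n_assessed:
            raise ConfigurationError("no SNVs could be assessed")
        return 1.0 - self.n_projected_false_negative / self.n_assessed


def sensitivity_projection(
    known_snvs: Sequence[SnvCall],
    alignment_panel: Sequence[tuple[str, str]],
    carrier_freq: float = 9.0,
    artefact_fraction: float = 30.0,
    gates: QualityGates = QualityGates(),
    zero_depth_in_denominator: bool = True,
) -> SensitivityReport:
    """Project the comparator filter's false-negative rate on known SNVs.

    Per SNV: files whose alt read frequency is >= ``carrier_freq`` percent
    (among qualifying depth > 0) are true carriers and are excluded; among
    the remaining files, if the fraction showing the allele in any read is
    >= ``artefact_fraction`` percent the SNV is a projected false negative.
    Files with zero depth cannot be carriers; by default they stay in the
    remaining-file denominator (``zero_depth_in_denominator=False`` restricts
    the denominator to covered files). An SNV uncovered in every file is
    skipped with a warning.
    """
    if len(alignment_panel) < 2:
        raise ConfigurationError("sensitivity projection needs a panel of >= 2 files")
    handles = [(sid, open_alignment(path)) for sid, path in alignment_panel]
    try:
        report = SensitivityReport()
        for snv in known_snvs:
            evidences = [
                collect_pileup_evidence(bam, snv.locus, snv.alt_base, gates, sample_id=sid)
                for sid, bam in handles
            ]
            if all(ev.depth == 0 for ev in evidences):
                logger.warning("known SNV %s uncovered in every file; skipped", snv.identity)
                report.skipped.append(snv.identity)
                continue
            carriers = [
                ev.sample_id
                for ev in evidences
                if ev.depth > 0
                and percent_at_least(100 * ev.alt_count, 100 * ev.depth, carrier_freq)
            ]
            remaining = [
                ev for ev in evidences
                if ev.sample_id not in carriers
                and (zero_depth_in_denominator or ev.depth > 0)
            ]
            if not remaining:
                logger.warning(
                    "known SNV %s: every file is a carrier; skipped", snv.identity
                )
                report.skipped.append(snv.identity)
                continue
            with_evidence = sum(1 for ev in remaining if ev.alt_count >= 1)
            fraction = with_evidence / len(remaining)
            projected_fn = percent_at_least(
                with_evidence, len(remaining), artefact_fraction
            )
            report.assessments.append(
                SnvAssessment(
                    identity=snv.identity,
                    carrier_ids=carriers,
                    n_remaining=len(remaining),
                    n_remaining_with_evidence=with_evidence,
                    evidence_fraction=fraction,
                    projected_false_negative=projected_fn,
                )
            )
        return report
    finally:
        for _, bam in handles:
            bam.close()
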