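"""Rare-and-true filter: discard variants whose signature recurs in too many
unrelated comparator alignment files.

A comparator sample is *variant-like* at a candidate locus when the number of
its reads carrying the alt base reaches the read threshold ``t_reads``. A
candidate is discarded when the percentage of variant-like comparators
reaches ``p_samples``; under a rare-variant model this removes both common
variants and recurrent mapping artefacts without distinguishing them.
Study settings used throughout the tests: ``t_reads=1``, ``p_samples=30``
with a panel of 8 comparators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .io import (
    ConfigurationError,
    FilterOutcome,
    PileupEvidence,
    QualityGates,
    SnvCall,
    collect_pileup_evidence,
    logger,
    open_alignment,
    percent_at_least,
)


@dataclass
class FilterConfig:
    """Parameters of the rare-and-true filter.

    ``comparator_panel`` is an ordered list of ``(sample_id, bam_path)``
    pairs; it must exclude the test sample and its relatives (the caller's
    duty — the tool verifies sample-id uniqueness and warns if the test
    sample id appears).
    """

    read_threshold: int = 1
    percent_threshold: float = 30.0
    comparator_panel: Sequence[tuple[str, str]] = ()
    quality_gates: QualityGates = field(default_factory=QualityGates)
    test_sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.read_threshold < 1:
            raise ConfigurationError("read_threshold must be >= 1")
        if not (0 < self.percent_threshold <= 100):
            raise ConfigurationError("percent_threshold must be in (0, 100]")
        if not self.comparator_panel:
            raise ConfigurationError("comparator panel must not be empty")
        ids = [sid for sid, _ in self.comparator_panel]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("comparator sample ids must be unique")
        if self.test_sample_id is not None and self.test_sample_id in ids:
            logger.warning(
                "test sample id %r appears in the comparator panel", self.test_sample_id
            )


def is_variant_like(evidence: PileupEvidence, t_reads: int) -> bool:
    """True iff the sample has >= ``t_reads`` alt-supporting reads."""
    if t_reads < 1:
        raise ConfigurationError("t_reads must be >= 1")
    return evidence.alt_count >= t_reads


def comparator_percent(
    panel_evidences: Sequence[PileupEvidence], t_reads: int
) -> float:
    """Percent of the full panel that is variant-like.

    The denominator is the panel size regardless of coverage: an uncovered
    comparator contributes depth 0 and cannot be variant-like, but still
    counts as an examined file.
    """
    if not panel_evidences:
        raise ConfigurationError("comparator panel must not be empty")
    n_like = sum(1 for ev in panel_evidences if is_variant_like(ev, t_reads))
    return 100.0 * n_like / len(panel_evidences)


def apply_rare_and_true(
    variants: Sequence[SnvCall], config: FilterConfig
) -> FilterOutcome:
    """Partition ``variants`` by the comparator-signature rule.

    A variant is binned iff the variant-like percentage is >= the percent
    threshold (kept only strictly *below* it); the comparison is done in
    exact rational arithmetic so threshold boundaries are unambiguous.
    """
    panel = [(sid, open_alignment(path)) for sid, path in config.comparator_panel]
    try:
        kept: list[SnvCall] = []
        binned: list[SnvCall] = []
        provenance: list[dict] = []
        for variant in variants:
            evidences = [
                collect_pileup_evidence(
                    bam,
                    variant.locus,
                    variant.alt_base,
                    config.quality_gates,
                    sample_id=sid,
                )
                for sid, bam in panel
            ]
            flags = [is_variant_like(ev, config.read_threshold) for ev in evidences]
            n_like = sum(flags)
            percent = 100.0 * n_like / len(panel)
            discard = percent_at_least(n_like, len(panel), config.percent_threshold)
            counts = ",".join(
                f"{ev.sample_id}:{ev.alt_count}/{ev.depth}" for ev in evidences
            )
            annotations = {
                **variant.annotations,
                "SIEVE_CMP": counts,
                "SIEVE_CMP_PCT": f"{percent:.2f}",
            }
            if discard:
                annotations["SIEVE_BIN"] = "comparator-signature"
            out = replace(
                variant,
                passthrough=dict(variant.passthrough),
                annotations=annotations,
            )
            (binned if discard else kept).append(out)
            provenance.append(
                {
                    "identity": variant.identity,
                    "comparators": [
                        (ev.sample_id, ev.alt_count, ev.depth, flag)
                        for ev, flag in zip(evidences, flags)
                    ],
                    "percent_variant_like": percent,
                    "reason": "comparator-signature" if discard else None,
                }
            )
        return FilterOutcome(kept=kept, binned=binned, provenance=provenance)
    finally:
        for _, bam in panel:
            bam.close()
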