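"""Paired-end bias filter for imbalanced chemistries.

Imbalanced paired-end sequencing (e.g. SOLiD4's 50-base + 35-base mates)
produces artefactual calls supported only by the shorter mate. This filter
re-examines the test sample's own alignments and bins any candidate whose
alt support comes exclusively from short-mate reads. It is a no-op on
balanced chemistries (no read classifies as short) and is not needed there.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .io import (
    FilterOutcome,
    MateClassConfig,
    QualityGates,
    SnvCall,
    collect_pileup_evidence,
    mate_class,
    open_alignment,
)

__all__ = ["MateClassConfig", "mate_class", "apply_pe_bias_filter"]


def apply_pe_bias_filter(
    variants: Sequence[SnvCall],
    test_bam_path: str,
    mate_config: MateClassConfig = MateClassConfig(),
    gates: QualityGates = QualityGates(),
) -> FilterOutcome:
    """Bin variants evident only in short-mate reads of the test sample.

    A variant is binned iff it has >= 1 alt-supporting read and zero
    long-mate alt support. Variants with no alt support at all in the test
    BAM are kept and flagged ``no-support-observed`` for audit: they are not
    "evident only in short reads".
    """
    bam = open_alignment(test_bam_path)
    try:
        kept: list[SnvCall] = []
        binned: list[SnvCall] = []
        provenance: list[dict] = []
        for variant in variants:
            ev = collect_pileup_evidence(
                bam, variant.locus, variant.alt_base, gates, mate_config
            )
            short_only = ev.alt_count >= 1 and ev.alt_count_long_mate == 0
            annotations = {
                **variant.annotations,
                "SIEVE_PE": f"{ev.alt_count_long_mate}/{ev.alt_count_short_mate}",
            }
            flag = None
            if short_only:
                annotations["SIEVE_BIN"] = "short-mate-only"
            elif ev.alt_count == 0:
                flag = "no-support-observed"
                annotations["SIEVE_FLAG"] = flag
            out = replace(
                variant,
                passthrough=dict(variant.passthrough),
                annotations=annotations,
            )
            (binned if short_only else kept).append(out)
            provenance.append(
                {
                    "identity": variant.identity,
                    "alt_count": ev.alt_count,
                    "alt_count_long_mate": ev.alt_count_long_mate,
                    "alt_count_short_mate": ev.alt_count_short_mate,
                    "reason": "short-mate-only" if short_only else None,
                    "flag": flag,
                }
            )
        return FilterOutcome(kept=kept, binned=binned, provenance=provenance)
    finally:
        bam.close()
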