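"""Family annotation: attach read-level evidence from relatives' alignments.

Unlike joint calling on VCFs, this looks directly at relatives' BAM files,
so a variant shared within a family is flagged even when it fell below the
caller's thresholds in the relative — avoiding false negatives from rigid
threshold settings. Annotation never removes or adds variants.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .io import (
    QualityGates,
    SnvCall,
    collect_pileup_evidence,
    open_alignment,
)


def annotate_family(
    variants: Sequence[SnvCall],
    relative_panel: Sequence[tuple[str, str]],
    t_reads: int = 1,
    gates: QualityGates = QualityGates(),
) -> list[SnvCall]:
    """Annotate each variant with per-relative alt/depth counts.

    ``relative_panel`` is a list of ``(sample_id, bam_path)`` pairs.
    Relatives are reported in lexicographic sample-id order. The default
    evidence threshold of one read implements "any reads" semantics.
    Re-annotating with the same panel overwrites the annotation keys.
    """
    panel = sorted(relative_panel, key=lambda item: item[0])
    handles = [(sid, open_alignment(path)) for sid, path in panel]
    try:
        annotated: list[SnvCall] = []
        for variant in variants:
            entries = []
            n_with_evidence = 0
            for sid, bam in handles:
                ev = collect_pileup_evidence(
                    bam, variant.locus, variant.alt_base, gates, sample_id=sid
                )
                shared = ev.alt_count >= t_reads
                n_with_evidence += int(shared)
                entries.append(f"{sid}:{ev.alt_count}/{ev.depth}")
            annotated.append(
                replace(
                    variant,
                    passthrough=dict(variant.passthrough),
                    annotations={
                        **variant.annotations,
                        "SIEVE_FAM": ",".join(entries),
                        "SIEVE_FAM_N": str(n_with_evidence),
                    },
                )
            )
        return annotated
    finally:
        for _, bam in handles:
            bam.close()
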