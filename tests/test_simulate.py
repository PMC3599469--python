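"""Synthetic cohort generator: determinism, truth consistency, planting."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pytest

from raresieve import (
    ConfigurationError,
    GenomicLocus,
    SimulationConfig,
    SitePlan,
    collect_pileup_evidence,
    open_alignment,
    plant_read_support,
    read_snv_calls,
    shared_snvs,
    simulate_cohort,
)
from raresieve.simulate import SimRead

SMALL = dict(
    n_samples=6,
    n_cousin_pairs=1,
    reference_length=3000,
    mean_coverage=15.0,
    site_plan=SitePlan(n_rare_per_cousin=12, n_true_rare_per_sample=2,
                       n_common=4, n_artefact_mapping=6, n_artefact_pe=4),
)


def _checksums(directory):
    out = {}
    for path in sorted(Path(directory).iterdir()):
        out[path.name] = hashlib.md5(path.read_bytes()).hexdigest()
    return out


def test_same_seed_reproduces_cohort_byte_for_byte(tmp_path):
    a = simulate_cohort(SimulationConfig(seed=7, **SMALL), str(tmp_path / "a"))
    simulate_cohort(SimulationConfig(seed=7, **SMALL), str(tmp_path / "b"))
    assert _checksums(tmp_path / "a") == _checksums(tmp_path / "b")
    # and a different seed differs
    simulate_cohort(SimulationConfig(seed=8, **SMALL), str(tmp_path / "c"))
    assert _checksums(tmp_path / "a") != _checksums(tmp_path / "c")
    assert a.truth.sites().site_class.notna().all()


def test_truth_matches_pileup_exactly_at_zero_error(cohort):
    handles = {s: open_alignment(p) for s, p in cohort.bam_paths.items()}
    try:
        for row in cohort.truth.table.itertuples():
            ev = collect_pileup_evidence(
                handles[row.sample_id],
                GenomicLocus(row.chrom, int(row.pos)),
                row.alt,
            )
            assert (ev.alt_count, ev.depth) == (row.n_alt_reads, row.depth), \
                f"site {row.site_index} sample {row.sample_id}"
            if row.mate_restricted:
                assert ev.alt_count_long_mate == 0
    finally:
        for handle in handles.values():
            handle.close()


def test_candidate_vcfs_list_every_site_with_alt_support(cohort):
    truth = cohort.truth.table
    for sample, vcf_path in cohort.vcf_paths.items():
        calls, _ = read_snv_calls(vcf_path)
        listed = {v.identity for v in calls}
        planted = {
            (r.chrom, int(r.pos), r.ref, r.alt)
            for r in truth[(truth.sample_id == sample)
                           & (truth.n_alt_reads >= 1)].itertuples()
        }
        assert listed == planted


def test_artefact_fractions_stay_sub_homozygous(cohort):
    truth = cohort.truth.table
    artefacts = truth[truth.site_class.str.startswith("artefact")]
    assert not artefacts.empty
    assert (artefacts.alt_fraction <= 0.4 + 1e-12).all()
    assert (artefacts.alt_fraction < 0.5).all()
    carriers = artefacts[artefacts.n_alt_reads >= 1]
    assert len(carriers) == len(artefacts)  # every artefact carrier shows >=1 read


def test_true_rare_sites_have_one_carrier_at_het_fraction(cohort):
    truth = cohort.truth.table
    rare = truth[truth.site_class == "true_rare"]
    assert rare.groupby("site_index").size().eq(1).all()
    assert ((rare.alt_fraction - 0.5).abs() <= 0.51 / rare.depth.min() + 0.05).all()
    shared = truth[truth.site_class == "shared_family"]
    assert shared.groupby("site_index").size().eq(2).all()


# --- plant_read_support ----------------------------------------------------

def _sim_reads(n_long, n_short, start=0):
    reads = []
    for i in range(n_long):
        reads.append(SimRead(name=f"L{i}", start=start, query_length=50,
                             blocks=((start, 50),), is_short=False,
                             is_read2=False, reverse=False, mate_start=start,
                             tlen=100))
    for i in range(n_short):
        reads.append(SimRead(name=f"S{i}", start=start, query_length=35,
                             blocks=((start, 35),), is_short=True,
                             is_read2=True, reverse=True, mate_start=start,
                             tlen=-100))
    return reads


def test_planting_rounds_target_times_depth():
    reads = _sim_reads(15, 15)
    n_alt, depth, achieved = plant_read_support(
        reads, pos=10, alt_base="C", target_fraction=0.5,
        rng=np.random.default_rng(0))
    assert (n_alt, depth) == (15, 30)
    assert achieved == pytest.approx(0.5)
    assert sum(1 for r in reads if r.muts.get(9) == "C") == 15


def test_mate_restriction_caps_at_available_short_mates():
    reads = _sim_reads(6, 4)
    n_alt, depth, achieved = plant_read_support(
        reads, pos=10, alt_base="C", target_fraction=0.5,
        rng=np.random.default_rng(0), mate_restriction="short_mate")
    assert (n_alt, depth) == (4, 10)
    assert achieved == pytest.approx(0.4)
    assert all(r.is_short for r in reads if r.muts)


def test_zero_target_leaves_reads_unchanged():
    reads = _sim_reads(5, 5)
    n_alt, _, achieved = plant_read_support(
        reads, pos=10, alt_base="C", target_fraction=0.0,
        rng=np.random.default_rng(0))
    assert n_alt == 0 and achieved == 0.0
    assert all(not r.muts for r in reads)


def test_planting_without_coverage_is_an_error():
    with pytest.raises(ConfigurationError):
        plant_read_support(_sim_reads(2, 0), pos=500, alt_base="C",
                           target_fraction=0.5, rng=np.random.default_rng(0))


# --- cohort-level statistical structure ------------------------------------

def test_cousin_sharing_follows_binomial_kinship(tmp_path):
    n = 400
    config = SimulationConfig(
        seed=13, n_samples=2, n_cousin_pairs=1, reference_length=20000,
        mean_coverage=15.0,
        site_plan=SitePlan(n_rare_per_cousin=n, n_true_rare_per_sample=0,
                           n_common=0, n_artefact_mapping=0, n_artefact_pe=0),
    )
    result = simulate_cohort(config, str(tmp_path))
    calls_a, _ = read_snv_calls(result.vcf_paths["S00"])
    calls_b, _ = read_snv_calls(result.vcf_paths["S01"])
    assert len(calls_a) == n and len(calls_b) == n
    observed = len(shared_snvs(calls_a, calls_b))
    mean = n * 0.125
    sd = math.sqrt(n * 0.125 * 0.875)
    assert abs(observed - mean) <= 3 * sd
    truth_shared = result.truth.sites("shared_family")
    assert observed == len(truth_shared)


def test_infeasible_site_plan_is_rejected(tmp_path):
    config = SimulationConfig(
        seed=1, n_samples=2, n_cousin_pairs=0, reference_length=200,
        fragment_length=120,
        site_plan=SitePlan(n_rare_per_cousin=0, n_true_rare_per_sample=200,
                           n_common=0, n_artefact_mapping=0, n_artefact_pe=0),
    )
    with pytest.raises(ConfigurationError):
        simulate_cohort(config, str(tmp_path))


def test_balanced_cohort_has_no_short_mate_class(balanced_cohort):
    truth = balanced_cohort.truth.table
    assert (truth.site_class != "artefact_pe").all()
    bam = open_alignment(balanced_cohort.bam_paths["S00"])
    lengths = {read.query_length for read in bam.fetch()}
    bam.close()
    assert lengths == {balanced_cohort.config.read_length_long}
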