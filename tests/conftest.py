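"""Shared fixtures: tiny references, panels and cohorts generated at test
time (no stored data files)."""

from __future__ import annotations

import pytest

from mipmosaic.synthetic_data import (
    CohortConfig,
    random_reference,
    tile_panel,
)
from mipmosaic.types import AlleleEvidence, Interval, MipRead, SiteEvidence


@pytest.fixture(scope="session")
def small_reference():
    return random_reference({"chr1": 400, "chr2": 400}, seed=101)


@pytest.fixture(scope="session")
def small_panel(small_reference):
    return tile_panel(small_reference)


@pytest.fixture
def micro_cohort_config():
    """Small cohort that still exercises every stage."""
    return CohortConfig(
        n_als=2,
        n_ftd=1,
        n_control=1,
        regions=("PFC", "PMC"),
        contig_length=240,
        mean_unique_depth=150.0,
        target_len=80,
        arm_len=16,
        step=50,
        germline_per_individual=1.0,
        somatic_per_individual=1.0,
        somatic_vaf_tiers=(0.05, 0.10),
    )


def make_read(
    contig="chr1",
    start=1,
    bases="ACGT",
    quals=None,
    umi="AAAAACCCCC",
    probe_id="p1",
    arm_spans=(),
):
    quals = quals if quals is not None else tuple([37] * len(bases))
    return MipRead(
        contig=contig,
        start=start,
        end=start + len(bases) - 1,
        probe_id=probe_id,
        umi=umi,
        bases=bases,
        quals=tuple(quals),
        arm_spans=tuple(arm_spans),
    )


def make_evidence(
    contig="chr1",
    pos=50,
    ref="A",
    alt="T",
    depth=1000,
    alt_total=20,
    alt_offarm=None,
    mean_qual=37.0,
    n_probes=2,
):
    """Directly assemble SiteEvidence for filter tests."""
    alt_offarm = alt_total if alt_offarm is None else alt_offarm
    probes = {f"p{i}" for i in range(n_probes)}
    ev = SiteEvidence(contig=contig, pos=pos, ref=ref, total_depth=depth)
    ev.alleles[alt] = AlleleEvidence(
        count_total=alt_total,
        count_offarm=alt_offarm,
        qual_sum=mean_qual * alt_total,
        probe_ids=set(probes),
        probe_ids_all=set(probes),
    )
    ev.alleles[ref] = AlleleEvidence(count_total=depth - alt_total, count_offarm=depth - alt_total)
    ev.covering_probe_ids = set(probes) | {"pref"}
    return ev


@pytest.fixture
def evidence_factory():
    return make_evidence


@pytest.fixture
def read_factory():
    return make_read


@pytest.fixture
def arm_interval():
    return Interval
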