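"""Shared synthetic fixtures: a small genome, methylomes, and libraries."""

import numpy as np
import pytest
from hypothesis import settings

import recapseq as r

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def small_world():
    """A 300 kb single-contig genome with islands, catalog, and methylomes."""
    spec = r.GenomeSpec(n_contigs=1, contig_length=300_000, n_islands=20, seed=11)
    genome, islands, cpg = r.generate_genome(spec)
    catalog = r.build_catalog(genome, r.Motif("CGCG"))
    beta_n, markers = r.assign_methylation(cpg, islands, r.MethylomeSpec("normal"), seed=11)
    beta_t, _ = r.assign_methylation(cpg, islands, r.MethylomeSpec("tumor"), seed=11)
    return {
        "spec": spec,
        "genome": genome,
        "islands": islands,
        "cpg": cpg,
        "catalog": catalog,
        "beta_normal": beta_n,
        "beta_tumor": beta_t,
        "marker_islands": markers,
    }


@pytest.fixture(scope="session")
def small_library(small_world):
    """An EM-molecule pool and its digested library (default efficiencies)."""
    params = r.LibraryParams(depth=8000, seed=5)
    molecules = r.simulate_em_molecules(
        small_world["genome"], small_world["beta_normal"], params, 8000, seed=5
    )
    library = r.digest_molecules(molecules, params, small_world["catalog"], seed=6)
    return {"params": params, "molecules": molecules, "library": library}


@pytest.fixture(scope="session")
def small_cohort(small_world):
    """A shallow spike-in cohort counted through the standard filters."""
    design = r.SpikeInDesign(fractions=(0.0, 1.0), replicates=3, seed=13)
    params = r.LibraryParams(depth=10_000, seed=13)
    samples, truth = r.simulate_spikein_cohort(
        small_world["genome"],
        small_world["beta_normal"],
        small_world["beta_tumor"],
        design,
        params,
        small_world["catalog"],
    )
    matrix, accounting = r.process_cohort(samples, small_world["catalog"])
    return {
        "design": design,
        "params": params,
        "samples": samples,
        "truth": truth,
        "matrix": matrix,
        "accounting": accounting,
    }


def make_read(
    contig="chr1",
    start=0,
    end=None,
    seq="CGAACG",
    calls="MM",
    positions=(0, 4),
    sample_id="s1",
    nonconverted_ch=0,
    has_both_cuts=True,
    origin_class="normal",
):
    """Hand-built read for filter/counting unit tests."""
    if end is None:
        end = start + len(seq)
    return r.MethylRead(
        sample_id=sample_id,
        contig=contig,
        start=start,
        end=end,
        converted_seq=seq,
        cpg_calls=calls,
        origin_class=origin_class,
        origin_fragment_id=None,
        nonconverted_ch=nonconverted_ch,
        has_both_cuts=has_both_cuts,
        cpg_positions=np.array(positions, dtype=np.int64),
    )
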