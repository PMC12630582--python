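"""Protocol filters, fragment counting, QC, and AMF statistics."""

import re
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import recapseq as r
from recapseq.read_processing import (
    REASON_INTERNAL_MOTIF,
    REASON_MOTIF_INTEGRITY,
    REASON_NONCONVERSION,
    REASON_RETAINED,
    REASON_UNASSIGNED,
)

from conftest import make_read


@pytest.fixture(scope="module")
def toy_catalog():
    """Single fragment on a handcrafted genome: motifs at [10,14) and [70,74)."""
    seq = list("A" * 200)
    seq[10:14] = "CGCG"
    seq[70:74] = "CGCG"
    genome = r.GenomeSequence({"chr1": "".join(seq)})
    return r.build_catalog(genome, r.Motif("CGCG"))


@pytest.fixture(scope="module")
def toy_index(toy_catalog):
    return r.build_cut_site_index(toy_catalog)


def matched_read(**kw):
    """A read exactly matching the toy fragment's cut sites [12, 72)."""
    seq = "CG" + "A" * 56 + "CG"
    defaults = dict(contig="chr1", start=12, end=72, seq=seq, calls="MM",
                    positions=(12, 70))
    defaults.update(kw)
    return make_read(**defaults)


class TestFilters:
    def test_nonconversion_thresholds(self):
        assert r.filter_nonconversion(make_read(nonconverted_ch=0))
        assert not r.filter_nonconversion(make_read(nonconverted_ch=1))
        assert r.filter_nonconversion(make_read(nonconverted_ch=2), max_failures=2)

    def test_motif_integrity(self, toy_index):
        assert r.filter_motif_integrity(matched_read(), toy_index)
        # left terminal converted (unmethylated) -> mismatch in the site
        bad = matched_read(seq="TG" + "A" * 56 + "CG", calls="uM")
        assert not r.filter_motif_integrity(bad, toy_index)
        # coordinates matching no catalog fragment
        assert not r.filter_motif_integrity(matched_read(start=13, end=73), toy_index)

    def test_internal_motif(self, toy_index):
        internal = matched_read(seq="CG" + "A" * 20 + "CGCG" + "A" * 32 + "CG")
        assert not r.filter_internal_motif(internal)
        converted = matched_read(seq="CG" + "A" * 20 + "TGTG" + "A" * 32 + "CG")
        assert r.filter_internal_motif(converted)

    def test_internal_motif_agrees_with_regex_oracle(self, small_world, small_cohort):
        reads = small_cohort["samples"]["f0_r1"][:1000]
        for read in reads:
            assert r.filter_internal_motif(read) == (
                re.search("CGCG", read.converted_seq) is None
            )

    def test_motif_integrity_truth_oracle(self, small_world):
        """With perfect conversion chemistry, assigned complete-digest reads
        are kept exactly when their terminal CpG calls are methylated."""
        params = r.LibraryParams(
            conversion_rate=1.0, overconversion_rate=0.0,
            cut_efficiency=1.0, chimera_leak=0.0, depth=3000,
        )
        mols = r.simulate_em_molecules(
            small_world["genome"], small_world["beta_normal"], params, 3000, seed=31
        )
        lib = r.digest_molecules(mols, params, small_world["catalog"], seed=32)
        index = r.build_cut_site_index(small_world["catalog"])
        assigned = [x for x in lib if (x.contig, x.start, x.end) in index]
        assert assigned
        for read in assigned:
            keep = r.filter_motif_integrity(read, index)
            # terminal inner CpGs are the first and last call sites
            assert read.cpg_calls[0] == "M" and read.cpg_calls[-1] == "M"
            assert keep  # a cut can only have happened at a methylated site

    def test_filters_commute(self, small_cohort, small_world):
        reads = small_cohort["samples"]["f1_r1"][:2000]
        index = r.build_cut_site_index(small_world["catalog"])
        filters = {
            "conv": lambda x: r.filter_nonconversion(x, 0),
            "motif": lambda x: r.filter_motif_integrity(x, index),
            "internal": r.filter_internal_motif,
        }
        baseline = None
        for order in permutations(filters):
            kept = reads
            for name in order:
                kept = [x for x in kept if filters[name](x)]
            ids = [(x.contig, x.start, x.end, x.converted_seq) for x in kept]
            if baseline is None:
                baseline = ids
            assert ids == baseline

    def test_accounting_identity(self, small_cohort):
        acct = small_cohort["accounting"]
        reasons = [REASON_RETAINED, REASON_NONCONVERSION, REASON_UNASSIGNED,
                   REASON_MOTIF_INTEGRITY, REASON_INTERNAL_MOTIF]
        assert (acct["input_reads"] == acct[reasons].sum(axis=1)).all()


class TestCounting:
    def test_counts_and_unassigned(self, toy_catalog):
        fid = toy_catalog[0].id
        reads = [matched_read(sample_id="s1") for _ in range(3)]
        stray = make_read(sample_id="s1", contig="chr1", start=0, end=30,
                          seq="A" * 30, calls="", positions=())
        m = r.count_fragments(reads + [stray], toy_catalog)
        assert m.counts.loc[fid, "s1"] == 3
        assert m.unassigned["s1"] == 1
        assert m.library_sizes["s1"] == 4

    def test_duplicate_sample_ids_error(self, toy_catalog):
        with pytest.raises(ValueError, match="duplicate"):
            r.count_fragments([("s1", []), ("s1", [])], toy_catalog)

    def test_column_sums_match_origin_truth(self, small_world):
        """On a complete-digest library, counted reads are exactly the
        retained reads carrying a catalog origin."""
        params = r.LibraryParams(cut_efficiency=1.0, chimera_leak=0.0, depth=4000)
        mols = r.simulate_em_molecules(
            small_world["genome"], small_world["beta_normal"], params, 4000, seed=41
        )
        lib = r.digest_molecules(mols, params, small_world["catalog"], seed=42)
        index = r.build_cut_site_index(small_world["catalog"])
        kept, _ = r.apply_filters(lib, index)
        m = r.count_fragments({"s": kept}, small_world["catalog"])
        n_origin = sum(x.origin_fragment_id is not None for x in kept)
        assert m.counts["s"].sum() == n_origin
        assert m.unassigned["s"] == len(kept) - n_origin

    def test_qc_min_fragments_boundary(self):
        counts = pd.DataFrame(
            {"fail": [1] * 1999 + [0] * 2, "edge": [1] * 2000 + [0], "empty": [0] * 2001}
        )
        m = r.FragmentCountMatrix(
            counts=counts,
            library_sizes=pd.Series({"fail": 1999, "edge": 2000, "empty": 0}),
            unassigned=pd.Series({"fail": 0, "edge": 0, "empty": 0}),
        )
        qc = r.qc_min_fragments(m, 2000)
        assert not qc["fail"] and qc["edge"] and not qc["empty"]


class TestMethylationStats:
    def test_read_level_methylation(self):
        assert r.read_level_methylation(make_read(calls="MMMu", positions=(0, 2, 4, 6))) == 0.75
        assert r.read_level_methylation(make_read(calls="uu", positions=(0, 2))) == 0.0
        assert r.read_level_methylation(make_read(calls="", positions=())) is None

    def test_region_amf_pooling(self):
        reads = [
            make_read(calls="MM", positions=(10, 20)),
            make_read(calls="Mu", positions=(10, 30)),
        ]
        reg = r.region_amf(reads, r.Interval("chr1", 0, 100))
        assert (reg.n_meth, reg.n_unmeth) == (3, 1)
        assert reg.amf == 0.75
        # partial region: only position 10 inside
        reg2 = r.region_amf(reads, r.Interval("chr1", 0, 15))
        assert (reg2.n_meth, reg2.n_unmeth) == (2, 0)
        # no coverage -> undefined, never zero
        assert r.region_amf(reads, r.Interval("chr1", 500, 600)).amf is None

    def test_region_amf_matches_per_site_oracle(self, small_cohort):
        reads = small_cohort["samples"]["f1_r1"][:800]
        tally = {}
        for x in reads:
            for pos, call in zip(x.cpg_positions, x.cpg_calls):
                m, u = tally.get((x.contig, int(pos)), (0, 0))
                tally[(x.contig, int(pos))] = (m + (call == "M"), u + (call == "u"))
        region = r.Interval("chr1", 0, 150_000)
        exp_m = sum(v[0] for k, v in tally.items() if k[0] == "chr1" and region.start <= k[1] < region.end)
        exp_u = sum(v[1] for k, v in tally.items() if k[0] == "chr1" and region.start <= k[1] < region.end)
        reg = r.region_amf(reads, region)
        assert (reg.n_meth, reg.n_unmeth) == (exp_m, exp_u)

    def test_region_amf_batch_invariant(self, small_cohort):
        reads = small_cohort["samples"]["f0_r1"][:600]
        region = r.Interval("chr1", 0, 300_000)
        whole = r.region_amf(reads, region)
        m = u = 0
        for batch in (reads[:200], reads[200:500], reads[500:]):
            reg = r.region_amf(batch, region)
            m, u = m + reg.n_meth, u + reg.n_unmeth
        assert (whole.n_meth, whole.n_unmeth) == (m, u)

    def test_delta_amf_identical_samples_zero(self, toy_catalog):
        reads = [
            make_read(calls="Mu", positions=(11, 15)),
            make_read(calls="uM", positions=(60, 71)),
        ]
        table, dropped = r.delta_amf(reads, reads, toy_catalog)
        assert dropped == []
        assert np.allclose(table["motif_delta"], 0.0)
        assert np.allclose(table["insert_delta"], 0.0)

    def test_delta_amf_full_contrast_and_averaging(self, toy_catalog):
        # motif CpGs for the toy fragment: left motif [10,14) sites 10,12;
        # right motif [70,74) sites 70,72; insert (14..70)
        pos = (10, 12, 40, 70, 72)
        a = [make_read(calls="uuuuu", positions=pos)]
        b = [make_read(calls="MMMMM", positions=pos)]
        table, dropped = r.delta_amf(a, b, toy_catalog)
        assert dropped == []
        assert table.loc[0, "motif_delta"] == pytest.approx(1.0)
        assert table.loc[0, "insert_delta"] == pytest.approx(1.0)
        # asymmetric motifs: left delta 0.2 vs right delta 0.4 averages to 0.3
        a_reads = [make_read(calls="MMuuuuuuuu", positions=(10, 12) * 5),
                   make_read(calls="Muuuuuuuuu", positions=(70, 72) * 5),
                   make_read(calls="u", positions=(40,))]
        b_reads = [make_read(calls="MMMMuuuuuu", positions=(10, 12) * 5),
                   make_read(calls="MMMMMuuuuu", positions=(70, 72) * 5),
                   make_read(calls="u", positions=(40,))]
        table2, _ = r.delta_amf(a_reads, b_reads, toy_catalog)
        assert table2.loc[0, "motif_delta"] == pytest.approx(0.5 * (0.2 + 0.4))

    def test_delta_amf_drops_uncovered(self, toy_catalog):
        a = [make_read(calls="M", positions=(40,))]  # insert only, no motif coverage
        b = [make_read(calls="M", positions=(40,))]
        table, dropped = r.delta_amf(a, b, toy_catalog)
        assert table.empty and dropped == [toy_catalog[0].id]
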