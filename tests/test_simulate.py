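"""Genome generation, methylome assignment, conversion, and digestion."""

import numpy as np
import pytest

import recapseq as r
from recapseq.simulate import GenomeIndex, _simulate_recap_sample


def tiny_spec(**kw):
    base = dict(n_contigs=1, contig_length=100_000, n_islands=8, seed=1)
    base.update(kw)
    return r.GenomeSpec(**base)


class TestGenerateGenome:
    def test_deterministic_and_seed_sensitive(self):
        g1, isl1, _ = r.generate_genome(tiny_spec())
        g2, isl2, _ = r.generate_genome(tiny_spec())
        g3, _, _ = r.generate_genome(tiny_spec(seed=2))
        assert g1["chr1"] == g2["chr1"] and isl1 == isl2
        assert g3["chr1"] != g1["chr1"]

    def test_no_islands(self):
        _, islands, _ = r.generate_genome(tiny_spec(n_islands=0))
        assert islands == []

    def test_islands_nonoverlapping_and_catalogable(self):
        genome, islands, _ = r.generate_genome(tiny_spec())
        ivs = sorted(islands)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end <= b.start
        cat = r.build_catalog(genome, r.Motif("CGCG"))
        for iv in islands:
            inside = [
                f for f in cat if f.contig == iv.contig
                and iv.start <= f.left_motif.start and f.right_motif.end <= iv.end
            ]
            assert inside, f"island {iv} hosts no catalogable fragment"

    def test_island_cpg_density_exceeds_background(self):
        genome, islands, cpg = r.generate_genome(tiny_spec())
        seq = genome["chr1"]
        pos = cpg["chr1"]
        in_island = np.zeros(len(seq), dtype=bool)
        for iv in islands:
            in_island[iv.start : iv.end] = True
        island_bp = in_island.sum()
        isl_density = in_island[pos].sum() / island_bp
        bg_density = (~in_island[pos]).sum() / (len(seq) - island_bp)
        assert isl_density > bg_density

    def test_island_gc_near_target(self):
        spec = tiny_spec()
        genome, islands, _ = r.generate_genome(spec)
        for iv in islands[:5]:
            gc = r.gc_content(genome[iv.contig][iv.start : iv.end])
            assert gc >= spec.island_gc - 0.05

    def test_infeasible_spec_raises(self):
        with pytest.raises(ValueError):
            r.generate_genome(r.GenomeSpec(n_contigs=1, contig_length=5000, n_islands=10,
                                           island_length_mean=1500, seed=0))


class TestAssignMethylation:
    def test_zero_marker_fraction_matches_normal(self, small_world):
        cpg, islands = small_world["cpg"], small_world["islands"]
        spec_n = r.MethylomeSpec("normal", marker_island_fraction=0.0)
        spec_t = r.MethylomeSpec("tumor", marker_island_fraction=0.0)
        bn, mk_n = r.assign_methylation(cpg, islands, spec_n, seed=3)
        bt, mk_t = r.assign_methylation(cpg, islands, spec_t, seed=3)
        assert mk_n == mk_t == []
        for c in bn:
            assert np.array_equal(bn[c], bt[c])

    def test_full_marker_fraction_saturates_islands(self, small_world):
        cpg, islands = small_world["cpg"], small_world["islands"]
        spec = r.MethylomeSpec(
            "tumor", marker_island_fraction=1.0, island_beta_tumor_marker=1.0
        )
        beta, mk = r.assign_methylation(cpg, islands, spec, seed=3)
        assert len(mk) == len(islands)
        for iv in islands:
            pos = cpg[iv.contig]
            sel = (pos >= iv.start) & (pos < iv.end - 1)
            assert np.all(beta[iv.contig][sel] == 1.0)

    def test_marker_set_shared_across_classes(self, small_world):
        cpg, islands = small_world["cpg"], small_world["islands"]
        _, mk_n = r.assign_methylation(cpg, islands, r.MethylomeSpec("normal"), seed=9)
        _, mk_t = r.assign_methylation(cpg, islands, r.MethylomeSpec("tumor"), seed=9)
        assert mk_n == mk_t


class TestEmMolecules:
    def test_fully_methylated_no_overconversion(self, small_world):
        genome = small_world["genome"]
        beta = r.attach_rho(
            {c: np.ones(len(p)) for c, p in small_world["cpg"].items()}, 0.5
        )
        params = r.LibraryParams(overconversion_rate=0.0, depth=300)
        mols = r.simulate_em_molecules(genome, beta, params, 300, seed=4)
        for m in mols:
            assert set(m.cpg_calls) <= {"M"}
            for pos in m.cpg_positions:
                off = pos - m.start
                assert m.converted_seq[off : off + 2] == "CG"

    def test_fully_unmethylated_complete_conversion(self, small_world):
        genome = small_world["genome"]
        beta = r.attach_rho(
            {c: np.zeros(len(p)) for c, p in small_world["cpg"].items()}, 0.5
        )
        params = r.LibraryParams(conversion_rate=1.0, depth=300)
        mols = r.simulate_em_molecules(genome, beta, params, 300, seed=4)
        for m in mols:
            assert set(m.cpg_calls) <= {"u"}
            for pos in m.cpg_positions:
                assert m.converted_seq[pos - m.start] == "T"

    def test_high_processivity_gives_concordant_molecules(self, small_world):
        genome = small_world["genome"]
        beta = r.attach_rho(
            {c: np.full(len(p), 0.5) for c, p in small_world["cpg"].items()}, 0.999
        )
        mols = r.simulate_em_molecules(
            genome, beta, r.LibraryParams(conversion_rate=1.0, overconversion_rate=0.0),
            1000, seed=5,
        )
        multi = [m for m in mols if len(m.cpg_calls) >= 2]
        concord = np.mean([len(set(m.cpg_calls)) == 1 for m in multi])
        assert concord > 0.95

    def test_calls_align_with_contained_cpg_sites(self, small_world):
        genome, cpg = small_world["genome"], small_world["cpg"]
        mols = r.simulate_em_molecules(
            genome, small_world["beta_normal"], r.LibraryParams(), 200, seed=6
        )
        for m in mols:
            pos = cpg[m.contig]
            expected = pos[(pos >= m.start) & (pos <= m.end - 2)]
            assert np.array_equal(m.cpg_positions, expected)
            assert len(m.cpg_calls) == len(expected)
            assert len(m.converted_seq) == m.end - m.start


class TestDigestion:
    def test_complete_digest_all_both_cut(self, small_world, small_library):
        params = r.LibraryParams(cut_efficiency=1.0, chimera_leak=0.0)
        lib = r.digest_molecules(
            small_library["molecules"], params, small_world["catalog"], seed=1
        )
        assert lib
        for read in lib:
            assert read.has_both_cuts
            assert read.converted_seq.startswith("CG")
            assert read.converted_seq.endswith("CG")

    def test_no_cutting_no_library(self, small_world, small_library):
        params = r.LibraryParams(cut_efficiency=0.0, chimera_leak=0.0)
        assert r.digest_molecules(
            small_library["molecules"][:500], params, small_world["catalog"], seed=1
        ) == []

    def test_digestion_conserves_bases(self, small_world, small_library):
        """Emitted plus discarded pieces of a molecule tile it exactly."""
        params = small_library["params"]
        for i, m in enumerate(small_library["molecules"][:300]):
            lib, disc = r.digest_molecules(
                [m], params, small_world["catalog"], seed=i, return_discarded=True
            )
            pieces = sorted(lib + disc, key=lambda p: p.start)
            assert pieces[0].start == m.start and pieces[-1].end == m.end
            for a, b in zip(pieces, pieces[1:]):
                assert a.end == b.start
            assert "".join(p.converted_seq for p in pieces) == m.converted_seq
            assert "".join(p.cpg_calls for p in pieces) == m.cpg_calls

    def test_default_params_emit_mostly_both_cut(self, small_library):
        frac = np.mean([x.has_both_cuts for x in small_library["library"]])
        assert frac > 0.8

    def test_fused_path_agrees_with_object_path(self, small_world):
        """The streaming sample simulator and the explicit
        simulate-then-digest route give statistically matching libraries."""
        genome, cat = small_world["genome"], small_world["catalog"]
        bn = small_world["beta_normal"]
        params = r.LibraryParams(depth=6000, seed=21)
        idx = GenomeIndex(genome, cat)
        fused = _simulate_recap_sample(
            idx, bn, bn, 0.0, params, np.random.default_rng(21), "s"
        )
        mols = r.simulate_em_molecules(genome, bn, params, 6000, seed=22)
        objp = r.digest_molecules(mols, params, cat, seed=23)
        f1 = np.mean([x.has_both_cuts for x in fused])
        f2 = np.mean([x.has_both_cuts for x in objp])
        assert abs(f1 - f2) < 0.03
        n1 = sum(x.origin_fragment_id is not None for x in fused)
        n2 = sum(x.origin_fragment_id is not None for x in objp)
        assert abs(n1 - n2) / max(n1, n2) < 0.15


class TestSpikeInCohort:
    def test_pure_fractions(self, small_world):
        design = r.SpikeInDesign(fractions=(0.0, 1.0), replicates=1, seed=2)
        params = r.LibraryParams(depth=2000, seed=2)
        samples, truth = r.simulate_spikein_cohort(
            small_world["genome"], small_world["beta_normal"], small_world["beta_tumor"],
            design, params, small_world["catalog"],
        )
        assert all(x.origin_class == "normal" for x in samples["f0_r1"])
        assert all(x.origin_class == "tumor" for x in samples["f1_r1"])
        assert set(truth["fraction"]) == {0.0, 1.0}

    def test_mixture_share_within_binomial_error(self, small_world):
        """With identical methylomes the emitted-read tumour share is an
        unbiased estimate of the molecule-level mixing fraction."""
        bn = small_world["beta_normal"]
        design = r.SpikeInDesign(fractions=(0.1,), replicates=1, seed=8)
        params = r.LibraryParams(depth=10_000, seed=8)
        samples, _ = r.simulate_spikein_cohort(
            small_world["genome"], bn, bn, design, params, small_world["catalog"]
        )
        reads = samples["f0.1_r1"]
        share = np.mean([x.origin_class == "tumor" for x in reads])
        sd = np.sqrt(0.1 * 0.9 / len(reads))
        assert abs(share - 0.1) < 3 * sd

    def test_cohort_deterministic_under_seed(self, small_world):
        design = r.SpikeInDesign(fractions=(0.5,), replicates=1, seed=3)
        params = r.LibraryParams(depth=1000, seed=3)
        args = (
            small_world["genome"], small_world["beta_normal"],
            small_world["beta_tumor"], design, params, small_world["catalog"],
        )
        s1, _ = r.simulate_spikein_cohort(*args)
        s2, _ = r.simulate_spikein_cohort(*args)
        r1, r2 = s1["f0.5_r1"], s2["f0.5_r1"]
        assert len(r1) == len(r2)
        assert all(
            a.start == b.start and a.converted_seq == b.converted_seq for a, b in zip(r1, r2)
        )
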