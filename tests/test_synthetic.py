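"""Generators: determinism, planted structure, internal consistency."""

import numpy as np
import pytest

from beecaste.io_core import write_cgmap, write_fasta, read_cgmap, read_fasta
from beecaste.methylation import COMPLEMENT, context_census
from beecaste.synthetic import (MethylomeSimParams, OntologySimParams,
                                OrthoSimParams, OverlapSimParams,
                                simulate_de_pair, simulate_methylome,
                                simulate_ontology, simulate_orthogroup_matrix)


class TestDeterminism:
    """Identical (params, seed) must give byte-identical outputs."""

    def test_methylome(self, tmp_path):
        for d in ("x", "y"):
            fasta, cgmap, truth = simulate_methylome(
                MethylomeSimParams(n_transcripts=30, seed=42))
            write_fasta(fasta, tmp_path / f"{d}.fa")
            write_cgmap(cgmap, tmp_path / f"{d}.cgmap")
            truth.to_csv(tmp_path / f"{d}.tsv", sep="\t")
        for ext in (".fa", ".cgmap", ".tsv"):
            assert (tmp_path / f"x{ext}").read_bytes() == \
                   (tmp_path / f"y{ext}").read_bytes()

    def test_de_pair_and_orthogroups_and_ontology(self):
        a1 = simulate_de_pair(OverlapSimParams(seed=7))
        a2 = simulate_de_pair(OverlapSimParams(seed=7))
        assert [r.gene_id for r in a1[0]] == [r.gene_id for r in a2[0]]
        assert [r.annotation for r in a1[1]] == [r.annotation for r in a2[1]]

        m1, l1 = simulate_orthogroup_matrix(OrthoSimParams(seed=7))
        m2, l2 = simulate_orthogroup_matrix(OrthoSimParams(seed=7))
        assert l1 == l2 and (m1.counts == m2.counts).all().all()

        o1 = simulate_ontology(OntologySimParams(seed=7))
        o2 = simulate_ontology(OntologySimParams(seed=7))
        assert o1[1] == o2[1] and o1[2] == o2[2]


class TestMethylome:
    def test_null_methylome_has_no_methylated_reads(self):
        params = MethylomeSimParams(n_transcripts=20,
                                    p_meth={"CG": 0.0, "CW": 0.0, "CC": 0.0},
                                    seed=1)
        _, cgmap, truth = simulate_methylome(params)
        assert all(r.mc_count == 0 for r in cgmap)
        assert (truth["true_mean_mC"] == 0).all()

    def test_degenerate_all_cg_mix(self):
        params = MethylomeSimParams(
            n_transcripts=20, seed=2,
            context_mix={"CG": 1.0, "CA": 0.0, "CC": 0.0, "CT": 0.0})
        fasta, _, _ = simulate_methylome(params)
        census = context_census(fasta)
        assert census["CG"] == 1.0

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            simulate_methylome(MethylomeSimParams(
                context_mix={"CG": 0.5, "CA": 0.6, "CC": -0.1, "CT": 0.0}))

    def test_cgmap_consistent_with_fasta_both_strands(self):
        """Every CGmap row must agree with the FASTA base and dinucleotide."""
        fasta, cgmap, _ = simulate_methylome(
            MethylomeSimParams(n_transcripts=40, seed=3))
        seqs = dict(fasta)
        for r in cgmap:
            seq = seqs[r.seq_id]
            base = seq[r.position - 1]
            assert base == r.nucleotide
            if r.nucleotide == "C":
                assert "C" + seq[r.position] == r.dinucleotide or \
                    seq[r.position] == "N"
            else:  # minus-strand C: following base = complement of previous
                assert "C" + COMPLEMENT[seq[r.position - 2]] == r.dinucleotide

    def test_truth_counts_match_cgmap(self):
        fasta, cgmap, truth = simulate_methylome(
            MethylomeSimParams(n_transcripts=25, seed=4))
        by_seq = {}
        for r in cgmap:
            cls = "CG" if r.dinucleotide == "CG" else (
                "CW" if r.dinucleotide in ("CA", "CT") else "CC")
            d = by_seq.setdefault(r.seq_id, {"CG": 0, "CW": 0, "CC": 0})
            d[cls] += 1
        for sid, d in by_seq.items():
            for cls in ("CG", "CW", "CC"):
                assert truth.loc[sid, f"n_sites_{cls}"] == d[cls]

    def test_census_tracks_planted_mix(self):
        params = MethylomeSimParams(n_transcripts=200, seed=5)
        fasta, _, _ = simulate_methylome(params)
        census = context_census(fasta)
        n = census["n_defined"]
        p = params.context_mix["CG"]
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(census["CG"] - p) < 4 * sd


class TestDePair:
    def test_planted_zero_and_maximum(self):
        ta, tb, _, _ = simulate_de_pair(OverlapSimParams(
            planted_overlap=0, de_size_a=20, de_size_b=20, seed=6))
        terms_a = {r.annotation for r in ta}
        terms_b = {r.annotation for r in tb}
        assert not terms_a & terms_b

        n = 30
        ta, tb, _, _ = simulate_de_pair(OverlapSimParams(
            universe_size_a=n, universe_size_b=n, shared_universe_size=n,
            de_size_a=n, de_size_b=n, planted_overlap=n, seed=7))
        assert {r.annotation for r in ta} == {r.annotation for r in tb}

    def test_exact_planted_overlap(self):
        params = OverlapSimParams(shared_universe_size=1000,
                                  universe_size_a=1000, universe_size_b=1000,
                                  de_size_a=100, de_size_b=50,
                                  planted_overlap=30, seed=8)
        ta, tb, universes, truth = simulate_de_pair(params)
        shared = {r.annotation for r in ta} & {r.annotation for r in tb}
        assert len(shared) == 30
        assert shared == set(truth["term"])

    def test_resampled_mean_near_hypergeometric(self):
        from beecaste.overlap import overlap_random_test, term_set_from_table
        params = OverlapSimParams(shared_universe_size=1000,
                                  universe_size_a=1000, universe_size_b=1000,
                                  de_size_a=100, de_size_b=50,
                                  planted_overlap=30, seed=9)
        ta, tb, universes, _ = simulate_de_pair(params)
        ts_a = term_set_from_table(ta, universes["species_a"])
        ts_b = term_set_from_table(tb, universes["species_b"])
        reps = 4000
        res = overlap_random_test(ts_a, ts_b, reps=reps, seed=10,
                                  universe_mode="shared")
        expected = 100 * 50 / 1000  # n_A * n_B / N
        assert res.observed == 30
        assert abs(res.expected_mean - expected) < 3 * res.expected_sd / np.sqrt(reps)

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValueError):
            simulate_de_pair(OverlapSimParams(de_size_a=10, de_size_b=10,
                                              planted_overlap=11))


class TestOrthoSim:
    def test_planted_patterns_by_construction(self):
        matrix, labels = simulate_orthogroup_matrix(OrthoSimParams(
            category_counts={"apinae": 10, "species_specific_tangustula": 5},
            seed=11))
        apinae = [og for og, c in labels.items() if c == "apinae"]
        assert all((matrix.counts.loc[og] > 0).all() for og in apinae)
        solo = [og for og, c in labels.items()
                if c == "species_specific_tangustula"]
        for og in solo:
            row = matrix.counts.loc[og]
            assert row["T_angustula_transcriptome"] > 0
            assert (row.drop("T_angustula_transcriptome") == 0).all()

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            simulate_orthogroup_matrix(OrthoSimParams(
                category_counts={"martians": 1}))


class TestOntologySim:
    def test_min_levels_enforced(self):
        with pytest.raises(ValueError):
            simulate_ontology(OntologySimParams(n_levels=2))

    def test_level3_exists_and_planted_is_there(self):
        from beecaste.go_tools import term_depth
        dag, _, _, truth = simulate_ontology(OntologySimParams(seed=12))
        assert term_depth(dag)[truth["planted_term"]] == 3

    def test_null_odds_type_one_error_calibrated(self):
        """With odds 1 the planted term's Fisher p is ~uniform: the rejection
        rate at alpha=0.01 stays within 3 binomial SD (discreteness makes the
        test conservative, so only the upper bound binds)."""
        from beecaste.go_tools import fisher_enrichment, propagate
        n_runs, alpha = 400, 0.01
        hits = 0
        for s in range(n_runs):
            dag, ann, study, truth = simulate_ontology(
                OntologySimParams(enrichment_odds=1.0, n_genes=150,
                                  study_size=40, seed=1000 + s))
            prop = propagate(ann, dag)
            res = fisher_enrichment(study, set(ann), prop)
            p = {r.term_id: r.p_value for r in res}[truth["planted_term"]]
            hits += p < alpha
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_runs)
        assert hits / n_runs <= bound
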