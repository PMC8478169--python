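"""Profile-HMM engine: parsing, construction, scoring, E-values, search."""

import math

import numpy as np
import pytest

from cuprome.phmm import (
    AMINO_ACIDS,
    HmmParseError,
    ProfileHMM,
    build_profile_from_alignment,
    calibrate_model,
    evalue,
    read_hmm_file,
    search,
    viterbi_bitscore,
    write_hmm_file,
)
from cuprome.simulate import PlantedHomolog, seed_alignment, simulate_proteome

from oracles import brute_force_local_score, random_profile, random_sequence


def single_state_model(favored: str = "A", odds_bits: float = 2.0) -> ProfileHMM:
    """One match state whose favored residue has the given log2-odds."""
    bg = np.full(20, 1 / 20)
    m = np.full((1, 20), (1 - (2.0**odds_bits) / 20) / 19)
    m[0, AMINO_ACIDS.index(favored)] = (2.0**odds_bits) / 20
    return ProfileHMM(
        name="one", accession="ONE",
        match_emissions=m, insert_emissions=bg.reshape(1, 20).copy(),
        transitions=np.array([[1.0, 0, 0, 1.0, 0, 1.0, 0]]),
        background=bg,
    )


class TestViterbi:
    def test_single_state_scores_its_log_odds_with_envelope(self):
        model = single_state_model("A", 2.0)
        score, start, end = viterbi_bitscore(model, "A")
        assert score == pytest.approx(2.0, abs=1e-9)
        assert (start, end) == (1, 1)

    def test_flanking_residues_are_free(self):
        model = single_state_model("A", 2.0)
        score, start, end = viterbi_bitscore(model, "CCWACWC")
        assert score == pytest.approx(2.0, abs=1e-9)
        assert (start, end) == (4, 4)

    def test_score_never_decreases_with_appended_suffix(self, rng):
        for _ in range(30):
            model = random_profile(rng)
            seq = random_sequence(rng, max_len=4, allow_x=False)
            suffix = random_sequence(rng, max_len=3, allow_x=False)
            s1, *_ = viterbi_bitscore(model, seq)
            s2, *_ = viterbi_bitscore(model, seq + suffix)
            assert s2 >= s1 - 1e-9

    def test_all_negative_emissions_fall_back_to_best_single_residue(self):
        # model emitting only W: every other sequence residue scores << 0,
        # the best local alignment is a single aligned residue, never a
        # flank-penalised longer one
        bg = np.full(20, 1 / 20)
        m = np.zeros((1, 20))
        m[0, AMINO_ACIDS.index("W")] = 1.0
        model = ProfileHMM(
            name="w", accession="W", match_emissions=m,
            insert_emissions=bg.reshape(1, 20).copy(),
            transitions=np.array([[1.0, 0, 0, 1.0, 0, 1.0, 0]]), background=bg,
        )
        score, start, end = viterbi_bitscore(model, "AAAA")
        # every residue scores the same (hugely negative) amount, so the
        # best alignment is a single residue, never a flank-penalised run
        assert start == end

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(40):
            model = random_profile(rng)
            seq = random_sequence(rng)
            expected = brute_force_local_score(model, seq)
            got, _, _ = viterbi_bitscore(model, seq)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_x_scores_zero_bits(self):
        model = single_state_model("A", 2.0)
        score, _, _ = viterbi_bitscore(model, "X")
        assert score == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bad", ["", "AB1", "A-C"])
    def test_rejects_empty_or_non_amino_input(self, bad):
        model = single_state_model()
        with pytest.raises(ValueError):
            viterbi_bitscore(model, bad)


class TestBuildProfile:
    def test_identical_sequences_give_indicator_emissions(self):
        prof = build_profile_from_alignment(["ACD", "ACD", "ACD"], alpha=0.0)
        assert prof.length == 3
        for k, a in enumerate("ACD"):
            assert prof.match_emissions[k, AMINO_ACIDS.index(a)] == pytest.approx(1.0)

    def test_pseudocount_formula_on_mixed_column(self):
        # column A, A, C with alpha=1: m(A) = (2+1)/(3+20)
        prof = build_profile_from_alignment(["A", "A", "C"], alpha=1.0)
        assert prof.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(3 / 23)
        assert prof.match_emissions[0, AMINO_ACIDS.index("C")] == pytest.approx(2 / 23)

    def test_gappy_column_excluded_from_match_states(self):
        # middle column is 60% gaps (3 of 5) -> insert column
        seqs = ["A-D", "A-D", "A-D", "ACD", "AWD"]
        prof = build_profile_from_alignment(seqs, alpha=0.5, match_column_max_gap_fraction=0.5)
        assert prof.length == 2

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile_from_alignment(["ACD", "AC"])

    def test_generating_sequence_outranks_single_mutants(self):
        # substitutions to residues seen elsewhere in the alignment strictly
        # lower the score; substitutions to unseen residues can only tie
        # (the pseudocount emission-to-background ratio coincides), never win
        base = "ACDEFGHIKL"
        prof = build_profile_from_alignment([base] * 3, alpha=0.1)
        base_score, _, _ = viterbi_bitscore(prof, base)
        for pos in range(len(base)):
            for sub in AMINO_ACIDS:
                if sub == base[pos]:
                    continue
                mutant = base[:pos] + sub + base[pos + 1 :]
                mut_score, _, _ = viterbi_bitscore(prof, mutant)
                if sub in base:
                    assert mut_score < base_score
                else:
                    assert mut_score <= base_score + 1e-9


class TestEvalue:
    def make_calibrated(self, mu=20.0, lam=math.log(2)):
        m = single_state_model()
        m.viterbi_calibration = (mu, lam)
        return m

    def test_analytic_value_at_mu(self):
        model = self.make_calibrated(mu=20.0)
        assert evalue(20.0, model, 1) == pytest.approx(1 - math.exp(-1), rel=1e-9)

    def test_linear_in_database_size(self):
        model = self.make_calibrated()
        assert evalue(35.0, model, 2000) == pytest.approx(2 * evalue(35.0, model, 1000), rel=1e-12)

    def test_monotone_decreasing_in_score(self):
        model = self.make_calibrated()
        scores = np.linspace(0, 200, 50)
        evs = [evalue(s, model, 100) for s in scores]
        assert all(e1 >= e2 for e1, e2 in zip(evs, evs[1:]))
        # strictly decreasing once above the double-precision saturation
        # region far below mu, where the survival function is exactly 1
        above = [evalue(s, model, 100) for s in np.linspace(20, 200, 30)]
        assert all(e1 > e2 for e1, e2 in zip(above, above[1:]))
        assert above[-1] < 1e-30

    def test_uncalibrated_model_raises(self):
        with pytest.raises(ValueError, match="calibrat"):
            evalue(50.0, single_state_model(), 100)


class TestSearch:
    def build_calibrated(self, accession: str) -> ProfileHMM:
        prof = build_profile_from_alignment(
            seed_alignment(accession, length=60), accession=accession, alpha=0.3
        )
        return calibrate_model(prof, n_decoys=60, decoy_length=80, seed=5)

    def test_planted_homolog_is_top_hit(self):
        acc = "COG2217"
        model = self.build_calibrated(acc)
        proteome, truth = simulate_proteome(
            n_decoys=25, planted=[PlantedHomolog(acc, n_copies=1, divergence=0.1)],
            seed=11, seed_length=60,
        )
        hits = search([model], proteome, max_evalue=1e-30)
        assert not hits.empty
        assert hits.sort_values("evalue").iloc[0]["protein_id"].startswith("planted_COG2217")

    def test_pure_decoys_give_empty_table_at_stringent_cutoff(self):
        model = self.build_calibrated("TIGR02044")
        proteome, _ = simulate_proteome(n_decoys=30, planted=[], seed=3)
        hits = search([model], proteome, max_evalue=1e-30)
        assert hits.empty

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            search([], {"p": "ACDE"})

    def test_duplicate_protein_ids_rejected(self, tmp_path):
        model = self.build_calibrated("COG0845")
        fasta = tmp_path / "dup.faa"
        fasta.write_text(">p1\nACDE\n>p1\nACDF\n")
        with pytest.raises(ValueError, match="duplicate"):
            search([model], fasta)

    def test_empty_proteome_warns_and_returns_empty(self):
        model = self.build_calibrated("COG5569")
        with pytest.warns(UserWarning):
            hits = search([model], {})
        assert hits.empty


class TestHmmFileIO:
    def test_round_trip_preserves_probabilities(self, tmp_path, rng):
        models = [random_profile(rng, max_states=4) for _ in range(3)]
        models[0].viterbi_calibration = (12.5, math.log(2))
        path = tmp_path / "models.hmm"
        write_hmm_file(models, path)
        back = read_hmm_file(path)
        assert len(back) == 3
        for orig, rt in zip(models, back):
            assert rt.length == orig.length
            np.testing.assert_allclose(rt.match_emissions, orig.match_emissions, atol=1e-9)
            np.testing.assert_allclose(rt.insert_emissions, orig.insert_emissions, atol=1e-9)
            np.testing.assert_allclose(rt.background, orig.background, atol=1e-9)
            # final-node exit group is conventional, compare the rest
            np.testing.assert_allclose(
                rt.transitions[:-1], orig.transitions[:-1], atol=1e-9
            )
        assert back[0].viterbi_calibration == pytest.approx((12.5, math.log(2)), abs=1e-5)
        assert back[1].viterbi_calibration is None

    def test_missing_stats_line_leaves_calibration_absent(self, tmp_path, rng):
        model = random_profile(rng)
        path = tmp_path / "nostats.hmm"
        write_hmm_file([model], path)
        assert read_hmm_file(path)[0].viterbi_calibration is None

    def test_leng_mismatch_names_a_line(self, tmp_path, rng):
        model = random_profile(rng, max_states=3)
        path = tmp_path / "bad.hmm"
        write_hmm_file([model], path)
        text = path.read_text().replace(f"LENG  {model.length}", f"LENG  {model.length + 1}")
        path.write_text(text)
        with pytest.raises(HmmParseError, match="line"):
            read_hmm_file(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "junk.hmm"
        path.write_text("NOT A PROFILE\n")
        with pytest.raises(HmmParseError, match="line 1"):
            read_hmm_file(path)

    def test_non_numeric_emission_field_names_line(self, tmp_path, rng):
        model = random_profile(rng, max_states=2)
        path = tmp_path / "nonnum.hmm"
        write_hmm_file([model], path)
        lines = path.read_text().splitlines()
        idx = next(i for i, l in enumerate(lines) if l.strip().startswith("1 "))
        fields = lines[idx].split()
        fields[1] = "oops"
        lines[idx] = "  " + "  ".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(HmmParseError, match="non-numeric"):
            read_hmm_file(path)

    def test_reads_hmmer_written_ascii(self, tmp_path):
        """A file written by HMMER's own toolkit parses to the same numbers."""
        pyhmmer = pytest.importorskip("pyhmmer")
        alphabet = pyhmmer.easel.Alphabet.amino()
        seqs = [
            pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=s)
            for i, s in enumerate(seed_alignment("TIGR02044", n_variants=5, length=40))
        ]
        msa = pyhmmer.easel.TextMSA(name=b"fam", sequences=seqs).digitize(alphabet)
        builder = pyhmmer.plan7.Builder(alphabet)
        hmm, _, _ = builder.build_msa(msa, pyhmmer.plan7.Background(alphabet))
        path = tmp_path / "hmmer.hmm"
        with open(path, "wb") as fh:
            hmm.write(fh, binary=False)
        ours = read_hmm_file(path)[0]
        assert ours.length == hmm.M
        ref_match = np.asarray(hmm.match_emissions)[1:]
        np.testing.assert_allclose(ours.match_emissions, ref_match, atol=2e-4)
        ref_ins = np.asarray(hmm.insert_emissions)[1:]
        np.testing.assert_allclose(ours.insert_emissions, ref_ins, atol=2e-4)
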