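"""Six-frame translation, local alignment and env genus assignment."""

import numpy as np
import pytest

from erv_activity import env_screen, synthetic

# Independent codon table for the translation oracle (standard code).
CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
COMPLEMENT = str.maketrans("ACGT", "TGCA")


def oracle_translate(seq, frame):
    if frame < 0:
        seq = seq.translate(COMPLEMENT)[::-1]
    off = abs(frame) - 1
    pep = []
    for i in range(off, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        pep.append(CODONS.get(codon, "X"))
    return "".join(pep)


def sw_oracle(query, target, matrix, open_cost=12, ext_cost=1):
    """Exhaustive affine-gap Smith-Waterman, plain dynamic programming."""
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in target (vertical)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in query (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] - open_cost, E[i - 1, j] - ext_cost)
            F[i, j] = max(H[i, j - 1] - open_cost, F[i, j - 1] - ext_cost)
            s = matrix[query[i - 1], target[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


class TestSixFrameTranslate:
    def test_simple_forward_frame(self):
        frames = dict(
            ((f, s), p) for f, s, p in env_screen.six_frame_translate("ATGGCC")
        )
        assert frames[(1, "+")] == "MA"

    def test_reverse_frame_equals_forward_of_revcomp(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
        rc = seq.translate(COMPLEMENT)[::-1]
        ours = {f: p for f, s, p in env_screen.six_frame_translate(seq)}
        theirs = {f: p for f, s, p in env_screen.six_frame_translate(rc)}
        for f in (1, 2, 3):
            assert ours[-f] == theirs[f]

    def test_matches_codon_table_oracle_on_random_sequence(self):
        rng = np.random.default_rng(4)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        for frame, strand, pep in env_screen.six_frame_translate(seq):
            assert pep == oracle_translate(seq, frame)

    def test_n_codons_translate_to_x(self):
        frames = {f: p for f, s, p in env_screen.six_frame_translate("ATGNNNGCC")}
        assert frames[1] == "MXA"


class TestLocalAlign:
    def test_self_alignment_score_is_sum_of_diagonal(self):
        pep = "MKVLAAGICQ"
        matrix = env_screen._blosum62_star()
        expected = sum(matrix[a, a] for a in pep)
        score, q_span, t_span, identity, aln_len, *_ = env_screen.local_align(pep, pep)
        assert score == expected
        assert identity == 1.0
        assert aln_len == len(pep)
        assert q_span == (0, len(pep)) and t_span == (0, len(pep))

    def test_dissimilar_peptides_score_zero(self):
        score, *_ = env_screen.local_align("WWWWWWWW", "PPPPPPPP")
        assert score == 0.0

    def test_substitution_only_score_is_symmetric(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = "".join(synthetic.AA20[i] for i in rng.integers(0, 20, 20))
            b = "".join(synthetic.AA20[i] for i in rng.integers(0, 20, 20))
            sa, *_ = env_screen.local_align(a, b)
            sb, *_ = env_screen.local_align(b, a)
            assert sa == sb

    def test_matches_exhaustive_dp_oracle_on_random_pairs(self):
        """50 random peptide pairs <= 30 aa: scores equal the plain DP."""
        rng = np.random.default_rng(6)
        matrix = env_screen._blosum62_star()
        aligner = env_screen.make_aligner()
        for _ in range(50):
            la, lb = rng.integers(5, 31, 2)
            a = "".join(synthetic.AA20[i] for i in rng.integers(0, 20, la))
            b = "".join(synthetic.AA20[i] for i in rng.integers(0, 20, lb))
            score, *_ = env_screen.local_align(a, b, aligner)
            assert score == sw_oracle(a, b, matrix)


class TestScreenLocus:
    def test_unmutated_planted_orf_found_at_full_identity(self):
        cfg = synthetic.SyntheticConfig(seed=8, n_erv_loci=300, n_env_loci=6, env_mutation_rate=0.0)
        res = synthetic.simulate(cfg)
        for lid, info in res.truth.env.items():
            hits = env_screen.screen_locus(lid, res.sequences[lid], res.queries)
            own = [h for h in hits if h.query_id == info["query_id"]]
            assert own, f"planted env not found in {lid}"
            best = max(own, key=lambda h: h.aln_len)
            assert best.identity == 1.0
            span = info["query_span"]
            assert best.aln_len == span[1] - span[0]

    def test_random_locus_has_no_hits(self):
        rng = np.random.default_rng(9)
        cfg = synthetic.SyntheticConfig(seed=8)
        queries = synthetic.generate_env_panel(cfg)
        for trial in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1200))
            assert env_screen.screen_locus(f"rand{trial}", seq, queries) == []

    def test_locus_span_consistent_with_frame_arithmetic(self):
        cfg = synthetic.SyntheticConfig(seed=8, n_erv_loci=300, n_env_loci=6, env_mutation_rate=0.0)
        res = synthetic.simulate(cfg)
        for lid in res.truth.env:
            for h in env_screen.screen_locus(lid, res.sequences[lid], res.queries):
                s, e = h.locus_span
                assert 0 <= s < e <= len(res.sequences[lid])
                # contiguous (gap-free) alignments: nt span is 3x the aa span
                if len(h.query_blocks) == 1:
                    assert e - s == 3 * h.aln_len


class TestAssignGenus:
    def hit(self, qid, genus, aln_len, score):
        return env_screen.EnvHit(
            "l1", qid, genus, score, aln_len, (0, aln_len), (0, 3 * aln_len),
            1, "+", 0.9, ((0, aln_len),),
        )

    def test_longest_hit_wins(self):
        hits = [
            self.hit("q1", "Gammaretrovirus", 80, 100.0),
            self.hit("q2", "Lentivirus", 45, 300.0),
        ]
        genus, chosen = env_screen.assign_genus(hits)
        assert genus == "Gammaretrovirus" and chosen.query_id == "q1"

    def test_equal_length_higher_score_wins(self):
        hits = [
            self.hit("q1", "Gammaretrovirus", 60, 95.0),
            self.hit("q2", "Lentivirus", 60, 120.0),
        ]
        assert env_screen.assign_genus(hits)[0] == "Lentivirus"

    def test_full_tie_breaks_by_query_id(self):
        hits = [
            self.hit("qB", "Lentivirus", 60, 100.0),
            self.hit("qA", "Gammaretrovirus", 60, 100.0),
        ]
        assert env_screen.assign_genus(hits)[1].query_id == "qA"

    def test_empty_hit_list_returns_none(self):
        assert env_screen.assign_genus([]) is None

    def test_genus_accuracy_at_low_mutation(self, sim):
        found = env_screen.screen_catalog(
            {lid: sim.sequences[lid] for lid in sim.truth.env}, sim.queries
        )
        assert set(found) == set(sim.truth.env)
        for lid, (genus, _) in found.items():
            assert genus == sim.truth.env[lid]["genus"]

    def test_mutation_rate_point_one_still_recovers_planted_hits(self):
        """At nucleotide mutation rate 0.1 roughly 27% of codons carry a hit,
        so amino-acid identity settles near 0.78; hits and genera survive."""
        cfg = synthetic.SyntheticConfig(seed=10, n_erv_loci=400, n_env_loci=10, env_mutation_rate=0.1)
        res = synthetic.simulate(cfg)
        found = env_screen.screen_catalog(
            {lid: res.sequences[lid] for lid in res.truth.env}, res.queries
        )
        assert len(found) == 10
        for lid, (genus, _) in found.items():
            assert genus == res.truth.env[lid]["genus"]
        identities = [hit.identity for _, hit in found.values()]
        assert 0.70 <= np.mean(identities) <= 0.88


class TestSuDomainCoverage:
    def make_hit(self, blocks):
        aln = sum(e - s for s, e in blocks)
        return env_screen.EnvHit(
            "l1", "q1", "Lentivirus", 100.0, aln, (blocks[0][0], blocks[-1][1]),
            (0, 3 * aln), 1, "+", 1.0, tuple(blocks),
        )

    def test_full_alignment_covers_whole_su_span(self):
        cov, flag = env_screen.su_domain_coverage(self.make_hit([(0, 300)]), (60, 210))
        assert (cov, flag) == (150, True)

    def test_alignment_outside_su_span(self):
        cov, flag = env_screen.su_domain_coverage(self.make_hit([(0, 50)]), (60, 210))
        assert (cov, flag) == (0, False)

    def test_exactly_seventy_is_not_flagged(self):
        cov, flag = env_screen.su_domain_coverage(self.make_hit([(10, 80)]), (10, 200))
        assert (cov, flag) == (70, False)

    def test_missing_su_annotation(self):
        cov, flag = env_screen.su_domain_coverage(self.make_hit([(0, 100)]), None)
        assert cov is None and flag is False


class TestEnvSummary:
    def test_active_ratio_reported(self, sim):
        from erv_activity import activity

        found = env_screen.screen_catalog(
            {lid: sim.sequences[lid] for lid in sim.truth.env}, sim.queries
        )
        table = activity.call_active(sim.erv_counts.values, sim.erv_counts.sample_sheet)
        summary = env_screen.env_expression_summary(found, sim.erv_counts.values, table, None)
        truly_active = sum(1 for lid in found if sim.truth.activity[lid])
        assert summary["n_env_loci"] == len(found)
        assert summary["n_active"] == truly_active
        assert summary["active_ratio"] == pytest.approx(truly_active / len(found))

    def test_missing_locus_raises(self, sim):
        from erv_activity import activity

        table = activity.call_active(sim.erv_counts.values, sim.erv_counts.sample_sheet)
        fake = {"not_a_locus": ("Lentivirus", None)}
        with pytest.raises(KeyError, match="not_a_locus"):
            env_screen.env_expression_summary(fake, sim.erv_counts.values, table, None)


def test_panel_fasta_round_trip(sim, tmp_path):
    path = tmp_path / "panel.fa"
    synthetic.write_env_panel(sim.queries, path)
    back = env_screen.read_env_panel(path)
    assert back == sim.queries
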