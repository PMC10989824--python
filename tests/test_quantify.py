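"""Union-mode counting, TPM conversion and the PCA report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from erv_activity import quantify, synthetic
from erv_activity.catalog import ErvLocus


def make_features(spec):
    return [
        ErvLocus(name, chrom, start, end, "+", "fam", "ERV1")
        for name, chrom, start, end in spec
    ]


def sam_text(reads, chroms={"chr1": 10000}):
    lines = ["@HD\tVN:1.6"]
    for c, L in chroms.items():
        lines.append(f"@SQ\tSN:{c}\tLN:{L}")
    for name, flag, chrom, pos1, cigar in reads:
        if cigar == "*":
            seq, qual = "*", "*"
        else:
            n = int(cigar[:-1])
            seq, qual = "A" * n, "I" * n
        lines.append(f"{name}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}")
    return "\n".join(lines) + "\n"


class TestCountReads:
    def test_read_inside_one_feature(self, tmp_path):
        feats = make_features([("A", "chr1", 100, 300), ("B", "chr1", 500, 700)])
        sam = tmp_path / "r.sam"
        sam.write_text(sam_text([("r1", 0, "chr1", 151, "50M")]))
        counts, counters = quantify.count_reads(sam, feats)
        assert counts["A"] == 1 and counts["B"] == 0
        assert counters["assigned"] == 1

    def test_read_spanning_two_features_is_ambiguous(self, tmp_path):
        feats = make_features([("A", "chr1", 100, 200), ("B", "chr1", 200, 300)])
        sam = tmp_path / "r.sam"
        sam.write_text(sam_text([("r1", 0, "chr1", 176, "50M")]))
        counts, counters = quantify.count_reads(sam, feats)
        assert counts.sum() == 0
        assert counters["ambiguous"] == 1

    def test_no_overlap_is_no_feature(self, tmp_path):
        feats = make_features([("A", "chr1", 100, 200)])
        sam = tmp_path / "r.sam"
        sam.write_text(sam_text([("r1", 0, "chr1", 5001, "50M")]))
        counts, counters = quantify.count_reads(sam, feats)
        assert counters["no_feature"] == 1

    def test_unmapped_and_secondary_skipped(self, tmp_path):
        feats = make_features([("A", "chr1", 100, 200)])
        sam = tmp_path / "r.sam"
        sam.write_text(
            sam_text([("r1", 4, "chr1", 0, "*"), ("r2", 256, "chr1", 101, "50M")])
        )
        _, counters = quantify.count_reads(sam, feats)
        assert counters["skipped"] == 2

    def test_sam_without_header_errors(self, tmp_path):
        sam = tmp_path / "r.sam"
        sam.write_text("r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\tAAAA\tIIII\n")
        with pytest.raises(ValueError):
            quantify.count_reads(sam, make_features([("A", "chr1", 100, 200)]))

    def test_paired_fragment_counted_once(self, tmp_path):
        feats = make_features([("A", "chr1", 100, 400)])
        sam = tmp_path / "r.sam"
        # both mates inside A: one assigned fragment, not two
        sam.write_text(
            sam_text(
                [("p1", 99, "chr1", 101, "50M"), ("p1", 147, "chr1", 301, "50M")]
            )
        )
        counts, counters = quantify.count_reads(sam, feats)
        assert counts["A"] == 1
        assert counters["assigned"] == 1

    def test_simulated_reads_match_per_read_oracle(self, sim, tmp_path):
        """Emitted SAM counts equal an independent per-read overlap scan."""
        feats = sim.catalog[:300]
        planted = pd.Series(
            np.random.default_rng(4).integers(0, 4, len(feats)),
            index=[f.locus_id for f in feats],
        )
        text = synthetic.sam_from_counts(
            planted, feats, sim.annotation.chrom_lengths, seed=9
        )
        sam = tmp_path / "sim.sam"
        sam.write_text(text)
        counts, counters = quantify.count_reads(sam, feats)
        # oracle: brute-force overlap of each read against every feature
        oracle = {f.locus_id: 0 for f in feats}
        n_amb = n_none = 0
        for line in text.splitlines():
            if line.startswith("@"):
                continue
            parts = line.split("\t")
            chrom, pos1, cigar = parts[2], int(parts[3]), parts[5]
            rlen = int(cigar[:-1])
            s, e = pos1 - 1, pos1 - 1 + rlen
            hits = [
                f.locus_id
                for f in feats
                if f.chrom == chrom and not (f.end <= s or f.start >= e)
            ]
            if len(hits) == 1:
                oracle[hits[0]] += 1
            elif len(hits) == 0:
                n_none += 1
            else:
                n_amb += 1
        assert counts.to_dict() == oracle
        assert counters["ambiguous"] == n_amb
        assert counters["no_feature"] == n_none

    def test_conservation_of_fragments(self, sim, tmp_path):
        feats = sim.catalog[:100]
        planted = pd.Series(2, index=[f.locus_id for f in feats])
        sam = tmp_path / "c.sam"
        sam.write_text(
            synthetic.sam_from_counts(planted, feats, sim.annotation.chrom_lengths, seed=2)
        )
        counts, counters = quantify.count_reads(sam, feats)
        assert sum(counters.values()) == 200


class TestTpm:
    def make_matrix(self, counts, lengths):
        n = counts.shape[1]
        sheet = pd.DataFrame(
            {"tissue": ["t"] * n, "replicate": range(1, n + 1)},
            index=counts.columns,
        )
        return quantify.ExpressionMatrix(counts, lengths, sheet, "counts")

    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        em = self.make_matrix(counts, pd.Series({"a": 100, "b": 100}))
        tpm = quantify.compute_tpm(em)
        assert tpm.values["s1"].tolist() == [500000.0, 500000.0]

    def test_length_normalisation_hand_computed(self):
        """counts (10,10), lengths (100,200) -> TPM (2/3, 1/3) of a million."""
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        em = self.make_matrix(counts, pd.Series({"a": 100, "b": 200}))
        tpm = quantify.compute_tpm(em)
        np.testing.assert_allclose(
            tpm.values["s1"].to_numpy(), [666666.6667, 333333.3333], atol=0.01
        )

    def test_sums_to_one_million_and_scale_invariant(self, sim):
        tpm = quantify.compute_tpm(sim.erv_counts)
        sums = tpm.values.sum(axis=0)
        np.testing.assert_allclose(sums.to_numpy(), 1e6, atol=1e-3)
        scaled = quantify.ExpressionMatrix(
            sim.erv_counts.values * 7,
            sim.erv_counts.lengths,
            sim.erv_counts.sample_sheet,
            "counts",
        )
        np.testing.assert_allclose(
            quantify.compute_tpm(scaled).values.to_numpy(),
            tpm.values.to_numpy(),
            rtol=1e-9,
        )

    def test_all_zero_sample_stays_zero(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [1, 1]}, index=["a", "b"])
        em = self.make_matrix(counts, pd.Series({"a": 100, "b": 100}))
        tpm = quantify.compute_tpm(em)
        assert tpm.values["s1"].tolist() == [0.0, 0.0]
        assert tpm.values["s2"].sum() == 1e6

    def test_missing_length_raises(self):
        counts = pd.DataFrame({"s1": [1, 1]}, index=["a", "b"])
        sheet = pd.DataFrame({"tissue": ["t"], "replicate": [1]}, index=["s1"])
        with pytest.raises(ValueError, match="b"):
            em = quantify.ExpressionMatrix(counts, pd.Series({"a": 100}), sheet, "counts")

    @given(st.integers(min_value=2, max_value=9))
    def test_tpm_invariant_under_sample_scaling(self, factor):
        counts = pd.DataFrame({"s1": [3, 9, 1], "s2": [5, 0, 2]}, index=list("abc"))
        em = self.make_matrix(counts, pd.Series({"a": 50, "b": 150, "c": 200}))
        t1 = quantify.compute_tpm(em).values
        em2 = self.make_matrix(counts * factor, em.lengths)
        t2 = quantify.compute_tpm(em2).values
        np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy(), rtol=1e-12)


class TestPca:
    def test_identical_samples_degenerate(self):
        counts = pd.DataFrame({"s1": [5, 5], "s2": [5, 5]}, index=["a", "b"])
        sheet = pd.DataFrame({"tissue": ["t", "t"], "replicate": [1, 2]}, index=["s1", "s2"])
        em = quantify.ExpressionMatrix(
            counts.astype(float), pd.Series({"a": 1, "b": 1}), sheet, "tpm"
        )
        coords, varfrac = quantify.pca_report(em)
        assert coords["PC1"]["s1"] == pytest.approx(coords["PC1"]["s2"])
        assert varfrac.sum() == 0

    def test_matches_sklearn_eigendecomposition(self, sim):
        """Coordinates agree (up to the fixed sign convention) with sklearn PCA."""
        from sklearn.decomposition import PCA

        tpm = quantify.compute_tpm(sim.erv_counts)
        coords, varfrac = quantify.pca_report(tpm)
        X = np.log2(tpm.values.to_numpy(float).T + 1)
        ref = PCA(n_components=2, svd_solver="full").fit(X)
        ref_coords = ref.transform(X)
        for k in range(2):
            got = coords[f"PC{k+1}"].to_numpy()
            assert np.allclose(got, ref_coords[:, k], atol=1e-8) or np.allclose(
                got, -ref_coords[:, k], atol=1e-8
            )
        np.testing.assert_allclose(varfrac, ref.explained_variance_ratio_, atol=1e-8)

    def test_replicates_cluster_by_tissue(self, sim):
        """Replicates of one tissue are mutual nearest neighbours in PC1-2."""
        tpm = quantify.compute_tpm(sim.erv_counts)
        coords, _ = quantify.pca_report(tpm)
        xy = coords[["PC1", "PC2"]].to_numpy()
        tissue = coords["tissue"].to_numpy()
        for i in range(len(xy)):
            d = np.linalg.norm(xy - xy[i], axis=1)
            d[i] = np.inf
            assert tissue[int(np.argmin(d))] == tissue[i]

    def test_sign_convention_is_deterministic(self, sim):
        tpm = quantify.compute_tpm(sim.erv_counts)
        c1, _ = quantify.pca_report(tpm)
        c2, _ = quantify.pca_report(tpm)
        pd.testing.assert_frame_equal(c1, c2)
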