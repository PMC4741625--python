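"""MATCH-style scoring, promoter extraction, scanning, gene sets, enrichment."""

import math
from math import comb, log

import numpy as np
import pytest

from mycnet import pwm as pw
from mycnet.pwm import (
    PWM,
    PWMError,
    PromoterRecord,
    build_gene_sets,
    extract_promoters,
    load_pwms,
    match_score,
    matrix_enrichment,
    reverse_complement,
    scan_promoters,
    scan_sequence,
)
from mycnet.simulate import simulate_pwm_library

BASES = "ACGT"


def write_jaspar(path, matrices):
    """matrices: list of (id, name, counts array Lx4)."""
    with open(path, "w") as fh:
        for mid, name, counts in matrices:
            fh.write(f">{mid} {name}\n")
            for bi, base in enumerate(BASES):
                fh.write(f"{base} [ " + " ".join(str(int(c[bi])) for c in counts) + " ]\n")


def brute_mss_css(pwm, window):
    """Straight-line reimplementation of the information-vector score."""
    def info(row):
        return sum(f * log(4 * f) for f in row if f > 0)

    def score(rows, chars):
        iv = [info(r) for r in rows]
        cur = sum(
            i * (min(r) if c == "N" else r[BASES.index(c)])
            for i, r, c in zip(iv, rows, chars)
        )
        mn = sum(i * min(r) for i, r in zip(iv, rows))
        mx = sum(i * max(r) for i, r in zip(iv, rows))
        return 1.0 if mx == mn else (cur - mn) / (mx - mn)

    rows = [list(r) for r in pwm.freq]
    core = slice(pwm.core_start, pwm.core_start + 5)
    return score(rows, window), score(rows[core], window[core])


class TestLoad:
    def test_pure_counts_no_pseudocount(self, tmp_path):
        counts = np.array([[10, 0, 0, 0]] * 6)
        write_jaspar(tmp_path / "m.jaspar", [("M1", "tf", counts)])
        (p,) = load_pwms(tmp_path / "m.jaspar", pseudocount=0)
        assert np.allclose(p.freq, np.tile([1, 0, 0, 0], (6, 1)))
        assert p.consensus == "AAAAAA"

    def test_half_half_information(self, tmp_path):
        counts = np.array([[5, 5, 0, 0]] * 5)
        write_jaspar(tmp_path / "m.jaspar", [("M1", "tf", counts)])
        (p,) = load_pwms(tmp_path / "m.jaspar", pseudocount=0)
        assert np.allclose(p.freq[:, :2], 0.5)
        # I = sum f ln 4f = 2 * 0.5 * ln 2
        assert p.info_vector == pytest.approx([math.log(2)] * 5)

    def test_short_matrix_rejected(self, tmp_path):
        write_jaspar(tmp_path / "m.jaspar", [("M1", "tf", np.array([[4, 1, 1, 1]] * 4))])
        with pytest.raises(PWMError, match="length"):
            load_pwms(tmp_path / "m.jaspar")

    def test_zero_column_rejected(self, tmp_path):
        counts = np.array([[4, 1, 1, 1]] * 6)
        counts[2] = 0
        write_jaspar(tmp_path / "m.jaspar", [("M1", "tf", counts)])
        with pytest.raises(PWMError, match="zero total"):
            load_pwms(tmp_path / "m.jaspar")

    def test_core_is_most_informative_window(self):
        # informative positions 3..7, uniform elsewhere -> core starts at 3
        freq = np.full((10, 4), 0.25)
        freq[3:8] = [0.97, 0.01, 0.01, 0.01]
        p = PWM(id="m", tf_name="t", freq=freq)
        assert p.core_start == 3

    def test_core_tie_leftmost(self):
        freq = np.full((8, 4), 0.25)  # all windows tie
        p = PWM(id="m", tf_name="t", freq=freq)
        assert p.core_start == 0


class TestMatchScore:
    @pytest.fixture(scope="class")
    def library(self):
        return simulate_pwm_library(6, seed=9)

    def test_consensus_and_anticonsensus(self, library):
        for p in library:
            consensus = p.consensus
            anti = "".join(BASES[i] for i in p.freq.argmin(axis=1))
            assert match_score(p, consensus) == (pytest.approx(1.0), pytest.approx(1.0))
            mss, css = match_score(p, anti)
            assert mss == pytest.approx(0.0)
            assert css == pytest.approx(0.0)

    def test_exhaustive_windows_match_brute_force(self):
        freq = np.array(
            [
                [0.7, 0.1, 0.1, 0.1],
                [0.1, 0.4, 0.4, 0.1],
                [0.25, 0.25, 0.25, 0.25],
                [0.05, 0.05, 0.85, 0.05],
                [0.3, 0.3, 0.2, 0.2],
            ]
        )
        p = PWM(id="toy", tf_name="toy", freq=freq)
        for idx in range(4**5):
            window = "".join(BASES[(idx // 4**k) % 4] for k in range(5))
            assert match_score(p, window) == pytest.approx(brute_mss_css(p, window))

    def test_scores_in_unit_interval(self, library):
        rng = np.random.default_rng(0)
        for p in library:
            for _ in range(50):
                w = "".join(rng.choice(list("ACGTN"), size=len(p)))
                mss, css = match_score(p, w)
                assert 0 <= mss <= 1 and 0 <= css <= 1

    def test_lower_frequency_base_never_increases_mss(self, library):
        rng = np.random.default_rng(1)
        p = library[2]
        for _ in range(50):
            codes = rng.integers(0, 4, size=len(p))
            w = "".join(BASES[c] for c in codes)
            i = rng.integers(0, len(p))
            worse = [b for b in range(4) if p.freq[i, b] < p.freq[i, codes[i]]]
            if not worse:
                continue
            codes2 = codes.copy()
            codes2[i] = worse[0]
            w2 = "".join(BASES[c] for c in codes2)
            assert match_score(p, w2)[0] <= match_score(p, w)[0] + 1e-12

    def test_length_mismatch_fatal(self, library):
        with pytest.raises(PWMError, match="length"):
            match_score(library[0], "ACGT")

    def test_degenerate_matrix_scores_one(self):
        p = PWM(id="flat", tf_name="flat", freq=np.full((6, 4), 0.25))
        assert match_score(p, "ACGTAC") == (1.0, 1.0)


class TestScan:
    def test_planted_ebox_hits_both_strands(self):
        lib = simulate_pwm_library(1, seed=0)
        ebox = lib[0]
        seq = "A" * 40 + "CACGTG" + "T" * 40
        hits = scan_sequence(ebox, seq)
        assert (40, "+") in {(h[0], h[1]) for h in hits}
        # palindromic consensus also matches the minus strand at the same locus
        assert (40, "-") in {(h[0], h[1]) for h in hits}

    def test_all_n_promoter_no_hits(self):
        lib = simulate_pwm_library(3, seed=2)
        proms = [PromoterRecord("g", "c", "+", 0, "N" * 200)]
        assert scan_promoters(lib, proms) == []

    def test_scan_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        lib = simulate_pwm_library(3, seed=5)
        for _ in range(15):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            for p in lib:
                got = {(h[0], h[1]): (h[2], h[3]) for h in scan_sequence(p, seq)}
                expected = {}
                for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                    for off in range(len(s) - len(p) + 1):
                        mss, css = brute_mss_css(p, s[off : off + len(p)])
                        if mss >= p.matrix_cutoff and css >= p.core_cutoff:
                            plus = off if strand == "+" else len(seq) - len(p) - off
                            expected[(plus, strand)] = (mss, css)
                assert got.keys() == expected.keys()
                for key, (mss, css) in expected.items():
                    assert got[key] == (pytest.approx(mss), pytest.approx(css))

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(6)
        lib = simulate_pwm_library(2, seed=6)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        p = lib[1]
        fwd = scan_sequence(p, seq)
        rev = scan_sequence(p, reverse_complement(seq))
        flip = {"+": "-", "-": "+"}
        mirrored = {(len(seq) - len(p) - off, flip[st], round(m, 9), round(c, 9))
                    for off, st, m, c in rev}
        assert {(o, s, round(m, 9), round(c, 9)) for o, s, m, c in fwd} == mirrored

    def test_short_promoter_skipped_with_warning(self):
        lib = simulate_pwm_library(1, seed=1)
        proms = [PromoterRecord("g", "c", "+", 0, "ACG")]
        with pytest.warns(UserWarning, match="shorter"):
            assert scan_promoters(lib, proms) == []


class TestExtractPromoters:
    @pytest.fixture
    def genome(self, tmp_path):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=10000))
        fasta = tmp_path / "genome.fa"
        with open(fasta, "w") as fh:
            fh.write(">chr1\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
        return fasta, seq

    def _annotate(self, tmp_path, rows):
        ann = tmp_path / "ann.tsv"
        with open(ann, "w") as fh:
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")
        return ann

    def test_plus_strand_window(self, tmp_path, genome):
        fasta, seq = genome
        ann = self._annotate(tmp_path, [("chr1", 5000, "+", "gene1")])
        (rec,) = extract_promoters(fasta, ann)
        assert rec.seq == seq[4000:5100].upper()
        assert len(rec.seq) == 1100

    def test_minus_strand_window(self, tmp_path, genome):
        fasta, seq = genome
        ann = self._annotate(tmp_path, [("chr1", 5000, "-", "gene1")])
        (rec,) = extract_promoters(fasta, ann)
        assert rec.seq == reverse_complement(seq[4900:6000].upper())

    def test_left_edge_padded(self, tmp_path, genome):
        fasta, seq = genome
        ann = self._annotate(tmp_path, [("chr1", 500, "+", "gene1")])
        (rec,) = extract_promoters(fasta, ann)
        assert rec.seq == "N" * 500 + seq[0:600].upper()
        assert len(rec.seq) == 1100

    def test_unknown_chromosome_skipped(self, tmp_path, genome):
        fasta, _ = genome
        ann = self._annotate(tmp_path, [("chrX", 5000, "+", "gene1")])
        with pytest.warns(UserWarning, match="unknown chromosome"):
            assert extract_promoters(fasta, ann) == []

    def test_malformed_strand_fatal(self, tmp_path, genome):
        fasta, _ = genome
        ann = self._annotate(tmp_path, [("chr1", 5000, "*", "gene1")])
        with pytest.raises(PWMError, match="strand"):
            extract_promoters(fasta, ann)


class TestGeneSets:
    def _hits(self, pairs):
        return [pw.SiteHit(g, m, 0, "+", 0.95, 0.95) for g, m in pairs]

    def test_background_exhausted_fatal(self):
        genes = ["a", "b", "c"]
        hits = self._hits([(g, "MYC") for g in genes])
        with pytest.raises(PWMError, match="background exhausted"):
            build_gene_sets(genes, [], [], ["MYC"], hits)

    def test_set_arithmetic_against_enumeration(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(100)]
        myc_carriers = set(rng.choice(genes, size=30, replace=False))
        degs = set(rng.choice(genes, size=10, replace=False))
        hits = self._hits([(g, "MYC") for g in myc_carriers])
        sets = build_gene_sets(genes, degs, [], ["MYC"], hits)
        expected_no = {g for g in genes if g not in degs and g not in myc_carriers}
        assert sets.no_set == expected_no
        assert sets.yes_set == degs
        assert not sets.yes_set & sets.no_set

    def test_subcutoff_match_stays_in_background(self):
        # hits list only ever contains supra-cutoff matches, so a gene whose
        # best E-box-like site scored below cutoff has no hit entries at all
        sets = build_gene_sets(["a", "b"], ["a"], [], ["MYC"], [])
        assert "b" in sets.no_set

    def test_background_filter_removes_regulated(self):
        sets = build_gene_sets(["a", "b", "c"], ["a"], ["b"], ["MYC"], [])
        assert sets.no_set == {"c"}


class TestEnrichment:
    def _pwm(self, pid):
        return PWM(id=pid, tf_name=pid, freq=np.tile([0.97, 0.01, 0.01, 0.01], (6, 1)))

    def test_equal_proportions_not_enriched(self):
        yes = {f"y{i}" for i in range(10)}
        no = {f"n{i}" for i in range(10)}
        # every gene a carrier: the over-representation tail is the whole mass
        hits = [pw.SiteHit(g, "M", 0, "+", 0.9, 0.9) for g in yes | no]
        table = matrix_enrichment([self._pwm("M")], hits, yes, no)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)
        assert not table.loc[0, "enriched"]
        # matched intermediate proportions are not enriched either
        hits = [pw.SiteHit(g, "M", 0, "+", 0.9, 0.9) for g in sorted(yes)[:5] + sorted(no)[:5]]
        table = matrix_enrichment([self._pwm("M")], hits, yes, no)
        assert table.loc[0, "p_value"] > 0.5
        assert not table.loc[0, "enriched"]

    def test_fisher_matches_hypergeometric_tail(self):
        yes = {f"y{i}" for i in range(27)}
        no = {f"n{i}" for i in range(1000)}
        carriers = list(yes)[:20] + list(no)[:100]
        hits = [pw.SiteHit(g, "M", 0, "+", 0.9, 0.9) for g in carriers]
        table = matrix_enrichment([self._pwm("M")], hits, yes, no)
        # tail P(X >= 20) for X ~ Hypergeom(N=1027, K=120, n=27), exact
        N, K, n = 1027, 120, 27
        p_tail = sum(comb(K, k) * comb(N - K, n - k) for k in range(20, n + 1)) / comb(N, n)
        assert table.loc[0, "p_value"] == pytest.approx(p_tail, rel=1e-9)

    def test_no_hits_p_one(self):
        table = matrix_enrichment([self._pwm("M")], [], {"y"}, {"n1", "n2"})
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_empty_yes_fatal(self):
        with pytest.raises(PWMError, match="YES"):
            matrix_enrichment([self._pwm("M")], [], set(), {"n"})


class TestPlantedRecovery:
    def test_planted_instances_recovered(self):
        # motifs planted from the matrix at probability 1 scan positive at the
        # default cutoffs in >= 99% of instances
        from mycnet.simulate import PlantingSpec, simulate_promoters

        lib = simulate_pwm_library(3, seed=21)
        genes = [f"g{i}" for i in range(60)]
        planting = {lib[0].id: PlantingSpec(genes=tuple(genes), probability=1.0, score_floor=0.9)}
        proms, truth = simulate_promoters(genes, lib, planting, seed=21)
        hits = scan_promoters([lib[0]], proms)
        found = {(h.gene_id, h.offset) for h in hits}
        planted = {(m["gene"], m["offset"]) for m in truth.planted_motifs}
        recovered = sum(1 for key in planted if key in found)
        assert recovered / len(planted) >= 0.99
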