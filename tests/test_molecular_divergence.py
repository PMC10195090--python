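import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import hybridreg as hr
from hybridreg.molecular_divergence import BASES, translate_codon

# --- independent brute-force oracle (Biopython translation) ----------------

def oracle_translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str):
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if oracle_translate(mut) == oracle_translate(codon):
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def oracle_path_counts(c1: str, c2: str):
    """Recursive enumeration of stop-free minimal mutational paths."""
    results = []

    def rec(cur, remaining, syn, nonsyn):
        if not remaining:
            results.append((syn, nonsyn))
            return
        for i in remaining:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if oracle_translate(nxt) == "*":
                continue
            step_syn = oracle_translate(nxt) == oracle_translate(cur)
            rec(nxt, [j for j in remaining if j != i],
                syn + step_syn, nonsyn + (not step_syn))

    rec(c1, [i for i in range(3) if c1[i] != c2[i]], 0, 0)
    if not results:
        return None
    return (float(np.mean([r[0] for r in results])),
            float(np.mean([r[1] for r in results])))


def oracle_kaks(s1: str, s2: str):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i:i + 3], s2[i:i + 3]
        counts = oracle_path_counts(c1, c2)
        if counts is None:
            continue
        sa, na = oracle_sites(c1)
        sb, nb = oracle_sites(c2)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += counts[0]
        Nd += counts[1]
    jc = lambda p: None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(Nd / N), jc(Sd / S)


def random_cds(n_codons: int, rng) -> str:
    out = []
    while len(out) < n_codons:
        c = "".join(rng.choice(list(BASES), 3))
        if translate_codon(c) != "*":
            out.append(c)
    return "".join(out)


def mutated_copy(seq: str, n_diffs: int, rng) -> str:
    s = list(seq)
    done = 0
    while done < n_diffs:
        i = int(rng.integers(len(s)))
        b = rng.choice([x for x in "TCAG" if x != s[i]])
        old = s[i]
        s[i] = b
        start = (i // 3) * 3
        if translate_codon("".join(s[start:start + 3])) == "*":
            s[i] = old
            continue
        done += 1
    return "".join(s)


class TestSnpLevel:
    @pytest.mark.parametrize("f, o, d", [(1.0, 0.0, 1.0), (0.5, 0.5, 0.0),
                                         (0.9, 0.2, 0.7)])
    def test_differentiation_index(self, f, o, d):
        assert hr.snp_d(f, o) == pytest.approx(d)

    def test_out_of_range_frequency_errors(self):
        with pytest.raises(ValueError):
            hr.snp_d(1.2, 0.5)

    @pytest.mark.parametrize("ds,expected", [
        ([1.0, 1.0, 0.3, 0.4], 0.5),
        ([1.0, 1.0], 1.0),
        ([0.2, 0.4, 0.1], 0.0),
    ])
    def test_dxy_fixed_fraction(self, ds, expected):
        assert hr.dxy(ds) == pytest.approx(expected)

    def test_dxy_empty_is_undefined_and_order_invariant(self):
        assert hr.dxy([]) is None
        ds = [1.0, 0.2, 1.0, 0.5]
        assert hr.dxy(ds) == hr.dxy(ds[::-1])

    def test_dxy_table_excludes_low_maf_noise(self):
        t = pd.DataFrame({
            "transcript_id": ["a"] * 3,
            "position": [1, 2, 3],
            "freq_frat": [1.0, 0.01, 0.5],
            "freq_obliq": [0.0, 0.005, 0.5],
        })
        t["d"] = (t.freq_frat - t.freq_obliq).abs()
        out = hr.dxy_table(t)
        # the near-monomorphic same-allele SNP is dropped: 1 fixed of 2
        assert out["a"] == pytest.approx(0.5)


class TestSites:
    def test_phenylalanine_codon_fractional_sites(self):
        s, n = hr.ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_sites_sum_to_sequence_length(self):
        cds = random_cds(40, np.random.default_rng(1))
        s, n = hr.ng86_sites(cds)
        assert s + n == pytest.approx(len(cds), abs=1e-9)

    def test_random_codons_match_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            codon = random_cds(1, rng)
            got = hr.ng86_sites(codon)
            want = oracle_sites(codon)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_length_not_multiple_of_three_errors(self):
        with pytest.raises(ValueError):
            hr.ng86_sites("TTTA")

    def test_internal_stop_errors(self):
        with pytest.raises(ValueError, match="stop"):
            hr.ng86_sites("TAATTT")

    def test_terminal_stop_tolerated_and_excluded(self):
        s, n = hr.ng86_sites("TTTTAA")
        assert s + n == pytest.approx(3.0)

    def test_ambiguous_codon_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            s, n = hr.ng86_sites("TTTNNN")
        assert s + n == pytest.approx(3.0)


class TestKaKs:
    def test_identical_sequences_have_zero_rates(self):
        cds = random_cds(30, np.random.default_rng(3))
        rec = hr.kaks_ng86(cds, cds)
        assert rec.Ka == 0.0 and rec.Ks == 0.0
        assert rec.ka_ks is None  # Ks = 0

    def test_single_nonsynonymous_change(self):
        a = "TTT" * 20
        b = "GTT" + "TTT" * 19  # F -> V
        rec = hr.kaks_ng86(a, b)
        assert rec.Ka > 0 and rec.Ks == 0.0
        assert rec.ka_ks is None

    def test_random_pairs_match_pathway_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n_codons = int(rng.integers(5, 31))
            a = random_cds(n_codons, rng)
            b = mutated_copy(a, int(rng.integers(1, 4)), rng)
            rec = hr.kaks_ng86(a, b)
            ka, ks = oracle_kaks(a, b)
            assert rec.Ka == pytest.approx(ka, abs=1e-9)
            assert rec.Ks == pytest.approx(ks, abs=1e-9)

    def test_symmetric_in_sequence_order(self):
        rng = np.random.default_rng(5)
        a = random_cds(25, rng)
        b = mutated_copy(a, 5, rng)
        ab, ba = hr.kaks_ng86(a, b), hr.kaks_ng86(b, a)
        assert ab.Ka == pytest.approx(ba.Ka, abs=1e-12)
        assert ab.Ks == pytest.approx(ba.Ks, abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="lengths"):
            hr.kaks_ng86("TTT", "TTTTTT")

    def test_neutral_divergence_gives_unit_ratio(self):
        """Uniform random substitutions (no selection) drive Ka/Ks to 1."""
        rng = np.random.default_rng(6)
        ratios = []
        for _ in range(12):
            a = random_cds(800, rng)
            b = mutated_copy(a, 50, rng)
            rec = hr.kaks_ng86(a, b)
            if rec.ka_ks is not None:
                ratios.append(rec.ka_ks)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)


class TestFastaPlumbing:
    def test_pair_reading_and_table(self, tmp_path):
        rng = np.random.default_rng(8)
        a = random_cds(20, rng)
        b = mutated_copy(a, 2, rng)
        fasta = tmp_path / "cds.fasta"
        fasta.write_text(f">t1_frat\n{a}\n>t1_obliq\n{b}\n")
        pairs = hr.read_cds_pairs(fasta)
        assert pairs == {"t1": (a, b)}
        table = hr.divergence_table(pairs)
        assert table.loc["t1", "Ka"] == pytest.approx(
            hr.kaks_ng86(a, b).Ka or 0.0)

    def test_missing_partner_errors(self, tmp_path):
        fasta = tmp_path / "cds.fasta"
        fasta.write_text(">t1_frat\nTTTTTT\n")
        with pytest.raises(ValueError, match="missing one species"):
            hr.read_cds_pairs(fasta)

    def test_bad_suffix_errors(self, tmp_path):
        fasta = tmp_path / "cds.fasta"
        fasta.write_text(">t1\nTTTTTT\n")
        with pytest.raises(ValueError, match="suffix"):
            hr.read_cds_pairs(fasta)
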