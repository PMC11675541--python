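"""Ka/Ks, age classes, orthology, origination rates and the traffic test."""

import itertools
import math

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from retrokit.alignment_engine import CodonAlignment
from retrokit import molecular_evolution as me

CODON_AA = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    CODON_AA[stop] = "*"
NONSTOP = sorted(c for c, a in CODON_AA.items() if a != "*")


# ---------------------------------------------------------------------------
# brute-force NG86 oracle (built first; frozen expectations come from it)
# ---------------------------------------------------------------------------

def oracle_sites(codon):
    aa = CODON_AA[codon]
    syn = 0.0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1:]
        if CODON_AA[alt] == aa and CODON_AA[alt] != "*":
            syn += 1 / 3
    return 3 - syn, syn


def oracle_diffs(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    pathways, blocked = [], []
    for order in itertools.permutations(positions):
        nd = sd = 0.0
        cur = c1
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_AA[nxt] == "*" and nxt != c2:
                through_stop = True
            if CODON_AA[nxt] == CODON_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else pathways).append((nd, sd))
    use = pathways or blocked
    return (sum(p[0] for p in use) / len(use),
            sum(p[1] for p in use) / len(use))


def oracle_ng86(seq_a, seq_b):
    N = S = nd = sd = 0.0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        if "*" in (CODON_AA[ca], CODON_AA[cb]):
            continue
        na, sa = oracle_sites(ca)
        nb, sb = oracle_sites(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        d = oracle_diffs(ca, cb)
        nd += d[0]
        sd += d[1]
    if N == 0 and S == 0:
        return "no-pairs", None, 0.0, 0.0
    pn = nd / N if N else 0.0
    ps = sd / S if S else 0.0   # e.g. a lone Trp/Met codon has no syn sites
    ka = None if pn >= 0.75 else -0.75 * math.log(1 - 4 * pn / 3)
    ks = None if ps >= 0.75 else -0.75 * math.log(1 - 4 * ps / 3)
    return ka, ks, N, S


class TestNG86:
    def test_identical_pair_is_zero_with_undefined_ratio(self):
        res = me.ng86_kaks(CodonAlignment("ATGAAAGTTCTTGAA" * 2,
                                          "ATGAAAGTTCTTGAA" * 2))
        assert res.ka == 0.0 and res.ks == 0.0
        assert res.ratio is None          # the "NA" convention

    def test_single_synonymous_change(self):
        res = me.ng86_kaks(CodonAlignment("ATGAAAGTTCTTGAAGGG",
                                          "ATGAAGGTTCTTGAAGGG"))  # AAA->AAG
        assert res.ka == 0.0
        assert res.ks > 0.0
        assert res.ratio == 0.0

    def test_single_nonsynonymous_change(self):
        res = me.ng86_kaks(CodonAlignment("ATGAAAGTTCTTGAAGGG",
                                          "ATGGAAGTTCTTGAAGGG"))  # K->E
        assert res.ks == 0.0 and res.ka > 0.0
        assert res.ratio is None

    def test_site_decomposition_sums_to_three_per_codon(self):
        rng = np.random.default_rng(0)
        seq = "".join(NONSTOP[i] for i in rng.integers(0, len(NONSTOP), 20))
        res = me.ng86_kaks(CodonAlignment(seq, seq))
        assert res.n_sites + res.s_sites == pytest.approx(3 * 20)

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_pathway_enumeration_oracle(self, trial):
        """Exact agreement with the brute-force oracle on <=4-codon pairs."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(1, 5))
        a = [NONSTOP[i] for i in rng.integers(0, len(NONSTOP), n)]
        b = []
        for c in a:
            cl = list(c)
            for pos in range(3):
                if rng.random() < 0.3:
                    cl[pos] = "ACGT"[rng.integers(0, 4)]
            cand = "".join(cl)
            b.append(cand if CODON_AA[cand] != "*" else c)
        sa, sb = "".join(a), "".join(b)
        ka_o, ks_o, N_o, S_o = oracle_ng86(sa, sb)
        if ka_o == "no-pairs":
            with pytest.raises(ValueError):
                me.ng86_kaks(CodonAlignment(sa, sb))
            return
        res = me.ng86_kaks(CodonAlignment(sa, sb))
        assert res.n_sites == pytest.approx(N_o, abs=1e-9)
        assert res.s_sites == pytest.approx(S_o, abs=1e-9)
        if ka_o is None:
            assert res.saturated
        else:
            assert res.ka == pytest.approx(ka_o, abs=1e-9)
        if ks_o is None:
            assert res.saturated
        else:
            assert res.ks == pytest.approx(ks_o, abs=1e-9)

    def test_gap_and_stop_codons_excluded(self):
        res = me.ng86_kaks(CodonAlignment("ATG---AAATAA", "ATGCCCAAAGGG"))
        # only ATG/ATG and AAA/AAA compare; stops and gaps skipped
        assert res.ka == 0.0 and res.ks == 0.0

    def test_empty_alignment_errors(self):
        with pytest.raises(ValueError):
            me.ng86_kaks(CodonAlignment("---", "ATG"))

    def test_ks_monotone_under_added_synonymous_changes(self):
        base = "ATGAAAGTTCTTGAAGGTCATTATCAATGT" * 3
        # third positions of Leu CTT -> CTC etc., applied cumulatively
        syn_sites = [9 * k + 8 for k in range(8)]  # CTT codons? use set below
        seq = list(base)
        prev = 0.0
        changed = []
        for k in range(0, len(base) - 3, 15):
            codon_start = (k // 3) * 3
            c = base[codon_start : codon_start + 3]
            # pick a synonymous third-position variant when one exists
            for alt in "ACGT":
                cand = c[:2] + alt
                if cand != c and CODON_AA.get(cand) == CODON_AA.get(c):
                    seq[codon_start + 2] = alt
                    break
            res = me.ng86_kaks(CodonAlignment(base, "".join(seq)))
            assert res.ks >= prev - 1e-12
            prev = res.ks

    def test_parameter_recovery_at_synonymous_divergence(self):
        """Pairs simulated at synonymous-site divergence d recover ks ~ d."""
        rng = np.random.default_rng(9)
        d = 0.3
        p_change = 0.75 * (1 - math.exp(-4 * d / 3))
        seq_a = []
        seq_b = []
        fourfold = [c for c in NONSTOP
                    if all(CODON_AA[c[:2] + x] == CODON_AA[c] for x in "ACGT")]
        for _ in range(400):
            c = fourfold[rng.integers(0, len(fourfold))]
            seq_a.append(c)
            if rng.random() < p_change:
                alt = "ACGT"[rng.integers(0, 4)]
                seq_b.append(c[:2] + alt if alt != c[2] else c)
            else:
                seq_b.append(c)
        res = me.ng86_kaks(CodonAlignment("".join(seq_a), "".join(seq_b)))
        ps = res.sd / res.s_sites
        se = math.sqrt(ps * (1 - ps) / res.s_sites) / (1 - 4 * ps / 3)
        assert abs(res.ks - d) < 3 * se + 0.25 * d * (3 / 4)  # JC process noise
        assert res.ka < 0.05  # only 4-fold third positions were mutated


class TestAgeAndConstraint:
    @pytest.mark.parametrize("ks,expected", [
        (1.9, "young"), (2.0, "old"), (0.0, "young"), (3.5, "old"),
        (None, "unclassified"), (float("nan"), "unclassified"),
    ])
    def test_age_boundary(self, ks, expected):
        assert me.classify_age(ks) == expected

    def test_constraint_shares_from_published_style_counts(self):
        out = me.selective_constraint_summary(1761, 1904, 66, 89, n_total=1993)
        assert out["intact_lt_half_pct"] == 92.5
        assert out["pseudo_lt_half_pct"] == 74.2
        assert out["overall_lt_half_pct"] == 91.7


class TestOrthology:
    def test_identical_sequences_orthologous(self):
        rng = np.random.default_rng(2)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        pairs, sa, sb = me.find_orthologs({"a1": s}, {"b1": s})
        assert len(pairs) == 1 and not sa and not sb

    def test_seventy_percent_identity_not_orthologous(self):
        rng = np.random.default_rng(3)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        b = list(s)
        for i in rng.choice(300, size=90, replace=False):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        pairs, sa, sb = me.find_orthologs({"a1": s}, {"b1": "".join(b)})
        assert not pairs
        assert sa == {"a1"} and sb == {"b1"}

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        seqs = {
            f"x{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 200))
            for i in range(3)
        }
        other = {f"y{i}": s for i, s in enumerate(seqs.values())}
        p1, _, _ = me.find_orthologs(seqs, other)
        p2, _, _ = me.find_orthologs(other, seqs)
        assert {(p.retro_id_a, p.retro_id_b) for p in p1} == \
               {(p.retro_id_b, p.retro_id_a) for p in p2}

    def test_reverse_complement_counterpart_found(self):
        from Bio.Seq import Seq
        rng = np.random.default_rng(5)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        pairs, _, _ = me.find_orthologs(
            {"a": s}, {"b": str(Seq(s).reverse_complement())})
        assert len(pairs) == 1


TREE = "((((mori,mandarina)bombyx,sexta)bombycoidea,(litura,frugiperda)spodoptera),(ni,anynana),xylostella)root;"


class TestOriginBranches:
    def test_all_species_traces_to_root(self):
        leaves = ["mori", "mandarina", "sexta", "litura", "frugiperda",
                  "ni", "anynana", "xylostella"]
        assert me.assign_origin_branch(leaves, TREE) == "root"

    def test_single_species_is_terminal_branch(self):
        assert me.assign_origin_branch(["mori"], TREE) == "mori"

    def test_sister_pair_maps_to_their_ancestor(self):
        assert me.assign_origin_branch(["mori", "mandarina"], TREE) == "bombyx"

    def test_empty_presence_errors(self):
        with pytest.raises(ValueError):
            me.assign_origin_branch([], TREE)

    def test_unknown_species_errors(self):
        with pytest.raises(ValueError, match="not in tree"):
            me.assign_origin_branch(["yeti"], TREE)


class TestOriginationRates:
    def test_published_style_rows(self):
        branches, mean = me.origination_rates([
            ("b8", 14, 42.0), ("b7", 2, 3.0), ("b6", 13, 44.0),
            ("b5", 34, 51.0), ("b4", 73, 43.1), ("b3", 81, 66.99),
        ])
        by_id = {b.branch_id: b.rate for b in branches}
        assert by_id["b8"] == 0.333
        assert by_id["b3"] == 1.209
        assert mean == 0.811

    def test_zero_count_zero_rate(self):
        branches, mean = me.origination_rates([("b", 0, 10.0)])
        assert branches[0].rate == 0.0

    def test_counts_conserved(self):
        rows = [("a", 5, 10.0), ("b", 7, 14.0)]
        branches, _ = me.origination_rates(rows)
        assert sum(b.count for b in branches) == 12

    def test_bad_period_errors(self):
        with pytest.raises(ValueError):
            me.origination_rates([("a", 5, 0.0)])


class TestMovement:
    def _uniform_census(self):
        return me.ChromosomeCensus(
            {"chr1": "A", "chr2": "A", "chrZ": "Z"},
            {"chr1": 10, "chr2": 10, "chrZ": 10},
            {"chr1": 1000, "chr2": 1000, "chrZ": 1000},
        )

    def test_uniform_toy_closed_form(self):
        # each ordered pair gets T * (1/3) * (1/2) = 5 expected events
        exp = me.expected_movements(self._uniform_census(), 30)
        assert exp["A→A"] == pytest.approx(10.0)
        assert exp["A→Z"] == pytest.approx(10.0)
        assert exp["Z→A"] == pytest.approx(10.0)
        assert sum(exp.values()) == pytest.approx(30.0)

    def test_zero_events_all_zero(self):
        exp = me.expected_movements(self._uniform_census(), 0)
        assert all(v == 0 for v in exp.values())

    def test_all_genes_on_z_gives_no_autosomal_sources(self):
        census = me.ChromosomeCensus(
            {"chr1": "A", "chrZ": "Z"},
            {"chr1": 1, "chrZ": 100},
            {"chr1": 1000, "chrZ": 1000},
        )
        exp = me.expected_movements(census, 101)
        assert exp["A→Z"] == pytest.approx(101 * (1 / 101) * 1.0)
        assert exp["Z→A"] > exp["A→Z"]

    def test_missing_class_errors(self):
        census = me.ChromosomeCensus({"c": "A"}, {"c": 1}, {"other": 1})
        with pytest.raises(ValueError):
            me.expected_movements(census, 10)

    @pytest.mark.parametrize("expected,observed,excess", [
        (8, 12, 50.0), (200, 197, -1.5), (7, 7, 0.0), (7, 6, -14.29),
    ])
    def test_excess_percentages(self, expected, observed, excess):
        assert me.movement_excess(expected, observed) == pytest.approx(excess)

    def test_zero_expected_flagged(self):
        with pytest.raises(ValueError):
            me.movement_excess(0, 5)


class TestPackagedExamples:
    def test_period_table_reproduces_mean_rate(self):
        branches, mean = me.origination_rates(me.example_period_table())
        assert mean == 0.811

    def test_species_tree_parses_and_roots(self):
        tree = me.example_species_tree()
        assert me.assign_origin_branch(["B_mori", "B_mandarina"], tree) == "bombyx"
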