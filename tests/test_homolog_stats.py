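"""Hit filtering, group averages, permutation scheme, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tapslivr.homolog_stats import (
    HomologHit,
    SpeciesMeta,
    filter_hits,
    group_average_ratio,
    multicellular_compare,
    permutation_ratio_test,
    phylum_normalize,
    presence_screen,
    read_blast_tab,
    species_hit_matrix,
    trna_spearman,
)
from tapslivr.lcr_detect import ScanParams
from tapslivr.seq_core import ProteinRecord
from tapslivr.synthetic_data import gen_homolog_data


def hit(q, s, sp, ev=1e-5, ov=0.5):
    return HomologHit(query_id=q, subject_id=s, species_id=sp, evalue=ev, overlap_fraction=ov)


def meta_entry(sid, domain="Bacteria", phylum="P", mc=None, a34=0, div=0):
    return SpeciesMeta(sid, domain, phylum, mc, a34, div)


@pytest.fixture
def simple_meta():
    return {
        "pk1": meta_entry("pk1"),
        "pk2": meta_entry("pk2"),
        "eu1": meta_entry("eu1", "Eukarya", "Chordata", "multicellular", 40, 8),
        "eu2": meta_entry("eu2", "Eukarya", "Ascomycota", "unicellular", 10, 8),
    }


class TestFilterHits:
    def test_evalue_cutoff(self):
        assert filter_hits([hit("q", "s", "sp", ev=0.05)]) == []

    def test_overlap_threshold(self):
        assert filter_hits([hit("q", "s", "sp", ev=0.001, ov=0.10)]) == []

    def test_passing_hit_kept(self):
        h = hit("q", "s", "sp", ev=0.001, ov=0.5)
        assert filter_hits([h]) == [h]

    def test_boundaries_inclusive(self):
        kept = filter_hits([hit("q", "s", "sp", ev=0.01, ov=0.20)])
        assert len(kept) == 1

    def test_cap_applied_before_filters(self):
        # the cap keeps the best hits by e-value, then filters apply
        hits = [hit("q", f"s{i}", "sp", ev=1e-6 * (i + 1)) for i in range(5)]
        hits.append(hit("q", "worse", "sp", ev=0.5))
        kept = filter_hits(hits, max_hits_per_query=3)
        assert {h.subject_id for h in kept} == {"s0", "s1", "s2"}


class TestSpeciesHitMatrix:
    def test_counts_and_zeros(self, simple_meta):
        hits = [hit("q1", f"pk1|s{i}", "pk1") for i in range(3)]
        m = species_hit_matrix(hits, simple_meta)
        assert m.loc["q1", "pk1"] == 3
        assert m.loc["q1", "eu1"] == 0

    def test_duplicate_subject_counted_once(self, simple_meta):
        hits = [hit("q1", "pk1|s0", "pk1"), hit("q1", "pk1|s0", "pk1", ev=1e-9)]
        m = species_hit_matrix(hits, simple_meta)
        assert m.loc["q1", "pk1"] == 1

    def test_unknown_species_rejected(self, simple_meta):
        with pytest.raises(ValueError, match="mystery"):
            species_hit_matrix([hit("q", "s", "mystery")], simple_meta)


class TestGroupAverageRatio:
    def test_hand_computed_example(self, simple_meta):
        # q1: 1 prokaryote hit, 10 eukaryote; q2: 0 and 10
        m = pd.DataFrame(
            [[1, 0, 5, 5], [0, 0, 5, 5]],
            index=["q1", "q2"],
            columns=["pk1", "pk2", "eu1", "eu2"],
        )
        avg_p, avg_e, ratio = group_average_ratio(m, simple_meta)
        assert avg_p == pytest.approx(0.25)
        assert avg_e == pytest.approx(5.0)
        assert ratio == pytest.approx(0.05)

    def test_symmetry_gives_one(self, simple_meta):
        m = pd.DataFrame(
            [[2, 2, 2, 2]], index=["q1"], columns=["pk1", "pk2", "eu1", "eu2"]
        )
        assert group_average_ratio(m, simple_meta)[2] == pytest.approx(1.0)

    def test_zero_numerator(self, simple_meta):
        m = pd.DataFrame(
            [[0, 0, 3, 3]], index=["q1"], columns=["pk1", "pk2", "eu1", "eu2"]
        )
        assert group_average_ratio(m, simple_meta)[2] == 0.0

    def test_zero_denominator_flagged(self, simple_meta):
        m = pd.DataFrame(
            [[1, 1, 0, 0]], index=["q1"], columns=["pk1", "pk2", "eu1", "eu2"]
        )
        with pytest.warns(UserWarning, match="undefined"):
            assert group_average_ratio(m, simple_meta)[2] is None

    def test_genome_duplication_invariance(self, simple_meta):
        """Duplicating a group's genomes with their columns leaves rates unchanged."""
        m = pd.DataFrame(
            [[1, 3, 5, 2], [0, 2, 4, 4]],
            index=["q1", "q2"],
            columns=["pk1", "pk2", "eu1", "eu2"],
        )
        base = group_average_ratio(m, simple_meta)
        meta2 = dict(simple_meta)
        meta2["pk1b"] = meta_entry("pk1b")
        meta2["pk2b"] = meta_entry("pk2b")
        m2 = m.copy()
        m2["pk1b"], m2["pk2b"] = m["pk1"], m["pk2"]
        doubled = group_average_ratio(m2, meta2)
        assert doubled == pytest.approx(base)


class TestPermutationRatioTest:
    def test_whole_proteome_is_degenerate_zero(self, simple_meta):
        m = pd.DataFrame(
            np.arange(8).reshape(2, 4),
            index=["q1", "q2"],
            columns=["pk1", "pk2", "eu1", "eu2"],
        )
        r = permutation_ratio_test(m, simple_meta, ["q1", "q2"], B=50, seed=1)
        assert r.degenerate and r.z == 0.0 and r.p == 0.5

    def test_reproducible_under_seed(self, simple_meta):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(
            rng.poisson(2, size=(30, 4)),
            index=[f"q{i}" for i in range(30)],
            columns=["pk1", "pk2", "eu1", "eu2"],
        )
        a = permutation_ratio_test(m, simple_meta, ["q0", "q1", "q2"], B=200, seed=7)
        b = permutation_ratio_test(m, simple_meta, ["q0", "q1", "q2"], B=200, seed=7)
        assert a == b

    def test_planted_depletion_detected(self):
        hits, meta, truth = gen_homolog_data(
            n_queries=40,
            n_background=160,
            rate_query={"prokaryote": 0.1, "eukaryote": 5.0},
            rate_background={"prokaryote": 2.0, "eukaryote": 2.0},
            seed=42,
        )
        m = species_hit_matrix(filter_hits(hits), meta)
        queries = [q for q in truth.query_set if q in m.index]
        r = permutation_ratio_test(m, meta, queries, B=1000, seed=3)
        assert r.p < 0.001
        assert r.observed < r.null_mean  # depleted in prokaryotes


class TestPresenceAndPhylum:
    def test_presence_requires_region(self):
        records = {
            "sp1": {
                "q1": [ProteinRecord(id="h1", residues="G" * 50)],  # all-Gly
                "q2": [ProteinRecord(id="h2", residues="G" * 20 + "A" * 40 + "G" * 20)],
            },
            "sp2": {},
        }
        table = presence_screen(records, ScanParams())
        assert not table.loc["sp1", "q1"]
        assert table.loc["sp1", "q2"]  # planted 40-aa poly-Ala run
        assert not table.loc["sp2"].any()

    def test_phylum_fractions(self, simple_meta):
        presence = pd.DataFrame(
            {"q1": [True, False, True, False]},
            index=["pk1", "pk2", "eu1", "eu2"],
        )
        out = phylum_normalize(presence, simple_meta)
        frac = dict(zip(out["phylum"], out["fraction"]))
        assert frac["P"] == pytest.approx(0.5)  # pk1 of two species
        assert frac["Chordata"] == 1.0
        assert frac["Ascomycota"] == 0.0


class TestMulticellularCompare:
    def make_meta(self, n_uni, n_multi):
        meta = {}
        for i in range(n_uni):
            meta[f"u{i}"] = meta_entry(f"u{i}", "Eukarya", "Asco", "unicellular", 5, 8)
        for i in range(n_multi):
            meta[f"m{i}"] = meta_entry(f"m{i}", "Eukarya", "Chordata", "multicellular", 30, 8)
        return meta

    def test_fold_change_of_medians(self):
        meta = self.make_meta(3, 3)
        counts = {"u0": 10, "u1": 10, "u2": 10, "m0": 70, "m1": 70, "m2": 70}
        out = multicellular_compare(counts, meta)
        assert out["median_fold_change"] == pytest.approx(7.0)

    def test_identical_groups(self):
        meta = self.make_meta(3, 3)
        counts = {"u0": 5, "u1": 6, "u2": 7, "m0": 5, "m1": 6, "m2": 7}
        out = multicellular_compare(counts, meta)
        assert out["median_fold_change"] == pytest.approx(1.0)
        assert out["mannwhitney_p"] == pytest.approx(1.0)

    def test_mannwhitney_matches_exact_enumeration(self):
        # {1,2,3} vs {4,5,6}: 2 of C(6,3)=20 orderings as extreme, doubled
        meta = self.make_meta(3, 3)
        counts = {"u0": 1, "u1": 2, "u2": 3, "m0": 4, "m1": 5, "m2": 6}
        out = multicellular_compare(counts, meta)
        assert out["mannwhitney_p"] == pytest.approx(0.1)

    def test_exact_enumeration_small_groups(self):
        """scipy agrees with brute-force enumeration for group sizes <= 6."""
        import itertools

        rng = np.random.default_rng(12)
        # tie-free samples: with ties scipy's exact method is undefined
        # and the doubled-tail and count-both-tails definitions diverge
        pool_vals = rng.choice(1000, size=11, replace=False)
        x = list(pool_vals[:5])
        y = list(pool_vals[5:])
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        # enumerate all assignments of the pooled values to group labels
        pooled = x + y
        u_obs = res.statistic
        n_extreme = 0
        total = 0
        ux_all = []
        for idx in itertools.combinations(range(len(pooled)), len(x)):
            gx = [pooled[i] for i in idx]
            gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
            u = sum(
                sum(1.0 if a > b else (0.5 if a == b else 0.0) for b in gy)
                for a in gx
            )
            ux_all.append(u)
            total += 1
        mean_u = len(x) * len(y) / 2
        n_extreme = sum(1 for u in ux_all if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9)
        assert res.pvalue == pytest.approx(n_extreme / total, abs=1e-9)

    def test_zero_unicellular_median_flagged(self):
        meta = self.make_meta(3, 3)
        counts = {"u0": 0, "u1": 0, "u2": 0, "m0": 4, "m1": 5, "m2": 6}
        with pytest.warns(UserWarning, match="undefined"):
            out = multicellular_compare(counts, meta)
        assert out["median_fold_change"] is None


class TestTrnaSpearman:
    def make_meta(self, a34_counts):
        return {
            f"s{i}": meta_entry(f"s{i}", "Eukarya", "P", "unicellular", n, 8 if n else 0)
            for i, n in enumerate(a34_counts)
        }

    def test_perfect_monotone(self):
        meta = self.make_meta([10, 20, 30, 40])
        counts = {f"s{i}": (i + 1) * 3 for i in range(4)}
        out = trna_spearman(counts, meta)
        assert out["rho"] == pytest.approx(1.0)

    def test_perfect_antitone(self):
        meta = self.make_meta([10, 20, 30, 40])
        counts = {f"s{i}": 100 - i for i in range(4)}
        assert trna_spearman(counts, meta)["rho"] == pytest.approx(-1.0)

    def test_exclusion_boundary_strictly_above_400(self):
        meta = self.make_meta([10, 20, 400, 401])
        counts = {f"s{i}": i + 1 for i in range(4)}
        out = trna_spearman(counts, meta)
        assert out["excluded_species"] == ["s3"]
        assert out["n_used"] == 3

    def test_constant_vector_flagged(self):
        meta = self.make_meta([10, 10, 10])
        counts = {"s0": 1, "s1": 2, "s2": 3}
        with pytest.warns(UserWarning, match="constant"):
            out = trna_spearman(counts, meta)
        assert out["rho"] is None


class TestBlastTabReader:
    def test_thirteen_column_qlen(self, tmp_path, simple_meta):
        f = tmp_path / "hits.tsv"
        f.write_text(
            "q1\tpk1|s1\t90.0\t50\t5\t0\t1\t50\t1\t50\t1e-20\t180\t100\n"
            "q1\tpk1|s2\t90.0\t10\t1\t0\t1\t10\t1\t10\t1e-3\t40\t100\n"
        )
        hits = read_blast_tab(f)
        assert hits[0].overlap_fraction == pytest.approx(0.5)
        assert hits[0].species_id == "pk1"
        kept = filter_hits(hits)
        assert len(kept) == 1  # second hit fails the 20% overlap filter

    def test_query_lengths_mapping(self, tmp_path):
        f = tmp_path / "hits.tsv"
        f.write_text("q1\tsp9|h\t90.0\t30\t0\t0\t1\t30\t1\t30\t1e-9\t99\n")
        hits = read_blast_tab(f, query_lengths={"q1": 60})
        assert hits[0].overlap_fraction == pytest.approx(0.5)
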