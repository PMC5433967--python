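"""Genotypic diversity, pi with resampling CIs, Tajima's D and Fu's Fs."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from clonescape import (
    MultilocusDataset,
    SimulationConfig,
    diversity_table,
    fus_Fs,
    gdiv,
    nucleotide_diversity,
    pi_confidence_interval,
    simulate,
    tajimas_D,
)
from clonescape.diversity import encode, ewens_log_pmf, mean_pairwise_differences

from conftest import make_aln, random_aln


class TestGdiv:
    @pytest.mark.parametrize(
        "m,m_star,expected",
        [(9, 5, 0.556), (10, 10, 1.000), (135, 25, 0.185), (39, 14, 0.359)],
    )
    def test_reported_three_decimal_values(self, m, m_star, expected):
        assert round(gdiv(m, m_star), 3) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            gdiv(0, 0)
        with pytest.raises(ValueError):
            gdiv(5, 6)


def brute_force_pi(seqs, site_mode="complete_deletion"):
    """Exhaustive pair enumeration oracle over raw strings."""
    n = len(seqs)
    if site_mode == "complete_deletion":
        keep = [
            i for i in range(len(seqs[0]))
            if all(s[i] in "ACGT" for s in seqs)
        ]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    total = 0.0
    for a, b in combinations(seqs, 2):
        cols = [
            (x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"
        ]
        total += sum(x != y for x, y in cols) / len(cols)
    return total / math.comb(n, 2)


class TestNucleotideDiversity:
    def test_two_sequences_single_difference(self):
        aln = make_aln(["A" * 100, "A" * 99 + "T"])
        pi, n_eff = nucleotide_diversity(aln)
        assert pi == pytest.approx(0.01)
        assert n_eff == 100

    def test_monomorphic_is_zero(self):
        pi, _ = nucleotide_diversity(make_aln(["ACGT" * 10] * 4))
        assert pi == 0.0

    @pytest.mark.parametrize("site_mode", ["complete_deletion", "pairwise_deletion"])
    def test_matches_brute_force_enumeration(self, site_mode):
        rng = np.random.default_rng(11)
        for _ in range(10):
            aln = random_aln(rng, 5, 40, p_missing=0.05)
            pi, _ = nucleotide_diversity(aln, site_mode)
            assert pi == pytest.approx(
                brute_force_pi(list(aln.records.values()), site_mode)
            )

    def test_deletion_modes_agree_on_gap_free_data(self):
        rng = np.random.default_rng(12)
        aln = random_aln(rng, 6, 50)
        assert nucleotide_diversity(aln, "complete_deletion")[0] == pytest.approx(
            nucleotide_diversity(aln, "pairwise_deletion")[0]
        )

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="no comparable sites"):
            nucleotide_diversity(make_aln(["NN", "NN"]))


class TestPiConfidenceInterval:
    def test_monomorphic_interval_is_degenerate(self):
        aln = make_aln(["ACGT" * 5] * 6)
        assert pi_confidence_interval(aln, reps=50, seed=1) == (0.0, 0.0)

    @pytest.mark.parametrize("method", ["bootstrap_sequences", "subsample_permutation"])
    def test_reproducible_under_seed(self, method):
        rng = np.random.default_rng(13)
        aln = random_aln(rng, 8, 60)
        a = pi_confidence_interval(aln, method, reps=200, seed=99)
        b = pi_confidence_interval(aln, method, reps=200, seed=99)
        assert a == b
        assert a[0] <= a[1]


def spreadsheet_tajima(seqs):
    """Constant-by-constant recomputation of Tajima's statistic with exact
    rational arithmetic, straight from the defining formulas."""
    n = len(seqs)
    seg = [i for i in range(len(seqs[0])) if len({s[i] for s in seqs}) > 1]
    S = len(seg)
    if S == 0:
        return None
    k_total = Fraction(0)
    for a, b in combinations(seqs, 2):
        k_total += sum(x != y for x, y in zip(a, b))
    k_total /= math.comb(n, 2)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return float(k_total - S / a1) / math.sqrt(float(e1 * S + e2 * S * (S - 1)))


class TestTajimasD:
    def test_monomorphic_is_undefined(self):
        assert tajimas_D(make_aln(["ACGT" * 3] * 5)) is None

    def test_toy_alignment_matches_spreadsheet_recomputation(self):
        seqs = [
            "AAAAAACGTG",
            "AAAAT_CGTG".replace("_", "A"),
            "ATAAAACGTG",
            "AAAAAACGCG",
            "AAGAAACGTG",
        ]
        aln = make_aln(seqs)
        assert tajimas_D(aln) == pytest.approx(spreadsheet_tajima(seqs))

    def test_random_alignments_match_spreadsheet(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(20):
            aln = random_aln(rng, rng.integers(4, 9), 50)
            expected = spreadsheet_tajima(list(aln.records.values()))
            got = tajimas_D(aln)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)
                checked += 1
        assert checked >= 10

    def test_zero_when_pi_equals_watterson(self):
        # n=4: a1 = 11/6; 8 singleton sites (3 diff pairs each) and
        # 3 doubleton sites (4 diff pairs) give S=11, mean pairwise = 6 = S/a1
        sites = []
        sites += [["A", "A", "A", "C"]] * 4
        sites += [["A", "A", "C", "A"]] * 2
        sites += [["C", "A", "A", "A"]] * 2
        sites += [["A", "A", "C", "C"]] * 3
        sites += [["G", "G", "G", "G"]] * 9  # invariant padding
        seqs = ["".join(col[i] for col in sites) for i in range(4)]
        aln = make_aln(seqs)
        pi_total, _ = mean_pairwise_differences(encode(aln))
        assert pi_total == pytest.approx(6.0)
        assert tajimas_D(aln) == pytest.approx(0.0, abs=1e-12)

    def test_star_expansion_gives_negative_d(self):
        """Star genealogies are singleton-rich; D should be negative in the
        large majority of replicates."""
        neg = tot = 0
        for seed in range(20):
            ds, _ = simulate(
                SimulationConfig(
                    seed=seed, n_lineages=2, samples_per_lineage=[25, 1],
                    clone_fraction=0.0, chemotype_mix=[0.5, 0.5],
                )
            )
            sub = ds.loci[0].subset(
                [s for s in ds.loci[0].sample_ids if s.startswith("LA")]
            )
            d = tajimas_D(sub)
            if d is not None:
                tot += 1
                neg += d < 0
        assert tot >= 15
        assert neg / tot >= 0.75


def three_sample_fs(theta, k_obs):
    """Closed-form Fu's Fs for n=3 from the explicit Ewens distribution:
    |s(3,1)|=2, |s(3,2)|=3, |s(3,3)|=1."""
    denom = theta * (theta + 1) * (theta + 2)
    p = {1: 2 * theta / denom, 2: 3 * theta**2 / denom, 3: theta**3 / denom}
    sp = sum(p[k] for k in range(k_obs, 4))
    return math.log(sp / (1 - sp))


class TestFusFs:
    def test_monomorphic_is_undefined(self):
        assert fus_Fs(make_aln(["ACGT" * 3] * 5)) is None

    def test_three_sequences_closed_form(self):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAACC"]
        aln = make_aln(seqs)
        theta, _ = mean_pairwise_differences(encode(aln))
        assert fus_Fs(aln) == pytest.approx(three_sample_fs(theta, 3))

    def test_three_sequences_two_haplotypes(self):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAATT"]
        aln = make_aln(seqs)
        theta, _ = mean_pairwise_differences(encode(aln))
        assert fus_Fs(aln) == pytest.approx(three_sample_fs(theta, 2))

    def test_monotone_decreasing_in_haplotype_count(self):
        n, theta = 20, 3.0
        logp = ewens_log_pmf(n, theta)
        p = np.exp(logp)
        fs = []
        for k_obs in range(2, n + 1):
            sp = p[k_obs:].sum()
            fs.append(math.log(sp / (1 - sp)))
        assert all(a > b for a, b in zip(fs, fs[1:]))

    def test_expansion_gives_strongly_negative_fs(self):
        """Many rare haplotypes relative to theta drive Fs far negative."""
        neg = tot = 0
        for seed in range(10):
            ds, _ = simulate(
                SimulationConfig(
                    seed=100 + seed, n_lineages=2, samples_per_lineage=[30, 1],
                    clone_fraction=0.0, theta_within=0.001,
                    chemotype_mix=[0.5, 0.5],
                )
            )
            from clonescape import concatenate

            concat, _ = concatenate(ds)
            sub = concat.subset([s for s in concat.sample_ids if s.startswith("LA")])
            fs = fus_Fs(sub)
            if fs is not None:
                tot += 1
                neg += fs < -2.0
        assert tot >= 8
        assert neg / tot >= 0.7


class TestDiversityTable:
    def test_three_lineage_dataset_gives_three_rows(self, sim_default):
        ds, _ = sim_default
        rows = diversity_table(ds, "sim", reps=100, seed=1)
        assert len(rows) == 3
        assert [r.population for r in rows] == ["A", "B", "C"]

    def test_low_genotype_population_reports_na(self):
        ds, _ = simulate(
            SimulationConfig(
                seed=8, samples_per_lineage=[8, 6, 10],
                clone_fraction=1.0,  # one genotype per lineage... but first
                # sample mutates from founder, so exactly 1 genotype each
            )
        )
        rows = diversity_table(ds, "clonal", reps=50, seed=2)
        for r in rows:
            assert r.m_star == 1
            assert r.tajima_D is None and r.fu_Fs is None

    def test_clone_only_group_statistics(self):
        seqs = ["ACGTACGT"] * 5
        import pandas as pd

        meta = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(5)], "population": "P",
             "chemotype": "unknown", "morphotype": "unknown", "locality": "x",
             "lat": np.nan, "lon": np.nan}
        )
        ds = MultilocusDataset(
            [make_aln(seqs, ids=[f"s{i}" for i in range(5)])], meta
        )
        (row,) = diversity_table(ds, "t", reps=50, seed=3)
        assert row.Gdiv == pytest.approx(1 / 5)
        assert row.pi == 0.0
        assert row.pi_CI == (0.0, 0.0)
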