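"""Haplotype collapsing, the parsimony connection limit, and the network."""

import math

import numpy as np
import pandas as pd
import pytest

from clonescape import (
    Haplotype,
    build_parsimony_network,
    collapse_haplotypes,
    concatenate,
    parsimony_connection_limit,
    parsimony_probability,
    pairwise_steps,
    phenotype_crosstab,
    simulate,
    truth_summary,
    SimulationConfig,
)

from conftest import make_aln


class TestCollapse:
    def test_identical_sequences_one_haplotype(self):
        aln = make_aln(["ACGT" * 5] * 10)
        haps = collapse_haplotypes(aln)
        assert len(haps) == 1
        assert haps[0].frequency == 10
        assert haps[0].hap_id == "H1"

    def test_gap_mode_controls_merging(self):
        aln = make_aln(["ACGT", "AC-T"])
        assert len(collapse_haplotypes(aln, "missing")) == 1
        assert len(collapse_haplotypes(aln, "fifth_state")) == 2

    def test_frequencies_sum_to_sample_count(self, sim_default):
        ds, _ = sim_default
        concat, _ = concatenate(ds)
        haps = collapse_haplotypes(concat)
        assert sum(h.frequency for h in haps) == concat.n_samples

    def test_simulation_haplotype_count_matches_truth(self, sim_default):
        """Generator bookkeeping (clone pointers) predicts the genotype count."""
        ds, truth = sim_default
        concat, _ = concatenate(ds)
        haps = collapse_haplotypes(concat, "fifth_state")
        assert len(haps) == truth_summary(truth)["expected_m_star_total"]

    def test_labelling_by_descending_frequency(self):
        aln = make_aln(["AAAA", "AAAA", "CCCC", "CCCC", "CCCC", "GGGG"])
        haps = collapse_haplotypes(aln)
        assert [h.frequency for h in haps] == [3, 2, 1]
        assert haps[0].sequence == "CCCC"

    def test_collapse_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        seqs = ["AAAA"] * 3 + ["AATT"] * 2 + ["TTTT"]
        ids = [f"s{i}" for i in range(6)]
        base = collapse_haplotypes(make_aln(seqs, ids=ids))
        for _ in range(5):
            order = rng.permutation(6)
            shuffled = make_aln([seqs[i] for i in order], ids=[ids[i] for i in order])
            haps = collapse_haplotypes(shuffled)
            assert sorted(h.sequence for h in haps) == sorted(h.sequence for h in base)
            assert [h.frequency for h in haps] == [h.frequency for h in base]


class TestPairwiseSteps:
    @pytest.mark.parametrize(
        "a,b,mode,expected",
        [
            ("ACGT", "ACGT", "missing", 0),
            ("ACGT", "ACGA", "missing", 1),
            ("ACNT", "ACGA", "missing", 1),
            ("AC-T", "ACGT", "fifth_state", 1),
        ],
    )
    def test_step_counts(self, a, b, mode, expected):
        ha, hb = Haplotype("H1", a, ["x"]), Haplotype("H2", b, ["y"])
        assert pairwise_steps(ha, hb, mode) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pairwise_steps(Haplotype("H1", "ACG", ["x"]), Haplotype("H2", "AC", ["y"]))


def _oracle_limit(seq_length: int, confidence: float) -> int:
    """Independent scalar recomputation of the parsimony limit: largest j
    whose per-difference single-hit probability, under Poisson substitution
    with Jukes-Cantor correction of j/m, stays above the confidence when
    raised to the j-th power."""
    j = 1
    while True:
        cand = j + 1
        frac = cand / seq_length
        if frac >= 0.75:
            return j
        d = -0.75 * math.log(1.0 - 4.0 * frac / 3.0)
        single = d * math.exp(-d)
        differ = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
        if (single / differ) ** cand >= confidence:
            j = cand
        else:
            return j


class TestParsimonyLimit:
    def test_full_confidence_keeps_only_single_steps(self):
        assert parsimony_connection_limit(10, 600, confidence=1.0) == 1

    def test_user_override_wins(self):
        assert parsimony_connection_limit(10, 600, override=10) == 10

    @pytest.mark.parametrize("length", [100, 350, 600, 900, 2000])
    def test_matches_independent_recomputation(self, length):
        assert parsimony_connection_limit(20, length) == _oracle_limit(length, 0.95)

    def test_limit_grows_with_sequence_length(self):
        limits = [parsimony_connection_limit(10, L) for L in (200, 600, 1800)]
        assert limits == sorted(limits)
        assert limits[0] < limits[-1]

    def test_probability_decreases_with_steps(self):
        probs = [parsimony_probability(j, 600) for j in range(1, 20)]
        assert all(a > b for a, b in zip(probs, probs[1:]))


def _haps(seqs, freqs=None):
    freqs = freqs or [1] * len(seqs)
    return [
        Haplotype(f"H{i + 1}", s, [f"m{i}_{k}" for k in range(f)])
        for i, (s, f) in enumerate(zip(seqs, freqs))
    ]


class TestNetwork:
    def test_chain_with_median_expansion(self):
        # H1-H2 one step, H2-H3 two steps -> one median between H2 and H3
        haps = _haps(["AAAAA", "AAAAT", "AATTT"], [3, 2, 1])
        net = build_parsimony_network(haps, limit=5)
        assert len(net.medians) == 1
        g = net.graph
        assert g.has_edge("H1", "H2")
        import networkx as nx

        assert nx.shortest_path_length(g, "H2", "H3") == 2
        assert all(d["steps"] == 1 for _, _, d in g.edges(data=True))

    def test_star_center_degree(self):
        center = "A" * 20
        leaves = [center[:i] + "T" + center[i + 1:] for i in range(6)]
        haps = _haps([center] + leaves, [10] + [1] * 6)
        net = build_parsimony_network(haps, limit=3)
        assert net.graph.degree("H1") == 6
        assert net.ancestral_haplotype() == "H1"

    def test_distance_beyond_limit_splits_components(self):
        haps = _haps(["AAAAAAAA", "AAAAAAAT", "TTTTTTTT", "TTTTTTTA"])
        net = build_parsimony_network(haps, limit=2)
        assert len(net.components()) == 2

    def test_k_step_edge_adds_k_minus_1_medians(self):
        haps = _haps(["AAAAAA", "TTTTAA"])  # distance 4
        net = build_parsimony_network(haps, limit=5)
        assert len(net.medians) == 3
        assert net.graph.number_of_edges() == 4
        # medians interpolate column by column, left to right
        seqs = [net.nodes[f"M{i}"].sequence for i in (1, 2, 3)]
        assert seqs == ["TAAAAA", "TTAAAA", "TTTAAA"]

    def test_connected_at_max_pairwise_distance(self, sim_default):
        ds, _ = sim_default
        concat, _ = concatenate(ds)
        haps = collapse_haplotypes(concat)
        dmax = max(
            pairwise_steps(a, b)
            for i, a in enumerate(haps)
            for b in haps[i + 1:]
        )
        net = build_parsimony_network(haps, limit=dmax)
        assert len(net.components()) == 1


class TestCrosstab:
    def test_mixed_flags(self, meta_two_chemotypes):
        haps = [
            Haplotype("H1", "AAAA", ["s1", "s2"]),
            Haplotype("H2", "AAAT", ["s3", "s4"]),
        ]
        ct = phenotype_crosstab(haps, meta_two_chemotypes).set_index("hap_id")
        assert bool(ct.loc["H1", "chem_mixed"]) is True
        assert bool(ct.loc["H2", "chem_mixed"]) is False
        assert bool(ct.loc["H2", "morph_mixed"]) is True

    def test_unknown_sample_counted_as_unknown(self, meta_two_chemotypes):
        haps = [Haplotype("H1", "AAAA", ["s1", "ghost"])]
        ct = phenotype_crosstab(haps, meta_two_chemotypes)
        assert int(ct.loc[0, "n_unknown_samples"]) == 1
        assert int(ct.loc[0, "chem_unknown"]) == 1

    def test_mixture_rate_matches_binomial_expectation(self):
        """With chemotype assigned independently of genotype (p=0.5), the
        number of chemotype-mixed haplotypes should match the binomial
        expectation sum(1 - 2*(1/2)^f) within Monte-Carlo error."""
        observed = expected = var = 0.0
        for seed in range(15):
            ds, _ = simulate(
                SimulationConfig(
                    seed=seed, n_lineages=2, samples_per_lineage=[30, 1],
                    chemotype_mix=[0.5, 0.5],
                )
            )
            concat, _ = concatenate(ds)
            haps = [h for h in collapse_haplotypes(concat) if h.frequency >= 2]
            ct = phenotype_crosstab(haps, ds.metadata)
            observed += int(ct["chem_mixed"].sum())
            for f in ct["frequency"]:
                p_mixed = 1.0 - 2.0 * 0.5**int(f)
                expected += p_mixed
                var += p_mixed * (1.0 - p_mixed)
        assert abs(observed - expected) <= 4.0 * math.sqrt(var)
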