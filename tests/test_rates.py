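"""Clock-summary arithmetic, the Dayhoff model, and ML rate estimation."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from colchain.dayhoff import MODEL_ORDER, dayhoff_model
from colchain.rates import (
    ClockSummary,
    ClockSummaryError,
    DegenerateInputError,
    PartitionRateModel,
    estimate_partition_rates,
    per_chain_rate,
    pruning_loglik,
    read_clock_summary,
)
from colchain.records import CHAIN_ORDER, ConcatenatedAlignment

from conftest import simulate_rate_alignment

CANONICAL_LENGTHS = {"alpha1": 1058, "alpha2": 1041, "alpha3": 1062}


def _summary_from_site_rates(site_rates):
    mean = sum(site_rates.values()) / 3
    return ClockSummary(mean, {c: site_rates[c] / mean for c in site_rates})


class TestPerChainRate:
    def test_published_rate_table_arithmetic(self):
        summary = _summary_from_site_rates(
            {"alpha1": 0.00067, "alpha2": 0.00088, "alpha3": 0.00094}
        )
        table = per_chain_rate(summary, CANONICAL_LENGTHS)
        # exact products before any rounding
        assert table.table.loc["alpha1", "chain_rate"] == pytest.approx(0.70886)
        assert table.table.loc["alpha3", "chain_rate"] == pytest.approx(0.99828)
        disp = table.display()
        assert list(disp["chain_rate"]) == [0.7, 0.9, 1.0, 0.9]
        assert disp.loc["mean", "length"] == 1054
        assert disp.loc["mean", "site_rate"] == pytest.approx(0.00083)

    def test_chain_rate_identity_holds_exactly(self):
        summary = _summary_from_site_rates(
            {"alpha1": 0.0003, "alpha2": 0.0007, "alpha3": 0.0011}
        )
        table = per_chain_rate(summary, CANONICAL_LENGTHS)
        for chain in CHAIN_ORDER:
            row = table.table.loc[chain]
            assert row["chain_rate"] == row["site_rate"] * row["length"]

    def test_half_up_display_rounding(self):
        # 0.25 per site over a 3-site chain -> 0.75, displays 0.8 (half-up)
        summary = ClockSummary(0.25, {c: 1.0 for c in CHAIN_ORDER})
        table = per_chain_rate(summary, {c: 3 for c in CHAIN_ORDER})
        assert table.display().loc["alpha1", "chain_rate"] == 0.8

    def test_zero_clockrate_rejected(self):
        with pytest.raises(ClockSummaryError):
            ClockSummary(0.0, {c: 1.0 for c in CHAIN_ORDER})


class TestReadClockSummary:
    PSTAT = (
        "[ID: 1234]\n"
        "Parameter       Mean        Variance    Lower   Upper\n"
        "TL{all}         12.3        0.5         11.0    13.5\n"
        "Clockrate{all}  0.00083     1e-9        0.0007  0.0009\n"
        "m{1}            0.807       1e-4        0.79    0.82\n"
        "m{2}            1.060       1e-4        1.04    1.08\n"
        "m{3}            1.133       1e-4        1.11    1.15\n"
    )

    def test_parses_clockrate_and_multipliers(self, tmp_path):
        path = tmp_path / "run.pstat"
        path.write_text(self.PSTAT)
        summary = read_clock_summary(path)
        assert summary.mean_clockrate == 0.00083
        # multipliers back out the published per-site rates
        assert summary.site_rate("alpha1") == pytest.approx(0.00067, abs=5e-6)
        assert summary.site_rate("alpha2") == pytest.approx(0.00088, abs=5e-6)
        assert summary.site_rate("alpha3") == pytest.approx(0.00094, abs=5e-6)

    def test_extra_parameters_are_ignored(self, tmp_path):
        path = tmp_path / "extra.pstat"
        path.write_text(self.PSTAT + "alpha{all}  0.5  1e-3  0.4  0.6\n")
        summary = read_clock_summary(path)
        assert summary.mean_clockrate == 0.00083

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.pstat"
        path.write_text("")
        with pytest.raises(ClockSummaryError):
            read_clock_summary(path)

    def test_missing_clockrate_is_an_error(self, tmp_path):
        path = tmp_path / "noclock.pstat"
        path.write_text("Parameter Mean\nm{1} 1.0\n")
        with pytest.raises(ClockSummaryError):
            read_clock_summary(path)


class TestDayhoffModel:
    def test_rate_matrix_invariants(self, model):
        Q = model.rate_matrix
        pi = model.frequencies
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        # detailed balance (time reversibility)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-15)
        # one expected substitution per site per unit branch length
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_transition_probabilities_are_stochastic(self, model):
        P = model.transition_probabilities(0.37)
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0)


def _tiny_alignment(rows, widths=(4, 3, 3)):
    partitions, start = {}, 1
    for chain, w in zip(CHAIN_ORDER, widths):
        partitions[chain] = (start, start + w - 1)
        start += w
    return ConcatenatedAlignment(
        taxa=[f"s{i}" for i in range(len(rows))], matrix=rows, partitions=partitions
    )


def _enumeration_loglik(aln, tree, rates, model):
    """Oracle: marginalise internal states by explicit enumeration."""
    total = 0.0
    for chain in CHAIN_ORDER:
        sl = aln.partition_slice(chain)
        Ps = {
            id(nd): model.transition_probabilities(rates[chain] * (nd.edge.length or 0.0))
            for nd in tree.preorder_node_iter()
        }
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        for col in zip(*[row[sl] for row in aln.matrix]):
            obs = dict(zip(aln.taxa, col))
            lik = 0.0
            for assign in itertools.product(range(20), repeat=len(internals)):
                amap = {id(nd): s for nd, s in zip(internals, assign)}
                p = model.frequencies[amap[id(tree.seed_node)]]
                for nd in tree.preorder_node_iter():
                    if nd is tree.seed_node:
                        continue
                    parent = amap[id(nd.parent_node)]
                    if nd.is_leaf():
                        ch = obs[nd.taxon.label]
                        p *= 1.0 if ch in "-X" else Ps[id(nd)][parent, MODEL_ORDER.index(ch)]
                    else:
                        p *= Ps[id(nd)][parent, amap[id(nd)]]
                lik += p
            total += math.log(lik)
    return total


class TestPruningLikelihood:
    def test_zero_duration_tree_reduces_to_stationary_frequencies(self, model):
        seq = "GAPKGAPRGR"
        aln = _tiny_alignment([seq, seq])
        tree = dendropy.Tree.get(data="(s0:0,s1:0):0;", schema="newick")
        ll = pruning_loglik(aln, tree, {c: 0.01 for c in CHAIN_ORDER}, model)
        closed = sum(math.log(model.frequencies[MODEL_ORDER.index(ch)]) for ch in seq)
        assert ll == pytest.approx(closed, abs=1e-10)

    @pytest.mark.parametrize("newick,n_leaves", [
        ("((s0:10,s1:12):5,s2:20):0;", 3),
        ("((s0:10,s1:12):5,(s2:8,s3:9):6):0;", 4),
    ])
    def test_matches_internal_state_enumeration(self, model, newick, n_leaves):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(n_leaves):
            chars = rng.choice(list(MODEL_ORDER) + ["-", "X"], size=10,
                               p=[0.046] * 20 + [0.04, 0.04])
            rows.append("".join(chars))
        aln = _tiny_alignment(rows)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        rates = {"alpha1": 0.01, "alpha2": 0.02, "alpha3": 0.005}
        ll = pruning_loglik(aln, tree, rates, model)
        assert ll == pytest.approx(_enumeration_loglik(aln, tree, rates, model), abs=1e-9)

    def test_invariant_to_column_order_within_partition(self, model):
        rng = np.random.default_rng(6)
        rows = ["".join(rng.choice(list(MODEL_ORDER), size=10)) for _ in range(3)]
        aln = _tiny_alignment(rows)
        perm = [3, 0, 2, 1]  # shuffle α1's 4 columns only
        shuffled = [r[:4][perm[0]] + r[:4][perm[1]] + r[:4][perm[2]] + r[:4][perm[3]] + r[4:]
                    for r in rows]
        shuffled = ["".join(r[p] for p in perm) + r[4:] for r in rows]
        aln2 = _tiny_alignment(shuffled)
        tree = dendropy.Tree.get(data="((s0:10,s1:12):5,s2:20):0;", schema="newick")
        rates = {c: 0.01 for c in CHAIN_ORDER}
        assert pruning_loglik(aln, tree, rates, model) == pytest.approx(
            pruning_loglik(aln2, tree, rates, model), abs=1e-9
        )

    def test_leaf_mismatch_rejected(self, model):
        aln = _tiny_alignment(["GAPKGAPRGR"] * 2)
        tree = dendropy.Tree.get(data="(s0:1,other:1):0;", schema="newick")
        with pytest.raises(ValueError, match="leaf set"):
            pruning_loglik(aln, tree, {c: 0.01 for c in CHAIN_ORDER}, model)


class TestRateEstimation:
    def test_recovers_rates_and_ordering_on_simulated_data(self, small_rate_sim, model):
        aln, tree = small_rate_sim
        results = PartitionRateModel(aln, tree, model).fit()
        true = {"alpha1": 0.00067, "alpha2": 0.00088, "alpha3": 0.00094}
        for chain in CHAIN_ORDER:
            rel = abs(results.site_rates[chain] - true[chain]) / true[chain]
            assert rel < 0.25  # 400-site partitions: generous Monte-Carlo band
            lo, hi = results.conf_ints[chain]
            assert lo < results.site_rates[chain] < hi
        assert results.site_rates["alpha3"] > results.site_rates["alpha1"]

    def test_bias_shrinks_with_partition_length(self, model):
        true = {"alpha1": 0.00067, "alpha2": 0.00088, "alpha3": 0.00094}
        errors = {}
        for L in (200, 3000):
            lengths = {c: L for c in CHAIN_ORDER}
            aln, tree = simulate_rate_alignment(31, n_taxa=12, lengths=lengths, model=model)
            res = PartitionRateModel(aln, tree, model).fit()
            errors[L] = np.mean(
                [abs(res.site_rates[c] - true[c]) / true[c] for c in CHAIN_ORDER]
            )
        assert errors[3000] < errors[200]
        assert errors[3000] < 0.10

    def test_doubling_branch_durations_halves_rates(self, small_rate_sim, model):
        aln, tree = small_rate_sim
        res1 = PartitionRateModel(aln, tree, model).fit()
        doubled = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                                    schema="newick", preserve_underscores=True)
        for edge in doubled.edges():
            if edge.length is not None:
                edge.length *= 2
        res2 = PartitionRateModel(aln, doubled, model).fit()
        for chain in CHAIN_ORDER:
            assert res2.site_rates[chain] == pytest.approx(
                res1.site_rates[chain] / 2, rel=1e-3
            )

    def test_all_gap_partition_is_an_error(self, model):
        rows = ["GAPK" + "GAP" + "---", "GAPR" + "GAP" + "---"]
        aln = _tiny_alignment(rows)
        tree = dendropy.Tree.get(data="(s0:10,s1:10):0;", schema="newick")
        with pytest.raises(DegenerateInputError):
            PartitionRateModel(aln, tree, model)

    def test_zero_duration_tree_cannot_be_fit(self, model):
        aln = _tiny_alignment(["GAPKGAPRGR"] * 2)
        tree = dendropy.Tree.get(data="(s0:0,s1:0):0;", schema="newick")
        with pytest.raises(DegenerateInputError):
            estimate_partition_rates(aln, tree, model)

    def test_summary_reports_rates_and_intervals(self, small_rate_sim, model):
        aln, tree = small_rate_sim
        results = PartitionRateModel(aln, tree, model).fit()
        text = results.summary()
        assert "alpha1" in text and "95% CI" in text
        table = results.rate_table()
        for chain in CHAIN_ORDER:
            row = table.table.loc[chain]
            assert row["chain_rate"] == row["site_rate"] * row["length"]
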