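import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngslod.replicate_stats import (
    AccuracyResult,
    accuracy_vs_reference,
    aggregate_replicates,
    bin_rsd,
    summarize_accuracy,
)
from ngslod.variant_io import TargetVariant

from conftest import make_af_table


def tables_from_af_matrix(matrix, label="15Gbp", depth=200):
    """One AFTable per column of replicate AFs (rows = loci)."""
    matrix = np.asarray(matrix, dtype=float)
    return [
        make_af_table(matrix[:, j], replicate_id=f"rep{j + 1}", label=label, depth=depth)
        for j in range(matrix.shape[1])
    ]


class TestAggregateReplicates:
    def test_zero_variance(self):
        (p,) = aggregate_replicates(tables_from_af_matrix([[10, 10, 10, 10]]))
        assert (p.mean_af, p.sd_af, p.rsd) == (10.0, 0.0, 0.0)
        assert p.n_replicates == 4

    def test_hand_computed_sd_and_rsd(self):
        # sample SD of [8, 10, 12, 10] with n-1 = 3 denominator
        (p,) = aggregate_replicates(tables_from_af_matrix([[8, 10, 12, 10]]))
        assert p.mean_af == pytest.approx(10.0)
        assert p.sd_af == pytest.approx(1.6330, abs=1e-4)
        assert p.rsd == pytest.approx(16.330, abs=1e-3)

    def test_all_zero_locus_excluded_with_warning(self, caplog):
        tables = tables_from_af_matrix([[0, 0, 0, 0], [8, 10, 12, 10]])
        with caplog.at_level("WARNING"):
            out = aggregate_replicates(tables)
        assert len(out) == 1
        assert any("mean AF 0" in r.message for r in caplog.records)

    def test_undefined_af_locus_dropped(self, caplog):
        tables = tables_from_af_matrix([[10, 10, 10, 10], [5, 5, 5, 5]])
        tables[0].data.loc[1, ["depth", "alt_count", "af_percent"]] = [0, 0, math.nan]
        with caplog.at_level("WARNING"):
            out = aggregate_replicates(tables)
        assert [p.locus for p in out] == [tables[0].data["locus"][0]]

    def test_fewer_than_two_tables_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            aggregate_replicates(tables_from_af_matrix([[10]]))

    def test_mismatched_tiers_rejected(self):
        t1 = make_af_table([10.0], label="5Gbp")
        t2 = make_af_table([10.0], label="15Gbp")
        with pytest.raises(ValueError, match="tiers"):
            aggregate_replicates([t1, t2])

    def test_permutation_invariance(self):
        tables = tables_from_af_matrix([[8, 10, 12, 10], [1, 2, 3, 4]])
        fwd = aggregate_replicates(tables)
        rev = aggregate_replicates(tables[::-1])
        assert fwd == rev

    @given(st.floats(0.1, 10.0), st.lists(st.floats(1.0, 50.0), min_size=3, max_size=6))
    @settings(max_examples=40, deadline=None)
    def test_rsd_scale_invariant(self, c, afs):
        """%RSD is unchanged and SD scales by c when all AFs are scaled by c."""
        base = np.array(afs)
        scaled = base * c
        if scaled.max() > 100:
            scaled = scaled * (99.0 / scaled.max())
            c = scaled[0] / base[0]
        (p0,) = aggregate_replicates(tables_from_af_matrix([base], depth=10**6))
        (p1,) = aggregate_replicates(tables_from_af_matrix([scaled], depth=10**6))
        assert p1.rsd == pytest.approx(p0.rsd, rel=1e-3, abs=1e-3)
        assert p1.sd_af == pytest.approx(c * p0.sd_af, rel=1e-3, abs=1e-3)

    def test_binomial_sampling_theory_rsd(self, rng):
        """Across many binomial replicates at depth D and fraction p, the
        %RSD approaches 100*sqrt((1-p)/(D*p))."""
        D, p, n_rep = 189, 0.05, 400
        alts = rng.binomial(D, p, size=n_rep)
        afs = 100.0 * alts / D
        tables = [
            make_af_table([af], replicate_id=f"r{i}", depth=10**6)
            for i, af in enumerate(afs)
        ]
        # construct exact tables: bypass rounding by direct assignment
        for table, af in zip(tables, afs):
            table.data.loc[0, "af_percent"] = af
            table.data.loc[0, "alt_count"] = round(af / 100 * 10**6)
        (prec,) = aggregate_replicates(tables)
        theory = 100.0 * math.sqrt((1 - p) / (D * p))
        assert prec.rsd == pytest.approx(theory, rel=0.15)


class TestBinRSD:
    def make(self, rsds):
        from ngslod.replicate_stats import LocusPrecision

        return [
            LocusPrecision(f"chr1:{i}:G>T", 4, 10.0, 10.0 * r / 100.0, r)
            for i, r in enumerate(rsds, start=1)
        ]

    def test_one_locus_per_bin(self):
        counts = bin_rsd(self.make([5, 15, 25, 35]))
        assert counts == {"<10": 1, "10-<20": 1, "20-<30": 1, ">=30": 1}

    def test_boundary_goes_to_upper_bin(self):
        counts = bin_rsd(self.make([30.0]))
        assert counts[">=30"] == 1

    def test_empty_input_all_zero(self):
        assert all(v == 0 for v in bin_rsd([]).values())

    @given(st.lists(st.floats(0, 100, allow_nan=False), max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_counts_sum_to_input_size(self, rsds):
        assert sum(bin_rsd(self.make(rsds)).values()) == len(rsds)

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_rsd([], edges=[10, 10, 30])


def pearson_oracle(x, y):
    """Hand formula for r and the two-sided t-distribution p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    r = sxy / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    t = r * math.sqrt((n - 2) / (1 - r * r))
    from scipy import stats

    return r, 2 * stats.t.sf(abs(t), df=n - 2)


class TestAccuracyVsReference:
    def targets_for(self, loci, validated):
        return [
            TargetVariant("chrS", 10_000 + i * 1000, "G", "T", v)
            for i, v in enumerate(validated)
        ]

    def test_identity_measurement(self):
        validated = [1.0 + 1.5 * i for i in range(20)]
        table = make_af_table(validated, depth=10**6)
        for i, v in enumerate(validated):  # exact values, no rounding
            table.data.loc[i, "af_percent"] = v
            table.data.loc[i, "alt_count"] = round(v * 10**4)
        targets = self.targets_for(table.data["locus"], validated)
        res = accuracy_vs_reference(table, targets)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.p_value < 1e-20

    def test_hand_computed_r_and_p(self):
        # pairs (1,2), (2,1), (3,4), (4,3): cov-sum 3, var-sums 5 and 5
        # -> r = 3/5 = 0.6; with n = 4 the two-sided t p-value reduces to
        # 1 - |r| = 0.4 in closed form
        table = make_af_table([2, 1, 4, 3], depth=100)
        targets = self.targets_for(table.data["locus"], [1, 2, 3, 4])
        res = accuracy_vs_reference(table, targets)
        assert res.pearson_r == pytest.approx(0.6)
        assert res.p_value == pytest.approx(0.4)
        r_o, p_o = pearson_oracle([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.pearson_r == pytest.approx(r_o)
        assert res.p_value == pytest.approx(p_o)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_hand_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        x = rng.uniform(1, 30, n).round(2)
        y = (x + rng.normal(0, 3, n)).clip(0.01, 99).round(2)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        table = make_af_table(y, depth=10**6)
        for i, v in enumerate(y):
            table.data.loc[i, "af_percent"] = float(v)
            table.data.loc[i, "alt_count"] = round(v * 10**4)
        targets = self.targets_for(table.data["locus"], x)
        res = accuracy_vs_reference(table, targets)
        r_o, p_o = pearson_oracle(x, y)
        assert res.pearson_r == pytest.approx(r_o, abs=1e-9)
        assert res.p_value == pytest.approx(p_o, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        table = make_af_table([1, 2])
        targets = self.targets_for(table.data["locus"], [1, 2])
        with pytest.raises(ValueError, match=">= 3"):
            accuracy_vs_reference(table, targets)

    def test_constant_predictor_rejected(self):
        table = make_af_table([1, 2, 3])
        targets = self.targets_for(table.data["locus"], [5, 5, 5])
        with pytest.raises(ValueError, match="zero variance"):
            accuracy_vs_reference(table, targets)


class TestSummarizeAccuracy:
    def res(self, r, p=0.01):
        return AccuracyResult("rep", 20, r, p, 1.0, 0.0)

    def test_constant_values(self):
        s = summarize_accuracy([self.res(0.9)] * 4)
        assert s["mean_r"] == pytest.approx(0.9)
        assert s["sd_r"] == 0.0

    def test_hand_computed_sd(self):
        s = summarize_accuracy([self.res(0.8), self.res(1.0)])
        assert s["mean_r"] == pytest.approx(0.9)
        assert s["sd_r"] == pytest.approx(math.sqrt(0.02), abs=1e-6)  # 0.1414

    def test_single_result_rejected(self):
        with pytest.raises(ValueError):
            summarize_accuracy([self.res(0.9)])
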