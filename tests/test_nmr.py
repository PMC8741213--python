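"""Composite shifts, significance cutoff, dR_ex and the exchange network."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allonet import nmr
from allonet.communities import CommunityPartition
from allonet.errors import InputError
from allonet.synthetic import planted_network


def table(rows):
    df = pd.DataFrame(rows, columns=["residue", "ddH_ppm", "ddN_ppm",
                                     "broadened", "dispersive", "rex_s1"])
    df["broadened"] = df["broadened"].astype(bool)
    df["dispersive"] = df["dispersive"].astype(bool)
    return df


class TestCompositeShift:
    def test_zero(self):
        assert nmr.composite_shift(0.0, 0.0) == 0.0

    def test_worked_value(self):
        # sqrt(1/2 (0.1^2 + (0.5/5)^2)) = 0.1 ppm
        assert nmr.composite_shift(0.1, 0.5) == pytest.approx(0.1)

    def test_proton_only_closed_form(self):
        x = 0.37
        assert nmr.composite_shift(x, 0.0) == pytest.approx(x / np.sqrt(2))

    def test_sign_symmetric_and_monotone(self):
        assert nmr.composite_shift(-0.1, 0.5) == nmr.composite_shift(0.1, -0.5)
        grid = np.linspace(0, 1, 9)
        comp = nmr.composite_shift(grid, 0.2)
        assert (np.diff(comp) > 0).all()

    def test_broadened_records_carry_no_composite(self):
        df = nmr.add_composite(table([(1, 0.1, 0.5, True, False, np.nan),
                                      (2, 0.1, 0.5, False, False, np.nan)]))
        assert np.isnan(df.loc[0, "composite_ppm"])
        assert df.loc[1, "composite_ppm"] == pytest.approx(0.1)


class TestSignificanceCutoff:
    def test_constant_shifts_nothing_flagged(self):
        res = nmr.significance_cutoff([0.2] * 8)
        assert res.threshold == pytest.approx(0.2)
        assert len(res.significant) == 0

    def test_hand_built_ten_value_oracle(self):
        x = np.array([0.01, 0.02, 0.02, 0.03, 0.03, 0.04, 0.05, 0.05, 0.3, 0.4])
        res = nmr.significance_cutoff(x)
        expected = stats.trim_mean(x, 0.1) + 1.5 * np.std(x, ddof=1)
        assert res.threshold == pytest.approx(expected)
        above = np.where(x > expected)[0] + 1
        assert np.array_equal(res.significant, above)

    def test_outlier_separation(self):
        x = [0.01] * 9 + [1.0]
        res = nmr.significance_cutoff(x, residue_ids=np.arange(100, 110))
        assert list(res.significant) == [109]

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 0.5, size=20)
        a = nmr.significance_cutoff(x, residue_ids=np.arange(20))
        perm = rng.permutation(20)
        b = nmr.significance_cutoff(x[perm], residue_ids=np.arange(20)[perm])
        assert a.threshold == pytest.approx(b.threshold)
        assert sorted(a.significant) == sorted(b.significant)

    def test_broadened_nan_excluded_and_minimum_count(self):
        x = [0.1, np.nan, 0.2, 0.1, 0.15, 0.12]
        res = nmr.significance_cutoff(x)
        assert np.isfinite(res.threshold)
        with pytest.raises(InputError):
            nmr.significance_cutoff([0.1, np.nan, np.nan, 0.2])


class TestDeltaRex:
    def test_identity_zero(self):
        t = table([(i, 0, 0, False, True, 5.0 + i) for i in range(5)])
        out = nmr.delta_rex(t, t)
        assert np.allclose(out["delta_rex"], 0.0)
        assert out.attrs["mean_abs"] == 0.0

    def test_hand_subtraction(self):
        wt = table([(i, 0, 0, False, True, float(i)) for i in range(1, 6)])
        var = table([(i, 0, 0, False, True, float(2 * i)) for i in range(1, 6)])
        out = nmr.delta_rex(var, wt)
        assert list(out["delta_rex"]) == [1.0, 2.0, 3.0, 4.0, 5.0]
        assert out.attrs["mean_abs"] == pytest.approx(3.0)

    def test_one_sided_residues_excluded(self):
        wt = table([(1, 0, 0, False, True, 2.0), (2, 0, 0, False, True, 3.0)])
        var = table([(2, 0, 0, False, True, 4.0), (3, 0, 0, False, True, 9.0)])
        out = nmr.delta_rex(var, wt)
        assert list(out["residue"]) == [2]
        with pytest.raises(InputError):
            nmr.delta_rex(var, table([(9, 0, 0, False, True, 1.0)]))


class TestExchangeNetwork:
    def _partition(self):
        return CommunityPartition(
            assignment={**{i: 0 for i in range(5)}, **{i: 1 for i in range(5, 10)},
                        **{i: 2 for i in range(10, 15)}})

    def test_no_dispersive_residues(self):
        part = self._partition()
        cpmg = table([(i, 0, 0, False, False, np.nan) for i in range(15)])
        exch = nmr.cpmg_exchange_network(cpmg, part, adjacency={(0, 1), (1, 2)})
        assert np.allclose(exch.weights, 0.0)

    def test_worked_adjacent_pair_weight(self):
        """2 and 3 actives in adjacent communities, 5 total -> 6/25 = 0.24."""
        part = self._partition()
        active = [0, 1, 5, 6, 7]  # 2 in community 0, 3 in community 1
        cpmg = table([(i, 0, 0, False, i in active, np.nan) for i in range(15)])
        exch = nmr.cpmg_exchange_network(cpmg, part, adjacency={(0, 1)})
        assert exch.pair_weight(0, 1) == pytest.approx(0.24)
        assert exch.active_counts == {0: 2, 1: 3, 2: 0}

    def test_non_adjacent_pair_stays_zero(self):
        part = self._partition()
        cpmg = table([(i, 0, 0, False, True, np.nan) for i in range(15)])
        exch = nmr.cpmg_exchange_network(cpmg, part, adjacency={(0, 1)})
        assert exch.pair_weight(1, 2) == 0.0
        assert exch.pair_weight(0, 2) == 0.0

    def test_scale_invariance_of_default_normalization(self):
        big = CommunityPartition(
            assignment={**{i: 0 for i in range(10)},
                        **{i: 1 for i in range(10, 20)}})
        small_active = [0, 1, 10, 11, 12]
        doubled_active = [0, 1, 2, 3, 10, 11, 12, 13, 14, 15]
        def weight(active):
            cpmg = table([(i, 0, 0, False, i in active, np.nan)
                          for i in range(20)])
            return nmr.cpmg_exchange_network(cpmg, big,
                                             adjacency={(0, 1)}).pair_weight(0, 1)
        assert weight(small_active) == pytest.approx(weight(doubled_active))

    def test_adjacency_from_network(self):
        net, blocks = planted_network(n_residues=30, n_blocks=3, seed=1)
        part = CommunityPartition(
            assignment={int(r): int(b) for r, b in zip(net.residue_ids, blocks)})
        cpmg = table([(int(r), 0, 0, False, True, np.nan) for r in net.residue_ids])
        exch = nmr.cpmg_exchange_network(cpmg, part, net=net)
        # chain layout: blocks 0-1 and 1-2 touch, 0-2 do not
        assert exch.pair_weight(0, 1) > 0
        assert exch.pair_weight(1, 2) > 0
        assert exch.pair_weight(0, 2) == 0.0

    def test_active_residue_outside_partition_rejected(self):
        part = self._partition()
        cpmg = table([(99, 0, 0, False, True, np.nan)])
        with pytest.raises(InputError, match="99"):
            nmr.cpmg_exchange_network(cpmg, part, adjacency={(0, 1)})


def test_read_nmr_table_fills_defaults(tmp_path):
    path = tmp_path / "shifts.csv"
    pd.DataFrame({"residue": [1, 2], "ddH_ppm": [0.1, 0.2],
                  "ddN_ppm": [0.5, 0.1]}).to_csv(path, index=False)
    df = nmr.read_nmr_table(path)
    assert not df["broadened"].any()
    assert df["rex_s1"].isna().all()
    with pytest.raises(InputError):
        bad = tmp_path / "bad.csv"
        pd.DataFrame({"x": [1]}).to_csv(bad, index=False)
        nmr.read_nmr_table(bad)
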