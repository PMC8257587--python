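"""Peptide filtering, DE-peptide calling and protein rollup."""

import numpy as np
import pandas as pd
import pytest

from permdiff.exceptions import ConfigError, PermdiffError
from permdiff.proteomics import (
    DEPCall, build_channel_null, call_de_peptides, cross_fraction_overlap,
    filter_peptides, rollup_proteins,
)
from permdiff.simulate import simulate_tmt

from conftest import make_peptide_table


def de_frame(rows):
    return pd.DataFrame(rows, columns=["peptide_id", "protein_group",
                                       "direction", "is_de"]).assign(
        T=1.0, LMR=1.0, p=0.01)


class TestFilterPeptides:
    def test_purity_boundary_strict(self, channel_map):
        intens = np.full((10, 6), 100.0)
        intens[:, 0] = np.arange(1, 11) * 100  # spread max intensities
        purity = [0.75] + [0.9] * 9
        table = make_peptide_table(intens, channel_map, purity=purity)
        kept = filter_peptides(table, purity_min=0.75, intensity_percentile=0.0)
        assert "pep0" not in set(kept.data["peptide_id"])

    def test_nonunique_removed(self, channel_map):
        intens = np.full((4, 6), 100.0) * np.arange(1, 5)[:, None]
        table = make_peptide_table(intens, channel_map,
                                   unique=[False, True, True, True],
                                   purity=0.99)
        kept = filter_peptides(table, intensity_percentile=0.0)
        assert "pep0" not in set(kept.data["peptide_id"])

    def test_percentile_on_linear_grid(self, channel_map):
        # 100 peptides with max log2-intensities 1..100: the 5th percentile
        # of the grid is 5.95 (linear interpolation), so peptides 1..5 fall
        intens = np.ones((100, 6))
        intens[:, 0] = np.exp2(np.arange(1, 101, dtype=float))
        table = make_peptide_table(intens, channel_map, purity=0.99)
        kept = filter_peptides(table, intensity_percentile=5.0)
        assert kept.n_peptides == 95
        dropped = set(table.data["peptide_id"]) - set(kept.data["peptide_id"])
        assert dropped == {f"pep{i}" for i in range(5)}

    def test_everything_filtered_errors(self, channel_map):
        intens = np.full((3, 6), 10.0)
        table = make_peptide_table(intens, channel_map, purity=0.5)
        with pytest.raises(PermdiffError, match="purity_min"):
            filter_peptides(table)


class TestCallDePeptides:
    @pytest.fixture()
    def planted(self, channel_map):
        # keep the planted fraction small: planted peptides contaminate the
        # pooled channel-permutation null and would inflate the LMR cutoff
        rng = np.random.default_rng(0)
        n = 120
        intens = rng.lognormal(np.log(1e5), 0.1, size=(n, 6))
        intens[:10, 3:] *= 8.0  # proteins P0..P4 strongly up in senescent
        return make_peptide_table(intens, channel_map, purity=0.99)

    def test_joint_rule(self, planted):
        null = build_channel_null(planted, ("senescent", "young"),
                                  n_perm=100, seed=0)
        de = call_de_peptides(planted, ("senescent", "young"), null)
        assert de.loc[:9, "is_de"].all()
        assert de.loc[:9, "direction"].eq("up").all()
        # joint rule: high |LMR| alone is insufficient without small p
        called = de.loc[de["is_de"]]
        assert (called["p"] < 0.05).all()
        assert (called["LMR"].abs() > null.lmr_cutoff).all()

    def test_unknown_condition_config_error(self, planted):
        null = build_channel_null(planted, ("senescent", "young"),
                                  n_perm=10, seed=0)
        with pytest.raises(ConfigError, match="absent"):
            call_de_peptides(planted, ("senescent", "treated"), null)

    def test_replicate_support_rule(self, channel_map):
        # peptide quantified in only 2 replicates per condition (zeros
        # elsewhere) cannot be DE under the >2-replicates support rule
        intens = np.full((40, 6), 1000.0)
        rng = np.random.default_rng(1)
        intens *= rng.lognormal(0, 0.05, size=intens.shape)
        intens[0, 3:] *= 100.0
        intens[0, 0] = 0.0
        intens[0, 3] = 0.0
        table = make_peptide_table(intens, channel_map, purity=0.99)
        null = build_channel_null(table, ("senescent", "young"),
                                  n_perm=100, seed=2)
        de = call_de_peptides(table, ("senescent", "young"), null)
        assert not de.loc[0, "is_de"]

    def test_planted_recovery_with_fp_control(self):
        # 50 planted 4-fold proteins among 950 null, 3v3, CV 0.1
        table, truth = simulate_tmt(n_proteins=1000, peptides_per_protein=2,
                                    frac_de=0.05, fold=4.0, cv=0.1, seed=3,
                                    frac_nonunique=0.0, frac_low_purity=0.0)
        filt = filter_peptides(table)
        with pytest.warns(UserWarning):
            null = build_channel_null(filt, ("senescent", "young"),
                                      n_perm=100, seed=4)
        de = call_de_peptides(filt, ("senescent", "young"), null)
        planted = truth.planted()
        mask = de["protein_group"].isin(planted)
        assert de.loc[mask, "is_de"].mean() >= 0.9
        assert de.loc[~mask, "is_de"].mean() <= 0.07


class TestRollup:
    def test_two_up_peptides_make_dep(self):
        de = de_frame([["p1", "A", "up", True], ["p2", "A", "up", True]])
        calls = rollup_proteins(de)
        assert len(calls) == 1
        assert calls[0].direction == "up"
        assert calls[0].n_de_peptides == 2

    def test_single_peptide_no_call(self):
        de = de_frame([["p1", "A", "up", True], ["p2", "A", "up", False]])
        assert rollup_proteins(de) == []

    def test_mixed_directions_no_call(self):
        de = de_frame([["p1", "A", "up", True], ["p2", "A", "down", True]])
        assert rollup_proteins(de) == []

    def test_empty_input_empty_output(self):
        assert rollup_proteins(de_frame([])) == []

    def test_sorted_by_protein(self):
        de = de_frame([["p1", "B", "up", True], ["p2", "B", "up", True],
                       ["p3", "A", "down", True], ["p4", "A", "down", True]])
        calls = rollup_proteins(de)
        assert [c.protein_group for c in calls] == ["A", "B"]

    def test_monotone_adding_consistent_peptide(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(2, 8)
            rows = [[f"p{i}", "A", "up", True] for i in range(n)]
            before = rollup_proteins(de_frame(rows))
            after = rollup_proteins(de_frame(rows + [["extra", "A", "up",
                                                      True]]))
            called_before = {c.protein_group for c in before}
            called_after = {c.protein_group for c in after}
            assert called_before <= called_after


class TestCrossFraction:
    def make(self, spec):
        return [DEPCall(protein_group=p, direction=d, n_de_peptides=2,
                        supporting_peptides=("x", "y")) for p, d in spec]

    def test_disjoint(self):
        out = cross_fraction_overlap(self.make([("A", "up")]),
                                     self.make([("B", "up")]))
        assert out["n_common"] == 0

    def test_identical_up_lists(self):
        deps = self.make([(f"P{i}", "up") for i in range(5)])
        out = cross_fraction_overlap(deps, deps)
        assert out["n_up"] == 5 and out["n_down"] == 0

    def test_hand_set_arithmetic(self):
        nuc = self.make([("A", "up"), ("B", "down"), ("C", "up")])
        cyt = self.make([("A", "up"), ("B", "up")])
        out = cross_fraction_overlap(nuc, cyt)
        assert out["common_up"] == {"A"}
        assert out["common_down"] == set()


class TestNullFalsePositives:
    def test_null_dep_rate_below_1pct(self):
        # fully null tables over 20 seeds: protein-level FP < 1%
        total_fp = 0
        total = 0
        for seed in range(20):
            table, _ = simulate_tmt(n_proteins=150, peptides_per_protein=2,
                                    frac_de=0.0, fold=4.0, cv=0.1, seed=seed,
                                    frac_nonunique=0.0, frac_low_purity=0.0)
            filt = filter_peptides(table)
            with pytest.warns(UserWarning):
                null = build_channel_null(filt, ("senescent", "young"),
                                          n_perm=100, seed=seed + 100)
            de = call_de_peptides(filt, ("senescent", "young"), null)
            total_fp += len(rollup_proteins(de))
            total += 150
        assert total_fp / total < 0.01

    def test_compartment_shift_recovery(self, channel_map):
        # proteins planted up in "nucleus" and down in "cytoplasm" are
        # recovered by the direction-opposite cross-fraction logic
        n = 200  # planted fraction kept at 5% to not contaminate the null

        def fraction_table(direction_factor, seed):
            r = np.random.default_rng(seed)
            intens = r.lognormal(np.log(1e5), 0.1, size=(n, 6))
            intens[:10, 3:] *= 4.0 ** direction_factor
            return make_peptide_table(intens, channel_map, purity=0.99)

        deps = {}
        for name, factor, seed in (("nucleus", 1, 7), ("cytoplasm", -1, 8)):
            table = fraction_table(factor, seed)
            null = build_channel_null(table, ("senescent", "young"),
                                      n_perm=100, seed=seed)
            de = call_de_peptides(table, ("senescent", "young"), null)
            deps[name] = rollup_proteins(de, fraction=name)
        up_nuc = {c.protein_group for c in deps["nucleus"]
                  if c.direction == "up"}
        down_cyt = {c.protein_group for c in deps["cytoplasm"]
                    if c.direction == "down"}
        planted = {f"P{i}" for i in range(5)}  # 10 peptides -> 5 proteins
        recovered = up_nuc & down_cyt & planted
        assert len(recovered) / len(planted) >= 0.9
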