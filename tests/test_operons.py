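"""Discretization, microarray scoring, log-odds adjustment, TU assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from omstress.operons import (
    adjust_prediction_scores,
    assemble_transcription_units,
    build_frequency_tables,
    classify_band,
    compute_base_values,
    discretize_matrix,
    microarray_score,
    refine_operons,
)
from omstress.operons import _discretize


class TestBaseValues:
    def test_mean_of_baseline_arrays(self):
        expr = pd.DataFrame(
            {"b1": [8.0, 7.0, 5.0], "b2": [8.0, 9.0, 5.0], "x1": [99.0, 99.0, 99.0]},
            index=["g1", "g2", "g3"],
        )
        base = compute_base_values(expr, ["b1", "b2"])
        assert list(base) == [8.0, 8.0, 5.0]
        single = compute_base_values(expr, ["b1"])
        assert list(single) == [8.0, 7.0, 5.0]

    def test_requires_baseline(self):
        expr = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            compute_base_values(expr, [])
        with pytest.raises(ValueError, match="not in matrix"):
            compute_base_values(expr, ["zzz"])


class TestDiscretize:
    @pytest.mark.parametrize(
        "diff,level",
        [
            (0.3, 0),
            (-0.3, 0),
            (-0.5, 0),  # the printed zero bin is closed on the left
            (0.5, 1),
            (1.6, 2),
            (2.4, 2),
            (3.5, 4),
            (4.2, 4),
            (-0.6, -1),
            (-1.5, -2),
            (-4.2, -4),
            (-100.0, -4),
            (100.0, 4),
        ],
    )
    def test_bin_examples(self, diff, level):
        assert _discretize(np.array([diff]))[0] == level

    @given(st.floats(min_value=0.0, max_value=10.0))
    @settings(max_examples=100, deadline=None)
    def test_mirror_symmetry_off_boundaries(self, d):
        # stay away from the half-integer bin edges where the closure differs
        assume(abs((d + 0.5) - round(d + 0.5)) > 1e-6)
        pos = _discretize(np.array([d]))[0]
        neg = _discretize(np.array([-d]))[0]
        assert neg == -pos
        assert -4 <= pos <= 4

    def test_matrix_uses_per_gene_base(self):
        expr = pd.DataFrame(
            {"b1": [10.0, 5.0], "b2": [10.0, 5.0], "x1": [11.6, 4.4]},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        disc = discretize_matrix(expr, compute_base_values(expr, ["b1", "b2"]))
        assert disc.loc["g1", "x1"] == 2  # diff 1.6
        assert disc.loc["g2", "x1"] == -1  # diff -0.6
        assert (disc[["b1", "b2"]] == 0).all().all()

    def test_nonfinite_cell_named(self):
        expr = pd.DataFrame({"a": [np.nan]}, index=pd.Index(["gX"], name="gene_id"))
        with pytest.raises(ValueError, match="gX"):
            discretize_matrix(expr, pd.Series([0.0], index=["gX"]))


class TestMicroarrayScore:
    def test_count_matching_positions(self):
        disc = pd.DataFrame(
            [[0, 1, 2, 0], [0, 2, 2, 1], [3, 3, 3, 3]],
            index=["g1", "g2", "g3"],
            columns=list("abcd"),
        )
        assert microarray_score("g1", "g2", disc) == 2
        assert microarray_score("g1", "g1", disc) == 4
        assert microarray_score("g1", "g3", disc) == 0
        assert microarray_score("g1", "missing", disc) is None


class TestFrequencyTables:
    def _setup(self):
        # 4 arrays; operon pairs engineered to X = {4, 4, 4, 2}
        disc = pd.DataFrame(
            [
                [0, 1, 2, 0],
                [0, 1, 2, 0],  # o1 pair: X=4
                [1, 1, 0, 0],
                [1, 1, 0, 0],  # o2 pair: X=4
                [2, 2, 2, 2],
                [2, 2, 2, 2],  # o3 pair: X=4
                [0, 0, 1, 1],
                [0, 0, 2, 2],  # o4 pair: X=2
                [3, 3, 3, 3],
                [0, 1, 0, 1],  # boundary pair: X=0
            ],
            index=[f"g{i}" for i in range(10)],
            columns=list("abcd"),
        )
        rows = []
        for i in range(0, 8, 2):
            rows.append(("g%d" % i, "g%d" % (i + 1), 1.0))  # confident operon
        rows.append(("g8", "g9", 8.0))  # confident boundary
        pairs = pd.DataFrame(rows, columns=["upstream_gene", "downstream_gene", "prediction_score"])
        return pairs, disc

    def test_unsmoothed_relative_frequencies(self):
        pairs, disc = self._setup()
        freq = build_frequency_tables(pairs, disc, alpha=0.0)
        assert freq.loc[4, "f_op"] == pytest.approx(0.75)
        assert freq.loc[2, "f_op"] == pytest.approx(0.25)
        assert freq.loc[0, "f_bp"] == pytest.approx(1.0)

    def test_smoothing_gives_full_positive_support(self):
        pairs, disc = self._setup()
        freq = build_frequency_tables(pairs, disc, alpha=0.5)
        assert list(freq.index) == [0, 1, 2, 3, 4]
        assert (freq > 0).all().all()
        assert freq.sum().round(12).eq(1.0).all()

    def test_ambiguous_pairs_never_contribute(self):
        pairs, disc = self._setup()
        with_amb = pd.concat(
            [pairs, pd.DataFrame([{"upstream_gene": "g0", "downstream_gene": "g1", "prediction_score": 3.0}])],
            ignore_index=True,
        )
        f1 = build_frequency_tables(pairs, disc)
        f2 = build_frequency_tables(with_amb, disc)
        pd.testing.assert_frame_equal(f1, f2)

    def test_missing_class_errors(self):
        pairs, disc = self._setup()
        only_op = pairs[pairs["prediction_score"] < 1.5]
        with pytest.raises(ValueError, match="boundary"):
            build_frequency_tables(only_op, disc)


class TestAdjustment:
    def _freq(self, f_bp, f_op):
        return pd.DataFrame({"f_bp": f_bp, "f_op": f_op}, index=pd.Index(range(len(f_bp)), name="X"))

    def test_equal_frequencies_leave_scores_unchanged(self):
        disc = pd.DataFrame([[0, 1], [0, 1]], index=["g1", "g2"], columns=["a", "b"])
        pairs = pd.DataFrame(
            [{"upstream_gene": "g1", "downstream_gene": "g2", "prediction_score": 3.0}]
        )
        freq = self._freq([0.3, 0.3, 0.4], [0.3, 0.3, 0.4])
        out = adjust_prediction_scores(pairs, disc, freq)
        assert out["adjusted_score"].iloc[0] == pytest.approx(3.0)

    def test_hand_computed_log_odds(self):
        # pair matches in 1 of 2 arrays -> X=1; f_bp(1)=0.4, f_op(1)=0.1
        disc = pd.DataFrame([[0, 1], [0, 2]], index=["g1", "g2"], columns=["a", "b"])
        pairs = pd.DataFrame(
            [{"upstream_gene": "g1", "downstream_gene": "g2", "prediction_score": 3.0}]
        )
        freq = self._freq([0.3, 0.4, 0.3], [0.6, 0.1, 0.3])
        out = adjust_prediction_scores(pairs, disc, freq)
        assert out["adjusted_score"].iloc[0] == pytest.approx(3.0 + math.log(4.0))
        assert out["microarray_score"].iloc[0] == 1

    @pytest.mark.parametrize("score", [1.2, 0.0, 5.5, 9.0])
    def test_non_ambiguous_never_modified(self, score):
        disc = pd.DataFrame([[0, 1], [0, 2]], index=["g1", "g2"], columns=["a", "b"])
        pairs = pd.DataFrame(
            [{"upstream_gene": "g1", "downstream_gene": "g2", "prediction_score": score}]
        )
        freq = self._freq([0.3, 0.4, 0.3], [0.6, 0.1, 0.3])
        out = adjust_prediction_scores(pairs, disc, freq)
        assert out["adjusted_score"].iloc[0] == score
        assert classify_band(score) != "ambiguous"

    def test_missing_expression_keeps_raw_score(self):
        disc = pd.DataFrame([[0, 1]], index=["g1"], columns=["a", "b"])
        pairs = pd.DataFrame(
            [{"upstream_gene": "g1", "downstream_gene": "gZ", "prediction_score": 3.0}]
        )
        freq = self._freq([0.5, 0.5], [0.5, 0.5])
        out = adjust_prediction_scores(pairs, disc, freq)
        assert out["adjusted_score"].iloc[0] == 3.0
        assert out["microarray_score"].isna().iloc[0]


class TestAssembly:
    def _pairs(self, scores):
        genes = [f"g{i}" for i in range(1, len(scores) + 2)]
        return (
            pd.DataFrame(
                {
                    "upstream_gene": genes[:-1],
                    "downstream_gene": genes[1:],
                    "prediction_score": scores,
                    "adjusted_score": scores,
                }
            ),
            genes,
        )

    def test_chain_merge(self):
        pairs, genes = self._pairs([1.0, 1.0, 8.0, 8.0])
        omap = assemble_transcription_units(pairs, genes)
        assert omap.units == [["g1", "g2", "g3"], ["g4"], ["g5"]]
        assert omap.summary["n_transcription_units"] == 3

    def test_no_links_all_singletons(self):
        pairs, genes = self._pairs([8.0, 8.0, 8.0])
        omap = assemble_transcription_units(pairs, genes)
        assert all(len(u) == 1 for u in omap.units)

    @given(st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_tu_count_identity(self, scores):
        pairs, genes = self._pairs(scores)
        omap = assemble_transcription_units(pairs, genes)
        assert (
            omap.summary["n_transcription_units"]
            == omap.summary["n_genes"] - omap.summary["n_operon_pair_calls"]
        )
        assert sorted(g for u in omap.units for g in u) == sorted(genes)

    def test_tau_outside_band_rejected(self):
        pairs, genes = self._pairs([1.0])
        with pytest.raises(ValueError, match="tau"):
            assemble_transcription_units(pairs, genes, tau=7.0)

    def test_non_consecutive_pair_rejected(self):
        pairs, genes = self._pairs([1.0, 1.0])
        pairs.loc[1, "downstream_gene"] = "g1"
        with pytest.raises(ValueError, match="consecutive"):
            assemble_transcription_units(pairs, genes)


class TestRefinement:
    def test_perfect_correlation_no_noise_gives_max_score(self):
        from omstress.simulate import SimulationConfig, gen_expression_with_operons

        cfg = SimulationConfig(
            seed=3, n_genes=60, within_operon_correlation=1.0, noise_sd=0.0
        )
        expr, pairs, baseline, truth = gen_expression_with_operons(cfg)
        base = compute_base_values(expr, baseline)
        disc = discretize_matrix(expr, base)
        op = truth[truth["true_class"] == "operon_pair"]
        xs = [
            microarray_score(r["upstream_gene"], r["downstream_gene"], disc)
            for _, r in op.iterrows()
        ]
        assert xs and all(x == cfg.n_arrays for x in xs)

    def test_adjustment_moves_ambiguous_toward_truth(self):
        from omstress.simulate import SimulationConfig, gen_expression_with_operons

        cfg = SimulationConfig(seed=4, n_genes=600)
        expr, pairs, baseline, truth = gen_expression_with_operons(cfg)
        adjusted, omap = refine_operons(pairs, expr, baseline)
        merged = adjusted.merge(
            truth[["upstream_gene", "downstream_gene", "true_class"]],
            on=["upstream_gene", "downstream_gene"],
        )
        amb = merged["band"] == "ambiguous"
        tau = 3.25
        raw = np.where(merged["prediction_score"] < tau, "operon_pair", "boundary_pair")
        adj = np.where(merged["adjusted_score"] < tau, "operon_pair", "boundary_pair")
        acc_raw = (raw[amb] == merged.loc[amb, "true_class"]).mean()
        acc_adj = (adj[amb] == merged.loc[amb, "true_class"]).mean()
        assert acc_adj >= acc_raw
        # confident pairs keep raw scores and calls
        conf = merged["band"] != "ambiguous"
        assert (merged.loc[conf, "adjusted_score"] == merged.loc[conf, "prediction_score"]).all()
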