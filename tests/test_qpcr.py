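"""2^-ddCt quantification, replicate handling, Tukey letters."""

import math

import numpy as np
import pandas as pd
import pytest

from mir166kit.qpcr import (
    analytic_log2_sem,
    delta_ct,
    fold_change,
    fold_change_table,
    tukey_letters,
)
from mir166kit.synthetic import QpcrDesign, generate_ct_table


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "treatment", "timepoint_h", "gene",
            "replicate_bio", "replicate_tech", "ct",
        ],
    )


def _cell(gene, cts, treatment="x", tp=0.0, bio=1):
    return [
        ("s", treatment, tp, gene, bio, i + 1, ct) for i, ct in enumerate(cts)
    ]


class TestDeltaCt:
    def test_tech_replicates_averaged(self):
        df = _records(_cell("g", [20, 20, 20]) + _cell("U6", [15, 15, 15]))
        out = delta_ct(df, "g")
        assert out["delta_ct"].tolist() == [5.0]

    def test_unbalanced_tech_replicates(self):
        df = _records(_cell("g", [20, 21]) + _cell("U6", [15]))
        assert delta_ct(df, "g")["delta_ct"].iloc[0] == pytest.approx(5.5)

    def test_reference_only_table_fails(self):
        df = _records(_cell("U6", [15, 15]))
        with pytest.raises(ValueError):
            delta_ct(df, "g")

    def test_missing_reference_names_cell(self):
        df = _records(
            _cell("g", [20], tp=0.0) + _cell("U6", [15], tp=0.0)
            + _cell("g", [19], tp=2.0)
        )
        with pytest.raises(ValueError, match="timepoint_h=2.0"):
            delta_ct(df, "g")


class TestFoldChange:
    def test_equal_delta_ct_gives_unit_fold(self):
        df = _records(
            _cell("g", [20], tp=0.0) + _cell("U6", [15], tp=0.0)
            + _cell("g", [20], tp=2.0) + _cell("U6", [15], tp=2.0)
        )
        results = {r.timepoint_h: r for r in fold_change(df, "g")}
        assert results[0.0].mean_fold == pytest.approx(1.0)
        assert results[2.0].mean_fold == pytest.approx(1.0)

    def test_ddct_minus_two_gives_fourfold(self):
        df = _records(
            _cell("g", [20], tp=0.0) + _cell("U6", [15], tp=0.0)
            + _cell("g", [18], tp=2.0) + _cell("U6", [15], tp=2.0)
        )
        results = {r.timepoint_h: r for r in fold_change(df, "g")}
        assert results[2.0].mean_fold == pytest.approx(4.0)

    def test_missing_control_fails(self):
        df = _records(
            _cell("g", [20], tp=2.0) + _cell("U6", [15], tp=2.0)
        )
        with pytest.raises(ValueError, match="control"):
            fold_change(df, "g")

    def test_reference_invariance_to_sample_shift(self):
        base = (
            _cell("g", [20, 20], tp=0.0) + _cell("U6", [15, 15], tp=0.0)
            + _cell("g", [18, 18], tp=2.0) + _cell("U6", [15, 15], tp=2.0)
        )
        shifted = [
            (s, tr, tp, gene, b, t, ct + (3.0 if tp == 2.0 else 0.0))
            for (s, tr, tp, gene, b, t, ct) in base
        ]
        r1 = {r.timepoint_h: r.mean_fold for r in fold_change(_records(base), "g")}
        r2 = {r.timepoint_h: r.mean_fold for r in fold_change(_records(shifted), "g")}
        assert r1 == pytest.approx(r2)


class TestGeneratorRoundTrip:
    def test_zero_noise_recovers_planted_folds_exactly(self):
        design = QpcrDesign(
            treatments={"freezing": [0.0, 2.0]},
            fold_profile={
                ("h3p", "freezing", 2.0): 18.6,
                ("i3p", "freezing", 2.0): 28.6,
            },
            noise_sd=0.0,
        )
        ct = generate_ct_table(design, seed=11)
        for gene, expected in (("h3p", 18.6), ("i3p", 28.6)):
            results = {r.timepoint_h: r for r in fold_change(ct, gene)}
            assert results[2.0].mean_fold == pytest.approx(expected)
            assert results[0.0].mean_fold == pytest.approx(1.0)

    def test_unit_profile_zero_noise_gives_unit_folds(self):
        design = QpcrDesign(
            treatments={"salt": [0.0, 6.0, 9.0]},
            fold_profile={("g", "salt", 6.0): 1.0},
            genes=["g"],
            noise_sd=0.0,
        )
        ct = generate_ct_table(design, seed=0)
        for r in fold_change(ct, "g"):
            assert r.mean_fold == pytest.approx(1.0)

    def test_missing_control_timepoint_rejected(self):
        with pytest.raises(ValueError, match="control"):
            QpcrDesign(
                treatments={"salt": [6.0, 9.0]},
                fold_profile={("g", "salt", 6.0): 2.0},
            )

    def test_noise_coverage_against_analytic_sem(self):
        sem = analytic_log2_sem(0.2, n_bio=3, n_tech=3)
        design = QpcrDesign(
            treatments={"cold": [0.0, 9.0]},
            fold_profile={("g", "cold", 9.0): 4.1},
            noise_sd=0.2,
        )
        covered = 0
        for seed in range(100):
            ct = generate_ct_table(design, seed=seed)
            r = [x for x in fold_change(ct, "g") if x.timepoint_h == 9.0][0]
            err = abs(math.log2(r.mean_fold) - math.log2(4.1))
            covered += err <= 3 * sem
        assert covered >= 95


class TestTukeyLetters:
    def test_identical_groups_share_one_letter(self):
        letters = tukey_letters({"a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1, 1]})
        assert set(letters.values()) == {"a"}

    def test_clear_separation_gets_two_letters(self):
        letters = tukey_letters(
            {
                "g1": [0.0, 0.01, -0.01],
                "g2": [0.01, -0.01, 0.0],
                "g3": [10.0, 10.01, 9.99],
            }
        )
        assert letters["g1"] == letters["g2"]
        assert letters["g3"] != letters["g1"]

    def test_alpha_one_separates_distinct_means(self):
        letters = tukey_letters(
            {
                "g1": [0.0, 0.01, -0.01],
                "g2": [5.0, 5.01, 4.99],
                "g3": [10.0, 10.01, 9.99],
            },
            alpha=1.0,
        )
        assert len(set(letters.values())) == 3

    def test_single_replicate_group_fails(self):
        with pytest.raises(ValueError):
            tukey_letters({"a": [1.0], "b": [1, 2]})


class TestFoldChangeTable:
    def test_full_table_with_letters(self):
        design = QpcrDesign(
            treatments={"freezing": [0.0, 2.0, 6.0]},
            fold_profile={("g", "freezing", 2.0): 18.6},
            noise_sd=0.05,
        )
        ct = generate_ct_table(design, seed=5)
        table = fold_change_table(ct, ["g"])
        assert set(table.columns) >= {
            "gene", "treatment", "timepoint_h", "mean_fold", "sd_fold",
            "n_bio", "letters",
        }
        row = table[table["timepoint_h"] == 2.0].iloc[0]
        assert row["mean_fold"] == pytest.approx(18.6, rel=0.2)
        base = table[table["timepoint_h"] == 0.0].iloc[0]
        assert row["letters"] != base["letters"]
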