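import logging
import math

import numpy as np
import pytest

from fepkit.cycle import (
    CorrectionSet,
    DeltaDeltaG,
    LegResult,
    apply_corrections,
    compare_to_experiment,
    ddg,
    ddg_correction_shift,
    fold_change_threshold,
    orient,
)
from fepkit.estimators import FreeEnergyEstimate, estimate_leg
from fepkit.fep_io import load_reference_records, load_reference_table


def leg(kind, value, stderr, mutation="D112E", label=None):
    return LegResult(
        leg=kind,
        estimate=FreeEnergyEstimate(value, stderr, "bar"),
        system_label=label or f"{mutation}:{kind}",
        mutation=mutation,
    )


class TestDdg:
    def test_three_four_five(self):
        out = ddg(leg("apo", 1.0, 0.3), leg("holo", 2.0, 0.4))
        assert out.value == pytest.approx(1.0)
        assert out.stderr == pytest.approx(0.5)

    def test_identical_legs_cancel(self):
        out = ddg(leg("apo", 2.2, 0.3), leg("holo", 2.2, 0.3))
        assert out.value == 0.0
        assert out.stderr == pytest.approx(math.sqrt(2) * 0.3)

    def test_cycle_closure_with_shared_ensembles(self, toy_windows):
        """Running the same window data through both legs closes the cycle
        exactly."""
        total = estimate_leg(toy_windows)
        out = ddg(
            leg("apo", total.value, total.stderr),
            leg("holo", total.value, total.stderr),
        )
        assert out.value == 0.0

    def test_mismatched_mutations_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ddg(leg("apo", 1.0, 0.1, "D112E"), leg("holo", 2.0, 0.1, "R208K"))

    def test_legs_must_be_apo_then_holo(self):
        with pytest.raises(ValueError):
            ddg(leg("holo", 1.0, 0.1), leg("apo", 2.0, 0.1))


class TestOrient:
    def test_forward_is_identity(self):
        d = DeltaDeltaG("V178A", 0.8, 0.3)
        assert orient(d, "forward") is d

    def test_reversed_negates_and_labels(self):
        d = DeltaDeltaG("S211R", -1.3, 0.4)
        out = orient(d, "reversed")
        assert out.value == pytest.approx(1.3)
        assert out.stderr == 0.4
        assert out.label == "-1x S211R"

    def test_involution(self):
        d = DeltaDeltaG("S211R", -1.3, 0.4)
        twice = orient(orient(d, "reversed"), "reversed")
        assert twice.value == pytest.approx(d.value)
        assert twice.stderr == d.stderr


class TestCorrections:
    def test_published_r211s_shift(self):
        """Finite-size corrections for the charge-changing mutation:
        apo -3.1042, holo(gbi1) -3.1030 -> net ddG shift +0.0012."""
        shift = ddg_correction_shift(-3.1042, -3.1030)
        assert shift == pytest.approx(0.0012, abs=1e-10)

    def test_packaged_corrections_applied_to_legs(self):
        from fepkit.fep_io import load_reference_corrections

        corr = load_reference_corrections()
        legs = [
            leg("apo", 10.0, 0.1, "R211S", label="R211S:apo"),
            leg("holo", 12.0, 0.2, "R211S", label="R211S:holo_gbi1"),
        ]
        apo_c, holo_c = apply_corrections(legs, corr)
        assert apo_c.estimate.value == pytest.approx(10.0 - 3.1042)
        assert holo_c.estimate.value == pytest.approx(12.0 - 3.1030)
        assert apo_c.estimate.stderr == 0.1  # corrections are analytic constants
        before = ddg(legs[0], legs[1]).value
        after = ddg(apo_c, holo_c).value
        assert after - before == pytest.approx(0.0012, abs=1e-9)

    def test_equal_corrections_cancel_in_ddg(self):
        corr = CorrectionSet({"m:apo": -1.7, "m:holo": -1.7})
        legs = [leg("apo", 1.0, 0.1, "m", "m:apo"), leg("holo", 3.0, 0.1, "m", "m:holo")]
        a, h = apply_corrections(legs, corr)
        assert ddg(a, h).value == pytest.approx(ddg(*legs).value)

    def test_missing_label_defaults_to_zero_with_warning(self, caplog):
        corr = CorrectionSet({})
        with caplog.at_level(logging.WARNING):
            (out,) = apply_corrections([leg("apo", 1.5, 0.1)], corr)
        assert out.estimate.value == 1.5
        assert any("no correction" in r.message for r in caplog.records)

    def test_nonfinite_correction_rejected(self):
        with pytest.raises(ValueError):
            CorrectionSet({"x": float("nan")})

    def test_uniform_shift_leaves_every_ddg_unchanged(self, rng):
        labels = [("m1:apo", "m1:holo"), ("m2:apo", "m2:holo")]
        legs = []
        for i, (la, lh) in enumerate(labels):
            m = f"m{i+1}"
            legs += [
                leg("apo", rng.normal(), 0.1, m, la),
                leg("holo", rng.normal(), 0.1, m, lh),
            ]
        shift = 4.2
        corr = CorrectionSet({l: shift for pair in labels for l in pair})
        shifted = apply_corrections(legs, corr)
        for i in range(0, 4, 2):
            assert ddg(shifted[i], shifted[i + 1]).value == pytest.approx(
                ddg(legs[i], legs[i + 1]).value
            )


class TestFoldChangeThreshold:
    def test_ten_fold_at_room_temperature(self):
        """A 10-fold change in K_eq at 300 K is ~1.4 kcal/mol."""
        v = fold_change_threshold(300.0, 10.0)
        assert v == pytest.approx(1.3727, abs=1e-4)
        assert round(v, 1) == 1.4

    def test_unit_fold_is_zero(self):
        assert fold_change_threshold(300.0, 1.0) == 0.0

    def test_linear_in_temperature(self):
        assert fold_change_threshold(600.0, 10.0) == pytest.approx(
            2.0 * fold_change_threshold(300.0, 10.0)
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fold_change_threshold(-1.0, 10.0)
        with pytest.raises(ValueError):
            fold_change_threshold(300.0, 0.0)


def reference_computed(tautomer: str):
    df = load_reference_table()
    return [
        DeltaDeltaG(row["mutation"], row[f"ddg_{tautomer}_kcal_mol"], row[f"err_{tautomer}_kcal_mol"])
        for _, row in df.iterrows()
    ]


class TestCompareToExperiment:
    def test_gbi2_mae_over_all_six_mutations(self):
        """Published gbi2 ddG values vs experiment give MAE 2.1 kcal/mol."""
        res = compare_to_experiment(reference_computed("gbi2"), load_reference_records())
        assert res.mae_rounded == pytest.approx(2.1)
        assert len(res.included) == 6

    def test_gbi2_mae_improves_without_the_outlier(self):
        res = compare_to_experiment(
            reference_computed("gbi2"), load_reference_records(), exclude={"R211S"}
        )
        assert res.mae_rounded == pytest.approx(1.1)
        assert "R211S" not in res.included

    def test_perfect_agreement_gives_zero_mae(self):
        records = load_reference_records()
        exact = [DeltaDeltaG(r.mutation, r.ddg_expt, 0.0) for r in records]
        res = compare_to_experiment(exact, records)
        assert res.mae == 0.0
        assert res.table["within_band"].all()

    def test_band_flag_uses_ten_fold_threshold(self):
        records = load_reference_records()
        res = compare_to_experiment(reference_computed("gbi2"), records)
        band = fold_change_threshold(300.0, 10.0)
        expected = res.table["deviation"].abs() <= band
        assert (res.table["within_band"] == expected).all()

    def test_excluding_never_increases_total_deviation(self):
        records = load_reference_records()
        computed = reference_computed("gbi1")
        full = compare_to_experiment(computed, records)
        reduced = compare_to_experiment(computed, records, exclude={"R208K"})
        assert (
            reduced.table["deviation"].abs().sum()
            <= full.table["deviation"].abs().sum()
        )

    def test_unknown_mutation_rejected(self):
        with pytest.raises(KeyError):
            compare_to_experiment(
                [DeltaDeltaG("Q999X", 0.0, 0.0)], load_reference_records()
            )

    def test_all_excluded_rejected(self):
        records = load_reference_records()
        with pytest.raises(ValueError):
            compare_to_experiment(
                reference_computed("gbi2"),
                records,
                exclude={r.mutation for r in records},
            )
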