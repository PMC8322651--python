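import math

import pytest
from hypothesis import given, settings, strategies as st

from cgsterol.composition import (
    SPECIES,
    BilayerComposition,
    SterolMeasurement,
    build_bilayer_composition,
    realize_counts,
    reference_systems,
    round_half_up,
    sterol_molpercent,
)


class TestSterolMolpercent:
    @pytest.mark.parametrize(
        "content,expected,ndigits",
        [
            (621.0, 38, 0),     # cholesterol after 50 mg/dl LDL
            (760.0, 43, 0),     # cholesterol after 250 mg/dl LDL
            (21.03, 2.06, 2),   # 7KC after oxLDL exposure
            (2.41, 0.24, 2),    # baseline 7KC
            (0.0, 0.0, 2),
        ],
    )
    def test_measured_contents_convert_to_printed_molpercent(
        self, content, expected, ndigits
    ):
        assert round_half_up(sterol_molpercent(content), ndigits) == expected

    def test_unrounded_values(self):
        assert sterol_molpercent(621.0) == pytest.approx(100 * 621 / 1621)
        assert sterol_molpercent(760.0) == pytest.approx(100 * 760 / 1760)

    def test_negative_content_rejected(self):
        with pytest.raises(ValueError):
            sterol_molpercent(-1.0)
        with pytest.raises(ValueError):
            SterolMeasurement("CHOL", -0.5)

    @given(st.floats(min_value=0, max_value=1e6))
    @settings(max_examples=200, deadline=None)
    def test_bounded_below_100(self, content):
        assert 0 <= sterol_molpercent(content) < 100

    @given(
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing(self, content, delta):
        assert sterol_molpercent(content + delta) > sterol_molpercent(content)


class TestBuildComposition:
    def test_sterol_free_membrane_splits_70_30_and_80_20(self):
        comp = build_bilayer_composition(0.0, 0.0)
        assert comp.rounded_percents() == {
            "POPC": 56, "DPPC": 14, "SM": 30, "CHOL": 0, "7KC": 0.0
        }

    @pytest.mark.parametrize(
        "chol,kc7,popc,dppc,sm",
        [
            (40.0, 0.24, 33, 8, 18),   # control
            (40.0, 2.06, 32, 8, 17),   # oxLDL-exposed
            (38.0, 0.04, 35, 9, 19),   # 50 mg/dl LDL
            (43.0, 0.04, 32, 8, 17),   # 250 mg/dl LDL
        ],
    )
    def test_reproduces_published_phospholipid_cells(
        self, chol, kc7, popc, dppc, sm
    ):
        r = build_bilayer_composition(chol, kc7).rounded_percents()
        assert (r["POPC"], r["DPPC"], r["SM"]) == (popc, dppc, sm)
        assert r["CHOL"] == chol
        assert r["7KC"] == kc7

    def test_reference_systems_match_published_table(self):
        expected = {
            "control": (33, 8, 18, 40, 0.24),
            "oxLDL": (32, 8, 17, 40, 2.06),
            "LDL50": (35, 9, 19, 38, 0.04),
            "LDL250": (32, 8, 17, 43, 0.04),
        }
        systems = reference_systems()
        for name, cells in expected.items():
            r = systems[name].rounded_percents()
            assert tuple(r[sp] for sp in SPECIES) == cells, name

    def test_sterols_at_or_above_100_rejected(self):
        with pytest.raises(ValueError):
            build_bilayer_composition(60.0, 40.0)
        with pytest.raises(ValueError):
            build_bilayer_composition(-1.0, 0.0)

    @given(
        st.floats(min_value=0, max_value=99),
        st.floats(min_value=0, max_value=99),
    )
    @settings(max_examples=200, deadline=None)
    def test_unrounded_percents_sum_to_100(self, chol, kc7):
        if chol + kc7 >= 100:
            return
        comp = build_bilayer_composition(chol, kc7)
        assert math.isclose(
            sum(comp.percents.values()), 100.0, abs_tol=1e-9
        )


def _largest_remainder_oracle(percents, seats):
    """Brute-force largest-remainder apportionment with a floor of 1."""
    targets = {sp: percents.get(sp, 0.0) / 100.0 * seats for sp in SPECIES}
    counts = {
        sp: max(math.floor(t), 1 if percents.get(sp, 0) > 0 else 0)
        for sp, t in targets.items()
    }
    rem = sorted(
        SPECIES,
        key=lambda sp: (-(max(targets[sp] - counts[sp], 0.0)), SPECIES.index(sp)),
    )
    for sp in rem[: seats - sum(counts.values())]:
        counts[sp] += 1
    return counts


class TestRealizeCounts:
    def test_single_species_splits_evenly(self):
        comp = BilayerComposition(percents={"POPC": 100.0})
        r = realize_counts(comp, 100)
        assert r.counts_per_leaflet["POPC"] == 50

    def test_half_half_over_ten_molecules(self):
        comp = BilayerComposition(percents={"POPC": 50.0, "CHOL": 50.0})
        r = realize_counts(comp, 10)
        # per-leaflet targets are 2.5 each; the tie goes to the earlier
        # species in canonical order
        assert r.counts_per_leaflet == {
            "POPC": 3, "DPPC": 0, "SM": 0, "CHOL": 2, "7KC": 0
        }

    def test_control_system_against_oracle(self):
        comp = reference_systems()["control"]
        r = realize_counts(comp, 8446)
        assert sum(r.counts_per_leaflet.values()) * 2 == 8446
        assert r.counts_per_leaflet["7KC"] >= 1  # >= 2 molecules overall
        assert r.counts_per_leaflet == _largest_remainder_oracle(
            dict(comp.percents), 4223
        )

    def test_idempotent_and_conserving(self):
        comp = reference_systems()["LDL250"]
        once = realize_counts(comp, 8444)
        twice = realize_counts(once, 8444)
        assert once.counts_per_leaflet == twice.counts_per_leaflet
        assert once.total_molecules == 8444

    def test_odd_total_rejected(self):
        comp = BilayerComposition(percents={"POPC": 100.0})
        with pytest.raises(ValueError):
            realize_counts(comp, 101)

    def test_too_many_species_for_total(self):
        comp = build_bilayer_composition(40.0, 0.24)
        with pytest.raises(ValueError):
            realize_counts(comp, 4)  # 2/leaflet cannot host 5 species

    @given(
        st.floats(min_value=0.01, max_value=99),
        st.floats(min_value=0.01, max_value=50),
        st.integers(min_value=10, max_value=5000),
    )
    @settings(max_examples=100, deadline=None)
    def test_counts_conserved_and_positive_species_present(
        self, chol, kc7, half_total
    ):
        if chol + kc7 >= 100:
            return
        comp = build_bilayer_composition(chol, kc7)
        try:
            r = realize_counts(comp, 2 * half_total)
        except ValueError:
            # legitimate refusal: the per-species floor of one molecule
            # cannot be honored within the requested total
            n_present = sum(1 for sp in SPECIES if comp.percent(sp) > 0)
            assert half_total < 2 * n_present or min(
                comp.percent(sp) for sp in SPECIES if comp.percent(sp) > 0
            ) < 100.0 / half_total
            return
        assert sum(r.counts_per_leaflet.values()) == half_total
        for sp in SPECIES:
            if comp.percent(sp) > 0:
                assert r.counts_per_leaflet[sp] >= 1
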