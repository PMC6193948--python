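"""Site classification, class occupancies and the filling order."""

import math

import numpy as np
import pytest

import allokin as ak
from allokin.occupancy import (
    ChainRecord,
    FillingStep,
    OccupancyTable,
    SiteClass,
    class_mean_occupancy,
    classify_sites,
    filling_order,
    load_reference_occupancy_series,
    read_occupancy_csv,
    symmetry_expand,
)
from allokin.simulate import TitrationSpec, simulate_titration


def _orthorhombic(occ_by_chain):
    chains = tuple(
        ChainRecord(cid, "closed" if cid in "AF" else "open", occ_by_chain.get(cid))
        for cid in "ABCDEF"
    )
    return OccupancyTable(
        "test", 1.0, chains, (("A", "D"), ("F", "C"), ("B", "E"))
    )


class TestClassification:
    def test_orthorhombic_topology(self):
        classes = classify_sites(_orthorhombic({}))
        assert classes["A"] is SiteClass.CLOSED
        assert classes["F"] is SiteClass.CLOSED
        assert classes["D"] is SiteClass.OPEN_IN_CLOSED_OPEN_DIMER
        assert classes["C"] is SiteClass.OPEN_IN_CLOSED_OPEN_DIMER
        assert classes["B"] is SiteClass.OPEN_IN_OPEN_OPEN_DIMER
        assert classes["E"] is SiteClass.OPEN_IN_OPEN_OPEN_DIMER

    def test_hexagonal_symmetry_expansion(self):
        chains = (
            ChainRecord("A", "closed", 0.8),
            ChainRecord("D", "open", 0.5),
            ChainRecord("B", "open", 0.4),
        )
        full_chains, pairs = symmetry_expand(chains, (("A", "D"), ("B", "B'")))
        tab = OccupancyTable("hex", 0.57, full_chains, pairs)
        classes = classify_sites(tab)
        assert classes["D"] is SiteClass.OPEN_IN_CLOSED_OPEN_DIMER
        assert classes["D'"] is SiteClass.OPEN_IN_CLOSED_OPEN_DIMER
        assert classes["B"] is SiteClass.OPEN_IN_OPEN_OPEN_DIMER
        assert tab.chain("A'").fa_occupancy == 0.8  # inherited

    def test_all_open_hexamer(self):
        chains = tuple(ChainRecord(c, "open", None) for c in "ABCDEF")
        tab = OccupancyTable("open", 1.0, chains, (("A", "B"), ("C", "D"), ("E", "F")))
        assert set(classify_sites(tab).values()) == {SiteClass.OPEN_IN_OPEN_OPEN_DIMER}

    def test_unpaired_chain_rejected(self):
        chains = tuple(ChainRecord(c, "open", None) for c in "ABC")
        with pytest.raises(ValueError, match="exactly one dimer"):
            OccupancyTable("bad", 1.0, chains, (("A", "B"),))


class TestClassMeanOccupancy:
    def test_closed_class_mean(self):
        tab = _orthorhombic({"A": 0.7, "F": 0.7})
        assert class_mean_occupancy(tab, SiteClass.CLOSED) == pytest.approx(0.7)

    def test_absent_ligands_count_as_zero(self):
        tab = _orthorhombic({"A": 0.6})
        assert class_mean_occupancy(tab, SiteClass.CLOSED) == pytest.approx(0.3)

    def test_class_without_members_is_nan(self):
        chains = tuple(ChainRecord(c, "open", None) for c in "AB")
        tab = OccupancyTable("d", 1.0, chains, (("A", "B"),))
        assert math.isnan(class_mean_occupancy(tab, SiteClass.CLOSED))


class TestFillingOrder:
    def test_reference_wt_series_closed_first(self):
        steps = filling_order(load_reference_occupancy_series("WT"), 0.4)
        assert steps[0].site_class is SiteClass.CLOSED
        assert steps[0].first_occupied_ratio == pytest.approx(0.14)
        assert {s.site_class: s.first_occupied_ratio for s in steps[1:]} == {
            SiteClass.OPEN_IN_CLOSED_OPEN_DIMER: pytest.approx(0.57),
            SiteClass.OPEN_IN_OPEN_OPEN_DIMER: pytest.approx(0.57),
        }

    def test_reference_dm_series_order_reversal(self):
        steps = filling_order(load_reference_occupancy_series("DM"), 0.4)
        order = [s.site_class for s in steps]
        assert order == [
            SiteClass.OPEN_IN_CLOSED_OPEN_DIMER,
            SiteClass.CLOSED,
            SiteClass.OPEN_IN_OPEN_OPEN_DIMER,
        ]
        assert [s.first_occupied_ratio for s in steps] == pytest.approx([0.4, 0.6, 1.2])

    @pytest.mark.parametrize("threshold", [0.35, 0.45, 0.55])
    def test_order_reversal_robust_to_threshold(self, threshold):
        wt = filling_order(load_reference_occupancy_series("WT"), threshold)
        dm = filling_order(load_reference_occupancy_series("DM"), threshold)
        assert wt[0].site_class is SiteClass.CLOSED
        assert dm[0].site_class is SiteClass.OPEN_IN_CLOSED_OPEN_DIMER

    def test_unoccupied_series_never_fills(self):
        tab = _orthorhombic({})
        steps = filling_order([tab], 0.4)
        assert all(s.first_occupied_ratio is None for s in steps)

    def test_relabeling_invariance(self):
        series = []
        for ratio, occ in [(0.5, {"A": 0.7, "F": 0.7}), (1.0, {c: 0.7 for c in "ABCDEF"})]:
            series.append(
                OccupancyTable(
                    f"t{ratio}", ratio,
                    tuple(
                        ChainRecord(c, "closed" if c in "AF" else "open", occ.get(c))
                        for c in "ABCDEF"
                    ),
                    (("A", "D"), ("F", "C"), ("B", "E")),
                )
            )
        relabel = {"A": "F", "F": "A", "D": "C", "C": "D", "B": "E", "E": "B"}
        series2 = [
            OccupancyTable(
                t.structure_id, t.molar_ratio,
                tuple(
                    ChainRecord(relabel[c.chain_id], c.conformation, c.fa_occupancy)
                    for c in t.chains
                ),
                tuple((relabel[x], relabel[y]) for x, y in t.dimer_map),
            )
            for t in series
        ]
        s1 = [(s.site_class, s.first_occupied_ratio) for s in filling_order(series, 0.4)]
        s2 = [(s.site_class, s.first_occupied_ratio) for s in filling_order(series2, 0.4)]
        assert s1 == s2

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filling_order([], 0.4)

    def test_agrees_with_titration_ground_truth(self):
        # a negatively-coupled dimer crosses the occupancy threshold later
        # than an independent-sites dimer at the same K1
        ratios = tuple(np.linspace(0.1, 6.0, 24))
        neg = simulate_titration(TitrationSpec(K1=2.0, coupling=0.02, ratios=ratios))
        ind = simulate_titration(TitrationSpec(K1=2.0, coupling=1.0, ratios=ratios))

        def first_ratio(tables):
            steps = filling_order(tables, 0.4)
            (step,) = [s for s in steps if s.site_class is SiteClass.OPEN_IN_OPEN_OPEN_DIMER]
            return step.first_occupied_ratio

        assert first_ratio(neg) > first_ratio(ind)


class TestCSV:
    def test_read_occupancy_csv(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text(
            "structure_id,space_group,molar_ratio,chain,partner,conformation,occupancy\n"
            "X,P212121,0.5,A,B,closed,0.7\n"
            "X,P212121,0.5,B,A,open,\n"
        )
        (tab,) = read_occupancy_csv(p)
        assert tab.chain("A").fa_occupancy == 0.7
        assert tab.chain("B").fa_occupancy is None

    def test_unknown_enzyme_form(self):
        with pytest.raises(ValueError, match="enzyme_form"):
            load_reference_occupancy_series("XX")
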