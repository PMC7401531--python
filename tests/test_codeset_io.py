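"""Codeset parsing, RCC round-trips, and run-set assembly."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rccpipe import (LaneAttributes, LaneCounts, StudyDesign, assemble_runset,
                     codeset_to_tsv, load_codeset, read_rcc, write_rcc)
from rccpipe.errors import ConsistencyError, JoinError, RCCFormatError
from rccpipe.simulate import default_design, SimConfig


class TestPanelFixture:
    def test_panel_composition(self, panel):
        assert len(panel.endogenous) == 12
        assert len(panel.reference) == 3
        assert len(panel.gene_probes) == 15
        assert len(panel.positives) == 6
        assert len(panel.negatives) == 6

    def test_reference_genes_are_the_housekeeping_trio(self, panel):
        assert panel.reference == ["GAPDH", "GUSB", "YWHAZ"]

    def test_ifng_probe_details(self, panel):
        p = panel["IFNG"]
        assert p.accession == "NM_174086.1"
        assert (p.target_start, p.target_end) == (503, 602)

    def test_all_gene_targets_are_100nt(self, panel):
        assert all(p.target_length == 100 for p in panel.gene_probes)

    def test_positive_ladder_is_fourfold(self, panel):
        concs = [p.concentration_fM for p in panel.positives]
        assert concs == [128, 32, 8, 2, 0.5, 0.125]

    def test_duplicate_probe_name_rejected(self, panel):
        text = codeset_to_tsv(panel)
        dup = text + text.splitlines()[1] + "\n"
        with pytest.raises(ConsistencyError):
            load_codeset(dup)

    def test_malformed_interval_rejected(self):
        text = ("name\tprobe_class\taccession\ttarget_start\ttarget_end\n"
                "G1\tendogenous\tNM_1\tfive\t100\n")
        with pytest.raises(ValueError):
            load_codeset(text)

    def test_tsv_round_trip(self, panel):
        again = load_codeset(codeset_to_tsv(panel), name=panel.name)
        assert again == panel


def _lane(panel, sample_id="S1", counts=None, fov=(555, 555), bd=0.8):
    counts = counts if counts is not None else {
        p.name: i + 1 for i, p in enumerate(panel)
    }
    return LaneCounts(
        sample_id=sample_id,
        attributes=LaneAttributes(lane_id="1", fov_requested=fov[0],
                                  fov_counted=fov[1], binding_density=bd,
                                  cartridge_id="C"),
        counts=counts,
    )


class TestRCCRoundTrip:
    def test_simple_round_trip(self, panel):
        lane = _lane(panel)
        assert len(lane.counts) == 27
        again = read_rcc(write_rcc(lane, panel))
        assert again == lane

    def test_fov_attributes_preserved(self, panel):
        lane = _lane(panel, fov=(555, 555))
        again = read_rcc(write_rcc(lane, panel))
        assert again.attributes.fov_requested == 555
        assert again.attributes.fov_counted == 555

    def test_missing_probe_serialized_as_zero(self, panel):
        counts = {p.name: 5 for p in panel}
        del counts["IL8"]
        lane = _lane(panel, counts=counts)
        again = read_rcc(write_rcc(lane, panel))
        assert again.counts["IL8"] == 0

    def test_output_is_deterministic_and_codeset_ordered(self, panel):
        lane = _lane(panel)
        text = write_rcc(lane, panel)
        assert text == write_rcc(lane, panel)
        body = text.split("<Code_Summary>")[1]
        names = [ln.split(",")[1] for ln in body.strip().splitlines()[1:-1]]
        assert names == panel.names()

    @pytest.mark.parametrize("section", ["Header", "Sample_Attributes",
                                         "Lane_Attributes", "Code_Summary"])
    def test_missing_section_is_named(self, panel, section):
        text = write_rcc(_lane(panel), panel)
        mutated = text.replace(f"<{section}>", "<Other>") \
                      .replace(f"</{section}>", "</Other>")
        with pytest.raises(RCCFormatError, match=section):
            read_rcc(mutated)

    def test_non_integer_count_reports_line_number(self, panel):
        text = write_rcc(_lane(panel), panel)
        bad = text.replace("Endogenous,IFNG,NM_174086.1,1",
                           "Endogenous,IFNG,NM_174086.1,one")
        with pytest.raises(ValueError, match=r"line \d+"):
            read_rcc(bad)

    def test_unknown_probe_rejected_on_write(self, panel):
        lane = _lane(panel, counts={"NOT_A_PROBE": 3})
        with pytest.raises(ConsistencyError):
            write_rcc(lane, panel)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_round_trip_identity_property(self, panel, data):
        counts = {
            p.name: data.draw(st.integers(min_value=0, max_value=10**7))
            for p in panel
        }
        fov_req = data.draw(st.integers(min_value=1, max_value=555))
        fov_cnt = data.draw(st.integers(min_value=0, max_value=fov_req))
        bd = data.draw(st.floats(min_value=0, max_value=5,
                                 allow_nan=False))
        lane = LaneCounts(
            sample_id=data.draw(st.text(
                alphabet=st.characters(whitelist_categories=("L", "N")),
                min_size=1, max_size=10)),
            attributes=LaneAttributes(
                lane_id="7", fov_requested=fov_req, fov_counted=fov_cnt,
                binding_density=bd, cartridge_id="X"),
            counts=counts,
        )
        assert read_rcc(write_rcc(lane, panel)) == lane


class TestAssembleRunset:
    def test_full_study_assembly(self, clean_runset):
        assert len(clean_runset.lanes) == 48
        assert len(clean_runset.design) == 48

    def test_lane_order_insensitive(self, panel):
        design = default_design(SimConfig(n_per_group=2, times_h=(0.0, 4.0)))
        lanes = [_lane(panel, sample_id=s) for s in design.sample_ids]
        a = assemble_runset(lanes, panel, design)
        b = assemble_runset(list(reversed(lanes)), panel, design)
        assert [l.sample_id for l in a.lanes] == [l.sample_id
                                                 for l in b.lanes]
        assert a.counts_frame().equals(b.counts_frame())

    def test_singleton_runset(self, panel):
        import pandas as pd
        design = StudyDesign(pd.DataFrame([{
            "sample_id": "S1", "animal_id": "A1", "group": "control",
            "time_h": 0.0}]))
        rs = assemble_runset([_lane(panel, "S1")], panel, design)
        assert len(rs.lanes) == 1

    def test_orphan_lane_raises_join_error(self, panel):
        import pandas as pd
        design = StudyDesign(pd.DataFrame([{
            "sample_id": "S1", "animal_id": "A1", "group": "control",
            "time_h": 0.0}]))
        with pytest.raises(JoinError, match="S2"):
            assemble_runset([_lane(panel, "S1"), _lane(panel, "S2")],
                            panel, design)

    def test_design_rejects_animal_in_two_groups(self):
        import pandas as pd
        with pytest.raises(ConsistencyError):
            StudyDesign(pd.DataFrame([
                {"sample_id": "S1", "animal_id": "A1", "group": "control",
                 "time_h": 0.0},
                {"sample_id": "S2", "animal_id": "A1",
                 "group": "treatment", "time_h": 4.0},
            ]))
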