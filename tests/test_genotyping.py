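"""Threshold calibration, molecule calls, integration rules, clones, audit."""

import numpy as np
import pandas as pd
import pytest

from targetseq.amplicons import AlleleCount, finalize_counts
from targetseq.genotyping import (
    CalibrationError,
    ThresholdSet,
    assign_clones,
    calibrate_thresholds,
    call_molecule,
    call_molecules_table,
    false_positive_audit,
    integrate_genotype,
    integrate_table,
    qc_cells,
)
from targetseq.panel import ConfigurationError, VariantSite

from conftest import counts_frame

CALLS = ("FAIL", "WT", "HET", "HOM", "ND")


def ac(n_ref, n_alt, n_other=0, cell="c1"):
    return AlleleCount(cell, "gJAK2", "JAK2:mut", n_ref, n_alt, n_other)


JAK2 = VariantSite(name="JAK2:mut", chrom="chr9", pos=150, ref="G", alt="T",
                   zygosity_critical=True)
TET2 = VariantSite(name="TET2:mut", chrom="chr4", pos=150, ref="G", alt="T")


class TestCalibration:
    def test_quiet_controls_hit_floor_and_lower_clamp(self, small_panel):
        blanks = counts_frame([("b1", a.amplicon_id, a.variants[0].name, 0, 0)
                               for a in small_panel])
        wt = counts_frame([("w1", a.amplicon_id, a.variants[0].name, 995, 5)
                           for a in small_panel])  # max WT AF 0.005
        with pytest.warns(UserWarning, match="fewer than 10"):
            th = calibrate_thresholds(blanks, wt, small_panel)
        for t in th.values():
            assert t.detection_min_reads == 30
            assert t.mutation_af_min == 0.015

    def test_upper_clamp_at_4_percent(self, small_panel):
        blanks = counts_frame([("b1", a.amplicon_id, a.variants[0].name, 0, 0)
                               for a in small_panel])
        wt = counts_frame([("w1", a.amplicon_id, a.variants[0].name, 970, 30)
                           for a in small_panel])  # 2 x 0.03 clamps to 0.04
        with pytest.warns(UserWarning):
            th = calibrate_thresholds(blanks, wt, small_panel)
        assert all(t.mutation_af_min == 0.04 for t in th.values())

    def test_blank_coverage_doubling_rule(self, small_panel):
        blanks = counts_frame([("b1", a.amplicon_id, a.variants[0].name, 40, 0)
                               for a in small_panel])
        wt = counts_frame([("w1", a.amplicon_id, a.variants[0].name, 1000, 0)
                           for a in small_panel])
        with pytest.warns(UserWarning):
            th = calibrate_thresholds(blanks, wt, small_panel)
        assert all(t.detection_min_reads == 80 for t in th.values())

    def test_absent_amplicon_raises(self, small_panel):
        blanks = counts_frame([("b1", "gJAK2", "JAK2:mut", 0, 0)])
        wt = counts_frame([("w1", "gJAK2", "JAK2:mut", 100, 0)])
        with pytest.raises(CalibrationError, match="mJAK2|gTET2|mTET2"):
            with pytest.warns(UserWarning):
                calibrate_thresholds(blanks, wt, small_panel)

    def test_provenance_recorded(self, small_panel):
        blanks = counts_frame([(f"b{i}", a.amplicon_id, a.variants[0].name, 10, 0)
                               for a in small_panel for i in range(12)])
        wt = counts_frame([(f"w{i}", a.amplicon_id, a.variants[0].name, 990, 10)
                           for a in small_panel for i in range(12)])
        th = calibrate_thresholds(blanks, wt, small_panel)
        t = th["gJAK2"]
        assert t.provenance["max_blank_coverage"] == 10
        assert t.provenance["n_wt_controls"] == 12
        assert t.provenance["max_wt_control_af"] == pytest.approx(0.01)


class TestCallMolecule:
    TH = ThresholdSet("gJAK2", min_coverage=30, detection_min_reads=30,
                      mutation_af_min=0.02)

    def test_low_coverage_fails(self):
        call = call_molecule(ac(25, 0), self.TH, JAK2)
        assert call.call == "FAIL"

    def test_nd_window_full_length_gdna(self):
        call = call_molecule(ac(940, 60), self.TH, JAK2, "full_length")
        assert call.call == "ND"  # af=0.06 inside (0.03, 0.1)

    def test_nd_window_three_prime_gdna_differs(self):
        # af = 0.035: ND for full-length gDNA, WT-side for 3' gDNA (window 0.04-0.1)
        a = ac(965, 35)
        assert call_molecule(a, self.TH, JAK2, "full_length").call == "ND"
        c = call_molecule(a, self.TH, JAK2, "three_prime")
        assert c.call == "HET"  # 0.035 >= af_min 0.02 on both alleles

    def test_non_critical_variant_skips_nd(self):
        call = call_molecule(ac(940, 60), self.TH, TET2)
        assert call.call == "HET"

    @pytest.mark.parametrize("n_alt,expected", [(500, "HET"), (995, "HOM"), (2, "WT")])
    def test_het_hom_wt_rule(self, n_alt, expected):
        call = call_molecule(ac(1000 - n_alt, n_alt), self.TH, TET2)
        assert call.call == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError, match="dataset_mode"):
            call_molecule(ac(10, 10), self.TH, JAK2, "nanopore")

    def test_af_min_monotonicity_never_creates_mutants(self):
        """Raising the mutation threshold can only demote calls toward WT."""
        rng = np.random.default_rng(0)
        counts = [ac(int(r), int(a)) for r, a in
                  rng.integers(0, 500, size=(50, 2))]
        order = {"WT": 0, "HET": 1, "HOM": 1}
        for lo, hi in [(0.015, 0.04), (0.02, 0.3), (0.1, 0.49)]:
            th_lo = ThresholdSet("gJAK2", mutation_af_min=lo)
            th_hi = ThresholdSet("gJAK2", mutation_af_min=hi)
            for c in counts:
                a = call_molecule(c, th_lo, TET2).call
                b = call_molecule(c, th_hi, TET2).call
                if a == "FAIL":
                    assert b == "FAIL"
                elif a == "WT":
                    assert b == "WT"

    def test_table_call_matches_scalar_call(self, small_panel):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(200):
            amp = small_panel.amplicons[i % 4]
            n_ref, n_alt = rng.integers(0, 200, size=2)
            rows.append((f"c{i}", amp.amplicon_id, amp.variants[0].name,
                         int(n_ref), int(n_alt)))
        counts = finalize_counts(counts_frame(rows), small_panel)
        th = {a.amplicon_id: ThresholdSet(a.amplicon_id, mutation_af_min=0.02)
              for a in small_panel}
        table = call_molecules_table(counts, th, small_panel)
        for row in table.itertuples():
            site = JAK2 if row.variant == "JAK2:mut" else TET2
            a = AlleleCount(row.cell_id, row.amplicon_id, row.variant,
                            row.n_ref, row.n_alt, row.n_other)
            single = call_molecule(a, th[row.amplicon_id], site,
                                   molecule=row.molecule)
            assert single.call == row.call


class TestIntegration:
    @pytest.mark.parametrize("pair,expected", [
        (("HET", "WT"), "HET"),
        (("WT", "HET"), "HET"),
        (("HOM", "WT"), "HET"),
        (("WT", "HOM"), "HET"),
        (("HOM", "FAIL"), "HOM"),
        (("WT", "FAIL"), "WT"),
        (("FAIL", "HOM"), "EXCLUDED"),
        (("FAIL", "WT"), "EXCLUDED"),
        (("FAIL", "FAIL"), "MISSING"),
        (("ND", "FAIL"), "ND"),
        (("HOM", "ND"), "HOM"),
    ])
    def test_stated_rules(self, pair, expected):
        assert integrate_genotype(*pair).call == expected

    def test_total_over_grid(self):
        for g in CALLS:
            for c in CALLS:
                out = integrate_genotype(g, c)
                assert out.call in ("WT", "HET", "HOM", "ND", "EXCLUDED", "MISSING")
                assert out.provenance == (g, c)

    def test_het_dominance_symmetric_everywhere(self):
        for other in CALLS:
            assert integrate_genotype("HET", other).call == "HET"
            assert integrate_genotype(other, "HET").call == "HET"

    def test_wt_hom_anchored_to_gdna_not_symmetric(self):
        # gDNA-only readouts are trusted; mRNA-only ones exclude the cell
        assert integrate_genotype("HOM", "FAIL").call == "HOM"
        assert integrate_genotype("FAIL", "HOM").call == "EXCLUDED"
        assert integrate_genotype("WT", "FAIL").call == "WT"
        assert integrate_genotype("FAIL", "WT").call == "EXCLUDED"

    def test_mismatched_cells_rejected(self):
        from targetseq.genotyping import MoleculeCall
        a = MoleculeCall("c1", "JAK2:mut", "gDNA", "WT", 0.0, 100)
        b = MoleculeCall("c2", "JAK2:mut", "mRNA", "WT", 0.0, 100)
        with pytest.raises(ValueError, match="different cells"):
            integrate_genotype(a, b)


def build_gm(small_panel, rows):
    """rows: (cell, variant, gdna_call, cdna_call) quadruples."""
    recs = []
    for cell, variant, g, c in rows:
        gene = variant.split(":")[0]
        recs.append({"cell_id": cell, "amplicon_id": f"g{gene}", "variant": variant,
                     "molecule": "gDNA", "call": g})
        recs.append({"cell_id": cell, "amplicon_id": f"m{gene}", "variant": variant,
                     "molecule": "mRNA", "call": c})
    return integrate_table(pd.DataFrame(recs), small_panel)


class TestQCAndClones:
    def test_cell_with_undetected_gene_dropped(self, small_panel):
        gm = build_gm(small_panel, [
            ("c1", "JAK2:mut", "WT", "WT"), ("c1", "TET2:mut", "FAIL", "FAIL"),
            ("c2", "JAK2:mut", "WT", "FAIL"), ("c2", "TET2:mut", "HET", "HET"),
        ])
        gm = qc_cells(gm)
        assert not gm.qc.loc["c1", "pass"]
        assert "gene_undetected:TET2" in gm.qc.loc["c1", "reasons"]
        assert gm.qc.loc["c2", "pass"]

    def test_empty_matrix_passes_through(self, small_panel):
        gm = build_gm(small_panel, [])
        gm = qc_cells(gm)
        assert len(gm.qc) == 0
        table, labels = assign_clones(gm)
        assert len(table) == 0 and len(labels) == 0

    def test_minor_clone_flagged(self, small_panel):
        rows = []
        for i in range(60):
            rows += [(f"w{i:03d}", "JAK2:mut", "WT", "WT"),
                     (f"w{i:03d}", "TET2:mut", "WT", "WT")]
        for i in range(36):
            rows += [(f"h{i:03d}", "JAK2:mut", "HET", "HET"),
                     (f"h{i:03d}", "TET2:mut", "WT", "WT")]
        for i in range(4):
            rows += [(f"m{i:03d}", "JAK2:mut", "HOM", "HOM"),
                     (f"m{i:03d}", "TET2:mut", "WT", "WT")]
        gm = qc_cells(build_gm(small_panel, rows))
        table, labels = assign_clones(gm.passing(), min_cells=5, min_frac=0.05)
        hom = table[table["clone"] == "JAK2:mut:HOM;TET2:mut:WT"]
        assert bool(hom["minor"].iloc[0])
        assert not table[table["clone"] == "JAK2:mut:HET;TET2:mut:WT"]["minor"].iloc[0]

    def test_missing_wildcard_needs_unique_clone(self, small_panel):
        rows = []
        for i in range(6):
            rows += [(f"a{i}", "JAK2:mut", "HET", "HET"),
                     (f"a{i}", "TET2:mut", "WT", "WT")]
            rows += [(f"b{i}", "JAK2:mut", "WT", "WT"),
                     (f"b{i}", "TET2:mut", "WT", "WT")]
        # ambiguous: JAK2 missing, TET2 WT matches both clones -> unassigned
        rows += [("amb", "JAK2:mut", "FAIL", "FAIL"), ("amb", "TET2:mut", "WT", "WT")]
        # unique: TET2 missing but JAK2 HET only matches the HET clone... add
        # a cell whose only consistent clone is JAK2-HET
        rows += [("uni", "JAK2:mut", "HET", "HET"), ("uni", "TET2:mut", "FAIL", "FAIL")]
        gm = build_gm(small_panel, rows)
        _, labels = assign_clones(gm)
        assert labels["amb"] == ""
        assert labels["uni"] == "JAK2:mut:HET;TET2:mut:WT"

    def test_recovered_clone_frequencies(self, small_panel):
        rng = np.random.default_rng(11)
        freqs = {"WT": 0.6, "HET": 0.3, "HOM": 0.1}
        states = rng.choice(list(freqs), p=list(freqs.values()), size=1000)
        rows = []
        for i, s in enumerate(states):
            rows += [(f"c{i:04d}", "JAK2:mut", s, s),
                     (f"c{i:04d}", "TET2:mut", "WT", "WT")]
        gm = qc_cells(build_gm(small_panel, rows))
        table, _ = assign_clones(gm.passing())
        table = table.set_index("clone")
        for s, f in freqs.items():
            got = table.loc[f"JAK2:mut:{s};TET2:mut:WT", "frac"]
            assert abs(got - f) < 3 * np.sqrt(f * (1 - f) / 1000)


class TestFalsePositiveAudit:
    def test_spiked_control_counted(self):
        calls = pd.DataFrame({"call": ["WT", "WT", "HET", "FAIL"]})
        assert false_positive_audit(calls) == 1

    def test_empty_set(self):
        assert false_positive_audit([]) == 0
        assert false_positive_audit(pd.DataFrame({"call": []})) == 0
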