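"""Control-calibrated single-cell genotyping and clone assignment.

The calling scheme works in three stages:

1. **Calibration** — per-amplicon detection thresholds come from blank
   (non-template) wells and mutation-calling AF thresholds from wild-type
   control cells, clamped to 1.5%–4% of reads.
2. **Per-molecule calls** — each (cell, variant, molecule) allele count is
   classified FAIL / WT / HET / HOM, with a not-determined (ND) window for
   zygosity-critical variants whose AF is too high for noise but too low to
   trust as heterozygous (e.g. 0.03 < AF < 0.1 for full-length gDNA).
3. **Integration** — the gDNA and cDNA calls for the same mutation are
   merged: any heterozygous readout wins; discordant HOM/WT readouts are
   heterozygous; WT and HOM anchor to gDNA; mutations seen only at the mRNA
   level exclude that cell for that variant.

A minimum coverage of 30 reads per amplicon is required for any mutational
readout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .panel import ConfigurationError, Panel, VariantSite

__all__ = [
    "CalibrationError",
    "ThresholdSet",
    "MoleculeCall",
    "IntegratedCall",
    "GenotypeMatrix",
    "ND_WINDOWS",
    "calibrate_thresholds",
    "call_molecule",
    "call_molecules_table",
    "integrate_genotype",
    "integrate_table",
    "qc_cells",
    "assign_clones",
    "false_positive_audit",
    "genotype_pipeline",
]

Call = Literal["FAIL", "WT", "HET", "HOM", "ND"]
IntCall = Literal["WT", "HET", "HOM", "ND", "EXCLUDED", "MISSING"]

DatasetMode = Literal["full_length", "three_prime"]

MIN_COVERAGE_DEFAULT = 30

#: ND allele-frequency windows per (dataset mode, molecule class).  The
#: full-length mRNA window is a package default chosen to match the others;
#: only the remaining three are protocol-published values.
ND_WINDOWS: dict[tuple[str, str], tuple[float, float]] = {
    ("full_length", "gDNA"): (0.03, 0.10),
    ("three_prime", "gDNA"): (0.04, 0.10),
    ("three_prime", "mRNA"): (0.03, 0.10),
    ("full_length", "mRNA"): (0.03, 0.10),
}


class CalibrationError(ValueError):
    """Raised when thresholds cannot be calibrated for an amplicon."""


@dataclass
class ThresholdSet:
    """Per-amplicon detection and mutation-calling thresholds.

    ``provenance`` records the control statistics that produced the
    thresholds, so calibration is auditable and overridable.
    """

    amplicon_id: str
    min_coverage: int = MIN_COVERAGE_DEFAULT
    detection_min_reads: int = MIN_COVERAGE_DEFAULT
    mutation_af_min: float = 0.015
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.mutation_af_min < 0.5):
            raise ConfigurationError(
                f"{self.amplicon_id}: mutation_af_min must be in (0, 0.5)"
            )


def calibrate_thresholds(
    blank_counts: pd.DataFrame,
    wt_counts: pd.DataFrame,
    panel: Panel,
    min_coverage: int = MIN_COVERAGE_DEFAULT,
    af_clamp: tuple[float, float] = (0.015, 0.04),
) -> dict[str, ThresholdSet]:
    """Set per-amplicon thresholds from blank and wild-type control wells.

    ``detection_min_reads`` is twice the maximum coverage seen in blanks
    (floored at ``min_coverage``); ``mutation_af_min`` is twice the maximum
    alt-allele fraction seen in WT controls, clamped to 1.5%–4%.  Both
    doubling rules are this package's calibration formulas; the control
    inputs and the clamp range follow the protocol.
    """
    thresholds: dict[str, ThresholdSet] = {}
    for amp in panel:
        blanks = blank_counts[blank_counts["amplicon_id"] == amp.amplicon_id]
        wt = wt_counts[wt_counts["amplicon_id"] == amp.amplicon_id]
        if blanks.empty and wt.empty:
            raise CalibrationError(
                f"amplicon {amp.amplicon_id} absent from all control wells"
            )
        n_blank = blanks["cell_id"].nunique()
        n_wt = wt["cell_id"].nunique()
        if n_blank < 10 or n_wt < 10:
            warnings.warn(
                f"{amp.amplicon_id}: calibrating on {n_blank} blanks / {n_wt} WT "
                "controls (fewer than 10)",
                stacklevel=2,
            )
        max_blank_cov = int(blanks["coverage"].max()) if len(blanks) else 0
        max_wt_af = float(wt["af"].max()) if len(wt) else 0.0
        detection = max(2 * max_blank_cov, min_coverage)
        af_min = float(np.clip(2 * max_wt_af, *af_clamp))
        thresholds[amp.amplicon_id] = ThresholdSet(
            amplicon_id=amp.amplicon_id,
            min_coverage=min_coverage,
            detection_min_reads=detection,
            mutation_af_min=af_min,
            provenance={
                "n_blanks": int(n_blank),
                "n_wt_controls": int(n_wt),
                "max_blank_coverage": max_blank_cov,
                "max_wt_control_af": max_wt_af,
            },
        )
    return thresholds


def thresholds_to_json(thresholds: Mapping[str, ThresholdSet], path: str | Path) -> None:
    data = {
        k: {
            "min_coverage": t.min_coverage,
            "detection_min_reads": t.detection_min_reads,
            "mutation_af_min": t.mutation_af_min,
            "provenance": t.provenance,
        }
        for k, t in thresholds.items()
    }
    Path(path).write_text(json.dumps(data, indent=2))


def thresholds_from_json(path: str | Path) -> dict[str, ThresholdSet]:
    data = json.loads(Path(path).read_text())
    return {k: ThresholdSet(amplicon_id=k, **v) for k, v in data.items()}


@dataclass(frozen=True)
class MoleculeCall:
    """Genotype readout from one molecule class (gDNA or mRNA)."""

    cell_id: str
    variant: str
    molecule: str
    call: Call
    af: float
    coverage: int


def _call_from_af(af: float, af_min: float) -> Call:
    ref_frac = 1.0 - af
    if af >= af_min and ref_frac >= af_min:
        return "HET"
    if af >= af_min:
        return "HOM"
    return "WT"


def call_molecule(
    count,
    th: ThresholdSet,
    site: VariantSite,
    dataset_mode: DatasetMode = "full_length",
    molecule: str = "gDNA",
) -> MoleculeCall:
    """Classify one allele count as FAIL / ND / WT / HET / HOM.

    ``count`` is an :class:`~targetseq.amplicons.AlleleCount` or any object
    with ``cell_id``, ``coverage`` and ``af`` attributes.  Coverage below
    ``max(min_coverage, detection_min_reads)`` fails the readout; for
    zygosity-critical variants an AF inside the mode/molecule ND window
    withholds the call; otherwise both allele fractions at or above
    ``mutation_af_min`` give HET, a depleted ref fraction gives HOM, and a
    sub-threshold alt fraction gives WT.
    """
    if dataset_mode not in ("full_length", "three_prime"):
        raise ConfigurationError(f"unknown dataset_mode {dataset_mode!r}")
    af = float(count.af)
    cov = int(count.coverage)
    cell = str(count.cell_id)
    if cov < max(th.min_coverage, th.detection_min_reads):
        return MoleculeCall(cell, site.name, molecule, "FAIL", af, cov)
    if site.zygosity_critical:
        lo, hi = ND_WINDOWS[(dataset_mode, molecule)]
        if lo < af < hi:
            return MoleculeCall(cell, site.name, molecule, "ND", af, cov)
    return MoleculeCall(cell, site.name, molecule, _call_from_af(af, th.mutation_af_min), af, cov)


def call_molecules_table(
    counts: pd.DataFrame,
    thresholds: Mapping[str, ThresholdSet],
    panel: Panel,
    dataset_mode: DatasetMode = "full_length",
) -> pd.DataFrame:
    """Vectorized :func:`call_molecule` over a finalized counts table.

    Returns the counts table with a ``call`` column added.
    """
    df = counts.copy()
    det = df["amplicon_id"].map(
        {k: max(t.min_coverage, t.detection_min_reads) for k, t in thresholds.items()}
    )
    af_min = df["amplicon_id"].map({k: t.mutation_af_min for k, t in thresholds.items()})
    if det.isna().any():
        missing = sorted(df.loc[det.isna(), "amplicon_id"].unique())
        raise CalibrationError(f"no thresholds for amplicons {missing}")

    af = df["af"].to_numpy(dtype=float)
    cov = df["coverage"].to_numpy()
    af_min_v = af_min.to_numpy(dtype=float)
    call = np.full(len(df), "WT", dtype=object)
    het = (af >= af_min_v) & ((1 - af) >= af_min_v)
    hom = (af >= af_min_v) & ~het
    call[het] = "HET"
    call[hom] = "HOM"

    zc = {
        (a.amplicon_id, v.name): v.zygosity_critical for a in panel for v in a.variants
    }
    crit = np.array(
        [zc.get((a, v), False) for a, v in zip(df["amplicon_id"], df["variant"])]
    )
    lo = np.array([ND_WINDOWS[(dataset_mode, m)][0] for m in df["molecule"]])
    hi = np.array([ND_WINDOWS[(dataset_mode, m)][1] for m in df["molecule"]])
    nd = crit & (af > lo) & (af < hi)
    call[nd] = "ND"
    call[cov < det.to_numpy()] = "FAIL"
    df["call"] = call
    return df


# ---------------------------------------------------------------------------
# integration


@dataclass(frozen=True)
class IntegratedCall:
    """Cell-level genotype after merging gDNA and cDNA readouts."""

    cell_id: str
    variant: str
    call: IntCall
    provenance: tuple[Call, Call]  # (gDNA call, cDNA call)


def _integrate(g: Call, c: Call) -> IntCall:
    # An ND molecule is removed from consideration; if dropping it leaves
    # no information at all the integrated call is ND rather than MISSING.
    if g == "HET" or c == "HET":
        return "HET"
    had_nd = "ND" in (g, c)
    g = "FAIL" if g == "ND" else g
    c = "FAIL" if c == "ND" else c
    if {g, c} == {"HOM", "WT"}:
        return "HET"
    if g == "HOM":
        return "HOM"
    if g == "WT":
        return "WT"
    # g == FAIL from here on
    if c in ("WT", "HOM"):
        return "EXCLUDED"
    return "ND" if had_nd else "MISSING"


_TABLE: dict[tuple[Call, Call], IntCall] = {
    (g, c): _integrate(g, c)
    for g in ("FAIL", "WT", "HET", "HOM", "ND")
    for c in ("FAIL", "WT", "HET", "HOM", "ND")
}


def integrate_genotype(gdna: MoleculeCall | Call, cdna: MoleculeCall | Call) -> IntegratedCall:
    """Merge the gDNA and cDNA molecule calls for one cell and variant.

    Total over the 5x5 call grid: heterozygous readouts dominate; a HOM/WT
    discrepancy in either order is heterozygous; WT and HOM require gDNA
    support; an mRNA-only WT or mutant readout excludes the cell for this
    variant; two failed molecules leave the genotype missing.
    """
    if isinstance(gdna, str):
        gdna = MoleculeCall("", "", "gDNA", gdna, 0.0, 0)
    if isinstance(cdna, str):
        cdna = MoleculeCall("", "", "mRNA", cdna, 0.0, 0)
    if (gdna.cell_id, gdna.variant) != (cdna.cell_id, cdna.variant):
        raise ValueError("integrating calls for different cells or variants")
    return IntegratedCall(
        cell_id=gdna.cell_id,
        variant=gdna.variant,
        call=_TABLE[(gdna.call, cdna.call)],
        provenance=(gdna.call, cdna.call),
    )


@dataclass
class GenotypeMatrix:
    """Integrated calls (cells x variants) plus per-molecule provenance.

    ``calls`` holds integrated call strings; ``gdna``/``cdna`` hold the
    per-molecule calls ("FAIL" where the amplicon was not assayed);
    ``qc`` records pass/fail and reason codes after :func:`qc_cells`.
    """

    calls: pd.DataFrame
    gdna: pd.DataFrame
    cdna: pd.DataFrame
    panel: Panel
    qc: pd.DataFrame | None = None

    @property
    def cells(self) -> list[str]:
        return list(self.calls.index)

    @property
    def variants(self) -> list[str]:
        return list(self.calls.columns)

    def passing(self) -> "GenotypeMatrix":
        """Restrict to cells passing genotyping QC (requires qc_cells)."""
        if self.qc is None:
            raise ValueError("run qc_cells first")
        keep = self.qc.index[self.qc["pass"]]
        return GenotypeMatrix(
            self.calls.loc[keep], self.gdna.loc[keep], self.cdna.loc[keep],
            self.panel, self.qc.loc[keep],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index_label="cell_id")


def integrate_table(calls: pd.DataFrame, panel: Panel) -> GenotypeMatrix:
    """Build the integrated genotype matrix from a molecule-call table.

    ``calls`` is the output of :func:`call_molecules_table` (one row per
    cell x amplicon x variant with a ``call`` column).  Variants are keyed
    by name so the gDNA and cDNA amplicons of the same mutation line up;
    a molecule class with no amplicon for a variant contributes FAIL.
    """
    variant_order = panel.variant_names
    if calls.empty:
        empty = pd.DataFrame(columns=variant_order, index=pd.Index([], name="cell_id"))
        return GenotypeMatrix(calls=empty, gdna=empty.copy(), cdna=empty.copy(), panel=panel)
    cells = sorted(calls["cell_id"].astype(str).unique())

    def pivot(mol: str) -> pd.DataFrame:
        sub = calls[calls["molecule"] == mol]
        p = sub.pivot_table(
            index="cell_id", columns="variant", values="call", aggfunc="first"
        )
        return p.reindex(index=cells, columns=variant_order).fillna("FAIL")

    g = pivot("gDNA")
    c = pivot("mRNA")
    integ = pd.DataFrame(
        {
            v: [_TABLE[(g.at[cell, v], c.at[cell, v])] for cell in cells]
            for v in variant_order
        },
        index=pd.Index(cells, name="cell_id"),
    )
    return GenotypeMatrix(calls=integ, gdna=g, cdna=c, panel=panel)


def qc_cells(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Flag cells in which a targeted gene is undetected by both molecules.

    A gene counts as detected in a cell if any of its amplicons (gDNA or
    mRNA) produced a non-FAIL molecule call; cells with a fully undetected
    gene fail QC with reason ``gene_undetected:<gene>``.  Per-variant
    EXCLUDED integrated calls are recorded as reasons but drop the cell
    only for that variant's analyses, not globally.
    """
    variant_gene: dict[str, str] = {}
    for amp in gm.panel:
        for v in amp.variants:
            variant_gene.setdefault(v.name, amp.gene)
    genes = sorted(set(variant_gene.values()))

    rows = []
    for cell in gm.cells:
        reasons = []
        for gene in genes:
            vs = [v for v, gn in variant_gene.items() if gn == gene]
            detected = any(
                gm.gdna.at[cell, v] != "FAIL" or gm.cdna.at[cell, v] != "FAIL"
                for v in vs
            )
            if not detected:
                reasons.append(f"gene_undetected:{gene}")
        for v in gm.variants:
            if gm.calls.at[cell, v] == "EXCLUDED":
                reasons.append(f"variant_excluded:{v}")
        ok = not any(r.startswith("gene_undetected") for r in reasons)
        rows.append((cell, ok, ";".join(reasons)))
    qc = pd.DataFrame(rows, columns=["cell_id", "pass", "reasons"]).set_index("cell_id")
    return GenotypeMatrix(gm.calls, gm.gdna, gm.cdna, gm.panel, qc)


_DETERMINATE = ("WT", "HET", "HOM")


def assign_clones(
    gm: GenotypeMatrix,
    min_cells: int = 5,
    min_frac: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Group cells into clones by identical integrated genotype vectors.

    Cells with fully determinate calls define the clones; cells with
    non-determinate entries (MISSING/ND/EXCLUDED) are wildcarded and
    assigned only when exactly one existing clone is consistent, otherwise
    left unassigned.  Clone labels join ``VARIANT:CALL`` in panel order.
    Clones smaller than ``min_cells`` *and* below ``min_frac`` of cells
    are flagged minor.

    Returns ``(clone_table, per-cell labels)``; unassigned cells get the
    empty string.
    """
    variants = [v for v in gm.panel.variant_names if v in gm.calls.columns]
    calls = gm.calls[variants]
    labels = pd.Series("", index=calls.index, dtype=object, name="clone")

    def label_of(row) -> str:
        return ";".join(f"{v}:{row[v]}" for v in variants)

    determinate = calls.isin(_DETERMINATE).all(axis=1)
    for cell in calls.index[determinate]:
        labels[cell] = label_of(calls.loc[cell])

    clone_vectors: dict[str, pd.Series] = {}
    for cell in calls.index[determinate]:
        clone_vectors.setdefault(labels[cell], calls.loc[cell])
    for cell in calls.index[~determinate]:
        row = calls.loc[cell]
        consistent = [
            lab
            for lab, vec in clone_vectors.items()
            if all(row[v] not in _DETERMINATE or row[v] == vec[v] for v in variants)
        ]
        if len(consistent) == 1:
            labels[cell] = consistent[0]

    n_total = len(calls)
    counts = labels[labels != ""].value_counts()
    table = pd.DataFrame(
        {
            "clone": counts.index,
            "n_cells": counts.values,
            "frac": counts.values / n_total if n_total else np.zeros(0),
        }
    )
    table["minor"] = (table["n_cells"] < min_cells) & (table["frac"] < min_frac)
    return table.reset_index(drop=True), labels


def false_positive_audit(calls: Iterable[MoleculeCall] | pd.DataFrame) -> int:
    """Count mutation (HET/HOM) calls among control wells.

    With properly calibrated thresholds this must be zero on wild-type
    controls and blanks — the pipeline-level specificity check.
    """
    if isinstance(calls, pd.DataFrame):
        return int(calls["call"].isin(["HET", "HOM"]).sum())
    return sum(1 for c in calls if c.call in ("HET", "HOM"))


def genotype_pipeline(
    counts: pd.DataFrame,
    blank_counts: pd.DataFrame,
    wt_counts: pd.DataFrame,
    panel: Panel,
    dataset_mode: DatasetMode = "full_length",
    min_cells: int = 5,
    min_frac: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.Series, dict[str, ThresholdSet]]:
    """Calibrate, call, integrate, QC and assign clones in one pass."""
    thresholds = calibrate_thresholds(blank_counts, wt_counts, panel)
    mol_calls = call_molecules_table(counts, thresholds, panel, dataset_mode)
    gm = qc_cells(integrate_table(mol_calls, panel))
    clone_table, labels = assign_clones(gm.passing(), min_cells, min_frac)
    return gm, clone_table, labels, thresholds
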