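"""Reference benchmark scenarios at the assay's published operating point.

Each function simulates a dataset under fixed study conditions (control
counts, per-amplicon depth, error rates mirroring the assay: 874 wild-type
control cells and 114 blanks, ~2641 reads per amplicon, 0.5% base error,
fd = 0.001 / ad = 0.01 for tree inference), runs the corresponding part of
the pipeline end to end, and returns the measured quantity together with
the problem size.  They power both the acceptance checks and the worked
examples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .amplicons import count_alleles_table
from .de import combined_de_test
from .expression import (
    ExpressionMatrix,
    ado_from_het_sites,
    dropout_frequency,
    highly_variable_genes,
    normalize_3p,
)
from .genotyping import (
    calibrate_thresholds,
    call_molecules_table,
    false_positive_audit,
    integrate_table,
)
from .panel import AmpliconSpec, Panel, VariantSite
from .simulate import (
    SimConfig,
    simulate_clonal_population,
    simulate_expression,
    simulate_lognormal_expression,
    simulate_panel_reads,
)
from .tree import ErrorRates, MutationTree, infer_tree

__all__ = [
    "example_panel",
    "specificity_scenario",
    "genotype_recovery_scenario",
    "tree_recovery_scenario",
    "null_type1_scenario",
    "ado_recovery_scenario",
    "hvg_recall_scenario",
    "dropout_recovery_scenario",
]

_PRIMERS = [
    "ACGTACGTAC", "TTGACCATGA", "GGCATCGATT", "CCATGGTTAA",
    "GATCCTGAAC", "TGGAACCTTG", "CAGGATCCAT", "ATCCGGATCA",
    "GTTAACCGGT", "AACCGGTTAC", "CGATATCGGA", "TACGGATCCA",
]

_GENES = ["JAK2", "TET2", "EZH2", "ASXL1", "SRSF2", "CBL"]


def example_panel(n_genes: int = 6) -> Panel:
    """A 12-amplicon myeloid panel: one gDNA + one mRNA amplicon per gene.

    JAK2 is marked zygosity-critical, so its calls get the ND window.
    """
    amps = []
    k = 0
    for i, gene in enumerate(_GENES[:n_genes]):
        for mol in ("gDNA", "mRNA"):
            v = VariantSite(
                name=f"{gene}:mut",
                chrom="chr9" if mol == "gDNA" else "tx",
                pos=100 + i * 1000 + 50,
                ref="G",
                alt="T",
                zygosity_critical=(gene == "JAK2"),
            )
            amps.append(
                AmpliconSpec(
                    amplicon_id=f"{'g' if mol == 'gDNA' else 'm'}{gene}",
                    gene=gene,
                    molecule=mol,
                    fwd_primer=_PRIMERS[k],
                    rev_primer="ACGT",
                    chrom=v.chrom,
                    start=100 + i * 1000,
                    end=400 + i * 1000,
                    variants=(v,),
                )
            )
            k += 1
    return Panel(amps)


def _simulate_counts(cfg: SimConfig):
    reads, truth = simulate_panel_reads(cfg)
    return count_alleles_table(reads, cfg.panel), truth


def specificity_scenario(seed: int) -> dict:
    """False-positive audit on 874 WT control cells and 114 blanks.

    Thresholds are calibrated on a held-out control plate of the same
    design (874 WT cells, 114 blanks — controls are processed in parallel
    with every experiment); the audited wells then run through the full
    molecule-calling path.  Returns the number of HET/HOM calls among all
    control wells (target: zero).
    """
    panel = example_panel()
    cal_counts, _ = _simulate_counts(
        SimConfig(seed=seed, n_cells=874, n_blanks=114, panel=panel,
                  depth_mean=2641, seq_error_rate=0.005)
    )
    blanks = cal_counts[cal_counts["cell_id"].str.startswith("blank")]
    wt = cal_counts[cal_counts["cell_id"].str.startswith("cell")]
    thresholds = calibrate_thresholds(blanks, wt, panel)

    counts, _ = _simulate_counts(
        SimConfig(seed=seed + 1, n_cells=874, n_blanks=114, panel=panel,
                  depth_mean=2641, seq_error_rate=0.005)
    )
    calls = call_molecules_table(counts, thresholds, panel, "full_length")
    return {
        "false_positive_calls": false_positive_audit(calls),
        "n_control_cells": 874,
        "n_blanks": 114,
        "n_molecule_calls": int((calls["call"] != "FAIL").sum()),
    }


def genotype_recovery_scenario(seed: int, n_cells: int = 1000) -> dict:
    """Integrated-genotype accuracy on cells with known zygosity.

    1000 cells, depth 500 reads/amplicon, 0.5% base error, no allelic
    dropout; per-variant genotypes drawn WT/HET/HOM with probabilities
    0.5/0.3/0.2.  Thresholds come from a parallel full-size control plate
    (874 WT, 114 blanks), whose size sets the calibrated AF threshold
    comfortably above the sequencing-error tail.  Accuracy is the fraction
    of (cell, variant) integrated calls matching the simulated truth.
    """
    panel = example_panel()
    rng = np.random.default_rng(seed)
    n_var = len(panel.variant_names)
    genotypes = rng.choice([0, 1, 2], p=[0.5, 0.3, 0.2], size=(n_cells, n_var))

    cal_counts, _ = _simulate_counts(
        SimConfig(seed=seed + 10, n_cells=874, n_blanks=114, panel=panel,
                  depth_mean=500, seq_error_rate=0.005)
    )
    thresholds = calibrate_thresholds(
        cal_counts[cal_counts["cell_id"].str.startswith("blank")],
        cal_counts[cal_counts["cell_id"].str.startswith("cell")],
        panel,
    )

    counts, truth = _simulate_counts(
        SimConfig(seed=seed, n_cells=n_cells, panel=panel, depth_mean=500,
                  seq_error_rate=0.005, ado_prob=0.0, genotypes=genotypes)
    )
    calls = call_molecules_table(counts, thresholds, panel, "full_length")
    gm = integrate_table(calls, panel)
    expected = truth.genotypes.replace({0: "WT", 1: "HET", 2: "HOM"})
    match = (gm.calls.loc[expected.index, expected.columns] == expected).to_numpy()
    return {
        "accuracy_pct": 100.0 * match.mean(),
        "n_cells": n_cells,
        "n_calls": int(match.size),
    }


_TREE_SHAPES = [
    (4, 0, 1, 2),  # linear chain
    (4, 0, 0, 2),  # branch under the first mutation
    (4, 4, 0, 1),  # two independent lineages
    (4, 0, 1, 1),  # fork at depth two
]


def tree_recovery_scenario(seed: int, n_reps: int = 50, n_cells: int = 200) -> dict:
    """Tree recovery over seeded replicates of 4-mutation populations.

    Mixed linear/branching truth trees, fd = 0.001 / ad = 0.01.  A
    replicate counts as recovered when the truth tree is among the
    exhaustive co-optima; the hill climb must match the exhaustive argmax
    every time.
    """
    rng = np.random.default_rng(seed)
    er = ErrorRates(fd=0.001, ad=0.01)
    recovered = search_matched = 0
    for rep in range(n_reps):
        shape = _TREE_SHAPES[int(rng.integers(len(_TREE_SHAPES)))]
        truth_tree = MutationTree(parents=shape, names=("A", "B", "C", "D"))
        mm, _ = simulate_clonal_population(
            truth_tree, n_cells, fd=er.fd, ad=er.ad,
            seed=int(rng.integers(2**31)),
        )
        best, ll = infer_tree(mm, er, mode="exhaustive")
        if truth_tree.parents in [t.parents for t in best]:
            recovered += 1
        sbest, sll = infer_tree(mm, er, mode="search",
                                seed=int(rng.integers(2**31)), restarts=3)
        if abs(sll - ll) < 1e-9 and sbest[0].parents in [t.parents for t in best]:
            search_matched += 1
    return {
        "recovery_pct": 100.0 * recovered / n_reps,
        "search_matches_exhaustive_pct": 100.0 * search_matched / n_reps,
        "n_reps": n_reps,
        "n_cells": n_cells,
    }


def null_type1_scenario(
    seed: int, n_datasets: int = 20, n_genes: int = 2000, n_per_group: int = 100
) -> dict:
    """Type-I error of the combined test on fully expressed null data.

    Every gene is detected in every cell, so the frequency axis is
    uninformative by construction and the combined p reduces to the
    rank-sum p (k = 1); the rejection rate at 0.05 should be nominal.
    """
    rng = np.random.default_rng(seed)
    total = rejected = 0
    for _ in range(n_datasets):
        vals = simulate_lognormal_expression(
            n_genes, 2 * n_per_group, seed=int(rng.integers(2**31))
        )
        a = list(vals.columns[:n_per_group])
        b = list(vals.columns[n_per_group:])
        res = combined_de_test(vals, a, b)
        rejected += int((res["p_combined"] < 0.05).sum())
        total += len(res)
    return {
        "type1_rate": rejected / total,
        "nominal": 0.05,
        "n_tests": total,
        "mc_3sd": 3 * float(np.sqrt(0.05 * 0.95 / total)),
    }


def ado_recovery_scenario(
    seed: int, n_cells: int = 500, depth: int = 100, ado: float = 0.1
) -> dict:
    """Estimate allelic dropout from heterozygous-site allele counts.

    One transcriptome het site, 500 cells at depth 100; each cell's
    molecule loses one allele with probability 0.1.
    """
    rng = np.random.default_rng(seed)
    lost = rng.random(n_cells) < ado
    af = np.where(lost, np.where(rng.random(n_cells) < 0.5, 0.0, 1.0), 0.5)
    n_alt = rng.binomial(depth, af)
    counts = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "variant": "het_site",
            "n_ref": depth - n_alt,
            "n_alt": n_alt,
        }
    )
    est = ado_from_het_sites(counts)
    return {
        "ado_estimate": float(est.loc["het_site", "ado_rate"]),
        "ado_true": ado,
        "n_cells": n_cells,
    }


def hvg_recall_scenario(seed: int, n_cells: int = 500, n_spikes: int = 50) -> dict:
    """Recall of genes injected with a 3x coefficient of variation."""
    spikes = list(range(0, n_spikes * 10, 10))
    cfg = SimConfig(seed=seed, n_cells=n_cells, n_genes=2000)
    cm, truth = simulate_expression(cfg, ["A"] * n_cells, hvg_genes=spikes)
    em = normalize_3p(cm)
    fit = highly_variable_genes(em)
    eligible = [g for g in truth.hvg_genes if fit.loc[g, "log2_mean"] >= 0]
    recall = float(fit.loc[eligible, "selected"].mean())
    return {
        "hvg_recall_pct": 100.0 * recall,
        "n_spikes_eligible": len(eligible),
        "n_cells": n_cells,
    }


def dropout_recovery_scenario(
    seed: int, n_cells: int = 500, dropout: float = 0.3
) -> dict:
    """Dropout-frequency estimator against the configured per-gene rate.

    Evaluated on genes whose pre-dropout counts were positive in every
    cell, where an observed zero can only be a dropout event; each gene's
    estimate should sit within 3 binomial SDs of the configured rate.
    """
    cfg = SimConfig(seed=seed, n_cells=n_cells, n_genes=500, dropout_prob=dropout)
    cm, truth = simulate_expression(cfg, ["A"] * n_cells)
    clean = truth.dropout_rates.index[truth.dropout_rates["predrop_all_detected"]]
    arr = cm.to_numpy(dtype=float)
    em = ExpressionMatrix(
        pd.DataFrame(
            np.where(arr >= 1, np.log2(np.where(arr >= 1, arr, 1.0)), 0.0),
            index=cm.index, columns=cm.columns,
        ),
        "log2",
    )
    freq = dropout_frequency(em, list(clean))
    sd3 = 3 * np.sqrt(dropout * (1 - dropout) / n_cells)
    within = float((np.abs(freq - dropout) <= sd3).mean())
    return {
        "dropout_mean_estimate": float(freq.mean()),
        "dropout_true": dropout,
        "frac_genes_within_3sd": within,
        "n_genes_evaluated": int(len(clean)),
        "n_cells": n_cells,
    }
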