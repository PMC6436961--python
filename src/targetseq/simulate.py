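"""Synthetic single-cell amplicon, genotype-matrix and expression data.

Every generator records ground truth (true genotypes, per-molecule dropout
events, injected differential/variable genes) so downstream estimates can
be checked against what was simulated, and is deterministic under a fixed
seed.

The read generator emulates a targeted single-cell experiment: each
(cell, amplicon) receives a Poisson number of reads; each read carries the
ref or alt allele of the cell's true genotype, perturbed by per-base
sequencing error; allelic dropout removes one allele of a heterozygous
molecule before amplification; base qualities follow a two-point q37/q10
mixture so the base-quality filter is exercised.  Blank (non-template)
wells receive only low-depth Poisson contamination reads, giving threshold
calibration non-degenerate input.  Defaults mirror the assay's reported
operating point: ~2641 reads per amplicon and a 12-amplicon panel scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import ConfigurationError, Panel
from .tree import MutationTree

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_panel_reads",
    "simulate_sequence_reads",
    "simulate_clonal_population",
    "simulate_expression",
    "simulate_lognormal_expression",
    "write_fastq",
]

_OTHER_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    ``genotypes`` holds per-cell alt-allele copy numbers (0 = WT, 1 = HET,
    2 = HOM) as an ``n_cells x n_variants`` array in panel variant order;
    omitted means all wild type.  ``depth_mean`` defaults to the assay's
    reported mean amplicon coverage; ``contamination_depth`` is the mean
    background depth in blank wells (a free parameter of the simulation,
    default 5 reads/amplicon).
    """

    seed: int
    n_cells: int
    panel: Panel | None = None
    n_blanks: int = 0
    depth_mean: float = 2641.0
    seq_error_rate: float = 0.005
    ado_prob: float = 0.0
    contamination_depth: float = 5.0
    q_high: int = 37
    q_low: int = 10
    q_low_frac: float = 0.1
    genotypes: np.ndarray | None = None
    # expression-side conditions
    n_genes: int = 2000
    de_spec: tuple = ()
    libsize_lognormal: tuple[float, float] = (np.log(20_000.0), 0.3)
    nb_dispersion: float = 2.0
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        for name in ("seq_error_rate", "ado_prob", "q_low_frac", "dropout_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.genotypes is not None:
            self.genotypes = np.asarray(self.genotypes, dtype=int)
            if self.genotypes.shape[0] != self.n_cells:
                raise ConfigurationError("genotypes rows must equal n_cells")

    def manifest(self) -> dict:
        return {
            "seed": int(self.seed),
            "n_cells": int(self.n_cells),
            "n_blanks": int(self.n_blanks),
            "depth_mean": float(self.depth_mean),
            "seq_error_rate": float(self.seq_error_rate),
            "ado_prob": float(self.ado_prob),
            "contamination_depth": float(self.contamination_depth),
        }


@dataclass
class SimTruth:
    """Ground-truth record accompanying each simulated dataset."""

    genotypes: pd.DataFrame | None = None       # cells x variants, copies 0/1/2
    dropout_events: pd.DataFrame | None = None  # cell, amplicon, lost allele
    tree: MutationTree | None = None
    attachments: np.ndarray | None = None
    true_matrix: pd.DataFrame | None = None
    de_genes: pd.DataFrame | None = None
    hvg_genes: list[str] = field(default_factory=list)
    dropout_rates: pd.DataFrame | None = None  # configured/realized per gene
    manifest: dict = field(default_factory=dict)

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=2))


def _cell_names(cfg: SimConfig) -> tuple[list[str], list[str]]:
    cells = [f"cell{i:05d}" for i in range(cfg.n_cells)]
    blanks = [f"blank{i:04d}" for i in range(cfg.n_blanks)]
    return cells, blanks


def simulate_panel_reads(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate aligned-dialect reads for every well and amplicon.

    Returns a read table with columns ``cell_id, amplicon_id, variant,
    base, qual`` and the truth record.  Only SNV target variants are
    simulated at read level (the panel's indels would need full alignment
    context, which is out of the generator's scope); each amplicon's first
    variant is the simulated one.  Fully vectorized: tens of millions of
    reads are feasible.
    """
    if cfg.panel is None or len(cfg.panel) == 0:
        raise ConfigurationError("cfg.panel must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    cells, blanks = _cell_names(cfg)
    wells = cells + blanks
    n_wells = len(wells)
    variant_names = cfg.panel.variant_names
    geno = (
        cfg.genotypes
        if cfg.genotypes is not None
        else np.zeros((cfg.n_cells, len(variant_names)), dtype=int)
    )
    if geno.shape[1] != len(variant_names):
        raise ConfigurationError("genotypes columns must match panel variants")

    frames = []
    dropout_rows = []
    for amp in cfg.panel:
        if not amp.variants:
            raise ConfigurationError(f"amplicon {amp.amplicon_id} has no variants")
        site = amp.variants[0]
        if site.vtype != "SNV":
            raise ConfigurationError(
                f"read-level simulation supports SNVs only ({site.name} is {site.vtype})"
            )
        vidx = variant_names.index(site.name)

        depth = np.concatenate(
            [
                rng.poisson(cfg.depth_mean, size=cfg.n_cells),
                rng.poisson(cfg.contamination_depth, size=cfg.n_blanks),
            ]
        ).astype(np.int64)
        g = np.concatenate([geno[:, vidx], np.zeros(cfg.n_blanks, dtype=int)])
        af_true = g / 2.0

        # allelic dropout: one allele of a heterozygous molecule is lost
        het = g == 1
        lost = het & (rng.random(n_wells) < cfg.ado_prob)
        lost_alt = rng.random(n_wells) < 0.5
        af_true = np.where(lost, np.where(lost_alt, 0.0, 1.0), af_true)
        for w in np.flatnonzero(lost):
            dropout_rows.append(
                (wells[w], amp.amplicon_id, site.name, "alt" if lost_alt[w] else "ref")
            )

        total = int(depth.sum())
        if total == 0:
            continue
        well_idx = np.repeat(np.arange(n_wells, dtype=np.int32), depth)
        true_alt = rng.random(total) < af_true[well_idx]
        # bases as ACGT codes throughout; a sequencing error moves the code
        # to one of the three other bases uniformly
        acgt = {b: i for i, b in enumerate("ACGT")}
        base = np.where(true_alt, acgt[site.alt], acgt[site.ref]).astype(np.int8)
        err = rng.random(total) < cfg.seq_error_rate
        n_err = int(err.sum())
        if n_err:
            base[err] = (base[err] + rng.integers(1, 4, size=n_err)) % 4
        qual = np.where(
            rng.random(total) < cfg.q_low_frac, cfg.q_low, cfg.q_high
        ).astype(np.int16)
        amp_codes = [a.amplicon_id for a in cfg.panel]
        amp_j = amp_codes.index(amp.amplicon_id)
        vcode = variant_names.index(site.name)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": pd.Categorical.from_codes(well_idx, categories=wells),
                    "amplicon_id": pd.Categorical.from_codes(
                        np.full(total, amp_j, dtype=np.int16), categories=amp_codes
                    ),
                    "variant": pd.Categorical.from_codes(
                        np.full(total, vcode, dtype=np.int16), categories=variant_names
                    ),
                    "base": pd.Categorical.from_codes(base, categories=list("ACGT")),
                    "qual": qual,
                }
            )
        )

    reads = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cell_id", "amplicon_id", "variant", "base", "qual"]
    )
    truth = SimTruth(
        genotypes=pd.DataFrame(geno, index=cells, columns=variant_names),
        dropout_events=pd.DataFrame(
            dropout_rows, columns=["cell_id", "amplicon_id", "variant", "lost_allele"]
        ),
        manifest=cfg.manifest(),
    )
    return reads, truth


def _amplicon_template(amp, rng_seed: int) -> str:
    """Deterministic reference-like sequence for one amplicon.

    The forward primer occupies the first bases; each covered variant's
    ref base sits at its fixed offset from the amplicon start.
    """
    length = amp.end - amp.start + 1
    rng = np.random.default_rng(rng_seed)
    seq = rng.choice(list("ACGT"), size=length)
    seq[: len(amp.fwd_primer)] = list(amp.fwd_primer)
    for v in amp.variants:
        seq[v.pos - amp.start] = v.ref
    return "".join(seq)


def simulate_sequence_reads(
    cfg: SimConfig, primer_error_rate: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate full-sequence reads (primer + insert) for demultiplexing tests.

    Builds on :func:`simulate_panel_reads`: every aligned read becomes a
    sequence beginning with its amplicon's forward primer (each primer base
    flipped independently with ``primer_error_rate``) followed by a
    deterministic insert carrying the read's allele at the variant offset.
    Returns ``(sequence reads, aligned truth reads, truth)``.
    """
    import zlib

    aligned, truth = simulate_panel_reads(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    templates = {
        a.amplicon_id: _amplicon_template(
            a, (cfg.seed ^ zlib.crc32(a.amplicon_id.encode())) & 0x7FFFFFFF
        )
        for a in cfg.panel
    }
    rows = []
    for i, r in enumerate(aligned.itertuples(index=False)):
        amp = cfg.panel[str(r.amplicon_id)]
        site = amp.variants[0]
        tmpl = list(templates[amp.amplicon_id])
        tmpl[site.pos - amp.start] = str(r.base)
        for j in range(len(amp.fwd_primer)):
            if rng.random() < primer_error_rate:
                tmpl[j] = rng.choice(_OTHER_BASES[tmpl[j]])
        seq = "".join(tmpl)
        quals = chr(int(r.qual) + 33) * len(seq)
        rows.append((str(r.cell_id), f"read{i:07d}", seq, quals, str(r.amplicon_id)))
    seq_reads = pd.DataFrame(
        rows, columns=["cell_id", "read_id", "seq", "quals", "true_amplicon"]
    )
    return seq_reads, aligned, truth


def write_fastq(seq_reads: pd.DataFrame, path: str | Path) -> None:
    """Write sequence reads as FASTQ (one record per read)."""
    with open(path, "w") as fh:
        for r in seq_reads.itertuples(index=False):
            fh.write(f"@{r.read_id} cell={r.cell_id}\n{r.seq}\n+\n{r.quals}\n")


def simulate_clonal_population(
    tree: MutationTree,
    n_cells: int,
    fd: float = 0.001,
    ad: float = 0.01,
    seed: int = 0,
    missing_rate: float = 0.0,
    clone_freqs: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw cells from a mutation tree and corrupt them with fd/ad noise.

    Cells attach uniformly to the ``m+1`` tree nodes (root included) or per
    ``clone_freqs``; the true genotype is the attachment's root path.  Each
    entry is flipped 0->1 with probability ``fd`` and 1->0 with probability
    ``ad``; ``missing_rate`` masks entries to NaN.
    """
    for name, v in (("fd", fd), ("ad", ad)):
        if not (0 <= v < 1):
            raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
    rng = np.random.default_rng(seed)
    m = tree.m
    if clone_freqs is None:
        attach = rng.integers(0, m + 1, size=n_cells)
    else:
        p = np.asarray(clone_freqs, dtype=float)
        if p.size != m + 1 or not np.isclose(p.sum(), 1.0):
            raise ConfigurationError("clone_freqs must have m+1 entries summing to 1")
        attach = rng.choice(m + 1, size=n_cells, p=p)
    E = tree.attachment_genotypes()
    true = E[attach]
    flip_up = (true == 0) & (rng.random(true.shape) < fd)
    flip_down = (true == 1) & (rng.random(true.shape) < ad)
    obs = np.where(flip_up, 1.0, np.where(flip_down, 0.0, true))
    if missing_rate > 0:
        obs = np.where(rng.random(obs.shape) < missing_rate, np.nan, obs)
    cells = [f"cell{i:05d}" for i in range(n_cells)]
    mm = pd.DataFrame(obs, index=cells, columns=tree.names)
    truth = SimTruth(
        tree=tree,
        attachments=attach,
        true_matrix=pd.DataFrame(true, index=cells, columns=tree.names),
        manifest={"seed": seed, "n_cells": n_cells, "fd": fd, "ad": ad,
                  "missing_rate": missing_rate},
    )
    return mm, truth


def simulate_expression(
    cfg: SimConfig,
    labels: Sequence[str],
    hvg_genes: Sequence[int] = (),
    hvg_cv_factor: float = 3.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Negative-binomial count matrix with known DE and variable genes.

    Per-gene base means are lognormal; per-cell library-size factors follow
    ``cfg.libsize_lognormal``; counts are gamma-Poisson with dispersion
    ``cfg.nb_dispersion``.  ``cfg.de_spec`` entries ``(gene, log2_effect,
    group)`` multiply the gene's mean by ``2**effect`` in that genotype
    group; ``hvg_genes`` get their squared coefficient of variation scaled
    by ``hvg_cv_factor**2``; ``cfg.dropout_prob`` zeroes observations
    per gene-cell at a known rate.
    """
    if cfg.n_genes < 100:
        raise ConfigurationError("n_genes must be >= 100")
    labels = np.asarray(labels, dtype=object)
    n_cells = labels.size
    groups = set(labels)
    if cfg.de_spec and len(groups) < 2:
        raise ConfigurationError("de_spec requires >= 2 genotype groups")
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    cells = [f"cell{i:05d}" for i in range(n_cells)]

    base_mu = rng.lognormal(mean=np.log(5.0), sigma=1.5, size=cfg.n_genes)
    mu = np.tile(base_mu[:, None], (1, n_cells))
    de_rows = []
    for gene, effect, group in cfg.de_spec:
        gi = genes.index(gene) if isinstance(gene, str) else int(gene)
        if group not in groups:
            raise ConfigurationError(f"de_spec group {group!r} not in labels")
        mu[gi, labels == group] *= 2.0 ** float(effect)
        de_rows.append((genes[gi], float(effect), group))

    sf = rng.lognormal(*cfg.libsize_lognormal, size=n_cells)
    sf = sf / sf.mean()
    mu = mu * sf[None, :]

    r = np.full(cfg.n_genes, float(cfg.nb_dispersion))
    hvg_names = []
    for gi in hvg_genes:
        gi = int(gi)
        # inflate CV^2 = 1/mu + 1/r by hvg_cv_factor^2 via the dispersion term
        inv_r = hvg_cv_factor**2 * (1.0 / base_mu[gi] + 1.0 / r[gi]) - 1.0 / base_mu[gi]
        r[gi] = 1.0 / inv_r
        hvg_names.append(genes[gi])

    lam = rng.gamma(shape=r[:, None], scale=mu / r[:, None])
    counts = rng.poisson(lam).astype(np.int64)
    predrop_all_detected = (counts > 0).all(axis=1)
    realized = np.zeros(cfg.n_genes)
    if cfg.dropout_prob > 0:
        mask = rng.random(counts.shape) < cfg.dropout_prob
        realized = mask.mean(axis=1)
        counts = np.where(mask, 0, counts)

    cm = pd.DataFrame(counts, index=genes, columns=cells)
    truth = SimTruth(
        de_genes=pd.DataFrame(de_rows, columns=["gene", "log2_effect", "group"]),
        hvg_genes=hvg_names,
        dropout_rates=pd.DataFrame(
            {
                "configured": cfg.dropout_prob,
                "realized": realized,
                "predrop_all_detected": predrop_all_detected,
            },
            index=genes,
        ),
        manifest={"seed": cfg.seed, "n_genes": cfg.n_genes, "n_cells": int(n_cells)},
    )
    return cm, truth


def simulate_lognormal_expression(
    n_genes: int, n_cells: int, seed: int, mean_log2: float = 5.0, sd_log2: float = 1.0
) -> pd.DataFrame:
    """Fully expressed log2 expression matrix (no zeros).

    Gaussian on the log2 scale around per-gene means; useful as a
    continuous null where every gene is detected in every cell.
    """
    rng = np.random.default_rng(seed)
    gene_means = rng.normal(mean_log2, 2.0, size=n_genes)
    vals = rng.normal(gene_means[:, None], sd_log2, size=(n_genes, n_cells))
    vals = np.maximum(vals, 0.01)
    return pd.DataFrame(
        vals,
        index=[f"G{i:05d}" for i in range(n_genes)],
        columns=[f"cell{i:05d}" for i in range(n_cells)],
    )
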