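"""Read demultiplexing by primer and base-quality-filtered allele counting.

Two read representations are supported:

* **sequence reads** — a table with columns ``cell_id, read_id, seq, quals``
  (FASTQ content in tabular form), demultiplexed to amplicons by anchored
  forward-primer prefix match;
* **aligned reads** — a table with columns
  ``cell_id, amplicon_id, variant, base, qual`` (optionally ``fragment_id``)
  giving the observed allele at each target variant, which is what an
  upstream aligner + pileup would produce.  All counting operates on this
  dialect; ``reads_from_fastq``/``demux_reads`` convert into it.

Counting follows samtools mpileup conventions: per-base quality filter
(default minimum 30), orphan reads kept, overlapping mates of a fragment
deduplicated keeping the higher-quality base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd

from .panel import ConfigurationError, Panel, VariantSite

__all__ = [
    "AlleleCount",
    "PrimerAmbiguityError",
    "DemuxResult",
    "demux_reads",
    "count_alleles",
    "count_alleles_table",
    "count_alleles_sam",
    "split_by_molecule",
    "reads_from_fastq",
    "write_counts_tsv",
    "read_counts_tsv",
]

ALIGNED_COLUMNS = ["cell_id", "amplicon_id", "variant", "base", "qual"]


class PrimerAmbiguityError(ValueError):
    """A read's start matches more than one forward primer."""


@dataclass(frozen=True)
class AlleleCount:
    """Quality-filtered allele tally for one cell at one target variant."""

    cell_id: str
    amplicon_id: str
    variant: str
    n_ref: int
    n_alt: int
    n_other: int

    @property
    def coverage(self) -> int:
        return self.n_ref + self.n_alt + self.n_other

    @property
    def af(self) -> float:
        """Alt-allele fraction among ref+alt reads (0 when neither seen).

        Third alleles are excluded from the denominator so the fraction
        stays interpretable against the ND windows.
        """
        denom = self.n_ref + self.n_alt
        return self.n_alt / denom if denom else 0.0


@dataclass
class DemuxResult:
    """Aligned-read table plus the tally of reads no primer claimed."""

    reads: pd.DataFrame
    unassigned: int
    n_input: int

    @property
    def assigned(self) -> int:
        return len(self.reads["read_id"].unique()) if len(self.reads) else 0


def _prefix_mismatches(seqs: pd.Series, primer: str) -> np.ndarray:
    """Vectorized Hamming distance of each read's 5' prefix to a primer."""
    L = len(primer)
    padded = seqs.str.slice(0, L).str.pad(L, side="right", fillchar="N")
    arr = np.frombuffer("".join(padded).encode(), dtype="S1").reshape(-1, L)
    ref = np.frombuffer(primer.encode(), dtype="S1")
    return (arr != ref).sum(axis=1)


def demux_reads(
    reads: pd.DataFrame,
    panel: Panel,
    max_mismatch: int = 1,
) -> DemuxResult:
    """Assign sequence reads to amplicons by anchored forward-primer match.

    A read is assigned to the amplicon whose forward primer matches the read
    start with at most ``max_mismatch`` mismatches; matching is anchored at
    the 5' end (no scanning).  Reads matching no primer are tallied as
    unassigned and dropped; a read matching two primers raises
    :class:`PrimerAmbiguityError` naming the offending pair.  The result
    is the aligned dialect: the base observed at each covered variant is
    extracted at its fixed offset within the amplicon.
    """
    if reads.empty:
        return DemuxResult(pd.DataFrame(columns=ALIGNED_COLUMNS + ["read_id"]), 0, 0)
    seqs = reads["seq"].astype(str)
    n = len(reads)
    mm = np.stack(
        [_prefix_mismatches(seqs, a.fwd_primer) for a in panel], axis=1
    )  # n_reads x n_amplicons
    hits = mm <= max_mismatch
    n_hits = hits.sum(axis=1)
    multi = np.flatnonzero(n_hits > 1)
    if multi.size:
        i = multi[0]
        pair = [panel.amplicons[j].amplicon_id for j in np.flatnonzero(hits[i])[:2]]
        raise PrimerAmbiguityError(
            f"read {reads.iloc[i]['read_id']!r} matches primers of amplicons "
            f"{pair[0]} and {pair[1]} within {max_mismatch} mismatches"
        )
    assigned_idx = np.flatnonzero(n_hits == 1)
    amp_idx = hits[assigned_idx].argmax(axis=1)

    rows = []
    for j, amp in enumerate(panel):
        sel = assigned_idx[amp_idx == j]
        if sel.size == 0:
            continue
        sub = reads.iloc[sel]
        for v in amp.variants:
            offset = v.pos - amp.start  # variant offset within the amplicon
            base = sub["seq"].str.slice(offset, offset + len(v.ref if v.vtype != "SNV" else v.alt))
            if v.vtype == "SNV":
                base = sub["seq"].str.slice(offset, offset + 1)
            qual = sub["quals"].str.slice(offset, offset + 1).map(
                lambda q: (ord(q) - 33) if q else 0
            )
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": sub["cell_id"].values,
                        "amplicon_id": amp.amplicon_id,
                        "variant": v.name,
                        "base": base.values,
                        "qual": qual.values,
                        "read_id": sub["read_id"].values,
                    }
                )
            )
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=ALIGNED_COLUMNS + ["read_id"])
    )
    return DemuxResult(out, unassigned=int((n_hits == 0).sum()), n_input=n)


def count_alleles(
    reads: pd.DataFrame,
    site: VariantSite,
    min_base_quality: int = 30,
    cell_id: str | None = None,
    amplicon_id: str | None = None,
) -> AlleleCount:
    """Tally ref/alt/other alleles for one read group at one variant.

    Bases below ``min_base_quality`` are discarded entirely.  When a
    ``fragment_id`` column is present, overlapping mates are deduplicated
    keeping the higher-quality observation (mpileup's overlap handling).
    For indels the ``base`` column carries the full observed allele string,
    so exact-match tallying covers SNVs and indels uniformly.
    """
    g = reads
    if len(g) == 0:
        return AlleleCount(cell_id or "", amplicon_id or "", site.name, 0, 0, 0)
    if "variant" in g.columns:
        g = g[g["variant"] == site.name]
    if cell_id is None:
        cell_id = str(g["cell_id"].iloc[0]) if len(g) else ""
    if amplicon_id is None and "amplicon_id" in g.columns and len(g):
        amplicon_id = str(g["amplicon_id"].iloc[0])
    if "fragment_id" in g.columns and len(g):
        # overlapping mates: keep the higher-quality base, first mate on ties
        g = g.sort_values("qual", kind="stable", ascending=False).drop_duplicates(
            "fragment_id", keep="first"
        )
    g = g[g["qual"] >= min_base_quality]
    base = g["base"].astype(str)
    n_ref = int((base == site.ref).sum())
    n_alt = int((base == site.alt).sum())
    return AlleleCount(
        cell_id=cell_id,
        amplicon_id=amplicon_id or "",
        variant=site.name,
        n_ref=n_ref,
        n_alt=n_alt,
        n_other=int(len(g) - n_ref - n_alt),
    )


def count_alleles_table(
    reads: pd.DataFrame,
    panel: Panel,
    min_base_quality: int = 30,
) -> pd.DataFrame:
    """Vectorized allele counting over a whole aligned-read table.

    Returns one row per (cell, amplicon, variant) with columns
    ``cell_id, amplicon_id, gene, variant, molecule, n_ref, n_alt, n_other,
    coverage, af``.  Equivalent to calling :func:`count_alleles` per group
    but scales to tens of millions of reads.
    """
    g = reads
    if "fragment_id" in reads.columns:
        g = g.sort_values("qual", kind="stable", ascending=False).drop_duplicates(
            "fragment_id", keep="first"
        )
    g = g[g["qual"] >= min_base_quality]

    def codes(col: pd.Series) -> tuple[np.ndarray, list]:
        if isinstance(col.dtype, pd.CategoricalDtype):
            return col.cat.codes.to_numpy(), list(col.cat.categories)
        c, uniq = pd.factorize(col.astype(str), sort=True)
        return c, list(uniq)

    cell_f, cell_u = codes(g["cell_id"])
    amp_f, amp_u = codes(g["amplicon_id"])
    var_f, var_u = codes(g["variant"])
    base_f, base_u = codes(g["base"])

    n_amp, n_var = len(amp_u), len(var_u)
    amp_idx = {a: i for i, a in enumerate(amp_u)}
    var_idx = {v: i for i, v in enumerate(var_u)}
    base_idx = {b: i for i, b in enumerate(base_u)}
    ref_code = np.full(n_amp * n_var, -2, dtype=np.int64)
    alt_code = np.full(n_amp * n_var, -2, dtype=np.int64)
    for amp in panel:
        if amp.amplicon_id not in amp_idx:
            continue
        for v in amp.variants:
            if v.name not in var_idx:
                continue
            k = amp_idx[amp.amplicon_id] * n_var + var_idx[v.name]
            ref_code[k] = base_idx.get(v.ref, -2)
            alt_code[k] = base_idx.get(v.alt, -2)

    key = amp_f.astype(np.int64) * n_var + var_f
    is_ref = base_f == ref_code[key]
    is_alt = base_f == alt_code[key]
    gid = (cell_f.astype(np.int64) * n_amp + amp_f) * n_var + var_f
    size = len(cell_u) * n_amp * n_var
    total = np.bincount(gid, minlength=size)
    n_ref = np.bincount(gid, weights=is_ref, minlength=size).astype(np.int64)
    n_alt = np.bincount(gid, weights=is_alt, minlength=size).astype(np.int64)
    present = np.flatnonzero(total > 0)
    cell_i = present // (n_amp * n_var)
    amp_i = (present // n_var) % n_amp
    var_i = present % n_var
    out = pd.DataFrame(
        {
            "cell_id": np.array(cell_u, dtype=object)[cell_i],
            "amplicon_id": np.array(amp_u, dtype=object)[amp_i],
            "variant": np.array(var_u, dtype=object)[var_i],
            "n_ref": n_ref[present],
            "n_alt": n_alt[present],
            "n_other": total[present] - n_ref[present] - n_alt[present],
        }
    ).sort_values(["cell_id", "amplicon_id", "variant"], ignore_index=True)
    return finalize_counts(out, panel)


def finalize_counts(counts: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    """Attach gene/molecule metadata and derived coverage/af columns."""
    counts = counts.copy()
    gene = {a.amplicon_id: a.gene for a in panel}
    mol = {a.amplicon_id: a.molecule for a in panel}
    counts["gene"] = counts["amplicon_id"].map(gene)
    counts["molecule"] = counts["amplicon_id"].map(mol)
    counts["coverage"] = counts["n_ref"] + counts["n_alt"] + counts["n_other"]
    denom = (counts["n_ref"] + counts["n_alt"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(denom > 0, counts["n_alt"].to_numpy(dtype=float) / np.where(denom > 0, denom, 1), 0.0)
    counts["af"] = af
    cols = [
        "cell_id", "amplicon_id", "gene", "variant", "molecule",
        "n_ref", "n_alt", "n_other", "coverage", "af",
    ]
    return counts[cols]


def count_alleles_sam(
    path: str | Path,
    site: VariantSite,
    min_base_quality: int = 30,
    cell_id: str = "",
    amplicon_id: str = "",
) -> AlleleCount:
    """Pileup-based allele counting at one site from a SAM/BAM file.

    Mirrors ``samtools mpileup --minBQ 30 --count-orphans --ignore-overlaps``:
    orphan reads are kept, overlapping mates counted once, bases below the
    quality floor dropped.  Indels are tallied by the pileup indel length at
    the anchor base (exact-event matching for the panel's known indels).
    """
    import pysam

    pos0 = site.pos - 1
    indel_len = len(site.alt) - len(site.ref)
    # fragment-level observations: (base or indel class, qual), dedup by name
    frags: dict[str, tuple[str, int]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name != site.chrom:
                continue
            if not (read.reference_start <= pos0 < read.reference_end):
                continue
            obs: tuple[str, int] | None = None
            if site.vtype == "SNV":
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if rpos == pos0:
                        q = read.query_qualities[qpos]
                        obs = (read.query_sequence[qpos], q)
                        break
            else:
                # walk the CIGAR to find an indel anchored right after pos0
                rpos, qpos = read.reference_start, 0
                event = 0
                anchor_q = None
                for op, ln in read.cigartuples:
                    if op in (0, 7, 8):  # aligned block
                        if rpos <= pos0 < rpos + ln:
                            anchor_q = qpos + (pos0 - rpos)
                        rpos += ln
                        qpos += ln
                    elif op == 1:  # insertion
                        if rpos == pos0 + 1:
                            event = ln
                        qpos += ln
                    elif op == 2:  # deletion
                        if rpos == pos0 + 1:
                            event = -ln
                        rpos += ln
                    elif op in (4,):  # soft clip
                        qpos += ln
                if anchor_q is not None:
                    q = read.query_qualities[anchor_q]
                    if event == indel_len and event != 0:
                        obs = ("alt", q)
                    elif event == 0:
                        obs = ("ref", q)
                    else:
                        obs = ("other", q)
            if obs is None:
                continue
            prev = frags.get(read.query_name)
            if prev is None or obs[1] > prev[1]:
                frags[read.query_name] = obs

    n_ref = n_alt = n_other = 0
    for b, q in frags.values():
        if q < min_base_quality:
            continue
        label = b
        if site.vtype == "SNV":
            label = "ref" if b == site.ref else "alt" if b == site.alt else "other"
        if label == "ref":
            n_ref += 1
        elif label == "alt":
            n_alt += 1
        else:
            n_other += 1
    return AlleleCount(cell_id, amplicon_id or site.name, site.name, n_ref, n_alt, n_other)


def split_by_molecule(
    counts: pd.DataFrame, panel: Panel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a counts table into disjoint gDNA and mRNA tables.

    Every amplicon must carry a declared molecule class; the two outputs
    partition the input rows, and a gene assayed by both molecule classes
    appears in both tables.
    """
    known = {a.amplicon_id for a in panel}
    unknown = set(counts["amplicon_id"].astype(str)) - known
    if unknown:
        raise ConfigurationError(f"amplicons without molecule class: {sorted(unknown)}")
    if "molecule" not in counts.columns:
        counts = finalize_counts(counts, panel)
    g = counts[counts["molecule"] == "gDNA"].reset_index(drop=True)
    m = counts[counts["molecule"] == "mRNA"].reset_index(drop=True)
    return g, m


def reads_from_fastq(path: str | Path, cell_id: str) -> pd.DataFrame:
    """Load one cell's FASTQ into the sequence-read table."""
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        rows.append((cell_id, rec.id, str(rec.seq), quals))
    return pd.DataFrame(rows, columns=["cell_id", "read_id", "seq", "quals"])


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str})
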