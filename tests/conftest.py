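"""Shared fixtures: a small paired gDNA/mRNA panel and count-row helpers."""

import pandas as pd
import pytest

from targetseq.panel import AmpliconSpec, Panel, VariantSite

# 10-bp primers, pairwise distant enough for a 1-mismatch budget
PRIMERS = [
    "ACGTACGTAC", "TTGACCATGA", "GGCATCGATT", "CCATGGTTAA",
    "GATCCTGAAC", "TGGAACCTTG", "CAGGATCCAT", "ATCCGGATCA",
    "GTTAACCGGT", "AACCGGTTAC", "CGATATCGGA", "TACGGATCCA",
]

GENES = ["JAK2", "TET2", "EZH2", "ASXL1", "SRSF2", "CBL"]


def make_panel(n_genes: int = 6) -> Panel:
    """Panel with one gDNA + one mRNA amplicon per gene, one SNV each.

    JAK2 is zygosity-critical (gets the ND window)."""
    amps = []
    k = 0
    for i, gene in enumerate(GENES[:n_genes]):
        for mol in ("gDNA", "mRNA"):
            v = VariantSite(
                name=f"{gene}:mut",
                chrom="chr9" if mol == "gDNA" else "tx",
                pos=100 + i * 1000 + 50,
                ref="G",
                alt="T",
                zygosity_critical=(gene == "JAK2"),
            )
            prefix = "g" if mol == "gDNA" else "m"
            amps.append(
                AmpliconSpec(
                    amplicon_id=f"{prefix}{gene}",
                    gene=gene,
                    molecule=mol,
                    fwd_primer=PRIMERS[k],
                    rev_primer="ACGT",
                    chrom=v.chrom,
                    start=100 + i * 1000,
                    end=400 + i * 1000,
                    variants=(v,),
                )
            )
            k += 1
    return Panel(amps)


@pytest.fixture(scope="session")
def panel() -> Panel:
    return make_panel()


@pytest.fixture(scope="session")
def small_panel() -> Panel:
    return make_panel(2)


def count_row(
    cell_id: str,
    amplicon_id: str,
    variant: str,
    n_ref: int,
    n_alt: int,
    n_other: int = 0,
) -> dict:
    denom = n_ref + n_alt
    return {
        "cell_id": cell_id,
        "amplicon_id": amplicon_id,
        "variant": variant,
        "n_ref": n_ref,
        "n_alt": n_alt,
        "n_other": n_other,
        "coverage": n_ref + n_alt + n_other,
        "af": n_alt / denom if denom else 0.0,
    }


def counts_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([count_row(*r) if isinstance(r, tuple) else r for r in rows])
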