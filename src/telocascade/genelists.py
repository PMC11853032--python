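"""Packaged gene lists used by the screen presets and the synthetic fixture.

The telomere-maintenance (TMM) list ships as an editable TSV
(``data/tmm_genes.tsv``) with one of four functional categories per gene:
telomere machinery, telomere topology, DNA-damage/checkpoint regulators, and
TMM effectors (recombination/ALT).  Users may replace it with their own
curation; the screen only needs symbols.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["DEG_GENES", "PAX_GENES", "DAMAGE_GENES", "tmm_gene_table", "tmm_genes"]

# Differentially expressed genes reported for the paired NF→MPNST comparison
# (11 up, 11 down); used as the default source set of the first screen stage
# and as planted DEGs in the paper-shaped synthetic fixture.
DEG_GENES_UP = [
    "NUF2", "ASPM", "SOX11", "BUB1", "ANLN", "KCNE3", "FOXM1", "NELL2", "FOXG1",
    "DLGAP5", "SIX1",
]
DEG_GENES_DOWN = [
    "GRIK3", "CHL1", "CLDN1", "BAI3", "SORBS1", "ARHGAP20", "PRIMA1", "LPCAT2",
    "CDH19", "DMD", "SLITRK2",
]
DEG_GENES = DEG_GENES_UP + DEG_GENES_DOWN

# The nine paired-box developmental transcription factors.
PAX_GENES = [f"PAX{i}" for i in range(1, 10)]

# DNA-damage markers screened against the TMM list.
DAMAGE_GENES = ["H2AFX", "PARP1", "TP53", "RB1"]


def tmm_gene_table(path: str | None = None) -> pd.DataFrame:
    """The 100-gene TMM table (columns: gene, category); ``path`` overrides the packaged copy."""
    if path is not None:
        df = pd.read_csv(path, sep="\t")
    else:
        with resources.files("telocascade.data").joinpath("tmm_genes.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    if not {"gene", "category"}.issubset(df.columns):
        raise ValueError("TMM gene table needs 'gene' and 'category' columns")
    return df


def tmm_genes(path: str | None = None) -> list[str]:
    return list(tmm_gene_table(path)["gene"])
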