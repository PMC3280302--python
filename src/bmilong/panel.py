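"""Candidate SNP panel: annotations that parameterize simulation, QC and reporting.

The default panel is the set of 23 GWAS-significant BMI SNPs used throughout the
pipeline, with their genes, genomic coordinates (NCBI B36), minor/major alleles
and minor-allele frequencies in the study population.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

PANEL_COLUMNS = [
    "snp_id", "gene", "chr", "strand", "position",
    "minor_allele", "major_allele", "maf",
]

# snp_id, gene, chr, strand, position (bp), minor, major, MAF
_DEFAULT_PANEL = """\
rs2568958	NEGR1	1	+	72537704	G	A	0.38
rs2815752	NEGR1	1	-	72585028	C	T	0.38
rs1514175	TNNI3K	1	-	74764232	T	C	0.40
rs2867125	TMEM18	2	-	612827	A	G	0.18
rs7561317	TMEM18	2	+	634953	A	G	0.19
rs13078807	CADM2	3	+	85966840	G	A	0.22
rs7647305	ETV5	3	+	187316984	T	C	0.22
rs13107325	SLC39A8	4	+	103407732	T	C	0.09
rs987237	TFAP2B	6	+	50911009	G	A	0.17
rs10968576	LRRN6C	9	+	28404339	G	A	0.30
rs925946	BDNF	11	+	27623778	T	G	0.33
rs6265	BDNF	11	-	27636492	A	G	0.19
rs10767664	BDNF	11	+	27682562	T	A	0.20
rs10838738	MTCH2	11	+	47619625	G	A	0.35
rs7138803	FAIM2	12	+	48533735	A	G	0.37
rs2241423	MAP2K5	15	+	65873892	A	G	0.22
rs6499640	FTO	16	+	52327178	G	A	0.39
rs1121980	FTO	16	-	52366748	T	C	0.42
rs8050136	FTO	16	+	52373776	A	C	0.40
rs571312	MC4R	18	-	55990749	T	G	0.23
rs12970134	MC4R	18	+	56035730	A	G	0.27
rs29941	KCTD15	19	-	39001372	T	C	0.31
rs2287019	QPCTL	19	+	50894012	T	C	0.17
"""


@dataclass(frozen=True)
class SnpPanel:
    """Annotation table for a set of candidate SNPs.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per SNP with columns ``snp_id, gene, chr, strand, position,
        minor_allele, major_allele, maf``. SNP ids must be unique and MAFs must
        lie in [0, 0.5].
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PANEL_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate SNP ids in panel: {dup}")
        maf = t["maf"].astype(float)
        if ((maf < 0) | (maf > 0.5)).any():
            bad = t.loc[(maf < 0) | (maf > 0.5), "snp_id"].tolist()
            raise ValueError(f"MAF outside [0, 0.5] for: {bad}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def mafs(self) -> pd.Series:
        return self.table.set_index("snp_id")["maf"].astype(float)

    def __len__(self) -> int:
        return len(self.table)

    def alleles(self, snp_id: str) -> tuple[str, str]:
        """Return (minor_allele, major_allele) for one SNP."""
        row = self.table.set_index("snp_id").loc[snp_id]
        return str(row["minor_allele"]), str(row["major_allele"])

    def subset(self, snp_ids: list[str]) -> "SnpPanel":
        t = self.table.set_index("snp_id").loc[list(snp_ids)].reset_index()
        return SnpPanel(t)


def default_panel() -> SnpPanel:
    """The built-in 23-SNP candidate panel (GWAS BMI hits, study-population MAFs)."""
    table = pd.read_csv(
        io.StringIO(_DEFAULT_PANEL), sep="\t", names=PANEL_COLUMNS,
        dtype={"chr": str},
    )
    return SnpPanel(table)


def read_panel(path) -> SnpPanel:
    """Read a SNP annotation table (tab-separated, header row) from ``path``."""
    table = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return SnpPanel(table)


def write_panel(panel: SnpPanel, path) -> None:
    """Write the panel as a tab-separated table with a header row."""
    panel.table.to_csv(path, sep="\t", index=False)
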