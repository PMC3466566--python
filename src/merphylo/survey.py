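"""Published mer-operon survey summaries as package inputs.

A December-2011 survey of all completed microbial genomes tabulated 272 mer
operons (53 plasmid-borne, the rest chromosomal, distributed over 246
genomes of which 23 carry two or three operons) and printed, for every scored
gene trait, its presence/absence counts with and without the plasmid-borne
operons. Those printed marginal counts ship with the package
(``data/mer_survey_table1.tsv``) and are the inputs to the percentage
arithmetic and the plasmid-bias regression.

``build_survey_catalog`` expands the marginals into a SYNTHETIC catalog: row
counts, replicon split, genome multiplicities and every per-trait marginal
match the published survey, but the joint (operon-by-operon) gene content is
an arbitrary marginals-consistent assignment. It supports count/percentage
operations only; gene-gene co-occurrence on it reflects the assignment, not
biology, and the full supplementary catalog is required for that.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .traits import TraitMatrix

__all__ = [
    "load_survey_table",
    "build_survey_catalog",
    "survey_percent_pairs",
    "N_OPERONS",
    "N_PLASMID",
    "N_GENOMES",
    "N_MULTI_GENOMES",
]

N_OPERONS = 272
N_PLASMID = 53
N_CHROM = N_OPERONS - N_PLASMID
N_GENOMES = 246
N_MULTI_GENOMES = 23


def load_survey_table() -> pd.DataFrame:
    """The printed per-trait signal/count table (both replicon arms)."""
    ref = resources.files("merphylo.data") / "mer_survey_table1.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def survey_percent_pairs() -> pd.DataFrame:
    """The 16 printed (chromosome-only %, all-operons %) pairs, one per trait."""
    tab = load_survey_table()
    return pd.DataFrame(
        {
            "trait": tab["trait"],
            "percent_chromosome": tab["percent_chrom"].astype(float),
            "percent_all": tab["percent_all"].astype(float),
        }
    )


def _genome_ids() -> list[str]:
    """272 genome ids realizing 246 genomes with 23 multi-operon genomes.

    The survey reports multi-operon genomes carry two or three operons; with
    23 such genomes and 26 excess operons the split is forced: 3 genomes with
    three operons and 20 with two (3*3 + 20*2 + 223*1 = 272).
    """
    ids: list[str] = []
    g = 0
    for _ in range(3):
        g += 1
        ids.extend([f"g{g:03d}"] * 3)
    for _ in range(20):
        g += 1
        ids.extend([f"g{g:03d}"] * 2)
    while len(ids) < N_OPERONS:
        g += 1
        ids.append(f"g{g:03d}")
    assert g == N_GENOMES
    return ids


def build_survey_catalog() -> TraitMatrix:
    """Synthetic marginals-matched expansion of the printed survey counts.

    Chromosomal rows come first (219), then plasmid rows (53). Each trait's
    presences fill the leading rows of each replicon block, except the merR
    orientation variants, which are assigned disjointly so that core merR
    (= convergent OR divergent) reproduces its own printed counts.
    """
    tab = load_survey_table().set_index("trait")
    cols: dict[str, np.ndarray] = {"merA": np.ones(N_OPERONS, dtype=int)}

    def fill(pres_chrom: int, pres_plasmid: int, chrom_offset=0, plasmid_offset=0):
        v = np.zeros(N_OPERONS, dtype=int)
        v[chrom_offset : chrom_offset + pres_chrom] = 1
        v[N_CHROM + plasmid_offset : N_CHROM + plasmid_offset + pres_plasmid] = 1
        return v

    div_c = int(tab.loc["merR_divergent", "presence_chrom"])
    div_p = int(tab.loc["merR_divergent", "presence_all"]) - div_c
    conv_c = int(tab.loc["merR_convergent", "presence_chrom"])
    conv_p = int(tab.loc["merR_convergent", "presence_all"]) - conv_c
    cols["merR_divergent"] = fill(div_c, div_p)
    cols["merR_convergent"] = fill(conv_c, conv_p, chrom_offset=div_c, plasmid_offset=div_p)
    cols["merR"] = (cols["merR_divergent"] | cols["merR_convergent"]).astype(int)

    for trait, row in tab.iterrows():
        if trait in cols:
            continue
        pres_chrom = int(row["presence_chrom"])
        pres_plasmid = int(row["presence_all"]) - pres_chrom
        if pres_chrom < 0 or pres_plasmid < 0 or pres_plasmid > N_PLASMID:
            raise ValueError(f"inconsistent printed counts for {trait!r}")
        cols[trait] = fill(pres_chrom, pres_plasmid)

    df = pd.DataFrame(
        {
            "operon_id": [f"op{i + 1:03d}" for i in range(N_OPERONS)],
            "taxon_label": [f"op{i + 1:03d}" for i in range(N_OPERONS)],
            "genome_id": _genome_ids(),
            "replicon": ["chromosome"] * N_CHROM + ["plasmid"] * N_PLASMID,
            **cols,
        }
    )
    return TraitMatrix(df)
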