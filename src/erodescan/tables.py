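"""Flat-file I/O for site tables and the screen's tabular inputs.

Conserved/eroded sites travel as BED6+ TSV: the first six columns are BED
(score = −log10 empirical P), followed by the BBL score, species count,
conservation bin, empirical P and the comma-separated matching species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import GeneModel
from .prediction import ConservedSite

SITE_COLUMNS = ["chrom", "start", "end", "motif_id", "score", "strand",
                "bbl", "n_species", "conservation_bin", "empirical_p",
                "matching_species"]


def sites_to_frame(sites) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append({
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "motif_id": s.motif_id,
            "score": -np.log10(s.empirical_p),
            "strand": s.strand, "bbl": s.bbl, "n_species": s.n_species,
            "conservation_bin": s.conservation_bin,
            "empirical_p": s.empirical_p,
            "matching_species": ",".join(sorted(s.matching_species)),
        })
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def frame_to_sites(df: pd.DataFrame) -> list[ConservedSite]:
    out = []
    for r in df.itertuples():
        out.append(ConservedSite(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            strand=str(r.strand), motif_id=str(r.motif_id),
            matching_species=frozenset(str(r.matching_species).split(",")),
            bbl=float(r.bbl), conservation_bin=int(r.conservation_bin),
            empirical_p=float(r.empirical_p)))
    return out


def write_sites(path, sites, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        if params:
            for k, v in params.items():
                fh.write(f"# {k} = {v}\n")
        sites_to_frame(sites).to_csv(fh, sep="\t", index=False)


def read_sites(path) -> list[ConservedSite]:
    return frame_to_sites(pd.read_csv(path, sep="\t", comment="#"))


def read_genes_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
            for r in df.itertuples()]


def read_gmt(path) -> dict[str, list[str]]:
    terms: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = parts[2:]
    return terms


def read_regions_bed(path) -> list[tuple[str, int, int]]:
    """First three columns of a BED or site TSV (with or without header)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], comment="#", dtype=str)
    if len(df) and not df.iloc[0]["start"].lstrip("-").isdigit():
        df = df.iloc[1:]
    return [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]
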