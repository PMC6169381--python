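"""On-disk formats: TSV/CSV tables (UTF-8, header row, "NA" missing) and a
minimal VCF v4.2 export of line genotypes."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MISSING, GeneticMap

NA = "NA"


def write_table(df: pd.DataFrame, path, sep: str = "\t", index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index, na_rep=NA)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, na_values=[NA], keep_default_na=True)


def write_map_tsv(gmap: GeneticMap, path) -> None:
    write_table(gmap.frame[["marker", "chrom", "bp", "cM"]], path)


def read_map_tsv(path) -> GeneticMap:
    return GeneticMap(read_table(path))


def write_genotypes_csv(geno: np.ndarray, line_ids, markers, path) -> None:
    """Lines x markers dose matrix, 0/1/2 with NA for missing."""
    g = np.asarray(geno, dtype=float)
    g[np.asarray(geno) == MISSING] = np.nan
    df = pd.DataFrame(g, index=pd.Index(line_ids, name="line"), columns=markers)
    write_table(df, path, sep=",", index=True)


def read_genotypes_csv(path) -> pd.DataFrame:
    """Doses as float with NaN missing; use ``doses_to_int8`` for the packed
    form used by the population containers."""
    return pd.read_csv(path, sep=",", na_values=[NA], index_col=0)


def doses_to_int8(df: pd.DataFrame) -> np.ndarray:
    g = df.to_numpy(dtype=float)
    out = np.where(np.isnan(g), MISSING, np.rint(g)).astype(np.int8)
    bad = (out != MISSING) & ~np.isin(out, (0, 1, 2))
    if bad.any():
        raise ValueError("genotype doses must be 0/1/2 or missing")
    return out


def write_vcf(geno: np.ndarray, line_ids, gmap: GeneticMap, path) -> None:
    """Minimal unphased VCF v4.2 with GT fields; REF=A, ALT=T placeholders
    since the simulator tracks abstract biallelic states."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in gmap.chromosomes():
        idx = gmap.chrom_indices(chrom)
        length = int(gmap.frame["bp"].iloc[idx[-1]]) + 1
        lines.append(f"##contig=<ID={chrom},length={length}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + list(line_ids)
    lines.append("\t".join(header))
    frame = gmap.frame
    for j in range(gmap.n_markers):
        row = [str(frame["chrom"].iloc[j]), str(int(frame["bp"].iloc[j])),
               str(frame["marker"].iloc[j]), "A", "T", ".", "PASS", ".", "GT"]
        row.extend(gt_code[int(v)] for v in geno[:, j])
        lines.append("\t".join(row))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
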