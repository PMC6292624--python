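"""Text formats: PLINK PED/MAP, cohort tables, intensity records, call tables.

Haploid mtDNA genotypes travel as the PLINK text dialect: the MAP file lists
loci as ``MT  mt<pos>  0  <pos>``, and the PED file encodes each haploid call
as a homozygous diploid pair ("A A"), with missing calls as "0 0".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classify import HgCall, calls_to_frame
from .matrix import ALT, MISSING, REF, GenotypeMatrix

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "write_cohort",
    "read_cohort",
    "write_intensities",
    "read_intensities",
    "write_hgcalls",
]


def write_ped_map(g: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns both paths."""
    prefix = Path(prefix)
    map_path = prefix.parent / (prefix.name + ".map")
    ped_path = prefix.parent / (prefix.name + ".ped")
    with open(map_path, "w") as fh:
        for _, row in g.loci.iterrows():
            fh.write(f"MT\tmt{int(row['position'])}\t0\t{int(row['position'])}\n")
    ref = g.loci["ref"].to_numpy()
    alt = g.loci["alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for sid, row in zip(g.sample_ids, g.calls):
            alleles = np.where(row == REF, ref, np.where(row == ALT, alt, "0"))
            pairs = "\t".join(f"{a} {a}" for a in alleles)
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\t{pairs}\n")
    return ped_path, map_path


def read_ped_map(
    prefix: str | Path, loci: pd.DataFrame | None = None
) -> GenotypeMatrix:
    """Read a PED/MAP pair back into a GenotypeMatrix.

    If ``loci`` (position/ref/alt) is given it supplies the allele coding;
    otherwise REF/ALT are inferred per locus from the observed alleles
    (first-seen allele becomes REF — supply ``loci`` for stable coding).
    """
    prefix = Path(prefix)
    positions = []
    with open(prefix.parent / (prefix.name + ".map")) as fh:
        for line in fh:
            chrom, _, _, pos = line.split()
            positions.append(int(pos))
    sample_ids = []
    rows = []
    with open(prefix.parent / (prefix.name + ".ped")) as fh:
        for line in fh:
            fields = line.split()
            sample_ids.append(fields[1])
            alleles = fields[6::2]  # haploid encoded as homozygous pairs
            rows.append(alleles)
    if loci is None:
        ref = {}
        alt = {}
        for row in rows:
            for pos, a in zip(positions, row):
                if a == "0":
                    continue
                if pos not in ref:
                    ref[pos] = a
                elif a != ref[pos] and pos not in alt:
                    alt[pos] = a
        loci = pd.DataFrame(
            {
                "position": positions,
                "ref": [ref.get(p, "A") for p in positions],
                "alt": [alt.get(p, "T") for p in positions],
            }
        )
    else:
        loci = loci.reset_index(drop=True)
        if list(loci["position"]) != positions:
            raise ValueError("loci table does not match MAP positions")
    ref_arr = loci["ref"].to_numpy()
    alt_arr = loci["alt"].to_numpy()
    calls = np.full((len(rows), len(positions)), MISSING, dtype=np.int8)
    for i, row in enumerate(rows):
        arr = np.asarray(row)
        calls[i][arr == ref_arr] = REF
        calls[i][arr == alt_arr] = ALT
    return GenotypeMatrix(sample_ids, loci, calls)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "metro" in df:
        df["metro"] = df["metro"].astype(bool)
    return df


def write_intensities(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_intensities(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_hgcalls(calls: list[HgCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
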