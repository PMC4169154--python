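"""CSV / array-container readers and writers.

All tabular formats are plain CSV (UTF-8, LF, period decimal separator):

* marker map: ``marker,chr,bp,cM``
* genotype calls: one row per sample (``sample`` column first), one column
  per marker, values in {A,H,B,N}
* intensities: an X and a Y matrix in the same layout as calls
* phenotypes: ``sample,phenotype`` plus covariate columns
* founder SNP table: ``snp,chr,bp`` plus one 0/1 reference-allele column per
  founder

Large posterior arrays (samples x markers x 36 states) go to a compressed
``.npz`` container with a CSV export path for the per-sample summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dosage import SdpTable
from .genome import DiplotypeProbs, GenotypeCalls, IntensityData, MarkerMap


def read_map(path) -> MarkerMap:
    t = pd.read_csv(path, dtype={"chr": str})
    return MarkerMap(t)


def write_map(map: MarkerMap, path) -> None:
    map.table.to_csv(path, index=False, lineterminator="\n")


def read_calls(path) -> GenotypeCalls:
    t = pd.read_csv(path, dtype=str)
    if t.columns[0] != "sample":
        raise ValueError("first column of a call matrix must be 'sample'")
    samples = t["sample"].tolist()
    symbols = t.drop(columns="sample").to_numpy(dtype="U1")
    return GenotypeCalls.from_symbols(samples, symbols)


def write_calls(calls: GenotypeCalls, markers, path) -> None:
    df = pd.DataFrame(calls.to_symbols(), columns=list(markers))
    df.insert(0, "sample", calls.samples)
    df.to_csv(path, index=False, lineterminator="\n")


def read_intensities(path_x, path_y) -> IntensityData:
    tx = pd.read_csv(path_x)
    ty = pd.read_csv(path_y)
    if list(tx["sample"]) != list(ty["sample"]):
        raise ValueError("X and Y intensity files list different samples")
    samples = tx["sample"].tolist()
    return IntensityData(samples,
                         tx.drop(columns="sample").to_numpy(float),
                         ty.drop(columns="sample").to_numpy(float))


def write_intensities(data: IntensityData, markers, path_x, path_y) -> None:
    for mat, path in ((data.x, path_x), (data.y, path_y)):
        df = pd.DataFrame(mat, columns=list(markers))
        df.insert(0, "sample", data.samples)
        df.to_csv(path, index=False, lineterminator="\n")


def read_pheno(path, phenotype: str = "phenotype"):
    from .scan import PhenotypeTable

    t = pd.read_csv(path)
    if "sample" not in t.columns or phenotype not in t.columns:
        raise ValueError(f"phenotype file needs 'sample' and {phenotype!r} columns")
    return PhenotypeTable(t, phenotype)


def read_founder_snps(path, founder_labels) -> SdpTable:
    t = pd.read_csv(path, dtype={"chr": str})
    missing = [l for l in founder_labels if l not in t.columns]
    if missing:
        raise ValueError(f"founder SNP table missing allele columns: {missing}")
    G = t[list(founder_labels)].to_numpy(int)
    alleles = 1 - G  # file stores the reference indicator
    return SdpTable.from_alleles(t.iloc[:, 0].to_numpy(), t["chr"].to_numpy(),
                                 t["bp"].to_numpy(np.int64), alleles)


def write_founder_snps(sdp: SdpTable, founder_labels, path) -> None:
    from .dosage import sdp_table_to_frame

    sdp_table_to_frame(sdp, founder_labels).to_csv(path, index=False,
                                                   lineterminator="\n")


def write_probs(probs: DiplotypeProbs, states, path) -> None:
    np.savez_compressed(path, probs=probs.probs,
                        samples=np.array(probs.samples),
                        states=np.array(list(states)))


def read_probs(path) -> DiplotypeProbs:
    with np.load(path, allow_pickle=False) as z:
        return DiplotypeProbs(list(z["samples"]), z["probs"])
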