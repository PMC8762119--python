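"""Readers and writers for the formats the pipeline touches.

VCF 4.2 is the exchange format for haplotype panels and imputation results
(biallelic records only, one contig, 1-based POS; internal coordinates are
0-based half-open).  Reading goes through cyvcf2; writing emits the fixed
biallelic dialect directly.  Marker selections serialize to BED (0-based
half-open) and to a site-index TSV.  The benchmark's published summary
tables (variant counts per density level, reliability and error-rate grids)
ship as CSV fixtures for the aggregation layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from imputesim.ascertainment import MarkerSelection
from imputesim.demography import HaplotypePanel
from imputesim.imputation import ImputationResult, best_guess_genotype

__all__ = [
    "FixtureTable",
    "VcfError",
    "write_vcf",
    "read_vcf",
    "read_vcf_result",
    "write_population_labels",
    "read_population_labels",
    "selection_to_bed",
    "selection_to_tsv",
    "load_fixture",
]

logger = logging.getLogger("imputesim")


class VcfError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=imputesim
##contig=<ID={contig},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed allele dosage">
"""


def write_vcf(obj, path, *, contig: str = "1", sample_names=None) -> None:
    """Write a haplotype panel or an imputation result as VCF 4.2.

    Panels emit phased GT (``a|b``); imputation results emit GT from the
    best-guess genotype (heterozygotes written ``0|1`` by convention) plus
    the DS dosage field.  Internal 0-based positions become 1-based POS.
    """
    if isinstance(obj, HaplotypePanel):
        n = obj.n_individuals
        length = int(obj.sequence_length)
        positions = obj.positions
        def records():
            h1 = obj.matrix[0::2]
            h2 = obj.matrix[1::2]
            for s in range(obj.n_sites):
                yield positions[s], "GT", ["%d|%d" % (h1[k, s], h2[k, s]) for k in range(n)]
    elif isinstance(obj, ImputationResult):
        n = obj.dosage.shape[0]
        positions = obj.positions
        length = int(positions[-1]) + 1 if len(positions) else 1
        _GT = {0: "0|0", 1: "0|1", 2: "1|1"}
        def records():
            for s in range(len(positions)):
                yield positions[s], "GT:DS", [
                    "%s:%.4g" % (_GT[int(obj.best_guess[k, s])], obj.dosage[k, s])
                    for k in range(n)
                ]
    else:
        raise VcfError(f"cannot write object of type {type(obj).__name__} as VCF")

    if len(positions) and np.any(np.diff(positions) <= 0):
        raise VcfError("positions must be strictly increasing")
    if sample_names is None:
        sample_names = [f"ind{k}" for k in range(n)]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=contig, length=length))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for pos, fmt, cells in records():
            fh.write(f"{contig}\t{int(pos) + 1}\t.\tA\tT\t.\tPASS\t.\t{fmt}\t")
            fh.write("\t".join(cells) + "\n")


def _iter_vcf(path):
    from cyvcf2 import VCF

    if not Path(path).exists():
        raise VcfError(f"no such VCF: {path}")
    return VCF(str(path), gts012=False)


def read_vcf(path, *, labels_path=None, accept_unphased: bool = False) -> HaplotypePanel:
    """Read a phased biallelic VCF into a haplotype panel.

    Multiallelic records and missing GT are rejected.  Unphased genotypes
    (``/`` separator) are rejected unless ``accept_unphased`` is set, which
    treats the written allele order as the simulation-truth phase.
    Population labels come from the sidecar TSV (see
    :func:`write_population_labels`) when given, else every individual is
    labelled ``unknown``.
    """
    vcf = _iter_vcf(path)
    positions: list[int] = []
    haps: list[np.ndarray] = []
    length = None
    for contig in vcf.seqlens or []:
        length = contig
    for v in vcf:
        if len(v.ALT) != 1:
            raise VcfError(
                f"multiallelic record at POS {v.POS}: the pipeline is biallelic by construction"
            )
        gts = v.genotypes  # [[a, b, phased], ...]
        if gts is None:
            raise VcfError(f"missing GT at POS {v.POS}")
        row = np.empty(2 * len(gts), dtype=np.uint8)
        for k, g in enumerate(gts):
            if len(g) < 3:
                raise VcfError(f"haploid or malformed GT at POS {v.POS}")
            a, b, phased = g[0], g[1], g[-1]
            if a < 0 or b < 0:
                raise VcfError(f"missing allele at POS {v.POS}")
            if not phased and a != b and not accept_unphased:
                raise VcfError(
                    f"unphased heterozygote at POS {v.POS}; pass accept_unphased=True "
                    "to assume simulation-truth phase"
                )
            row[2 * k] = a
            row[2 * k + 1] = b
        haps.append(row)
        positions.append(v.POS - 1)
    n_samples = 2 * len(vcf.samples)
    matrix = (
        np.array(haps, dtype=np.uint8).T if haps else np.zeros((n_samples, 0), dtype=np.uint8)
    )
    pos_arr = np.array(positions, dtype=np.int64)
    if labels_path is not None:
        ind_pops = read_population_labels(labels_path)
        pops = np.repeat(ind_pops, 2)
    else:
        pops = np.array(["unknown"] * n_samples)
    if length is None:
        length = int(pos_arr[-1]) + 1 if len(pos_arr) else 1
    return HaplotypePanel(
        matrix=matrix,
        positions=pos_arr,
        sample_populations=pops,
        sequence_length=float(length),
    )


def read_vcf_result(path) -> ImputationResult:
    """Read imputed genotypes (GT, optionally DS) into an ImputationResult.

    When DS is present it takes precedence for the dosage while GT defines
    the best-guess genotype; a disagreement beyond rounding is logged as a
    warning.  Without DS, the dosage falls back to the GT allele count.
    """
    vcf = _iter_vcf(path)
    positions: list[int] = []
    gt_rows: list[np.ndarray] = []
    ds_rows: list[np.ndarray | None] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise VcfError(f"multiallelic record at POS {v.POS}")
        gts = v.genotypes
        if gts is None:
            raise VcfError(f"missing GT at POS {v.POS}")
        g = np.array([a + b if a >= 0 and b >= 0 else -1 for a, b, *_ in gts], dtype=np.int8)
        if np.any(g < 0):
            raise VcfError(f"missing allele at POS {v.POS}")
        ds = v.format("DS")
        ds_rows.append(None if ds is None else np.asarray(ds, dtype=float).ravel())
        gt_rows.append(g)
        positions.append(v.POS - 1)
    if not positions:
        raise VcfError(f"no records in {path}")
    best = np.array(gt_rows, dtype=np.int8).T  # individuals x sites
    dosage = np.empty_like(best, dtype=float)
    for s, ds in enumerate(ds_rows):
        if ds is None:
            dosage[:, s] = best[:, s]
        else:
            dosage[:, s] = ds
            if np.any(best_guess_genotype(ds) != best[:, s]):
                logger.warning(
                    "DS inconsistent with GT rounding at POS %d; DS wins for dosage, "
                    "GT for best-guess",
                    positions[s] + 1,
                )
    return ImputationResult(
        positions=np.array(positions, dtype=np.int64),
        dosage=dosage,
        best_guess=best,
    )


# ---------------------------------------------------------------------------
# Sidecars: population labels, BED, site-index TSV
# ---------------------------------------------------------------------------


def write_population_labels(panel: HaplotypePanel, path, sample_names=None) -> None:
    """Per-individual population labels as a two-column TSV sidecar."""
    pops = panel.individual_populations
    if sample_names is None:
        sample_names = [f"ind{k}" for k in range(panel.n_individuals)]
    pd.DataFrame({"sample": sample_names, "population": pops}).to_csv(
        path, sep="\t", index=False
    )


def read_population_labels(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df["population"].to_numpy()


def selection_to_bed(selection: MarkerSelection, positions: np.ndarray, path, *, contig="1") -> None:
    """Observed scaffold markers as BED intervals (0-based half-open)."""
    pos = np.asarray(positions)[selection.observed]
    with open(path, "w") as fh:
        for p in pos:
            fh.write(f"{contig}\t{int(p)}\t{int(p) + 1}\n")


def selection_to_tsv(selection: MarkerSelection, path) -> None:
    """Full selection as a site-index table (index, observed/hidden role)."""
    idx = np.concatenate([selection.observed, selection.hidden])
    role = ["observed"] * len(selection.observed) + ["hidden"] * len(selection.hidden)
    df = pd.DataFrame({"site_index": idx, "role": role}).sort_values("site_index")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Printed-table fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "T4": "table4_variant_counts.csv",
    "T5": "table5_reliability.csv",
    "T6": "table6_error_rate.csv",
}


@dataclass
class FixtureTable:
    """A published summary table, cells exactly as printed."""

    id: str
    table: pd.DataFrame

    def tidy(self) -> pd.DataFrame:
        """Long form: one row per (software, reference_size, density) cell."""
        if self.id == "T4":
            raise VcfError("T4 is a count table; use .table directly")
        long = self.table.melt(
            id_vars=["software", "reference_size"],
            var_name="density",
            value_name="value",
        )
        long["density"] = long["density"].astype(int)
        return long


def load_fixture(table_id: str) -> FixtureTable:
    """Load a packaged summary-table fixture: "T4", "T5" or "T6".

    T4: segregating-variant counts per density level and population (plus a
    ``total`` row and the SNPs/kb density column).  T5: imputation
    reliability grid (software x reference size x density).  T6: imputation
    error rate (%) grid in the same layout.
    """
    if table_id not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture table {table_id!r}; expected one of {sorted(_FIXTURE_FILES)}")
    ref = resources.files("imputesim").joinpath("data", _FIXTURE_FILES[table_id])
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    return FixtureTable(id=table_id, table=df)
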