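"""Bi-allelic genotype matrices and their CSV / minimal-VCF serialisation.

Genotypes are alternate-allele copy counts in {0, 1, 2}; missing calls are
encoded as -1 internally (and as NA in CSV, ./. in VCF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MISSING", "GenotypeMatrix", "read_genotype_csv", "read_vcf"]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """individuals x loci alternate-allele counts with colony assignments."""

    individual_ids: list[str]
    colony_of: dict[str, str]
    loci_ids: list[str]
    calls: np.ndarray  # int array, values in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = len(self.individual_ids), len(self.loci_ids)
        if self.calls.shape != (n, m):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n} individuals, {m} loci)"
            )
        unknown = [i for i in self.individual_ids if i not in self.colony_of]
        if unknown:
            raise ValueError(f"individuals without colony assignment: {unknown[:5]}")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype calls must be in {0, 1, 2, missing}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci_ids)

    @property
    def colonies(self) -> list[str]:
        seen: list[str] = []
        for i in self.individual_ids:
            c = self.colony_of[i]
            if c not in seen:
                seen.append(c)
        return seen

    def colony_mask(self, colony: str) -> np.ndarray:
        return np.array([self.colony_of[i] == colony for i in self.individual_ids])

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.individual_ids, self.colony_of,
            [l for l, k in zip(self.loci_ids, keep) if k],
            self.calls[:, keep],
        )

    # ---------------------------------------------------------------- I/O

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            np.where(self.calls == MISSING, np.nan, self.calls),
            index=self.individual_ids, columns=self.loci_ids,
        )
        df.insert(0, "colony", [self.colony_of[i] for i in self.individual_ids])
        df.to_csv(path, index_label="individual_id")

    def to_vcf(self, path) -> None:
        """Write a minimal bi-allelic VCF (GT only, chromosome '1')."""
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.individual_ids) + "\n")
            for j, locus in enumerate(self.loci_ids):
                gts = "\t".join(gt_map[int(g)] for g in self.calls[:, j])
                fh.write(f"1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotype_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    colony = df.pop("colony").astype(str)
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    ids = [str(i) for i in df.index]
    return GenotypeMatrix(ids, dict(zip(ids, colony)), [str(c) for c in df.columns],
                          calls)


def read_vcf(path, colony_of: dict[str, str]) -> GenotypeMatrix:
    """Minimal bi-allelic VCF reader (GT field only; phased or unphased)."""
    samples: list[str] = []
    loci: list[str] = []
    rows: list[list[int]] = []
    code = {"0": 0, "1": 1, ".": MISSING}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if "," in fields[4]:
                raise ValueError(f"multi-allelic site {fields[2]} not supported")
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            loci.append(fields[2] if fields[2] != "." else f"{fields[0]}:{fields[1]}")
            row = []
            for entry in fields[9:]:
                gt = entry.split(":")[gt_idx].replace("|", "/")
                alleles = [code[a] for a in gt.split("/")]
                row.append(MISSING if MISSING in alleles else sum(alleles))
            rows.append(row)
    calls = np.asarray(rows, dtype=np.int8).T
    return GenotypeMatrix(samples, colony_of, loci, calls)
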