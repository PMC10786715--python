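"""Genotype container and VCF input/output.

Dosages are stored as a dense ``float64`` matrix (donors x variants) with
``NaN`` marking missing calls, alongside a variant table carrying
chromosome, 1-based position, alleles and per-variant summaries (MAF, MAC,
missing rate, Hardy-Weinberg exact p).  VCF files are written as plain
text with a ``GT:DS`` FORMAT so that standard tooling can consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "maf", "mac", "missing_rate", "hwe_p"]


@dataclass
class GenotypeMatrix:
    """Donors x variants dosage matrix with variant metadata.

    Attributes
    ----------
    dosages : ndarray, shape (n_donors, n_variants)
        Allele dosages in [0, 2]; NaN marks missing.
    donors : list of str
    variants : DataFrame
        One row per variant with columns ``chrom, pos, id, ref, alt``
        plus summary columns filled by :meth:`recompute_summaries`.
    """

    dosages: np.ndarray
    donors: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.donors), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.donors)} donors x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def hard_calls(self) -> np.ndarray:
        """Round dosages to genotype calls {0,1,2} (thresholds 0.5/1.5); NaN kept."""
        calls = np.full_like(self.dosages, np.nan)
        ok = ~np.isnan(self.dosages)
        calls[ok] = np.where(
            self.dosages[ok] < 0.5, 0.0, np.where(self.dosages[ok] < 1.5, 1.0, 2.0)
        )
        return calls

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing donors."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def recompute_summaries(self) -> None:
        """Fill maf / mac / missing_rate / hwe_p columns from the dosages."""
        from .gwas import hwe_exact_test

        calls = self.hard_calls()
        freq = self.allele_frequencies()
        maf = np.minimum(freq, 1 - freq)
        n_obs = np.sum(~np.isnan(calls), axis=0)
        alt_count = np.nansum(calls, axis=0)
        mac = np.minimum(alt_count, 2 * n_obs - alt_count)
        miss = np.mean(np.isnan(self.dosages), axis=0)
        hwe = np.ones(self.n_variants)
        for j in range(self.n_variants):
            col = calls[:, j]
            col = col[~np.isnan(col)]
            n_aa = int(np.sum(col == 0))
            n_het = int(np.sum(col == 1))
            n_alt = int(np.sum(col == 2))
            if n_aa + n_het + n_alt > 0:
                hwe[j] = hwe_exact_test(n_aa, n_het, n_alt)
        self.variants = self.variants.assign(
            maf=maf, mac=mac, missing_rate=miss, hwe_p=hwe
        )

    def subset(self, donor_idx=None, variant_idx=None) -> "GenotypeMatrix":
        d = np.arange(self.n_donors) if donor_idx is None else np.asarray(donor_idx)
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(d, v)],
            donors=[self.donors[i] for i in d],
            variants=self.variants.iloc[v].reset_index(drop=True),
        )


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write genotypes as an uncompressed VCF 4.2 with GT:DS per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.donors)
            + "\n"
        )
        calls = gm.hard_calls()
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in enumerate(gm.variants.itertuples(index=False)):
            fields = [
                str(row.chrom),
                str(int(row.pos)),
                str(row.id),
                str(row.ref),
                str(row.alt),
                ".",
                "PASS",
                ".",
                "GT:DS",
            ]
            for i in range(gm.n_donors):
                ds = gm.dosages[i, j]
                if np.isnan(ds):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_map[calls[i, j]]}:{ds:g}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF with a DS FORMAT field back into a :class:`GenotypeMatrix`."""
    donors: list[str] = []
    records = []
    dosage_rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                donors = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            try:
                ds_idx = fmt.index("DS")
            except ValueError:
                ds_idx = None
            gt_idx = fmt.index("GT") if "GT" in fmt else None
            row = []
            for cell in parts[9:]:
                sub = cell.split(":")
                if ds_idx is not None and ds_idx < len(sub) and sub[ds_idx] not in (".", ""):
                    row.append(float(sub[ds_idx]))
                elif gt_idx is not None:
                    gt = sub[gt_idx].replace("|", "/")
                    if "." in gt:
                        row.append(np.nan)
                    else:
                        row.append(float(sum(int(a) for a in gt.split("/"))))
                else:
                    row.append(np.nan)
            records.append((chrom, pos, vid, ref, alt))
            dosage_rows.append(row)
    variants = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt"])
    for col in ("maf", "mac", "missing_rate", "hwe_p"):
        variants[col] = np.nan
    dos = np.asarray(dosage_rows, dtype=float).T if dosage_rows else np.empty((len(donors), 0))
    return GenotypeMatrix(dosages=dos, donors=donors, variants=variants)
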