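"""File I/O: PLINK text (.ped/.map), VCFv4.2, and the pipeline's TSV tables.

The dosage convention everywhere is the count of the variant table's ``alt``
allele (0/1/2, -1 missing); orientation to the minor allele happens later in
the association stage. Writing then reading a cohort reproduces the
in-memory objects exactly, including the missing mask.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort, GenotypeMatrix
from .ranking import GeneCatalog

_CHROM_SORT = {str(c): c for c in range(1, 23)} | {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}


def _sorted_variants(variants: pd.DataFrame) -> pd.DataFrame:
    key = variants["chrom"].map(lambda c: _CHROM_SORT.get(str(c).upper(), 99))
    return variants.assign(_k=key).sort_values(["_k", "pos"], kind="mergesort").drop(columns="_k")


def write_plink(geno: GenotypeMatrix, variants: pd.DataFrame, prefix: str | Path) -> tuple[Path, Path]:
    """Write PLINK text .ped/.map; SNP order follows (chrom, pos)."""
    prefix = Path(prefix)
    ordered = _sorted_variants(variants)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for row in ordered.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")

    col_of = {s: j for j, s in enumerate(geno.snp_ids)}
    order = [col_of[s] for s in ordered["snp_id"]]
    refs = ordered["ref"].to_numpy()
    alts = ordered["alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(geno.sample_ids):
            fields = [sample, sample, "0", "0", "0", "-9"]
            row = geno.dosages[i, order]
            for j, d in enumerate(row):
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [refs[j], refs[j]]
                elif d == 1:
                    fields += [refs[j], alts[j]]
                else:
                    fields += [alts[j], alts[j]]
            fh.write("\t".join(fields) + "\n")
    return ped_path, map_path


def read_plink(prefix: str | Path, variants: pd.DataFrame) -> GenotypeMatrix:
    """Read PLINK text .ped/.map back into alt-allele dosages.

    ``variants`` supplies the ref/alt labels needed to orient allele pairs
    (the .map format itself carries no alleles).
    """
    prefix = Path(prefix)
    vmeta = variants.set_index("snp_id")
    snp_order = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            _, snp_id, _, _ = line.split()
            snp_order.append(snp_id)
    sample_ids = []
    rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            sample_ids.append(fields[1])
            alleles = fields[6:]
            dose = np.empty(len(snp_order), dtype=np.int8)
            for j, snp in enumerate(snp_order):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    dose[j] = MISSING
                else:
                    alt = vmeta.at[snp, "alt"]
                    dose[j] = (a1 == alt) + (a2 == alt)
            rows.append(dose)
    return GenotypeMatrix(sample_ids=sample_ids, snp_ids=snp_order, dosages=np.vstack(rows))


def write_vcf(geno: GenotypeMatrix, variants: pd.DataFrame, path: str | Path) -> Path:
    """Write genotypes as an uncompressed VCFv4.2 file (GT field only)."""
    path = Path(path)
    ordered = _sorted_variants(variants)
    col_of = {s: j for j, s in enumerate(geno.snp_ids)}
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snpenrich\n")
        for chrom in dict.fromkeys(ordered["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.sample_ids) + "\n")
        for row in ordered.itertuples(index=False):
            doses = geno.dosages[:, col_of[row.snp_id]]
            gts = "\t".join(gt_code[int(d)] for d in doses)
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n"
            )
    return path


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read an uncompressed VCF with GT fields into alt-allele dosages."""
    sample_ids: list[str] = []
    snp_ids: list[str] = []
    meta_rows = []
    dose_rows = []
    gt_map = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING,
              "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2, ".|.": MISSING}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                sample_ids = fields[9:]
                continue
            chrom, pos, snp_id, ref, alt = fields[:5]
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            doses = [gt_map[f.split(":")[gt_idx]] for f in fields[9:]]
            snp_ids.append(snp_id)
            meta_rows.append({"snp_id": snp_id, "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt})
            dose_rows.append(doses)
    geno = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        dosages=np.array(dose_rows, dtype=np.int8).T,
    )
    return geno, pd.DataFrame(meta_rows)


def write_cohort(
    cohort: Cohort,
    outdir: str | Path,
    formats: tuple[str, ...] = ("plink", "vcf"),
) -> dict[str, Path]:
    """Emit the cohort as PLINK text and/or VCF plus TSV tables.

    Always writes ``variants.tsv`` (annotation), ``phenotypes.tsv`` and,
    when a catalog is attached, ``catalog.tsv`` + ``designations.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if "plink" in formats:
        ped, mp = write_plink(cohort.genotypes, cohort.variants, outdir / "cohort")
        paths["ped"], paths["map"] = ped, mp
    if "vcf" in formats:
        paths["vcf"] = write_vcf(cohort.genotypes, cohort.variants, outdir / "cohort.vcf")
    cohort.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    paths["variants"] = outdir / "variants.tsv"
    cohort.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    if cohort.catalog is not None:
        cohort.catalog.to_frame().to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        paths["catalog"] = outdir / "catalog.tsv"
        pd.DataFrame(
            sorted(cohort.catalog.designation.items()), columns=["gene", "designation"]
        ).to_csv(outdir / "designations.tsv", sep="\t", index=False)
        paths["designations"] = outdir / "designations.tsv"
    return paths


def read_cohort(outdir: str | Path, prefer: str = "plink") -> Cohort:
    """Read a cohort directory back; dosages reordered to variants.tsv order."""
    outdir = Path(outdir)
    variants = pd.read_csv(outdir / "variants.tsv", sep="\t", dtype={"chrom": str})
    if prefer == "vcf" and (outdir / "cohort.vcf").exists():
        geno, _ = read_vcf(outdir / "cohort.vcf")
    elif (outdir / "cohort.ped").exists():
        geno = read_plink(outdir / "cohort", variants)
    elif (outdir / "cohort.vcf").exists():
        geno, _ = read_vcf(outdir / "cohort.vcf")
    else:
        raise FileNotFoundError(f"no genotype file found under {outdir}")
    geno = geno.subset(snp_ids=variants["snp_id"].tolist())
    phenos = pd.read_csv(outdir / "phenotypes.tsv", sep="\t")
    catalog = None
    if (outdir / "catalog.tsv").exists():
        frame = pd.read_csv(outdir / "catalog.tsv", sep="\t")
        designation = {}
        if (outdir / "designations.tsv").exists():
            des = pd.read_csv(outdir / "designations.tsv", sep="\t")
            designation = dict(zip(des["gene"], des["designation"]))
        catalog = GeneCatalog.from_frame(frame, designation=designation)
    # design parameters are not serialized; a loaded cohort carries design=None
    return Cohort(design=None, genotypes=geno, variants=variants, phenotypes=phenos, catalog=catalog)
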