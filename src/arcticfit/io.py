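"""Readers and writers for PED/MAP, VCF 4.2 and the CSV tables.

PED/MAP use the white-space dialect with alleles as A/C/G/T and ``0 0`` for
missing calls.  Internally positions are 0-based; they are written 1-based to
MAP and VCF.  The pedigree and life-history CSVs are RFC-4180 with the column
headers produced by :mod:`arcticfit.synthpop`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from arcticfit.panel import GenotypePanel


def write_ped_map(panel: GenotypePanel, prefix: str, phenotypes: pd.Series | None = None,
                  sex: pd.Series | None = None) -> tuple[str, str]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns the two paths."""
    mmap = panel.marker_map
    map_path, ped_path = f"{prefix}.map", f"{prefix}.ped"
    with open(map_path, "w") as fh:
        for _, row in mmap.iterrows():
            fh.write(f"{row['scaffold']}\t{row['snp_id']}\t0\t{row['pos'] + 1}\n")

    a1 = mmap["a1"].to_numpy()
    a2 = mmap["a2"].to_numpy()
    sex_code = {"M": "1", "F": "2"}
    pheno_code = {"white": "1", "blue": "2"}
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(panel.ids):
            s = sex_code.get(sex.loc[ind], "0") if sex is not None else "0"
            ph = pheno_code.get(phenotypes.loc[ind], "-9") if phenotypes is not None else "-9"
            fields = ["FAM", str(ind), "0", "0", s, ph]
            dos = panel.dosage[i]
            for j in range(panel.n_snps):
                d = dos[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_ped_map(prefix: str, causal_snp_id: str | None = None) -> tuple[GenotypePanel, pd.DataFrame]:
    """Read ``<prefix>.ped``/``<prefix>.map``.

    Returns the panel plus a sample table (id, sex, phenotype).  Alternate
    alleles are taken from the MAP when it carries allele columns; otherwise
    the minor allele observed in the PED is counted as alternate, except that
    a SNP named by ``causal_snp_id`` counts its T allele.
    """
    mmap = pd.read_csv(
        f"{prefix}.map", sep=r"\s+", header=None,
        names=["scaffold", "snp_id", "cm", "pos"],
    )
    mmap["pos"] = mmap["pos"].astype(int) - 1
    m = len(mmap)

    ids, sexes, phenos, rows = [], [], [], []
    allele_sets: list[dict] = [dict() for _ in range(m)]
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError("PED row length does not match MAP")
            ids.append(parts[1])
            sexes.append({"1": "M", "2": "F"}.get(parts[4], "U"))
            phenos.append({"1": "white", "2": "blue"}.get(parts[5], None))
            alleles = parts[6:]
            rows.append(alleles)
            for j in range(m):
                for a in (alleles[2 * j], alleles[2 * j + 1]):
                    if a != "0":
                        allele_sets[j][a] = allele_sets[j].get(a, 0) + 1

    a1s, a2s = [], []
    for j, counts in enumerate(allele_sets):
        obs = sorted(counts, key=lambda a: (counts[a], a))
        if causal_snp_id is not None and mmap.loc[j, "snp_id"] == causal_snp_id and "T" in counts:
            alt = "T"
        elif obs:
            alt = obs[0]  # minor allele
        else:
            alt = "N"
        ref = next((a for a in sorted(counts) if a != alt), "N")
        a1s.append(ref)
        a2s.append(alt)
    mmap["a1"], mmap["a2"] = a1s, a2s

    dosage = np.full((len(ids), m), np.nan)
    for i, alleles in enumerate(rows):
        arr = np.asarray(alleles).reshape(m, 2)
        missing = (arr == "0").any(axis=1)
        dosage[i] = (arr == np.asarray(a2s)[:, None]).sum(axis=1).astype(float)
        dosage[i, missing] = np.nan

    causal_index = None
    if causal_snp_id is not None:
        hits = np.flatnonzero(mmap["snp_id"].to_numpy() == causal_snp_id)
        causal_index = int(hits[0]) if hits.size else None

    try:
        id_arr = np.asarray([int(v) for v in ids])
    except ValueError:
        id_arr = np.asarray(ids)
    panel = GenotypePanel(
        dosage=dosage,
        marker_map=mmap[["scaffold", "pos", "a1", "a2", "snp_id"]],
        ids=id_arr,
        causal_index=causal_index,
    )
    samples = pd.DataFrame({"id": id_arr, "sex": sexes, "colour": phenos})
    return panel, samples


def write_vcf(panel: GenotypePanel, path: str) -> str:
    """Minimal VCF 4.2 with GT fields (unphased)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for sc in panel.marker_map["scaffold"].unique():
            fh.write(f"##contig=<ID={sc}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in panel.ids) + "\n"
        )
        for j, row in panel.marker_map.iterrows():
            gts = [
                gt_map.get(panel.dosage[i, j], "./.") if not np.isnan(panel.dosage[i, j]) else "./."
                for i in range(panel.n_individuals)
            ]
            fh.write(
                f"{row['scaffold']}\t{row['pos'] + 1}\t{row['snp_id']}\t"
                f"{row['a1']}\t{row['a2']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


def read_vcf(path: str, causal_snp_id: str | None = None) -> GenotypePanel:
    """Read a VCF 4.2 with GT fields into a panel (cyvcf2 when available)."""
    try:
        from cyvcf2 import VCF  # optional dependency
    except ImportError:
        VCF = None
    rows, dosages, ids = [], [], None
    if VCF is not None:
        vcf = VCF(path)
        ids = vcf.samples
        for var in vcf:
            rows.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0], var.ID))
            gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            dos = np.where(gt == 3, 2.0, gt)
            dos[gt == 2] = np.nan
            dosages.append(dos)
    else:
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    ids = parts[9:]
                    continue
                rows.append((parts[0], int(parts[1]) - 1, parts[3], parts[4], parts[2]))
                dos = []
                for gt in parts[9:]:
                    alleles = gt.split(":")[0].replace("|", "/").split("/")
                    dos.append(np.nan if "." in alleles else float(sum(int(a) for a in alleles)))
                dosages.append(np.asarray(dos))
    mmap = pd.DataFrame(rows, columns=["scaffold", "pos", "a1", "a2", "snp_id"])
    causal_index = None
    if causal_snp_id is not None:
        hits = np.flatnonzero(mmap["snp_id"].to_numpy() == causal_snp_id)
        causal_index = int(hits[0]) if hits.size else None
    try:
        id_arr = np.asarray([int(v) for v in ids])
    except (TypeError, ValueError):
        id_arr = np.asarray(ids)
    return GenotypePanel(
        dosage=np.asarray(dosages).T,
        marker_map=mmap[["scaffold", "pos", "a1", "a2", "snp_id"]],
        ids=id_arr,
        causal_index=causal_index,
    )


def write_grm(grm, prefix: str) -> tuple[str, str]:
    """GRM as a square CSV plus an id index file."""
    mat_path, id_path = f"{prefix}.grm.csv", f"{prefix}.grm.ids.csv"
    pd.DataFrame(grm.matrix).to_csv(mat_path, index=False, header=False)
    pd.DataFrame({"id": grm.ids}).to_csv(id_path, index=False)
    return mat_path, id_path
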