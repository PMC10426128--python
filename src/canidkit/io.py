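"""Readers and writers for the standard formats the pipeline touches.

VCF reading goes through cyvcf2; writing emits plain VCF 4.2 text with
GT:DP:GQ:AD FORMAT fields.  Gene models round-trip as GFF3, tracks as BED
(0-based half-open), mitochondrial references as FASTA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from canidkit.cohort import (
    MISSING,
    CohortGenotypes,
    GeneModel,
    SampleRecord,
    SiteRecord,
)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=canidkit
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_vcf(cohort: CohortGenotypes, path: str | Path) -> None:
    """Write a cohort as uncompressed VCF 4.2 with GT[:DP:GQ:AD]."""
    has_q = cohort.DP is not None and cohort.GQ is not None and cohort.AD is not None
    fmt = "GT:DP:GQ:AD" if has_q else "GT"
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        for j, site in enumerate(cohort.sites):
            fields = [
                site.chrom,
                str(site.pos),
                ".",
                site.ref_allele,
                site.alt_allele,
                ".",
                "PASS",
                f"RC={site.region_class}",
                fmt,
            ]
            for i in range(cohort.n_samples):
                d = int(cohort.dosage[i, j])
                pl = int(cohort.ploidy[i, j])
                if d == MISSING:
                    gt = "." if pl == 1 else "./."
                elif pl == 1:
                    gt = str(d)
                else:
                    gt = "0/1" if d == 1 else f"{d // 2}/{d // 2}"
                if has_q:
                    ad = cohort.AD[i, j]
                    gt += f":{cohort.DP[i, j]}:{cohort.GQ[i, j]}:{ad[0]},{ad[1]}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path, metadata: dict[str, SampleRecord] | None = None) -> CohortGenotypes:
    """Read a biallelic SNV/indel VCF into a cohort via cyvcf2.

    Sample metadata defaults to category 'mixed' when not supplied.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    samples = [
        (metadata or {}).get(sid, SampleRecord(sid, "mixed")) for sid in sample_ids
    ]
    sites, dosages, ploidies = [], [], []
    dps, gqs, ads = [], [], []
    has_q = True
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        rc = "autosome"
        if isinstance(var.INFO.get("RC"), str):
            rc = var.INFO.get("RC")
        sites.append(SiteRecord(var.CHROM, var.POS, var.REF, var.ALT[0], rc))
        gts = var.genotypes  # [[a0, a1, phased], ...] or [[a0, phased]]
        dos, plo = [], []
        for g in gts:
            plo.append(max(1, len(g) - 1))
            if any(a < 0 for a in g[:-1]):
                dos.append(MISSING)
            else:
                dos.append(sum(g[:-1]))
        dosages.append(dos)
        ploidies.append(plo)
        try:
            dps.append(var.format("DP")[:, 0])
            gqs.append(var.format("GQ")[:, 0])
            ads.append(var.format("AD"))
        except (TypeError, KeyError):
            has_q = False
    dosage = np.array(dosages, dtype=np.int8).T
    ploidy = np.array(ploidies, dtype=np.int8).T
    DP = GQ = AD = None
    if has_q and dps:
        DP = np.array(dps).T
        GQ = np.array(gqs).T
        AD = np.transpose(np.array(ads), (1, 0, 2))
    return CohortGenotypes(samples, sites, dosage, ploidy, DP, GQ, AD)


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\t.\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id};Parent={g.gene_id}\n"
            )
            for k, (es, ee) in enumerate(sorted(g.exons)):
                fh.write(
                    f"{g.chrom}\t.\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.transcript_id}.e{k};Parent={g.transcript_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Minimal GFF3 gene/mRNA/exon reader (1-based closed -> 0-based half-open)."""
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "mRNA":
                tx_meta[a["ID"]] = (a.get("Parent", a["ID"]), chrom, strand)
                tx_exons.setdefault(a["ID"], [])
            elif ftype == "exon":
                tx_exons.setdefault(a["Parent"], []).append((int(start) - 1, int(end)))
    out = []
    for tx, exons in tx_exons.items():
        gene, chrom, strand = tx_meta.get(tx, (tx, "?", "+"))
        out.append(GeneModel(gene, tx, chrom, strand, sorted(exons)))
    return out


# ---------------------------------------------------------------------------
# BED tracks and FASTA


def write_bed_track(values_by_chrom: dict[str, np.ndarray], path: str | Path) -> None:
    """Per-base values as merged constant-value BED intervals."""
    with open(path, "w") as fh:
        for chrom in sorted(values_by_chrom):
            v = np.asarray(values_by_chrom[chrom])
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            bounds = np.concatenate([[0], change, [len(v)]])
            for i in range(len(bounds) - 1):
                s, e = int(bounds[i]), int(bounds[i + 1])
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]}\n")


def read_bed_track(path: str | Path, dtype=float) -> dict[str, np.ndarray]:
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split()[:4]
            spans.setdefault(chrom, []).append((int(s), int(e), dtype(v)))
    out = {}
    for chrom, ivs in spans.items():
        arr = np.zeros(max(e for _, e, _ in ivs), dtype=dtype)
        for s, e, v in ivs:
            arr[s:e] = v
        out[chrom] = arr
    return out


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            elif name is not None:
                out[name].append(line)
    return {k: "".join(v) for k, v in out.items()}
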