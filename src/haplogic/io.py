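"""Readers/writers for phased haplotype cohorts and annotation tables.

Supported formats:

* SHAPEIT HAPS/SAMPLE — space-delimited ``chrom id pos a0 a1`` followed by
  2N allele columns (``0``/``1``, ``?`` for missing); the SAMPLE file has the
  conventional two header lines and may carry a binary phenotype column and a
  ``cohort`` label column.
* Phased VCF 4.x — ``GT`` fields must use the ``|`` separator; ``.``
  components become missing.
* Gene tables and annotation tracks as BED-like TSV (0-based half-open on
  disk, converted to 1-based inclusive in memory).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .cohort import MISSING, PhasedCohort, Variant
from .windows import GeneRecord

_ALLELE = {"0": 0, "1": 1, "?": MISSING, ".": MISSING}


def read_haps_sample(haps_path: str, sample_path: str,
                     phenotype_path: str | None = None) -> PhasedCohort:
    """Read a SHAPEIT-style HAPS + SAMPLE file pair.

    Column pair ``(2j, 2j+1)`` of the HAPS allele block maps to subject
    ``j`` of the SAMPLE file.  Phenotypes come from a ``pheno`` column in
    the SAMPLE file (0/1) or from a separate two-column TSV
    (subject id, status) via ``phenotype_path``.
    """
    variants: list[Variant] = []
    rows: list[list[int]] = []
    with open(haps_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 7:
                raise ValueError(f"{haps_path}:{ln}: too few columns")
            chrom, vid, pos, a0, a1 = parts[:5]
            variants.append(Variant(vid, chrom, int(pos), a0, a1))
            try:
                rows.append([_ALLELE[t] for t in parts[5:]])
            except KeyError as exc:
                raise ValueError(
                    f"{haps_path}:{ln}: non-biallelic encoding {exc}") from exc
    alleles = np.asarray(rows, dtype=np.int8).T  # chromosomes x variants
    n_chrom = alleles.shape[0]
    if n_chrom % 2:
        raise ValueError("odd number of haplotype columns")

    sample = _read_sample_table(sample_path)
    if 2 * len(sample) != n_chrom:
        raise ValueError(
            f"sample file has {len(sample)} subjects but haps file has "
            f"{n_chrom} haplotype columns")
    if phenotype_path is not None:
        phen = pd.read_csv(phenotype_path, sep="\t", header=None,
                           names=["subject_id", "phenotype"], dtype=str)
        phen["phenotype"] = phen["phenotype"].astype(int)
        sample = sample.drop(columns=["phenotype"], errors="ignore").merge(
            phen, on="subject_id", how="left")
        if sample["phenotype"].isna().any():
            missing = sample.loc[sample["phenotype"].isna(), "subject_id"]
            raise ValueError(f"no phenotype for subjects: {list(missing)[:5]}")
        sample["phenotype"] = sample["phenotype"].astype(int)
    if "phenotype" not in sample.columns:
        raise ValueError("no phenotype column in sample file and no "
                         "phenotype table given")
    return PhasedCohort(variants, alleles, sample)


def _read_sample_table(path: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().split()
        fh.readline()  # type line ("0 0 0 ...")
        body = pd.read_csv(fh, sep=r"\s+", header=None, names=header,
                           dtype=str)
    out = pd.DataFrame({"subject_id": body["ID_2"] if "ID_2" in body
                        else body[header[0]]})
    for src, dst in (("pheno", "phenotype"), ("phenotype", "phenotype"),
                     ("cohort", "cohort")):
        if src in body.columns:
            out[dst] = body[src]
    if "phenotype" in out.columns:
        out["phenotype"] = out["phenotype"].astype(int)
    return out


def write_haps_sample(cohort: PhasedCohort, haps_path: str,
                      sample_path: str) -> None:
    """Write a cohort back to HAPS/SAMPLE (round-trips with the reader)."""
    inv = {0: "0", 1: "1", MISSING: "?"}
    with open(haps_path, "w") as fh:
        for j, v in enumerate(cohort.variants):
            col = " ".join(inv[int(a)] for a in cohort.haps[:, j])
            fh.write(f"{v.chrom} {v.id} {v.pos} {v.ref} {v.alt} {col}\n")
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing pheno cohort\n0 0 0 B D\n")
        for _, row in cohort.subjects.iterrows():
            fh.write(f"{row.subject_id} {row.subject_id} 0 "
                     f"{int(row.phenotype)} {row.cohort}\n")


def read_phased_vcf(path: str, subjects: pd.DataFrame | None = None,
                    phenotype_path: str | None = None) -> PhasedCohort:
    """Read a phased VCF (GT like ``0|1``); unphased ``/`` separators raise.

    Phenotypes are supplied via ``subjects`` (a ready subject table) or a
    two-column TSV (subject id, status).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    variants: list[Variant] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"{rec.ID or rec.POS}: only biallelic records "
                             "are supported")
        variants.append(Variant(rec.ID or f"{rec.CHROM}:{rec.POS}",
                                str(rec.CHROM), int(rec.POS),
                                rec.REF, rec.ALT[0]))
        gts = rec.genotypes  # [a0, a1, phased] per sample
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, (a0, a1, phased) in enumerate(gts):
            if not phased and not (a0 < 0 and a1 < 0):
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{rec.CHROM}:{rec.POS} (phased input required)")
            col[2 * i] = a0 if a0 >= 0 else MISSING
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING
        cols.append(col)
    haps = (np.stack(cols, axis=1) if cols
            else np.empty((2 * len(samples), 0), dtype=np.int8))
    if subjects is None:
        subjects = pd.DataFrame({"subject_id": samples})
        if phenotype_path is None:
            raise ValueError("phenotypes required: pass subjects= or "
                             "phenotype_path=")
        phen = pd.read_csv(phenotype_path, sep="\t", header=None,
                           names=["subject_id", "phenotype"], dtype=str)
        phen["phenotype"] = phen["phenotype"].astype(int)
        subjects = subjects.merge(phen, on="subject_id", how="left")
        if subjects["phenotype"].isna().any():
            raise ValueError("phenotype table does not cover all VCF samples")
        subjects["phenotype"] = subjects["phenotype"].astype(int)
    return PhasedCohort(variants, haps, subjects)


def write_phased_vcf(cohort: PhasedCohort, path: str) -> None:
    """Write a minimal phased VCF 4.2 (round-trips with the reader)."""
    code = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in cohort.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Phased genotype">\n')
        ids = "\t".join(cohort.subjects["subject_id"])
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{ids}\n")
        for j, v in enumerate(cohort.variants):
            col = cohort.haps[:, j]
            gts = "\t".join(f"{code[int(col[2 * i])]}|"
                            f"{code[int(col[2 * i + 1])]}"
                            for i in range(cohort.n_subjects))
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t"
                     f"PASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# BED-like tables
# ---------------------------------------------------------------------------

def read_gene_bed(path: str) -> list[GeneRecord]:
    """Gene table as BED-like TSV: chrom, start, end, gene_id, strand.

    On-disk coordinates are 0-based half-open; in-memory spans are 1-based
    inclusive.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_id", "strand"],
                     dtype={"chrom": str})
    return [GeneRecord(gene_id=str(r.gene_id), chrom=str(r.chrom),
                       tx_start=int(r.start) + 1, tx_end=int(r.end),
                       strand=str(r.strand))
            for r in df.itertuples()]


def write_gene_bed(genes: list[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tx_start - 1}\t{g.tx_end}\t"
                     f"{g.gene_id}\t{g.strand}\n")


def read_bed_track(path: str, track_id: str | None = None):
    """Read an interval track from BED (0-based half-open, kept as such)."""
    from .enrich import AnnotationTrack

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    intervals = [(str(c), int(s), int(e))
                 for c, s, e in df.itertuples(index=False)]
    return AnnotationTrack(track_id or os.path.basename(path), intervals)
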