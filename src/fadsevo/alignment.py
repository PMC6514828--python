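"""Phased haplotype alignments over a genomic region, with VCF/FASTA/TSV I/O.

The in-memory container is a dense haplotype-by-site base matrix covering
every position of the region (variant and invariant), together with the
reconstructed human--chimp ancestor sequence, a per-site ancestor-quality
mask, and per-haplotype metadata (sample of origin, population, local
ancestry, haplogroup cluster).

On disk an alignment is three text files: a phased VCF v4.2 holding the
sites at which any haplotype differs from the ancestor, a FASTA with the
full-length ancestor sequence, and TSV sidecars for haplotype metadata and
the site-quality mask.  Only phased ("|") genotypes are accepted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HaplotypeAlignment",
    "write_alignment_vcf",
    "read_alignment_vcf",
    "UnphasedGenotypeError",
]

BASES = np.array(["A", "C", "G", "T"])


class UnphasedGenotypeError(ValueError):
    """Raised when a VCF genotype uses the unphased '/' separator."""


@dataclass
class HaplotypeAlignment:
    """Haplotypes x sites base matrix plus ancestor, mask and labels.

    Attributes
    ----------
    haplotypes : (n_haplotypes, n_sites) array of single characters.
    positions : 1-based positions, strictly increasing.
    chrom : chromosome name shared by all sites.
    ancestor : reconstructed ancestor base per site.
    high_quality : per-site boolean; True where the ancestor reconstruction
        is trusted and the site may enter divergence counts.
    metadata : one row per haplotype, indexed like ``haplotypes`` rows, with
        columns ``haplotype_id, sample, hap_index, population, ancestry,
        cluster``.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    chrom: str
    ancestor: np.ndarray
    high_quality: np.ndarray
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype="<U1")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ancestor = np.asarray(self.ancestor, dtype="<U1")
        self.high_quality = np.asarray(self.high_quality, dtype=bool)
        n_hap, n_sites = self.haplotypes.shape
        if not (len(self.positions) == len(self.ancestor) == len(self.high_quality) == n_sites):
            raise ValueError("positions, ancestor and mask must match the site dimension")
        if len(self.metadata) != n_hap:
            raise ValueError("metadata must have one row per haplotype")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def variant_mask(self) -> np.ndarray:
        """Sites where any haplotype differs from the ancestor base."""
        return (self.haplotypes != self.ancestor[None, :]).any(axis=0)

    def polymorphic_mask(self) -> np.ndarray:
        """Sites segregating among the haplotypes themselves."""
        return (self.haplotypes != self.haplotypes[0][None, :]).any(axis=0)

    def site_index(self, pos: int) -> int:
        idx = np.searchsorted(self.positions, pos)
        if idx >= self.n_sites or self.positions[idx] != pos:
            raise KeyError(f"position {self.chrom}:{pos} not in alignment")
        return int(idx)

    def restrict(self, mask: np.ndarray) -> "HaplotypeAlignment":
        """New alignment keeping only the sites selected by ``mask``."""
        mask = np.asarray(mask)
        return HaplotypeAlignment(
            self.haplotypes[:, mask],
            self.positions[mask],
            self.chrom,
            self.ancestor[mask],
            self.high_quality[mask],
            self.metadata.copy(),
        )

    def take_haplotypes(self, rows) -> "HaplotypeAlignment":
        rows = np.asarray(rows)
        return HaplotypeAlignment(
            self.haplotypes[rows],
            self.positions,
            self.chrom,
            self.ancestor,
            self.high_quality,
            self.metadata.iloc[rows].reset_index(drop=True),
        )

    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.haplotypes]


def _vcf_records(aln: HaplotypeAlignment):
    """Yield (pos, ref, alts, per-haplotype allele index) for variant sites."""
    var_idx = np.flatnonzero(aln.variant_mask())
    for j in var_idx:
        ref = aln.ancestor[j]
        col = aln.haplotypes[:, j]
        alts = sorted(set(col) - {ref})
        allele_index = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
        codes = np.array([allele_index[b] for b in col])
        yield int(aln.positions[j]), ref, alts, codes


def write_alignment_vcf(aln: HaplotypeAlignment, out_prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>.vcf``, ``<prefix>.ancestor.fa``, ``<prefix>.samples.tsv``
    and ``<prefix>.mask.tsv``.

    Haplotypes are paired in row order into phased diploid pseudo-samples;
    an odd trailing haplotype becomes a haploid sample.  Raises ``ValueError``
    if the alignment has no variant site.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if not aln.variant_mask().any():
        raise ValueError("alignment has no variant sites; nothing to write as VCF")

    n = aln.n_haplotypes
    sample_names = [f"S{i:04d}" for i in range((n + 1) // 2)]

    vcf_path = out_prefix.with_suffix(".vcf")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={aln.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write(
            f"##region={aln.chrom}:{aln.positions[0]}-{aln.positions[-1]}\n"
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for pos, ref, alts, codes in _vcf_records(aln):
            gts = []
            for k in range(0, n - 1, 2):
                gts.append(f"{codes[k]}|{codes[k + 1]}")
            if n % 2:
                gts.append(str(codes[n - 1]))
            fh.write(
                f"{aln.chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )

    fa_path = Path(str(out_prefix) + ".ancestor.fa")
    record = SeqRecord(
        Seq("".join(aln.ancestor)),
        id=f"{aln.chrom}:{aln.positions[0]}-{aln.positions[-1]}",
        description="reconstructed ancestor",
    )
    SeqIO.write([record], fa_path, "fasta")

    meta_path = Path(str(out_prefix) + ".samples.tsv")
    meta = aln.metadata.copy()
    meta["vcf_sample"] = [sample_names[i // 2] for i in range(n)]
    meta["vcf_hap"] = [i % 2 for i in range(n)]
    meta.to_csv(meta_path, sep="\t", index=False)

    mask_path = Path(str(out_prefix) + ".mask.tsv")
    pd.DataFrame(
        {
            "CHROM": aln.chrom,
            "POS": aln.positions,
            "HIGH_QUALITY": aln.high_quality.astype(int),
        }
    ).to_csv(mask_path, sep="\t", index=False)

    return {"vcf": vcf_path, "ancestor": fa_path, "samples": meta_path, "mask": mask_path}


def read_alignment_vcf(
    vcf_path: str | Path,
    ancestor_fasta: str | Path,
    samples_tsv: str | Path | None = None,
    mask_tsv: str | Path | None = None,
) -> HaplotypeAlignment:
    """Reconstruct a full-length alignment from the on-disk representation.

    The ancestor FASTA record id must be ``chrom:start-end``; every position
    of that interval becomes a site, with haplotypes equal to the ancestor
    except where the VCF says otherwise.  Any unphased ("/") genotype raises
    :class:`UnphasedGenotypeError` naming the sample and site.
    """
    record = next(SeqIO.parse(str(ancestor_fasta), "fasta"))
    chrom, span = record.id.rsplit(":", 1)
    start, end = (int(x) for x in span.split("-"))
    ancestor = np.array(list(str(record.seq).upper()), dtype="<U1")
    if len(ancestor) != end - start + 1:
        raise ValueError("ancestor FASTA length disagrees with its id interval")
    positions = np.arange(start, end + 1, dtype=np.int64)

    if samples_tsv is None:
        samples_tsv = Path(str(vcf_path).removesuffix(".vcf") + ".samples.tsv")
    if mask_tsv is None:
        mask_tsv = Path(str(vcf_path).removesuffix(".vcf") + ".mask.tsv")

    meta = pd.read_csv(samples_tsv, sep="\t", dtype={"vcf_sample": str})
    n_hap = len(meta)

    haplotypes = np.tile(ancestor, (n_hap, 1))
    with pysam.VariantFile(str(vcf_path)) as vf:
        vcf_samples = list(vf.header.samples)
        # map haplotype row -> (sample name, haplotype slot within the sample)
        row_of = {
            (row.vcf_sample, int(row.vcf_hap)): i for i, row in meta.iterrows()
        }
        for rec in vf:
            if rec.pos < start or rec.pos > end:
                raise ValueError(f"VCF position {rec.pos} outside ancestor interval")
            j = rec.pos - start
            alleles = rec.alleles
            for sname in vcf_samples:
                call = rec.samples[sname]
                codes = call["GT"]
                if len(codes) > 1 and not call.phased:
                    raise UnphasedGenotypeError(
                        f"unphased genotype for sample {sname} at "
                        f"{rec.chrom}:{rec.pos}; phased input required"
                    )
                for slot, code in enumerate(codes):
                    key = (sname, slot)
                    if key not in row_of:
                        continue
                    if code is None:
                        haplotypes[row_of[key], j] = "N"
                    else:
                        haplotypes[row_of[key], j] = alleles[code]

    mask_df = pd.read_csv(mask_tsv, sep="\t")
    if len(mask_df) != len(positions):
        raise ValueError("mask TSV does not cover every site of the ancestor interval")
    high_quality = mask_df["HIGH_QUALITY"].to_numpy(dtype=bool)

    meta = meta.drop(columns=["vcf_sample", "vcf_hap"], errors="ignore")
    return HaplotypeAlignment(haplotypes, positions, chrom, ancestor, high_quality, meta)
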