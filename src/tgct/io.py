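"""Cohort serialization.

One VCF 4.2 per sample (somatic calls with annotation INFO fields), plus
cohort-level TSVs: sample sheet, per-exon coverage (BED-convention
coordinates), germline het sites, gene-model BED and the hidden truth
ledger.  A ``manifest.json`` records every file and the genome model so the
bundle round-trips exactly.

Float INFO fields pass through htslib's 32-bit representation; values are
written at a fixed precision (VAF 4 d.p., qualities 1 d.p., alignability
2 d.p., MAF 3 d.p.) and re-rounded on read, so write -> read -> write is
the identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam

from .genome import Chromosome, Genome
from .models import GeneModel, SampleRecord, VariantCall
from .synthetic import CohortBundle

__all__ = ["write_cohort", "read_cohort", "write_segments", "read_segments"]

_INFO_FIELDS = [
    ("GENE", "1", "String", "Gene symbol"),
    ("CSQ", "1", "String", "Consequence class"),
    ("VTYPE", "1", "String", "Variant type (SNV or indel)"),
    ("VAF", "1", "Float", "Variant allele fraction"),
    ("SAF", "1", "Integer", "Alt-supporting reads, forward strand"),
    ("SAR", "1", "Integer", "Alt-supporting reads, reverse strand"),
    ("MBQ", "1", "Float", "Mean Phred base quality of alt reads"),
    ("MMQ", "1", "Float", "Mean mapping quality"),
    ("ALN", "1", "Float", "Alignability site score"),
    ("PMAF", "1", "Float", "Population minor allele frequency"),
    ("TRUTH", "1", "String", "Hidden simulation truth label"),
]

COVERAGE_COLUMNS = ["sample_id", "chrom", "start", "end", "tumour_depth",
                    "normal_depth"]
HET_COLUMNS = ["sample_id", "chrom", "pos", "normal_ref_depth",
               "normal_alt_depth", "tumour_ref_depth", "tumour_alt_depth"]


def _vcf_header(genome: Genome) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in genome.chromosomes:
        header.contigs.add(c.name, length=c.length)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    return header


def _write_sample_vcf(path: Path, sample_id: str, variants: list[VariantCall],
                      genome: Genome) -> None:
    header = _vcf_header(genome)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda v: (genome.names.index(v.chrom),
                                                 v.pos, v.ref, v.alt)):
            rec = vf.new_record(contig=v.chrom, start=v.pos - 1,
                                alleles=(v.ref, v.alt))
            info = rec.info
            if v.gene is not None:
                info["GENE"] = v.gene
            info["CSQ"] = v.consequence
            info["VTYPE"] = v.variant_type
            info["VAF"] = v.vaf
            if v.alt_reads_fwd is not None:
                info["SAF"] = v.alt_reads_fwd
            if v.alt_reads_rev is not None:
                info["SAR"] = v.alt_reads_rev
            if v.mean_base_quality is not None:
                info["MBQ"] = v.mean_base_quality
            if v.mean_mapq is not None:
                info["MMQ"] = v.mean_mapq
            if v.alignability is not None:
                info["ALN"] = v.alignability
            if v.population_maf is not None:
                info["PMAF"] = v.population_maf
            if v.truth is not None:
                info["TRUTH"] = v.truth
            vf.write(rec)


def _read_sample_vcf(path: Path, sample_id: str) -> list[VariantCall]:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info

            def fget(key, nd):
                val = info.get(key)
                return None if val is None else round(float(val), nd)

            saf = info.get("SAF")
            sar = info.get("SAR")
            out.append(
                VariantCall(
                    sample_id=sample_id,
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    variant_type=info.get("VTYPE", "SNV"),
                    gene=info.get("GENE"),
                    consequence=info.get("CSQ", "other"),
                    vaf=fget("VAF", 4) or 0.0,
                    alt_reads_fwd=None if saf is None else int(saf),
                    alt_reads_rev=None if sar is None else int(sar),
                    mean_base_quality=fget("MBQ", 1),
                    mean_mapq=fget("MMQ", 1),
                    alignability=fget("ALN", 2),
                    population_maf=fget("PMAF", 3),
                    truth=info.get("TRUTH"),
                )
            )
    return out


def write_cohort(bundle: CohortBundle, directory) -> dict:
    """Write the bundle to ``directory`` and return the file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vcf_dir = directory / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    by_sample: dict[str, list[VariantCall]] = {s.sample_id: []
                                               for s in bundle.samples}
    for v in bundle.variants:
        by_sample[v.sample_id].append(v)
    vcfs = {}
    for sid, variants in by_sample.items():
        path = vcf_dir / f"{sid}.vcf"
        _write_sample_vcf(path, sid, variants, bundle.genome)
        vcfs[sid] = str(path.relative_to(directory))

    samples_df = pd.DataFrame(
        [{"sample_id": s.sample_id, "histology": s.histology,
          "age_years": s.age_years, "treatment_response": s.treatment_response}
         for s in bundle.samples]
    )
    samples_df.to_csv(directory / "samples.tsv", sep="\t", index=False)

    cov_frames = []
    for sid in bundle.sample_ids:
        df = bundle.coverage[sid].copy()
        df.insert(0, "sample_id", sid)
        cov_frames.append(df[COVERAGE_COLUMNS])
    pd.concat(cov_frames, ignore_index=True).to_csv(
        directory / "coverage.tsv", sep="\t", index=False)

    bundle.het_sites[HET_COLUMNS].to_csv(directory / "het_sites.tsv",
                                         sep="\t", index=False)

    with open(directory / "genes.bed", "w") as fh:
        for g in bundle.gene_models:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\n")

    bundle.truth_events.to_csv(directory / "truth.tsv", sep="\t", index=False)
    bundle.genome.arm_table().to_csv(directory / "arms.tsv", sep="\t",
                                     index=False)

    manifest = {
        "vcfs": vcfs,
        "tables": {
            "samples": "samples.tsv",
            "coverage": "coverage.tsv",
            "het_sites": "het_sites.tsv",
            "genes": "genes.bed",
            "truth": "truth.tsv",
        },
        "genome": {
            "chromosomes": [
                {"name": c.name, "length": c.length,
                 "centromere": c.centromere, "acrocentric": c.acrocentric}
                for c in bundle.genome.chromosomes
            ],
            "bin_spacing": bundle.genome.bin_spacing,
            "bin_length": bundle.genome.bin_length,
            "arms": "arms.tsv",
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_cohort(directory) -> CohortBundle:
    """Read a bundle previously written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    g = manifest["genome"]
    genome = Genome(
        tuple(Chromosome(c["name"], c["length"], c["centromere"],
                         c["acrocentric"]) for c in g["chromosomes"]),
        bin_spacing=g["bin_spacing"],
        bin_length=g["bin_length"],
    )
    samples_df = pd.read_csv(directory / "samples.tsv", sep="\t")
    samples = [SampleRecord(str(r.sample_id), r.histology, float(r.age_years),
                            r.treatment_response)
               for r in samples_df.itertuples()]
    variants: list[VariantCall] = []
    for sid in (s.sample_id for s in samples):
        variants.extend(_read_sample_vcf(directory / manifest["vcfs"][sid],
                                         sid))
    cov = pd.read_csv(directory / "coverage.tsv", sep="\t",
                      dtype={"sample_id": str, "chrom": str})
    coverage = {
        sid: sub.drop(columns="sample_id").reset_index(drop=True)
        for sid, sub in cov.groupby("sample_id", sort=False)
    }
    het = pd.read_csv(directory / "het_sites.tsv", sep="\t",
                      dtype={"sample_id": str, "chrom": str})
    genes = []
    with open(directory / "genes.bed") as fh:
        for line in fh:
            chrom, start, end, name = line.rstrip("\n").split("\t")
            genes.append(GeneModel(name, chrom, int(start), int(end)))
    truth = pd.read_csv(directory / "truth.tsv", sep="\t",
                        dtype={"sample_id": str, "chrom": str},
                        keep_default_na=False,
                        na_values={"ratio": [""]})
    truth["ratio"] = pd.to_numeric(truth["ratio"], errors="coerce")
    return CohortBundle(samples=samples, variants=variants, coverage=coverage,
                        het_sites=het, gene_models=genes, genome=genome,
                        truth_events=truth)


SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "n_bins",
                   "mean_ratio", "call", "specificity", "scale",
                   "low_specificity", "loh"]


def write_segments(segments, path) -> None:
    """Write CnvSegment records as a BED-like TSV."""
    rows = [{
        "sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
        "end": s.end, "n_bins": s.n_bins, "mean_ratio": round(s.mean_ratio, 6),
        "call": s.call,
        "specificity": "" if s.specificity is None else round(s.specificity, 6),
        "scale": s.scale or "", "low_specificity": int(s.low_specificity),
        "loh": "" if s.loh is None else int(s.loh),
    } for s in segments]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t",
                                                       index=False)


def read_segments(path) -> list:
    from .models import CnvSegment

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    out = []
    for r in df.itertuples():
        out.append(CnvSegment(
            sample_id=r.sample_id, chrom=r.chrom, start=int(r.start),
            end=int(r.end), n_bins=int(r.n_bins),
            mean_ratio=float(r.mean_ratio), call=r.call,
            specificity=None if pd.isna(r.specificity) else float(r.specificity),
            scale=None if pd.isna(r.scale) else str(r.scale),
            low_specificity=bool(r.low_specificity),
            loh=None if pd.isna(r.loh) else bool(r.loh),
        ))
    return out
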