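"""File formats.

External orientation follows array-platform conventions: the beta matrix is
probes x samples with a header row of sample ids; the sample sheet is CSV;
genotypes travel as VCF (GT field, 1-based positions; read back through
pysam) or as a dosage TSV (NA = missing); local-ancestry tracts as BED-like
TSV (0-based half-open bp, haplotype id, ancestry label); the truth record
as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import GeneticMap
from .ancestry import HaplotypeTracts, LocalAncestryMatrix
from .data import GenotypeMatrix, MethylationMatrix
from .simulate import SimulatedStudy, SimulationTruth

__all__ = [
    "write_beta_tsv",
    "read_beta_tsv",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_manifest",
    "read_manifest",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "write_tracts_bed",
    "read_tracts_bed",
    "write_truth_json",
    "write_study",
]


# ---------------------------------------------------------------------------
# methylation


def write_beta_tsv(meth: MethylationMatrix, path, detection_path=None):
    """Probes x samples TSV (transposed from the in-memory layout)."""
    meth.to_beta().values.T.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")
    if detection_path is not None and meth.detection_p is not None:
        meth.detection_p.T.to_csv(detection_path, sep="\t", index_label="probe_id", float_format="%.4g")


def read_beta_tsv(path, manifest: pd.DataFrame | None = None, detection_path=None) -> MethylationMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0).T
    det = None
    if detection_path is not None:
        det = pd.read_csv(detection_path, sep="\t", index_col=0).T
    return MethylationMatrix(values, scale="beta", manifest=manifest, detection_p=det)


def write_manifest(manifest: pd.DataFrame, path):
    manifest.to_csv(path, sep="\t", index_label="probe_id")


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(samples: pd.DataFrame, path):
    samples.to_csv(path, index_label="sample_id")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


# ---------------------------------------------------------------------------
# genotypes


def write_dosage_tsv(geno: GenotypeMatrix, path):
    out = geno.dosages.T
    out.insert(0, "pos", geno.positions_bp.astype(int))
    out.to_csv(path, sep="\t", index_label="snp_id", na_rep="NA", float_format="%g")


def read_dosage_tsv(path, genetic_map: GeneticMap | None = None) -> GenotypeMatrix:
    raw = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    pos = raw.pop("pos").astype(int).rename_axis(None)
    gmap = genetic_map or GeneticMap()
    dos = raw.T.astype(float).rename_axis(None, axis=0).rename_axis(None, axis=1)
    return GenotypeMatrix(dos, pos, pd.Series(gmap.bp_to_morgans(pos), index=pos.index))


def write_vcf(geno: GenotypeMatrix, path, chrom: str | None = None):
    """Minimal diploid GT-only VCF.  Dosage d is written as an unphased
    genotype with d alternate alleles; missing as ./.

    Allele identity per haplotype is not retained (dosages are sufficient
    for every analysis here).
    """
    chrom = chrom or geno.chrom
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    samples = list(geno.samples)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        dos = geno.dosages.to_numpy(dtype=float)
        for j, snp in enumerate(geno.snps):
            calls = "\t".join(gt.get(d, "./.") if not np.isnan(d) else "./." for d in dos[:, j])
            fh.write(f"{chrom}\t{int(geno.positions_bp[snp])}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path, genetic_map: GeneticMap | None = None) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        ids, pos, rows, chrom = [], [], [], "chr1"
        for rec in vf:
            chrom = rec.chrom
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            pos.append(rec.pos)
            row = []
            for s in samples:
                alleles = rec.samples[s]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    row.append(np.nan)
                else:
                    row.append(float(sum(alleles)))
            rows.append(row)
    dos = pd.DataFrame(np.asarray(rows).T, index=samples, columns=ids)
    pos = pd.Series(pos, index=ids)
    gmap = genetic_map or GeneticMap()
    return GenotypeMatrix(dos, pos, pd.Series(gmap.bp_to_morgans(pos), index=ids), chrom)


# ---------------------------------------------------------------------------
# local-ancestry tracts


def write_tracts_bed(local: LocalAncestryMatrix, path, chrom: str = "chr1"):
    """chrom, start, end (0-based half-open bp), haplotype id, ancestry."""
    gmap = local.genetic_map
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\thaplotype\tancestry\n")
        for sid, (h1, h2) in zip(local.sample_ids, local.haplotypes):
            for hap_no, h in ((1, h1), (2, h2)):
                starts = np.round(gmap.morgans_to_bp(h.starts) - 1).astype(int)
                ends = np.round(gmap.morgans_to_bp(h.ends) - 1).astype(int)
                for s, e, st in zip(starts, ends, h.states):
                    fh.write(f"{chrom}\t{s}\t{e}\t{sid}_h{hap_no}\t{local.labels[st]}\n")


def read_tracts_bed(path, labels: tuple[str, ...], genetic_map: GeneticMap | None = None) -> LocalAncestryMatrix:
    gmap = genetic_map or GeneticMap()
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["chrom", "start", "end", "haplotype", "ancestry"]
    )
    code = {lab: i for i, lab in enumerate(labels)}
    haps: dict[str, dict[int, HaplotypeTracts]] = {}
    order: list[str] = []
    for hap_id, sub in df.groupby("haplotype", sort=False):
        sid, hap_no = hap_id.rsplit("_h", 1)
        if sid not in haps:
            haps[sid] = {}
            order.append(sid)
        sub = sub.sort_values("start")
        haps[sid][int(hap_no)] = HaplotypeTracts(
            gmap.bp_to_morgans(sub["start"].to_numpy() + 1),
            gmap.bp_to_morgans(sub["end"].to_numpy() + 1),
            sub["ancestry"].map(code).to_numpy(),
        )
    pairs = [(haps[sid][1], haps[sid][2]) for sid in order]
    return LocalAncestryMatrix(pairs, labels, order, gmap)


# ---------------------------------------------------------------------------
# truth + bundles


def write_truth_json(truth: SimulationTruth, path):
    payload = {
        "cpg_ids": truth.cpg_ids,
        "cpg_pos_bp": truth.cpg_pos_bp.tolist(),
        "intercept": truth.intercept.tolist(),
        "meqtl_snp": truth.meqtl_snp.tolist(),
        "meqtl_effect": truth.meqtl_effect.tolist(),
        "theta": truth.theta.tolist(),
        "env": truth.env.tolist(),
        "cell_delta": truth.cell_delta.tolist(),
        "noise_sd": truth.noise_sd.tolist(),
        "group_order": truth.group_order,
        "q": truth.q.round(6).to_dict(orient="index"),
        "cell_props": truth.cell_props.round(6).to_dict(orient="index"),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def write_study(study: SimulatedStudy, outdir):
    """Write every external artifact of one simulated study."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_beta_tsv(study.meth, outdir / "beta.tsv", outdir / "detection_p.tsv")
    write_manifest(study.meth.manifest, outdir / "manifest.tsv")
    write_sample_sheet(study.samples, outdir / "samples.csv")
    write_dosage_tsv(study.genotypes, outdir / "dosages.tsv")
    write_vcf(study.genotypes, outdir / "genotypes.vcf")
    write_tracts_bed(study.local, outdir / "tracts.bed")
    write_truth_json(study.truth, outdir / "truth.json")
    return outdir
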