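"""Format adapters: call tables (TSV/VCF), manifests, BED targets, gene
models (CDS FASTA + segment TSV), SNP lists, plate CSVs, and report output.

Coordinate conventions: variant positions are VCF-style 1-based; BED targets
are 0-based half-open.  Multi-allelic VCF records are split into biallelic
keys, each alt carrying its own alt depth.
"""

from __future__ import annotations

import hashlib
import json
import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .annotate import TranscriptModel
from .drug_response import PlateData
from .variants import CallRecord, VariantKey, normalize_variant

__all__ = [
    "read_calls_tsv",
    "write_calls_tsv",
    "records_from_frame",
    "read_vcf_calls",
    "write_vcf_calls",
    "read_manifest",
    "write_manifest",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_snp_list",
    "write_snp_list",
    "read_plates",
    "write_plates",
    "config_hash",
    "write_report",
]

PathLike = Union[str, Path]

CALL_COLUMNS = ["sample", "caller", "chrom", "pos", "ref", "alt", "depth", "alt_depth", "run"]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Combined call-table TSV dialect


def read_calls_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "run": str},
                     comment="#")
    missing = [c for c in CALL_COLUMNS if c not in df.columns and c != "run"]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "run" not in df.columns:
        df["run"] = ""
    return df[CALL_COLUMNS]


def write_calls_tsv(frame: pd.DataFrame, path: PathLike) -> None:
    frame[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def records_from_frame(frame: pd.DataFrame) -> list[CallRecord]:
    """Typed, normalized call records from a combined call table."""
    records = []
    for row in frame.itertuples(index=False):
        key = normalize_variant(
            VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        )
        records.append(
            CallRecord(
                sample=str(row.sample),
                caller=str(row.caller),
                key=key,
                depth=int(row.depth),
                alt_depth=int(row.alt_depth),
                run=str(getattr(row, "run", "")),
            )
        )
    return records


# ---------------------------------------------------------------------------
# VCF (one file per sample × caller)


def read_vcf_calls(path: PathLike, sample: str, caller: str, run: str = "") -> list[CallRecord]:
    """Read one caller's VCF for one sample.

    Depth is taken from FORMAT/DP (falling back to INFO/DP) and per-allele
    alt depth from FORMAT/AD; multi-allelic records are split per alt.
    """
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            vcf_sample = rec.samples[0] if rec.samples else None
            if vcf_sample is not None and "DP" in vcf_sample and vcf_sample["DP"] is not None:
                depth = int(vcf_sample["DP"])
            elif "DP" in rec.info:
                depth = int(rec.info["DP"])
            else:
                raise ParseError(f"{path}: record at {rec.chrom}:{rec.pos} lacks DP")
            ad = vcf_sample["AD"] if vcf_sample is not None and "AD" in vcf_sample else None
            for i, alt in enumerate(rec.alts):
                if ad is None or ad[i + 1] is None:
                    raise ParseError(f"{path}: record at {rec.chrom}:{rec.pos} lacks AD")
                key = normalize_variant(VariantKey(rec.chrom, rec.pos, rec.ref, alt))
                records.append(
                    CallRecord(sample=sample, caller=caller, key=key,
                               depth=depth, alt_depth=int(ad[i + 1]), run=run)
                )
    return records


def write_vcf_calls(
    records: Sequence[CallRecord],
    path: PathLike,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write one sample × caller call set as a minimal VCF v4.2."""
    samples = {r.sample for r in records}
    if len(samples) != 1:
        raise ValueError("write_vcf_calls expects records of exactly one sample")
    sample = samples.pop()
    header = pysam.VariantHeader()
    if contig_lengths is None:
        contig_lengths = {}
        for r in records:
            contig_lengths[r.key.chrom] = max(
                contig_lengths.get(r.key.chrom, 0), r.key.pos + len(r.key.ref) + 1000
            )
    for chrom, length in sorted(contig_lengths.items()):
        header.contigs.add(chrom, length=length)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in sorted(records, key=lambda x: (x.key.chrom, x.key.pos, x.key.alt)):
            rec = vcf.new_record(
                contig=r.key.chrom, start=r.key.pos - 1, alleles=(r.key.ref, r.key.alt)
            )
            rec.samples[sample]["DP"] = r.depth
            rec.samples[sample]["AD"] = (r.depth - r.alt_depth, r.alt_depth)
            vcf.write(rec)


# ---------------------------------------------------------------------------
# Manifest, BED, gene models, SNP list


def read_manifest(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in ("sample", "cohort", "run"):
        if col not in df.columns:
            raise ParseError(f"{path}: manifest lacks column {col!r}")
    return df


def write_manifest(manifest: pd.DataFrame, path: PathLike) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_bed(path: PathLike) -> dict[str, list[tuple[int, int]]]:
    """Targets as {chrom: [(start0, end0), ...]} (0-based half-open)."""
    targets: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer interval") from exc
            targets.setdefault(parts[0], []).append((start0, end0))
    return targets


def write_bed(targets: dict[str, list[tuple[int, int]]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(targets):
            for start0, end0 in sorted(targets[chrom]):
                fh.write(f"{chrom}\t{start0}\t{end0}\n")


def read_gene_models(fasta_path: PathLike, segments_path: PathLike) -> list[TranscriptModel]:
    """Gene models from a CDS FASTA (record id = gene symbol) plus a segment
    table with columns gene, chrom, strand, start, end (1-based inclusive)."""
    cds = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    seg = pd.read_csv(segments_path, sep="\t", dtype={"chrom": str})
    models = []
    for gene, grp in seg.groupby("gene", sort=True):
        if gene not in cds:
            raise ParseError(f"gene {gene!r} in segment table but not in FASTA")
        strands = set(grp["strand"])
        chroms = set(grp["chrom"])
        if len(strands) != 1 or len(chroms) != 1:
            raise ParseError(f"gene {gene!r}: inconsistent strand/chrom")
        segments = sorted((int(s), int(e)) for s, e in zip(grp["start"], grp["end"]))
        models.append(
            TranscriptModel(str(gene), chroms.pop(), strands.pop(), segments, cds[gene])
        )
    return models


def write_gene_models(
    models: Sequence[TranscriptModel], fasta_path: PathLike, segments_path: PathLike
) -> None:
    with open(fasta_path, "w") as fh:
        for m in models:
            fh.write(f">{m.gene}\n")
            for i in range(0, len(m.cds_sequence), 60):
                fh.write(m.cds_sequence[i : i + 60] + "\n")
    rows = [
        {"gene": m.gene, "chrom": m.chrom, "strand": m.strand, "start": s, "end": e}
        for m in models
        for s, e in m.cds_segments
    ]
    pd.DataFrame(rows).to_csv(segments_path, sep="\t", index=False)


def read_snp_list(path: PathLike) -> set[VariantKey]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    return {
        normalize_variant(VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt)))
        for r in df.itertuples(index=False)
    }


def write_snp_list(keys: Iterable[VariantKey], path: PathLike) -> None:
    rows = [{"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt} for k in sorted(keys)]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Viability plates


def read_plates(path: PathLike) -> list[PlateData]:
    """Plate CSV → typed plates.

    Columns: cell_line, condition, dose_ug_per_ml, replicate, signal.
    Dose-0 rows are the condition's drug-free control; condition UNTREATED
    rows are the per-line no-drug/no-modulator reference.
    """
    df = pd.read_csv(path)
    return plates_from_frame(df)


def plates_from_frame(df: pd.DataFrame) -> list[PlateData]:
    required = {"cell_line", "condition", "dose_ug_per_ml", "replicate", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"plate table lacks columns {sorted(missing)}")
    plates = []
    for line, line_grp in df.groupby("cell_line", sort=True):
        untreated = line_grp[line_grp["condition"] == "UNTREATED"]
        untreated_raw = (
            untreated.sort_values("replicate")["signal"].to_numpy()
            if len(untreated)
            else None
        )
        for condition, grp in line_grp.groupby("condition", sort=True):
            if condition == "UNTREATED":
                continue
            zero = grp[grp["dose_ug_per_ml"] == 0.0]
            dosed = grp[grp["dose_ug_per_ml"] > 0.0]
            if zero.empty or dosed.empty:
                raise ParseError(
                    f"{line}/{condition}: needs dose-0 control and dosed wells"
                )
            doses = np.array(sorted(dosed["dose_ug_per_ml"].unique()))
            raw = [
                dosed[dosed["dose_ug_per_ml"] == d].sort_values("replicate")["signal"].to_numpy()
                for d in doses
            ]
            plates.append(
                PlateData(
                    cell_line=str(line),
                    condition=str(condition),
                    doses=doses,
                    raw=raw,
                    zero_dose_raw=zero.sort_values("replicate")["signal"].to_numpy(),
                    untreated_raw=untreated_raw,
                )
            )
    return plates


def write_plates(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reports


def config_hash(obj) -> str:
    """Stable short hash of a (dataclass) configuration object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(report: dict, path: PathLike) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
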