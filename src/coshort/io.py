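"""Readers and writers: TSV marker/phenotype tables, VCF, FASTA tag windows.

The interchange dialects are deliberately minimal and text-based:

* marker tables — TSV with columns ``marker``, ``chrom``, ``pos_bp``,
  ``origin`` followed by one column per individual (``NA`` = missing);
* phenotypes — TSV with ``id`` and ``call`` columns;
* variants — VCF 4.2 (8 fixed columns) with ``DP``, ``DP4``, ``ANN`` and
  ``LOF`` INFO fields, read through :mod:`pysam`;
* tag windows — FASTA with the focal span encoded in the description as
  ``span=START-END`` (1-based inclusive);
* per-variety k-mer counts — two-column TSV (k-mer, count), one file per
  variety.

Internal coordinates are 1-based (VCF convention); exported BED intervals
are converted to 0-based half-open.
"""

from __future__ import annotations

import hashlib
import logging
import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kmers import AlleleTagSet, build_tag_kmers
from .lofbulk import LOF_EFFECTS, VariantRecord
from .meiosis import Gamete
from .qtl import F1Population

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_marker_table",
    "write_marker_table",
    "read_phenotypes",
    "write_phenotypes",
    "read_tag_fasta",
    "write_tag_fasta",
    "read_kmer_counts",
    "write_kmer_counts",
    "write_gamete_pool",
    "write_interval_bed",
    "read_config",
    "config_hash",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
##INFO=<ID=DP4,Number=4,Type=Integer,Description="Ref-fwd, ref-rev, alt-fwd, alt-rev read counts">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotation: Allele|Effect|Impact|GeneName|GeneID">
##INFO=<ID=LOF,Number=.,Type=String,Description="Predicted loss-of-function genes: (GeneName|GeneID|N|Fraction)">
"""


def _ann_for_alt(ann_entries: Sequence[str], alt: str) -> tuple[str | None, str | None]:
    """(effect, gene_id) for one ALT from SnpEff-style ANN entries."""
    chosen = None
    for entry in ann_entries:
        if entry.split("|", 1)[0] == alt:
            chosen = entry
            break
    if chosen is None and ann_entries:
        chosen = ann_entries[0]
    if chosen is None:
        return None, None
    fields = chosen.split("|")
    effect = fields[1] if len(fields) > 1 and fields[1] else None
    gene_id = fields[4] if len(fields) > 4 and fields[4] else (fields[3] if len(fields) > 3 and fields[3] else None)
    return effect, gene_id


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Parse a (possibly header-only) VCF into :class:`VariantRecord` rows.

    Multi-allelic records are split into one record per ALT allele; the
    DP4 quad applies to the record as given.  INFO keys other than
    DP/DP4/ANN/LOF are preserved as opaque strings.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            dp = info.pop("DP", None)
            dp4 = info.pop("DP4", None)
            ann = info.pop("ANN", None)
            lof_tag = info.pop("LOF", None)
            if isinstance(ann, str):
                ann = (ann,)
            extra = {}
            for key, val in info.items():
                if isinstance(val, tuple):
                    extra[key] = ",".join(str(x) for x in val)
                else:
                    extra[key] = str(val)
            for alt in rec.alts or ():
                effect, gene_id = _ann_for_alt(tuple(ann) if ann else (), alt)
                lof = lof_tag is not None or (effect in LOF_EFFECTS)
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=float(rec.qual) if rec.qual is not None else None,
                        dp=int(dp) if dp is not None else None,
                        dp4=tuple(int(x) for x in dp4) if dp4 is not None else None,
                        effect=effect,
                        lof=bool(lof),
                        gene_id=gene_id,
                        info=extra,
                    )
                )
    return records


def _format_qual(q: float | None) -> str:
    if q is None:
        return "."
    return f"{q:g}"


def write_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records in the minimal 8-column VCF dialect."""
    contigs = sorted({v.chrom for v in records})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in records:
            info_parts = []
            if v.dp is not None:
                info_parts.append(f"DP={v.dp}")
            if v.dp4 is not None:
                info_parts.append("DP4=" + ",".join(str(x) for x in v.dp4))
            if v.effect is not None:
                gene = v.gene_id or ""
                info_parts.append(f"ANN={v.alt}|{v.effect}|.|{gene}|{gene}")
            if v.lof:
                gene = v.gene_id or ""
                info_parts.append(f"LOF=({gene}|{gene}|1|1.00)")
            for key, val in v.info.items():
                info_parts.append(f"{key}={val}")
            info = ";".join(info_parts) if info_parts else "."
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{_format_qual(v.qual)}\t.\t{info}\n"
            )


def write_marker_table(pop: F1Population, path: str | Path) -> None:
    out = pop.markers.copy()
    out = pd.concat([out, pop.genotypes.T], axis=1)
    out.index.name = "marker"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_marker_table(path: str | Path) -> F1Population:
    """Read a marker TSV into an :class:`F1Population`.

    Raises on duplicated marker ids and on genotype codes that do not
    match the marker's parental origin (the error names the cell).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    required = ["marker", "chrom", "pos_bp", "origin"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"marker table lacks columns: {missing}")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise ValueError(f"duplicated marker id: {dup!r}")
    df = df.set_index("marker")
    markers = df[["chrom", "pos_bp", "origin"]].copy()
    markers["pos_bp"] = markers["pos_bp"].astype(int)
    genotypes = df.drop(columns=["chrom", "pos_bp", "origin"]).T
    genotypes.index.name = "individual"
    genotypes.columns.name = None
    return F1Population(markers=markers, genotypes=genotypes)


_PHENOTYPE_CODES = {
    "wild_type": 0.0,
    "wild-type": 0.0,
    "wt": 0.0,
    "co_shortage": 1.0,
    "mutant": 1.0,
    "unknown": float("nan"),
    "undetermined": float("nan"),
}


def write_phenotypes(phen: pd.Series, path: str | Path) -> None:
    call = phen.map({0: "wild_type", 1: "co_shortage"})
    call = call.fillna("unknown")
    call.rename("call").rename_axis("id").to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> pd.Series:
    """Binary phenotype series (1 = mutant, 0 = wild type, NaN otherwise)."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    if "id" not in df.columns or "call" not in df.columns:
        raise ValueError("phenotype table needs 'id' and 'call' columns")
    calls = df["call"].str.lower()
    bad = set(calls.dropna()) - set(_PHENOTYPE_CODES)
    if bad:
        raise ValueError(f"unknown phenotype calls: {sorted(bad)}")
    return pd.Series(calls.map(_PHENOTYPE_CODES).to_numpy(), index=pd.Index(df["id"], name="id"), name="phenotype")


def write_tag_fasta(tags: Mapping[str, AlleleTagSet], path: str | Path) -> None:
    records = []
    for name, t in tags.items():
        s, e = t.focal_span  # 0-based half-open -> 1-based inclusive
        records.append(SeqRecord(Seq(t.window_seq), id=name, description=f"span={s + 1}-{e}"))
    SeqIO.write(records, os.fspath(path), "fasta")


def read_tag_fasta(path: str | Path, k: int = 31) -> dict[str, AlleleTagSet]:
    """Build tag sets from a FASTA of allele windows.

    The focal span is taken from a ``span=START-END`` token (1-based
    inclusive) in the description line.
    """
    tags: dict[str, AlleleTagSet] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        span = None
        for token in rec.description.split():
            if token.startswith("span="):
                a, b = token[len("span="):].split("-")
                span = (int(a) - 1, int(b))
        if span is None:
            raise ValueError(f"record {rec.id!r} lacks a span=START-END token")
        tags[rec.id] = build_tag_kmers(str(rec.seq).upper(), span, k=k, allele_name=rec.id)
    return tags


def write_kmer_counts(panel: Mapping[str, Mapping[str, int]], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for variety, counts in panel.items():
        with open(out_dir / f"{variety}.tsv", "w") as fh:
            fh.write("kmer\tcount\n")
            for km in sorted(counts):
                fh.write(f"{km}\t{counts[km]}\n")


def read_kmer_counts(path: str | Path) -> dict[str, dict[str, int]]:
    """Read per-variety k-mer counts from a TSV file or a directory of them."""
    path = Path(path)
    files = sorted(path.glob("*.tsv")) if path.is_dir() else [path]
    panel: dict[str, dict[str, int]] = {}
    for f in files:
        df = pd.read_csv(f, sep="\t", dtype={"kmer": str, "count": int})
        panel[f.stem] = dict(zip(df["kmer"], df["count"]))
    return panel


def write_gamete_pool(gametes: Iterable[Gamete], path: str | Path) -> None:
    """One row per gamete: meiosis id, ploidy class, balanced, copy numbers."""
    with open(path, "w") as fh:
        fh.write("meiosis_id\tploidy_class\tbalanced\tcopy_numbers\n")
        for g in gametes:
            copies = ",".join(str(int(c)) for c in g.copy_number)
            fh.write(f"{g.meiosis_id}\t{g.ploidy_class}\t{int(g.balanced)}\t{copies}\n")


def write_interval_bed(chrom: str, start_1based: int, end_exclusive: int, path: str | Path,
                       name: str = "candidate_interval") -> None:
    """Export a 1-based half-open interval as a 0-based half-open BED line."""
    with open(path, "w") as fh:
        fh.write(f"{chrom}\t{max(start_1based - 1, 0)}\t{end_exclusive - 1}\t{name}\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Key=value config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def config_hash(params: Mapping[str, object]) -> str:
    text = ";".join(f"{k}={params[k]}" for k in sorted(params))
    return hashlib.sha256(text.encode()).hexdigest()[:12]
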