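"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; region annotations travel as a
BED-like TSV (chrom, start, end, name, role — 0-based half-open);
progeny and Ct tables are plain CSV; generator configuration is a flat
``key = value`` file with a mandatory seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotyping import Primer, PrimerAssay
from .synthetic import RegionAnnotation, ReferenceMap

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_regions_tsv",
    "read_regions_tsv",
    "load_reference",
    "read_sample_sheet",
    "write_primer_sheet",
    "read_primer_sheet",
    "read_config",
    "write_config",
]


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: int = 40) -> None:
    """Phred+33 FASTQ with a constant base quality (qualities are not modelled)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_regions_tsv(reference: ReferenceMap, path: str | Path) -> None:
    """Regions plus named intervals (e.g. orf_interior, emitted with role
    'other') in BED-like TSV form."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\trole\n")
        for r in reference.regions:
            fh.write(f"{reference.identifier}\t{r.start}\t{r.end}\t{r.name}\t{r.role}\n")
        for name, (s, e) in reference.named_intervals.items():
            fh.write(f"{reference.identifier}\t{s}\t{e}\t{name}\tother\n")


def read_regions_tsv(path: str | Path) -> tuple[str, list[RegionAnnotation], dict]:
    """Parse a region TSV; rows named ``orf_interior`` are routed to the
    named-interval table (they may nest inside the query ORF)."""
    df = pd.read_csv(path, sep="\t")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("region TSV must describe a single reference")
    regions, named = [], {}
    for row in df.itertuples(index=False):
        if row.name == "orf_interior":
            named[row.name] = (int(row.start), int(row.end))
        else:
            regions.append(RegionAnnotation(str(row.name), str(row.role), int(row.start), int(row.end)))
    return str(chroms[0]), regions, named


def load_reference(fasta_path: str | Path, regions_path: str | Path) -> ReferenceMap:
    """Assemble a ReferenceMap from a FASTA record and its region TSV."""
    seqs = read_fasta(fasta_path)
    identifier, regions, named = read_regions_tsv(regions_path)
    if identifier not in seqs:
        raise ValueError(f"reference {identifier!r} not found in {fasta_path}")
    return ReferenceMap(identifier, seqs[identifier], regions, named)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet CSV: sample_id, fastq (path), optional class label."""
    df = pd.read_csv(path)
    missing = {"sample_id", "fastq"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def write_primer_sheet(assays: Iterable[PrimerAssay], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\trole\tpair_id\tmax_product\n")
        for i, a in enumerate(assays):
            fh.write(f"{a.forward.name}\t{a.forward.sequence}\t{a.role}\tpair{i}\t{a.max_product}\n")
            fh.write(f"{a.reverse.name}\t{a.reverse.sequence}\t{a.role}\tpair{i}\t{a.max_product}\n")


def read_primer_sheet(path: str | Path) -> list[PrimerAssay]:
    df = pd.read_csv(path, sep="\t")
    assays = []
    for pair_id, grp in df.groupby("pair_id", sort=False):
        if len(grp) != 2:
            raise ValueError(f"primer pair {pair_id!r} must have exactly two rows")
        fwd, rev = grp.itertuples(index=False)
        assays.append(
            PrimerAssay(
                Primer(str(fwd.name), str(fwd.sequence)),
                Primer(str(rev.name), str(rev.sequence)),
                str(fwd.role),
                int(fwd.max_product),
            )
        )
    return assays


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` generator config; a seed entry is mandatory."""
    cfg: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, value = line.split("=", 1)
        cfg[key.strip()] = value.strip()
    if "seed" not in cfg:
        raise ValueError("generator config must set a seed")
    return cfg


def write_config(cfg: Mapping[str, object], path: str | Path) -> None:
    if "seed" not in cfg:
        raise ValueError("generator config must set a seed")
    Path(path).write_text("".join(f"{k} = {v}\n" for k, v in cfg.items()))
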