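"""File-format plumbing: FASTA, GFF3, newick, TSV and YAML config.

Internal coordinates are 0-based half-open everywhere; GFF3 output follows
the format's 1-based closed convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from urllib.parse import quote

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    records = []
    for name, s in seqs.items():
        head, _, desc = name.partition(" ")
        records.append(SeqRecord(Seq(s), id=head, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


@dataclass
class GFF3Feature:
    contig: str
    source: str
    type: str
    start: int          # 0-based half-open (converted on write)
    end: int
    score: str = "."
    strand: str = "."
    attributes: dict | None = None


def write_gff3(features: list[GFF3Feature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={quote(str(v), safe=' /:.')}"
                             for k, v in (f.attributes or {}).items()) or "."
            fh.write("\t".join([f.contig, f.source, f.type,
                                str(f.start + 1), str(f.end), str(f.score),
                                f.strand, ".", attrs]) + "\n")


def read_gff3(path) -> list[GFF3Feature]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            attrs = {}
            if fields[8] != ".":
                for item in fields[8].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k] = v
            out.append(GFF3Feature(fields[0], fields[1], fields[2],
                                   int(fields[3]) - 1, int(fields[4]),
                                   fields[5], fields[6], attrs))
    return out


def write_newick(tree, path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_config(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
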