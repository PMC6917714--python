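"""Readers and writers for the on-disk formats the pipeline consumes.

GFF3 (1-based inclusive) and FASTA for genome annotations, BED (0-based
half-open) and TSV for island/prophage interval calls, TSV for reaction
catalogs, hit tables and result tables. Internally everything is 0-based
half-open; conversion happens here and only here.

Replicon topology metadata rides on the FASTA description line as
``key=value`` tokens (``circular=true chromosome=true``), the convention the
synthetic-panel writer emits; absent tokens default to a circular primary
chromosome for the first sequence.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    FeatureKind,
    GeneFeature,
    GenomeRecord,
    IntervalLabel,
    IntervalSet,
    Replicon,
    SourceEnv,
)

_KIND_MAP = {"CDS": FeatureKind.CDS, "rRNA": FeatureKind.rRNA}


def _parse_flags(description: str) -> dict[str, str]:
    flags = {}
    for token in description.split()[1:]:
        if "=" in token:
            k, v = token.split("=", 1)
            flags[k] = v
    return flags


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain id -> sequence mapping (used for proteomes and gene sequences)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome(
    annotation_file: str | Path,
    sequence_file: str | Path,
    genome_id: str | None = None,
    species_label: str = "",
    source_env: SourceEnv = SourceEnv.other,
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Read a GFF3 + FASTA pair into the internal genome model.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Replicon lengths come from the FASTA sequence lengths. A feature on a
    contig absent from the FASTA, or with end < start, is a hard error.
    """
    annotation_file, sequence_file = Path(annotation_file), Path(sequence_file)
    replicons: list[Replicon] = []
    lengths: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(sequence_file), "fasta")):
        flags = _parse_flags(rec.description)
        replicons.append(
            Replicon(
                replicon_id=rec.id,
                length=len(rec.seq),
                circular=flags.get("circular", "true").lower() == "true",
                is_chromosome=flags.get("chromosome", "true" if i == 0 else "false").lower()
                == "true",
            )
        )
        lengths[rec.id] = len(rec.seq)
    if not replicons:
        raise ValueError(f"{sequence_file}: no sequences")

    genome = GenomeRecord(
        genome_id=genome_id or annotation_file.stem,
        species_label=species_label,
        source_env=source_env,
        replicons=replicons,
    )

    db = gffutils.create_db(
        str(annotation_file),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    for f in db.all_features(order_by=("seqid", "start")):
        if f.featuretype == "region":
            continue
        fid = f.attributes.get("ID", [f.id])[0]
        if f.seqid not in lengths:
            raise ValueError(
                f"feature {fid}: parent sequence {f.seqid!r} absent from "
                f"{sequence_file.name}"
            )
        if f.end < f.start:
            raise ValueError(f"feature {fid}: end {f.end} < start {f.start}")
        start, end = f.start - 1, f.end  # GFF3 1-based inclusive -> half-open
        if start < 0 or end > lengths[f.seqid]:
            raise ValueError(
                f"feature {fid}: [{start}, {end}) outside replicon "
                f"{f.seqid} of length {lengths[f.seqid]}"
            )
        features.append(
            GeneFeature(
                feature_id=fid,
                replicon_id=f.seqid,
                start=start,
                end=end,
                strand=f.strand if f.strand in "+-" else "+",
                kind=_KIND_MAP.get(f.featuretype, FeatureKind.other),
                product=f.attributes.get("product", [""])[0],
            )
        )
    return genome, features


def write_gff3(
    path: str | Path,
    genome: GenomeRecord,
    features: Sequence[GeneFeature],
    source: str = "bacpanel",
) -> None:
    """Write features back out as GFF3 (converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons:
            fh.write(f"##sequence-region {rep.replicon_id} 1 {rep.length}\n")
        for f in features:
            ftype = f.kind.value if f.kind is not FeatureKind.other else "gene"
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.replicon_id}\t{source}\t{ftype}\t{f.start + 1}\t{f.end}\t."
                f"\t{f.strand}\t.\t{attrs}\n"
            )


def read_bed_intervals(
    path: str | Path, label: IntervalLabel = IntervalLabel.GI
) -> list[IntervalSet]:
    """Read a BED file (0-based half-open) into per-replicon interval sets."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["replicon", "start", "end"],
    )
    return _group_intervals(df, label)


def read_interval_tsv(path: str | Path) -> dict[str, list[IntervalSet]]:
    """Read a (strain, replicon, start, end, label) TSV of interval calls.

    Coordinates 0-based half-open. Returns strain -> interval sets.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[IntervalSet]] = {}
    for (strain, label), sub in df.groupby(["strain", "label"], sort=True):
        out.setdefault(str(strain), []).extend(
            _group_intervals(sub, IntervalLabel(label))
        )
    return out


def _group_intervals(df: pd.DataFrame, label: IntervalLabel) -> list[IntervalSet]:
    sets = []
    for rep, sub in df.groupby("replicon", sort=True):
        sets.append(
            IntervalSet(
                replicon_id=str(rep),
                intervals=list(zip(sub["start"].astype(int), sub["end"].astype(int))),
                label=label,
            )
        )
    return sets


def write_interval_tsv(
    path: str | Path, per_strain: Mapping[str, Sequence[IntervalSet]]
) -> None:
    rows = []
    for strain in sorted(per_strain):
        for iset in per_strain[strain]:
            for s, e in iset.intervals:
                rows.append((strain, iset.replicon_id, s, e, iset.label.value))
    pd.DataFrame(
        rows, columns=["strain", "replicon", "start", "end", "label"]
    ).to_csv(path, sep="\t", index=False)


def write_table(
    path: str | Path,
    df: pd.DataFrame,
    header_lines: Sequence[str] = (),
) -> None:
    """TSV writer with a '#'-prefixed header block (thresholds, provenance)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
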