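"""File formats: FASTA catalogs, count matrices, training directories, taxonomy tables."""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import GeneRecord
from .profiles import TrainingSet
from .taxonomy import TaxonomyTree


def write_fasta(sequences: list[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_gene_catalog(records: list[GeneRecord], outdir) -> dict[str, Path]:
    """Write genes.faa + genes.tsv + counts.tsv, the formats the catalog CLI reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genes.faa",
        "meta": outdir / "genes.tsv",
        "counts": outdir / "counts.tsv",
    }
    write_fasta([(g.gene_id, g.protein) for g in records], paths["fasta"])
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "contig_id": g.contig_id, "nt_length": g.nt_length}
            for g in records
        ]
    ).to_csv(paths["meta"], sep="\t", index=False)
    samples = sorted({s for g in records for s in g.counts})
    counts = pd.DataFrame(
        [[g.gene_id] + [g.counts.get(s, 0) for s in samples] for g in records],
        columns=["gene_id"] + samples,
    )
    counts.to_csv(paths["counts"], sep="\t", index=False)
    return paths


def read_gene_catalog(fasta_path, meta_path, counts_path) -> list[GeneRecord]:
    """Read the FASTA + metadata + counts triple back into gene records."""
    proteins = dict(read_fasta(fasta_path))
    meta = pd.read_csv(meta_path, sep="\t", dtype={"gene_id": str, "contig_id": str})
    counts = pd.read_csv(counts_path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    records = []
    for row in meta.itertuples():
        gene_id = str(row.gene_id)
        gene_counts = {}
        if gene_id in counts.index:
            gene_counts = {s: float(v) for s, v in counts.loc[gene_id].items()}
        records.append(
            GeneRecord(
                gene_id=gene_id,
                contig_id=str(row.contig_id),
                nt_length=int(row.nt_length),
                protein=proteins[gene_id],
                counts=gene_counts,
            )
        )
    return records


def write_training_dir(training: dict[str, TrainingSet], outdir) -> None:
    """Layout: ``<outdir>/<family>/positives.afa`` and ``negatives.fa``."""
    outdir = Path(outdir)
    for family, ts in training.items():
        fam_dir = outdir / family
        fam_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [(f"{family}_pos{i}", s) for i, s in enumerate(ts.positives)],
            fam_dir / "positives.afa",
        )
        if ts.negatives:
            write_fasta(
                [(f"{family}_neg{i}", s) for i, s in enumerate(ts.negatives)],
                fam_dir / "negatives.fa",
            )


def read_training_dir(path) -> dict[str, TrainingSet]:
    path = Path(path)
    out: dict[str, TrainingSet] = {}
    for fam_dir in sorted(p for p in path.iterdir() if p.is_dir()):
        positives = [seq for _, seq in read_fasta(fam_dir / "positives.afa")]
        neg_path = fam_dir / "negatives.fa"
        negatives = [seq for _, seq in read_fasta(neg_path)] if neg_path.exists() else []
        out[fam_dir.name] = TrainingSet(fam_dir.name, positives, negatives)
    return out


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    tree.to_frame().to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyTree:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return TaxonomyTree.from_frame(frame)
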