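"""Readers and writers for the pipeline's file formats.

Kinetic tables are CSV/TSV with a leading time column (minutes) and one
column per well; the plate map is a TSV of well_id, strain_id, substrate_id,
replicate, with substrate_id ``NONE`` marking negative-control wells.
Genomes travel as GFF3 (labels in the ``product`` attribute) plus protein
and optional nucleotide FASTA keyed by gene id.  Matrices, family tables,
species maps, fold changes and LGT calls are plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .growth import KineticCurve, PhenotypeMatrix
from .pangenome import AnnotatedGenome, Gene, GeneFamily

__all__ = [
    "read_kinetic_table",
    "write_kinetic_table",
    "read_plate_map",
    "write_plate_map",
    "load_curves",
    "write_matrix",
    "read_matrix",
    "write_genome",
    "read_genome",
    "write_families",
    "read_families",
    "read_species_map",
    "write_species_map",
    "read_fold_changes",
]


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_kinetic_table(path: str | Path) -> pd.DataFrame:
    """Time x wells table; first column is time in minutes."""
    df = pd.read_csv(path, sep=_sep(path))
    return df.set_index(df.columns[0])


def write_kinetic_table(curves: list[KineticCurve], path: str | Path) -> None:
    times = curves[0].times
    data = {"time_min": times}
    for c in curves:
        data[c.well_id] = c.a600
    pd.DataFrame(data).to_csv(path, sep=_sep(path), index=False)


def read_plate_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"well_id": str, "strain_id": str, "substrate_id": str})
    required = {"well_id", "strain_id", "substrate_id", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"plate map must contain columns {sorted(required)}")
    return df


def write_plate_map(curves: list[KineticCurve], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "well_id": c.well_id,
                "strain_id": c.strain_id,
                "substrate_id": c.substrate_id,
                "replicate": c.replicate,
            }
            for c in curves
        ]
    ).to_csv(path, sep="\t", index=False)


def load_curves(kinetic_path: str | Path, plate_map_path: str | Path) -> list[KineticCurve]:
    """Join a kinetic table with its plate map into KineticCurve objects."""
    table = read_kinetic_table(kinetic_path)
    plate_map = read_plate_map(plate_map_path).set_index("well_id")
    curves = []
    for well in table.columns:
        if well not in plate_map.index:
            raise ValueError(f"well {well} missing from plate map")
        row = plate_map.loc[well]
        curves.append(
            KineticCurve(
                well_id=well,
                strain_id=str(row.strain_id),
                substrate_id=str(row.substrate_id),
                replicate=int(row.replicate),
                times=table.index.to_numpy(dtype=float),
                a600=table[well].to_numpy(dtype=float),
            )
        )
    return curves


def write_matrix(m: PhenotypeMatrix, prefix: str | Path) -> None:
    """Write growth/rate matrices (and calls) as stage-stamped TSVs."""
    prefix = Path(prefix)
    m.growth.to_csv(f"{prefix}.{m.stage}.growth.tsv", sep="\t")
    m.rate.to_csv(f"{prefix}.{m.stage}.rate.tsv", sep="\t")
    if m.is_growth is not None:
        m.is_growth.to_csv(f"{prefix}.{m.stage}.is_growth.tsv", sep="\t")


def read_matrix(prefix: str | Path, stage: str) -> PhenotypeMatrix:
    prefix = Path(prefix)
    growth = pd.read_csv(f"{prefix}.{stage}.growth.tsv", sep="\t", index_col=0)
    rate = pd.read_csv(f"{prefix}.{stage}.rate.tsv", sep="\t", index_col=0)
    calls_path = Path(f"{prefix}.{stage}.is_growth.tsv")
    is_growth = (
        pd.read_csv(calls_path, sep="\t", index_col=0).astype(bool) if calls_path.exists() else None
    )
    return PhenotypeMatrix(growth=growth, rate=rate, stage=stage, is_growth=is_growth)


def write_genome(genome: AnnotatedGenome, outdir: str | Path) -> None:
    """Write <genome>.gff3, <genome>.faa and (if present) <genome>.fna."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gff = outdir / f"{genome.genome_id}.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            labels = ",".join(sorted(g.labels))
            attrs = f"ID={g.gene_id};product={labels};species={genome.species_id}"
            fh.write(
                f"{g.contig}\tglycotype\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )
    SeqIO.write(
        [SeqRecord(Seq(g.protein), id=g.gene_id, description="") for g in genome.genes],
        outdir / f"{genome.genome_id}.faa",
        "fasta",
    )
    if all(g.dna is not None for g in genome.genes):
        SeqIO.write(
            [SeqRecord(Seq(g.dna), id=g.gene_id, description="") for g in genome.genes],
            outdir / f"{genome.genome_id}.fna",
            "fasta",
        )


def read_genome(genome_id: str, indir: str | Path, species_id: str | None = None) -> AnnotatedGenome:
    indir = Path(indir)
    proteins = {r.id: str(r.seq) for r in SeqIO.parse(indir / f"{genome_id}.faa", "fasta")}
    fna = indir / f"{genome_id}.fna"
    dnas = {r.id: str(r.seq) for r in SeqIO.parse(fna, "fasta")} if fna.exists() else {}
    db = gffutils.create_db(
        str(indir / f"{genome_id}.gff3"),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.all_features(order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        labels = frozenset(feat.attributes.get("product", ["other"])[0].split(","))
        if species_id is None:
            species_id = feat.attributes.get("species", ["unknown"])[0]
        genes.append(
            Gene(
                gene_id=gid,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or "+",
                protein=proteins[gid],
                labels=labels,
                dna=dnas.get(gid),
            )
        )
    return AnnotatedGenome(genome_id=genome_id, species_id=species_id or "unknown", genes=genes)


def write_families(families: list[GeneFamily], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"family_id": f.family_id, "genome_id": genome, "gene_id": gene}
            for f in families
            for genome, gene in f.members
        ]
    ).to_csv(path, sep="\t", index=False)


def read_families(path: str | Path) -> dict[tuple[str, str], str]:
    """Families TSV -> (genome_id, gene_id) -> family_id map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {(r.genome_id, r.gene_id): r.family_id for r in df.itertuples()}


def read_species_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]], df[cols[1]]))


def write_species_map(species_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(species_map.items()), columns=["genome_id", "species_id"]
    ).to_csv(path, sep="\t", index=False)


def read_fold_changes(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
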