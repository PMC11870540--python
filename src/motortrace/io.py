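"""Readers and writers for the pipeline's file formats.

GFF3 gene tables (1-based inclusive coordinates), HMMER3
domtblout-dialect domain hit tables, BLAST outfmt-6-style sequence hit
TSVs, metadata/feature TSVs and protein FASTA stubs.  GFF3 lines are
parsed with gffutils; domtblout files with Bio.SearchIO; FASTA through
Bio.SeqIO.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SearchIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .models import (
    DOMHIT_COLUMNS,
    FeatureTable,
    GeneRecord,
    GenomeAnnotation,
    GenomeMeta,
    LINEAGE_RANKS,
    ProteinFeature,
    SEQHIT_COLUMNS,
    ValidationError,
)

# ---------------------------------------------------------------------------
# GFF3 gene tables


def genome_to_gff3(genome: GenomeAnnotation) -> str:
    lines = ["##gff-version 3"]
    for replicon_id in genome.replicons:
        recs = genome.genes_on(replicon_id)
        region_end = max(g.end for g in recs) if recs else 1
        lines.append(f"##sequence-region {replicon_id} 1 {region_end}")
        circular = "true" if genome.is_circular(replicon_id) else "false"
        lines.append(
            f"{replicon_id}\tmotortrace\tregion\t1\t{region_end}\t.\t+\t.\t"
            f"ID=region-{replicon_id};Is_circular={circular}"
        )
        for g in recs:
            attrs = (
                f"ID=cds-{g.locus_tag};locus_tag={g.locus_tag};"
                f"protein_id={g.protein_id};product={g.product}"
            )
            lines.append(
                f"{replicon_id}\tmotortrace\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}"
            )
    return "\n".join(lines) + "\n"


def read_gff3(path: str | Path, genome_id: str | None = None) -> GenomeAnnotation:
    """Read a GFF3 gene table into an ordered genome annotation.

    CDS features become gene records; per-replicon ordinal indices follow
    file order.  A ``region`` feature with ``Is_circular=true`` marks its
    replicon as circular.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    genes: list[GeneRecord] = []
    circular: set[str] = set()
    counters: dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype == "region":
                if feat.attributes.get("Is_circular", ["false"])[0] == "true":
                    circular.add(feat.seqid)
                continue
            if feat.featuretype != "CDS":
                continue
            idx = counters.get(feat.seqid, 0)
            counters[feat.seqid] = idx + 1
            genes.append(
                GeneRecord(
                    genome_id=genome_id,
                    replicon_id=feat.seqid,
                    index=idx,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    locus_tag=feat.attributes["locus_tag"][0],
                    protein_id=feat.attributes.get("protein_id", [""])[0],
                    product=feat.attributes.get("product", ["hypothetical protein"])[0],
                )
            )
    return GenomeAnnotation(genome_id, genes, circular_replicons=circular)


# ---------------------------------------------------------------------------
# domain hits (HMMER3 domtblout dialect)

_DOMTBL_HEADER = (
    "#                                                       --- full sequence ---"
    " -------------- this domain -------------   hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen"
    "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
    "  from    to  from    to  acc description of target\n"
)


def domain_hits_to_domtblout(
    hits: pd.DataFrame, features: FeatureTable | None = None
) -> str:
    """Serialize a domain-hit table in HMMER3 per-domain tabular format."""
    out = [_DOMTBL_HEADER.rstrip("\n")]
    groups = hits.groupby(["profile_id", "protein_id"], sort=False)
    totals = groups.size().to_dict()
    counters: dict[tuple[str, str], int] = {}
    for row in hits.itertuples():
        key = (row.profile_id, row.protein_id)
        counters[key] = counters.get(key, 0) + 1
        tlen = (
            features.get(row.protein_id).length
            if features is not None and row.protein_id in features
            else 0
        )
        span = int(row.env_end - row.env_start + 1)
        out.append(
            f"{row.protein_id} - {tlen} {row.profile_id} - {span} "
            f"{row.evalue:.3e} {row.bitscore:.1f} 0.0 "
            f"{counters[key]} {totals[key]} {row.evalue:.3e} {row.evalue:.3e} "
            f"{row.bitscore:.1f} 0.0 1 {span} "
            f"{int(row.env_start)} {int(row.env_end)} "
            f"{int(row.env_start)} {int(row.env_end)} 0.90 -"
        )
    out.append("#")
    return "\n".join(out) + "\n"


def read_domtblout(path: str | Path) -> pd.DataFrame:
    """Parse a per-domain tabular file into the domain-hit schema.

    Envelope coordinates are returned 1-based inclusive; ``evalue`` is
    the independent (per-domain) E-value, ``bitscore`` the domain score.
    """
    rows = []
    with open(path) as fh:
        for qresult in SearchIO.parse(fh, "hmmsearch3-domtab"):
            for hit in qresult:
                for hsp in hit:
                    rows.append(
                        {
                            "protein_id": hit.id,
                            "profile_id": qresult.id,
                            "env_start": hsp.env_start + 1,
                            "env_end": hsp.env_end,
                            "evalue": hsp.evalue,
                            "bitscore": hsp.bitscore,
                        }
                    )
    return pd.DataFrame(rows, columns=list(DOMHIT_COLUMNS))


# ---------------------------------------------------------------------------
# sequence hits (BLAST outfmt 6 dialect)


def sequence_hits_to_tsv(hits: pd.DataFrame) -> str:
    buf = _stdio.StringIO()
    for row in hits.itertuples():
        buf.write(
            f"{row.qseqid}\t{row.sseqid}\t{row.pident:.1f}\t{int(row.length)}\t"
            f"{int(row.mismatch)}\t{int(row.gapopen)}\t{int(row.qstart)}\t"
            f"{int(row.qend)}\t{int(row.sstart)}\t{int(row.send)}\t"
            f"{row.evalue:.3e}\t{row.bitscore:.1f}\n"
        )
    return buf.getvalue()


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular sequence hit file (BLAST outfmt 6)."""
    df = pd.read_csv(
        path, sep="\t", names=list(SEQHIT_COLUMNS), header=None, comment="#"
    )
    if df.empty:
        return pd.DataFrame(columns=list(SEQHIT_COLUMNS))
    return df


def read_query_families(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"query", "family"} <= set(df.columns):
        raise ValidationError(
            f"{path}: query-family sidecar needs 'query' and 'family' columns"
        )
    return dict(zip(df["query"], df["family"]))


def attach_query_families(
    hits: pd.DataFrame, mapping: dict[str, str]
) -> pd.DataFrame:
    """Add a ``query_family`` column from a query -> family mapping."""
    out = hits.copy()
    out["query_family"] = out["qseqid"].map(mapping)
    missing = out["query_family"].isna()
    if missing.any():
        bad = sorted(out.loc[missing, "qseqid"].unique())
        raise ValidationError(f"queries without family mapping: {bad}")
    return out


# ---------------------------------------------------------------------------
# metadata and protein features

_META_COLUMNS = (
    ["genome_id"]
    + list(LINEAGE_RANKS)
    + ["assembly_level", "completeness", "contamination", "model_priority"]
)


def metadata_to_tsv(metas: Iterable[GenomeMeta]) -> str:
    lines = ["\t".join(_META_COLUMNS)]
    for m in metas:
        lineage = [m.lineage.get(rank, "") for rank in LINEAGE_RANKS]
        lines.append(
            "\t".join(
                [m.genome_id, *lineage, m.assembly_level,
                 f"{m.completeness:.2f}", f"{m.contamination:.2f}",
                 str(m.model_priority)]
            )
        )
    return "\n".join(lines) + "\n"


def read_metadata_tsv(path: str | Path) -> list[GenomeMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    required = {"genome_id", "assembly_level", "completeness", "contamination"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {sorted(missing)}")
    metas = []
    for _, row in df.iterrows():
        if pd.isna(row["completeness"]) or pd.isna(row["contamination"]):
            raise ValidationError(
                f"genome {row['genome_id']}: missing completeness/contamination"
            )
        lineage = {
            rank: str(row[rank])
            for rank in LINEAGE_RANKS
            if rank in df.columns and not pd.isna(row[rank])
        }
        metas.append(
            GenomeMeta(
                genome_id=row["genome_id"],
                lineage=lineage,
                assembly_level=row["assembly_level"],
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                model_priority=int(row["model_priority"])
                if "model_priority" in df.columns and not pd.isna(row["model_priority"])
                else 0,
            )
        )
    return metas


_FEATURE_COLUMNS = (
    "protein_id",
    "length",
    "has_tm",
    "has_signal_peptide",
    "has_beta_pair",
    "blacklist_domains",
    "struct_confirmed",
)


def features_to_tsv(features: FeatureTable) -> str:
    lines = ["\t".join(_FEATURE_COLUMNS)]
    for f in features:
        domains = ",".join(sorted(f.blacklist_domains)) or "-"
        lines.append(
            "\t".join(
                [
                    f.protein_id,
                    str(f.length),
                    str(int(f.has_tm)),
                    str(int(f.has_signal_peptide)),
                    str(int(f.has_beta_pair)),
                    domains,
                    str(int(f.struct_confirmed)),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_features_tsv(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t")
    table = FeatureTable()
    for row in df.itertuples():
        domains = (
            frozenset()
            if row.blacklist_domains in ("-", "", None)
            or pd.isna(row.blacklist_domains)
            else frozenset(str(row.blacklist_domains).split(","))
        )
        table.add(
            ProteinFeature(
                protein_id=row.protein_id,
                length=int(row.length),
                has_tm=bool(int(row.has_tm)),
                has_signal_peptide=bool(int(row.has_signal_peptide)),
                has_beta_pair=bool(int(row.has_beta_pair)),
                blacklist_domains=domains,
                struct_confirmed=bool(int(row.struct_confirmed)),
            )
        )
    return table


# ---------------------------------------------------------------------------
# protein FASTA stubs

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


def stub_protein_fasta(
    genome: GenomeAnnotation,
    features: FeatureTable,
    rng: np.random.Generator,
) -> str:
    """Random-residue FASTA whose lengths match the feature table."""
    records = []
    for gene in genome:
        length = (
            features.get(gene.protein_id).length
            if gene.protein_id in features
            else max((gene.end - gene.start + 1) // 3, 50)
        )
        letters = rng.choice(_AA, size=length)
        seq = b"".join(letters).decode()
        records.append(
            SeqRecord(Seq(seq), id=gene.protein_id, description=gene.product)
        )
    buf = _stdio.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
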