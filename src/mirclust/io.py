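"""Readers and writers for the formats the pipeline touches.

GFF3 follows the miRBase dialect: precursor rows have feature type
``miRNA_primary_transcript`` and carry ``ID``/``Name`` attributes; mature
products (type ``miRNA``) are skipped.  The parser is deliberately local
(tab-split, attribute dict) so that errors can name the offending line.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .errors import GFF3ParseError
from .model import HomologyMap, MicroRNALocus, SpeciesPhylogeny

PRECURSOR_TYPE = "miRNA_primary_transcript"

_FAMILY_ATTRS = ("annotation_family", "phylo_family")


def _parse_attributes(field: str, line_number: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise GFF3ParseError(f"malformed attribute {chunk!r}", line_number)
        key, value = chunk.split("=", 1)
        attrs[key] = value
    return attrs


def read_mirna_gff3(
    path,
    species_id: str,
    feature_type: str = PRECURSOR_TYPE,
) -> list[MicroRNALocus]:
    """Read precursor features from a miRBase-style GFF3 file.

    Rows whose type differs from ``feature_type`` (e.g. mature ``miRNA``
    rows) are skipped.  Coordinates stay 1-based inclusive.
    """
    loci: list[MicroRNALocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"expected 9 tab-separated columns, found {len(fields)}",
                    line_number,
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype != feature_type:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GFF3ParseError(
                    f"non-integer coordinates {start_s!r}..{end_s!r}", line_number
                ) from None
            attrs = _parse_attributes(attr_s, line_number)
            mirna_id = attrs.get("Name") or attrs.get("ID")
            if not mirna_id:
                raise GFF3ParseError("feature without ID or Name attribute", line_number)
            if mirna_id in seen:
                raise GFF3ParseError(f"duplicate ID {mirna_id!r}", line_number)
            seen.add(mirna_id)
            try:
                locus = MicroRNALocus(
                    mirna_id=mirna_id,
                    species_id=species_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    annotation_family=attrs.get("annotation_family", ""),
                    phylo_family=attrs.get("phylo_family", ""),
                    host_transcript=attrs.get("Derives_from"),
                )
            except ValueError as exc:
                raise GFF3ParseError(str(exc), line_number) from None
            loci.append(locus)
    return loci


def write_mirna_gff3(
    loci: Iterable[MicroRNALocus],
    path,
    feature_type: str = PRECURSOR_TYPE,
    source: str = "mirclust",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            attrs = [f"ID={locus.mirna_id}", f"Name={locus.mirna_id}"]
            if locus.annotation_family != locus.mirna_id:
                attrs.append(f"annotation_family={locus.annotation_family}")
            if locus.phylo_family != locus.mirna_id:
                attrs.append(f"phylo_family={locus.phylo_family}")
            if locus.host_transcript:
                attrs.append(f"Derives_from={locus.host_transcript}")
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        source,
                        feature_type,
                        str(locus.start),
                        str(locus.end),
                        ".",
                        locus.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_species_tree(path, **kwargs) -> SpeciesPhylogeny:
    """Read a rooted Newick tree with named internal lineages."""
    return SpeciesPhylogeny.from_newick_file(path, **kwargs)


# -- homology tables -------------------------------------------------------

_HOMOLOGY_COLUMNS = [
    "phylo_family",
    "species_id",
    "mirna_id",
    "chrom",
    "start",
    "end",
    "strand",
    "annotation_family",
]


def read_homology_tsv(path, species: Sequence[str]) -> HomologyMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    hom = HomologyMap(species)
    for row in df.itertuples(index=False):
        hom.add(
            MicroRNALocus(
                mirna_id=row.mirna_id,
                species_id=row.species_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                annotation_family=getattr(row, "annotation_family", "") or "",
                phylo_family=row.phylo_family,
            )
        )
    return hom


def write_homology_tsv(hom: HomologyMap, path) -> None:
    rows = [
        {
            "phylo_family": locus.phylo_family,
            "species_id": locus.species_id,
            "mirna_id": locus.mirna_id,
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
            "strand": locus.strand,
            "annotation_family": locus.annotation_family,
        }
        for locus in hom.all_loci()
    ]
    pd.DataFrame(rows, columns=_HOMOLOGY_COLUMNS).to_csv(path, sep="\t", index=False)


# -- BED export ------------------------------------------------------------


def clusters_to_bed6(clusters, path) -> None:
    """Write clusters as BED6 (0-based half-open) for genome browsers."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.start - 1),
                        str(c.end),
                        c.cluster_id,
                        str(len(c.members)),
                        c.strand,
                    ]
                )
                + "\n"
            )
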