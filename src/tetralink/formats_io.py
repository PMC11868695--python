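"""Readers and writers for every tabular dialect the pipeline touches.

All file dialects are fixed here and nowhere else: UTF-8, tab-separated,
``#``-prefixed comment lines ignored, no quoting.  Tabular BLAST coordinates
stay 1-based inclusive as in the format; all conversions to internal
conventions happen in this module.  Readers reject malformed rows with the
offending line number instead of coercing them.
"""

from __future__ import annotations

import os
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .depth_abundance import DepthRecord, TaxonDepthProfile
from .errors import ConsistencyError, ParseError, ValidationError
from .homology_screen import HomologHit
from .lipid_quant import ADDUCT_MASS
from .marker_concat import MagQuality
from .taxonomy_resolve import Lineage

__all__ = [
    "read_blast6",
    "write_blast6",
    "read_depth_table",
    "write_depth_table",
    "read_lineage_table",
    "write_lineage_table",
    "read_bin_table",
    "write_bin_table",
    "read_quality_table",
    "write_quality_table",
    "read_peak_table",
    "write_peak_table",
    "read_presence_table",
    "write_presence_table",
    "read_profile_table",
    "write_profile_table",
    "read_lipid_profile_table",
    "write_lipid_profile_table",
    "read_ani_matrix",
    "write_ani_matrix",
    "read_fasta",
    "write_fasta",
]

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def _data_rows(path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _write_rows(path, header: Optional[Sequence[str]], rows: Iterable[Sequence]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header is not None:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def split_subject_id(subject: str, sep: str = "_") -> tuple[str, int]:
    """Split a gene-caller protein id into (scaffold id, ORF number).

    The common convention appends the ORF number after the last separator
    (``scaffold_12`` -> ``("scaffold", 12)``).
    """
    scaffold, _, index = subject.rpartition(sep)
    if not scaffold or not index.isdigit():
        raise ParseError(f"cannot split subject id {subject!r} on {sep!r}")
    return scaffold, int(index)


def read_blast6(
    path,
    query_to_family: Optional[Mapping[str, str]] = None,
    subject_sep: str = "_",
) -> list[HomologHit]:
    """Read standard 12-column tabular protein-alignment output.

    The query id names the gene family (optionally translated through
    ``query_to_family``); the subject id is split into scaffold id and
    protein index on the last ``subject_sep``.  Coordinates are kept
    1-based inclusive.
    """
    hits: list[HomologHit] = []
    for lineno, fields in _data_rows(path):
        if len(fields) < 12:
            raise ParseError(
                f"{path}: line {lineno}: expected >=12 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            pident = float(fields[2])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        family = fields[0]
        if query_to_family is not None:
            family = query_to_family.get(family, family)
        scaffold, protein_index = split_subject_id(fields[1], subject_sep)
        hits.append(
            HomologHit(
                family=family,
                scaffold_id=scaffold,
                protein_index=protein_index,
                pident=pident,
                evalue=evalue,
                bitscore=bitscore,
                qstart=qstart,
                qend=qend,
                sstart=sstart,
                send=send,
            )
        )
    return hits


def write_blast6(path, rows: Iterable[Sequence]) -> None:
    """Write raw 12-field tabular alignment rows (no header, per the format)."""
    _write_rows(path, None, rows)


DEPTH_HEADER = (
    "scaffold",
    "assembly_sample",
    "mapping_sample",
    "avg_depth",
    "mapping_total_reads",
)


def read_depth_table(path) -> list[DepthRecord]:
    """Read per-(scaffold, mapping sample) average-depth records."""
    records: list[DepthRecord] = []
    rows = _data_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: missing header") from None
    if tuple(header) != DEPTH_HEADER:
        raise ParseError(f"{path}: unexpected header {header}")
    for lineno, fields in rows:
        if len(fields) != 5:
            raise ParseError(f"{path}: line {lineno}: expected 5 fields")
        try:
            avg_depth = float(fields[3])
            total = float(fields[4])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        try:
            records.append(
                DepthRecord(fields[0], fields[1], fields[2], avg_depth, total)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_depth_table(path, records: Iterable[DepthRecord]) -> None:
    _write_rows(
        path,
        DEPTH_HEADER,
        (
            (
                r.scaffold_id,
                r.assembly_sample,
                r.mapping_sample,
                repr(r.avg_depth),
                repr(r.mapping_total_reads),
            )
            for r in records
        ),
    )


def read_lineage_table(path) -> dict[str, Lineage]:
    """Read an id -> classification table (CAT/BAT style)."""
    out: dict[str, Lineage] = {}
    for lineno, fields in _data_rows(path):
        if fields and fields[0] == "id":
            continue
        if len(fields) < 1:
            raise ParseError(f"{path}: line {lineno}: empty row")
        ident = fields[0]
        classification = fields[1] if len(fields) > 1 else ""
        if ident in out:
            raise ValidationError(f"{path}: duplicate id {ident!r}")
        try:
            out[ident] = Lineage.parse(classification)
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_lineage_table(path, lineages: Mapping[str, Lineage]) -> None:
    _write_rows(
        path,
        ("id", "classification"),
        ((ident, lin.to_string()) for ident, lin in lineages.items()),
    )


def read_bin_table(path) -> dict[str, str]:
    """Read scaffold -> bin membership; a scaffold in two bins is an error."""
    out: dict[str, str] = {}
    for lineno, fields in _data_rows(path):
        if fields and fields[0] == "scaffold":
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields")
        scaffold, bin_id = fields[0], fields[1]
        if scaffold in out and out[scaffold] != bin_id:
            raise ConsistencyError(
                f"{path}: scaffold {scaffold!r} assigned to two bins"
            )
        out[scaffold] = bin_id
    return out


def write_bin_table(path, bins: Mapping[str, str]) -> None:
    _write_rows(path, ("scaffold", "bin"), bins.items())


def read_quality_table(path) -> list[MagQuality]:
    """Read a CheckM-style MAG quality table."""
    out: list[MagQuality] = []
    for lineno, fields in _data_rows(path):
        if fields and fields[0] == "mag":
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields")
        try:
            out.append(MagQuality(fields[0], float(fields[1]), float(fields[2])))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_quality_table(path, rows: Iterable[MagQuality]) -> None:
    _write_rows(
        path,
        ("mag", "completeness", "contamination"),
        ((q.mag_id, repr(q.completeness), repr(q.contamination)) for q in rows),
    )


PEAK_HEADER = ("lipid", "sample_depth_m", "adduct", "area", "is_area", "litres")


def read_peak_table(path) -> pd.DataFrame:
    """Read a lipid peak table; missing adduct rows mean "adduct absent".

    Validates adduct labels, non-negative areas, positive internal-standard
    areas and positive litres.
    """
    rows = []
    it = _data_rows(path)
    try:
        _, header = next(it)
    except StopIteration:
        raise ParseError(f"{path}: missing header") from None
    if tuple(header) != PEAK_HEADER:
        raise ParseError(f"{path}: unexpected header {header}")
    for lineno, fields in it:
        if len(fields) != 6:
            raise ParseError(f"{path}: line {lineno}: expected 6 fields")
        lipid, sample, adduct = fields[0], fields[1], fields[2]
        if adduct not in ADDUCT_MASS:
            raise ValidationError(
                f"{path}: line {lineno}: unknown adduct label {adduct!r}"
            )
        try:
            area = float(fields[3])
            is_area = float(fields[4])
            litres = float(fields[5])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        if area < 0:
            raise ValidationError(f"{path}: line {lineno}: negative area")
        if is_area <= 0:
            raise ValidationError(
                f"{path}: line {lineno}: internal-standard area must be positive"
            )
        if litres <= 0:
            raise ValidationError(f"{path}: line {lineno}: litres must be positive")
        rows.append((lipid, sample, adduct, area, is_area, litres))
    df = pd.DataFrame(rows, columns=PEAK_HEADER)
    if df.duplicated(["lipid", "sample_depth_m", "adduct"]).any():
        raise ValidationError(f"{path}: duplicate (lipid, sample, adduct) rows")
    return df


def write_peak_table(path, peaks: pd.DataFrame) -> None:
    _write_rows(
        path,
        PEAK_HEADER,
        (
            (
                r.lipid,
                r.sample_depth_m,
                r.adduct,
                repr(float(r.area)),
                repr(float(r.is_area)),
                repr(float(r.litres)),
            )
            for r in peaks.itertuples()
        ),
    )


def read_presence_table(path) -> dict[tuple[str, str], list[str]]:
    """Read (family, unit) presence with contributing scaffolds."""
    out: dict[tuple[str, str], list[str]] = {}
    for lineno, fields in _data_rows(path):
        if fields and fields[0] == "family":
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields")
        out.setdefault((fields[0], fields[1]), []).append(fields[2])
    return {key: sorted(v) for key, v in out.items()}


def write_presence_table(path, presence: Mapping[tuple[str, str], list[str]]) -> None:
    rows = [
        (family, unit, scaffold)
        for (family, unit), scaffolds in sorted(presence.items())
        for scaffold in scaffolds
    ]
    _write_rows(path, ("family", "unit", "scaffold"), rows)


def read_profile_table(path) -> list[TaxonDepthProfile]:
    """Read taxon x gene profiles from long-format TSV."""
    acc: dict[tuple[str, str], dict[str, float]] = {}
    for lineno, fields in _data_rows(path):
        if fields and fields[0] == "taxon":
            continue
        if len(fields) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 fields")
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        acc.setdefault((fields[0], fields[1]), {})[fields[2]] = value
    return [
        TaxonDepthProfile(taxon, family, values)
        for (taxon, family), values in sorted(acc.items())
    ]


def write_profile_table(path, profiles: Iterable[TaxonDepthProfile]) -> None:
    rows = [
        (p.taxon, p.family, sample, repr(value))
        for p in profiles
        for sample, value in p.values.items()
    ]
    _write_rows(path, ("taxon", "family", "sample", "normalized_depth"), rows)


def read_lipid_profile_table(path) -> dict[str, dict[str, float]]:
    """Read lipid -> sample -> response units per litre."""
    out: dict[str, dict[str, float]] = {}
    for lineno, fields in _data_rows(path):
        if fields and fields[0] == "lipid":
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields")
        try:
            out.setdefault(fields[0], {})[fields[1]] = float(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_lipid_profile_table(path, profiles: Mapping[str, Mapping[str, float]]) -> None:
    rows = [
        (lipid, sample, repr(float(value)))
        for lipid, values in sorted(profiles.items())
        for sample, value in values.items()
    ]
    _write_rows(path, ("lipid", "sample", "response_per_litre"), rows)


def read_ani_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_ani_matrix(path, ani: pd.DataFrame) -> None:
    ani.to_csv(path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValidationError(f"{path}: duplicate sequence id {record.id!r}")
        out[record.id] = str(record.seq)
    return out


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=ident, description="")
        for ident, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
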