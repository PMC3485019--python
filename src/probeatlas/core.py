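"""Domain types, identifier scheme, standard-format I/O and assembly statistics.

The central object is the :class:`TranscriptomeAssembly`: isogroups (gene-level
isoform families) contain isotigs (assembled transcripts); reads the assembler
could not place are singletons.  Isogroups and singletons are the units of
probe uniqueness and coverage throughout the package.

Conventions used everywhere: sequences are uppercase over ``{A,C,G,T,N}``,
coordinates are 0-based half-open on the forward strand of the stored
sequence, and tables are tab-delimited UTF-8 with a header row and ``.`` for
missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
VALID_KINDS = frozenset(
    {"read", "est", "isotig", "singleton", "contig", "genome"}
)

#: Level infixes of the identifier scheme, e.g. ``CripIG000001`` for the
#: first isogroup of an assembly renamed with prefix ``Crip``.
LEVEL_INFIX = {"isogroup": "IG", "isotig": "IT", "singleton": "SI"}


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""


class SchemaError(ValueError):
    """Raised when a table does not match its declared schema."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with its role in the pipeline."""

    id: str
    sequence: str
    kind: str = "read"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.kind not in VALID_KINDS:
            raise ValueError(f"record {self.id!r}: unknown kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence


@dataclass
class TranscriptomeAssembly:
    """Isogroup → isotig structure plus unassembled singletons.

    ``isogroups`` maps isogroup id to the list of member isotig ids;
    ``isotigs`` and ``singletons`` map ids to their sequence records.
    ``contig_membership`` optionally records which contigs ("exons") each
    isotig is built from.
    """

    isogroups: dict[str, list[str]]
    isotigs: dict[str, SequenceRecord]
    singletons: dict[str, SequenceRecord] = field(default_factory=dict)
    contig_membership: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for ig, members in self.isogroups.items():
            for it in members:
                if it in seen:
                    raise ValueError(
                        f"isotig {it!r} in both {seen[it]!r} and {ig!r}"
                    )
                seen[it] = ig
        missing = set(self.isotigs) - set(seen)
        if missing:
            raise ValueError(f"isotigs without isogroup: {sorted(missing)}")
        orphan = set(seen) - set(self.isotigs)
        if orphan:
            raise ValueError(f"isogroup members without record: {sorted(orphan)}")
        overlap = set(self.isotigs) & set(self.singletons)
        if overlap:
            raise ValueError(
                f"ids present at both isotig and singleton level: {sorted(overlap)}"
            )

    @property
    def isogroup_of(self) -> dict[str, str]:
        """Inverse map: isotig id → its isogroup id."""
        return {
            it: ig for ig, members in self.isogroups.items() for it in members
        }

    def n_isotigs(self) -> int:
        return len(self.isotigs)

    def n_isogroups(self) -> int:
        return len(self.isogroups)

    def n_singletons(self) -> int:
        return len(self.singletons)


@dataclass
class AssemblyStats:
    """Per-level counts, base totals, N50s and structural means.

    Undefined statistics (empty level, zero denominator) are ``None`` —
    explicitly undefined rather than zero.
    """

    n_sequences: dict[str, int]
    total_bp: dict[str, int]
    n50: dict[str, int | None]
    mean_isotigs_per_isogroup: float | None
    mean_contigs_per_isotig: float | None = None


def read_fasta(path, kind: str = "read") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, uppercased.

    Raises :class:`FastaParseError` naming the line number for records with
    empty sequences or sequence data before any header.
    """
    records: list[SequenceRecord] = []
    # Manual line accounting wrapped around the same record grammar SeqIO
    # uses, so errors can name the offending line.
    header_line: int | None = None
    header_id: str | None = None
    chunks: list[str] = []

    def _flush(at_line: int) -> None:
        nonlocal header_id, chunks
        if header_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: record {header_id!r} at line {header_line} has an "
                "empty sequence"
            )
        records.append(SequenceRecord(header_id, seq, kind=kind))
        header_id, chunks = None, []

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                header_line = lineno
                header_id = line[1:].split()[0] if line[1:].strip() else None
                if header_id is None:
                    raise FastaParseError(
                        f"{path}: empty FASTA header at line {lineno}"
                    )
            else:
                if header_id is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                chunks.append(line)
        _flush(lineno)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FastaParseError(f"{path}: duplicate record ids {dupes}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write :class:`SequenceRecord` objects as FASTA (fixed line width)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def assign_ids(
    assembly: TranscriptomeAssembly, prefix: str
) -> tuple[TranscriptomeAssembly, dict[str, str]]:
    """Rename every isogroup/isotig/singleton to the canonical scheme.

    Ids become ``<prefix><infix><6-digit ordinal>`` (``CripIG000001`` style),
    ordinals 1-based in input order.  Returns the renamed assembly and the
    old → new id map (a bijection; apply its inverse to undo).
    """
    id_map: dict[str, str] = {}

    def _fmt(infix: str, ordinal: int, n_total: int) -> str:
        width = 6
        if n_total > 999_999:
            width = len(str(n_total))
            logger.warning(
                "more than 999,999 entities at level %s; id width grown to %d",
                infix,
                width,
            )
        return f"{prefix}{infix}{ordinal:0{width}d}"

    for i, ig in enumerate(assembly.isogroups, start=1):
        id_map[ig] = _fmt("IG", i, len(assembly.isogroups))
    for i, it in enumerate(assembly.isotigs, start=1):
        id_map[it] = _fmt("IT", i, len(assembly.isotigs))
    for i, si in enumerate(assembly.singletons, start=1):
        id_map[si] = _fmt("SI", i, len(assembly.singletons))

    renamed = TranscriptomeAssembly(
        isogroups={
            id_map[ig]: [id_map[it] for it in members]
            for ig, members in assembly.isogroups.items()
        },
        isotigs={
            id_map[it]: replace(rec, id=id_map[it])
            for it, rec in assembly.isotigs.items()
        },
        singletons={
            id_map[si]: replace(rec, id=id_map[si])
            for si, rec in assembly.singletons.items()
        },
        contig_membership=(
            None
            if assembly.contig_membership is None
            else {
                id_map[it]: list(contigs)
                for it, contigs in assembly.contig_membership.items()
            }
        ),
    )
    return renamed, id_map


def n50(lengths) -> int | None:
    """Weighted-median N50: half the bases lie in sequences ≥ this length.

    ``None`` for an empty collection (undefined, not zero).
    """
    lengths = sorted(int(x) for x in lengths)
    if not lengths:
        return None
    total = sum(lengths)
    acc = 0
    for length in reversed(lengths):
        acc += length
        if 2 * acc >= total:
            return length
    return lengths[0]  # pragma: no cover - loop always terminates above


def assembly_stats(assembly: TranscriptomeAssembly) -> AssemblyStats:
    """Summary statistics mirroring a transcriptome-assembly report table."""
    levels = {
        "isotig": list(assembly.isotigs.values()),
        "singleton": list(assembly.singletons.values()),
    }
    n_seq = {lvl: len(recs) for lvl, recs in levels.items()}
    n_seq["isogroup"] = len(assembly.isogroups)
    total = {lvl: sum(len(r) for r in recs) for lvl, recs in levels.items()}
    n50s = {lvl: n50(len(r) for r in recs) for lvl, recs in levels.items()}

    mean_iso = (
        len(assembly.isotigs) / len(assembly.isogroups)
        if assembly.isogroups
        else None
    )
    mean_contigs = None
    if assembly.contig_membership:
        counts = [len(v) for v in assembly.contig_membership.values()]
        if counts:
            mean_contigs = sum(counts) / len(counts)
    return AssemblyStats(
        n_sequences=n_seq,
        total_bp=total,
        n50=n50s,
        mean_isotigs_per_isogroup=mean_iso,
        mean_contigs_per_isotig=mean_contigs,
    )


MISSING = "."


def read_table(path, schema: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a tab-delimited table with a header row into typed columns.

    ``schema`` maps required column names to Python types (str/int/float/
    bool).  Missing columns raise :class:`SchemaError` listing all missing
    names; a cell that cannot be coerced raises an error naming its row.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        na_values=[MISSING],
        keep_default_na=False,
    )
    if schema is None:
        return df
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col, typ in schema.items():
        if typ is str:
            continue
        if typ is bool:
            df[col] = df[col].map(
                {"True": True, "False": False, "true": True, "false": False,
                 "1": True, "0": False}
            )
            continue
        try:
            df[col] = df[col].astype(float if typ is float else "Int64")
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = int(bad[0]) if len(bad) else -1
            raise SchemaError(
                f"{path}: column {col!r} has a non-{typ.__name__} value in "
                f"row {row} ({df[col].iloc[row]!r})"
            ) from None
        if typ is int:
            df[col] = df[col].astype("Int64")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as tab-delimited UTF-8, ``.`` for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_isogroup_mapping(path) -> dict[str, str]:
    """Read an isotig → isogroup mapping TSV (columns isotig_id, isogroup_id)."""
    df = read_table(path, {"isotig_id": str, "isogroup_id": str})
    return dict(zip(df["isotig_id"], df["isogroup_id"]))


def write_isogroup_mapping(assembly: TranscriptomeAssembly, path) -> None:
    rows = [
        {"isotig_id": it, "isogroup_id": ig}
        for ig, members in assembly.isogroups.items()
        for it in members
    ]
    write_table(pd.DataFrame(rows, columns=["isotig_id", "isogroup_id"]), path)
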