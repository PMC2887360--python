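"""Genome data model and readers/writers for the pipeline's flat-file inputs.

A *genome* here is an ordered list of protein-coding genes along one
replicon: each gene carries its locus tag, 1-based inclusive nucleotide
coordinates, strand, its 0-based rank in gene order, and the translated
protein sequence.  Domain evidence (pfam domain calls and whole-protein COG
assignments) is consumed from a pre-computed table rather than recomputed:
profile scanning against pfam/COG is an external published-tool step, and
every downstream rule in this package operates on the resulting accessions.

Three plain-text formats are supported:

* protein FASTA (one record per gene product),
* a GFF3 dialect whose CDS rows carry a ``locus_tag`` attribute,
* a tab-separated domain table with columns
  ``locus_tag  pfam  cog  dom_start  dom_end``.

Accessions are normalized to canonical zero-padded forms (``pfam00481``,
``PF481`` -> ``PF00481``; ``cog631`` -> ``COG0631``) because published
sources mix the spellings freely.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in protein sequences (20 canonical + ambiguity X)
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

_FORWARD_STRANDS = frozenset("+")
_REVERSE_STRANDS = frozenset({"-", "−"})  # ASCII hyphen and U+2212 minus
VALID_STRANDS = _FORWARD_STRANDS | _REVERSE_STRANDS


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class CrossReferenceError(ValueError):
    """Raised when FASTA, GFF and domain-table inputs disagree."""


@dataclass(frozen=True)
class Gene:
    """One protein-coding gene positioned on a replicon."""

    locus_tag: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive, end >= start
    strand: str  # '+' or '-' (U+2212 accepted and preserved)
    index: int  # 0-based rank in genome gene order
    protein: str

    def __post_init__(self) -> None:
        if not self.locus_tag:
            raise ValueError("locus_tag must be non-empty")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.locus_tag}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.locus_tag}: invalid strand {self.strand!r}")
        if not self.protein:
            raise ValueError(f"{self.locus_tag}: empty protein sequence")
        bad = set(self.protein) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"{self.locus_tag}: residues outside alphabet: {sorted(bad)}"
            )

    @property
    def is_reverse(self) -> bool:
        return self.strand in _REVERSE_STRANDS


@dataclass
class Genome:
    """An ordered gene list for one replicon, indexed by locus tag."""

    genome_id: str
    genes: list[Gene] = field(default_factory=list)
    _by_locus: dict[str, Gene] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_locus = {}
        starts = [g.start for g in self.genes]
        if starts != sorted(starts) or len(set(starts)) != len(starts):
            raise ValueError(f"{self.genome_id}: genes not strictly ordered by start")
        for i, g in enumerate(self.genes):
            if g.index != i:
                raise ValueError(
                    f"{self.genome_id}: gene {g.locus_tag} has index {g.index}, "
                    f"expected {i}"
                )
            if g.locus_tag in self._by_locus:
                raise ValueError(f"{self.genome_id}: duplicate locus {g.locus_tag}")
            self._by_locus[g.locus_tag] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._by_locus

    def gene(self, locus_tag: str) -> Gene:
        try:
            return self._by_locus[locus_tag]
        except KeyError:
            raise KeyError(f"{self.genome_id}: unknown locus {locus_tag}") from None

    @property
    def loci(self) -> list[str]:
        return [g.locus_tag for g in self.genes]

    def proteins(self) -> dict[str, str]:
        return {g.locus_tag: g.protein for g in self.genes}

    @property
    def total_residues(self) -> int:
        return sum(len(g.protein) for g in self.genes)


@dataclass(frozen=True)
class DomainCall:
    """One row of pfam/COG evidence for a locus.

    ``dom_start``/``dom_end`` are 1-based inclusive residue coordinates in
    the protein.  At least one of ``pfam``/``cog`` must be non-empty;
    accessions are stored normalized.
    """

    locus_tag: str
    pfam: str  # normalized 'PFxxxxx' / 'SMxxxxx' or ''
    cog: str  # normalized 'COGxxxx' or ''
    dom_start: int
    dom_end: int

    def __post_init__(self) -> None:
        if not self.pfam and not self.cog:
            raise ValueError(f"{self.locus_tag}: domain call with no pfam and no COG")
        if self.dom_start < 1 or self.dom_end < self.dom_start:
            raise ValueError(
                f"{self.locus_tag}: invalid domain coordinates "
                f"{self.dom_start}..{self.dom_end}"
            )

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(a for a in (self.pfam, self.cog) if a)


_PFAM_RE = re.compile(r"^(?:PF|PFAM)\s*0*([0-9]{1,5})$", re.IGNORECASE)
_SMART_RE = re.compile(r"^SM\s*0*([0-9]{1,5})$", re.IGNORECASE)
_COG_RE = re.compile(r"^COG\s*0*([0-9]{1,4})$", re.IGNORECASE)


def normalize_accession(accession: str) -> str:
    """Canonicalize a pfam/SMART/COG accession.

    ``pfam00481``, ``PF481`` and ``PF00481`` all normalize to ``PF00481``
    (5-digit zero-pad); ``cog631`` to ``COG0631`` (4-digit); SMART ids to
    ``SMxxxxx``.  Empty input stays empty; anything unrecognized raises.
    """
    acc = accession.strip()
    if not acc:
        return ""
    m = _PFAM_RE.match(acc)
    if m:
        return f"PF{int(m.group(1)):05d}"
    m = _SMART_RE.match(acc)
    if m:
        return f"SM{int(m.group(1)):05d}"
    m = _COG_RE.match(acc)
    if m:
        return f"COG{int(m.group(1)):04d}"
    raise ValueError(f"unrecognized accession: {accession!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased, whitespace is stripped, and a single terminal
    ``*`` stop character is removed.  Malformed headers or records with an
    empty sequence raise :class:`ParseError` naming the offending line.
    """
    records: list[tuple[str, str]] = []
    current_id: str | None = None
    current_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ParseError(
                f"{path}: empty sequence for record {current_id!r} "
                f"(header at line {current_line})"
            )
        records.append((current_id, seq))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                current_id = header.split()[0]
                current_line = lineno
                chunks = []
            else:
                if current_id is None:
                    raise ParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                chunks.append(line.replace(" ", "").replace("\t", ""))
        _flush()
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF


_GFF_FEATURE_TYPES = frozenset({"CDS", "gene"})


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff(
    path: str | Path,
    fasta_records: Iterable[tuple[str, str]],
    genome_id: str | None = None,
) -> Genome:
    """Assemble a :class:`Genome` from a GFF3 coordinate table plus proteins.

    Only CDS/gene feature rows are considered (pseudogene and RNA features,
    if present, are ignored for gene-distance purposes).  Every feature's
    ``locus_tag`` attribute must match a FASTA record id and vice versa;
    mismatches raise :class:`CrossReferenceError` listing all offenders.
    Genes are sorted by start coordinate and assigned contiguous 0-based
    indices regardless of the row order in the file.
    """
    proteins = dict(fasta_records)
    if len(proteins) != len(list(proteins)):  # pragma: no cover - dict dedup
        raise CrossReferenceError(f"{path}: duplicate FASTA ids")

    rows: list[tuple[str, int, int, str]] = []
    seqid: str | None = None
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if fields[2] not in _GFF_FEATURE_TYPES:
                continue
            attrs = _parse_attributes(fields[8])
            locus = attrs.get("locus_tag", "")
            if not locus:
                raise ParseError(f"{path}: line {lineno}: missing locus_tag attribute")
            if locus in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate locus_tag {locus}")
            seen.add(locus)
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            rows.append((locus, start, end, fields[6]))
            if seqid is None:
                seqid = fields[0]

    gff_loci = {r[0] for r in rows}
    missing_fasta = sorted(gff_loci - proteins.keys())
    missing_gff = sorted(proteins.keys() - gff_loci)
    if missing_fasta or missing_gff:
        raise CrossReferenceError(
            f"{path}: GFF loci without FASTA record: {missing_fasta}; "
            f"FASTA ids without GFF row: {missing_gff}"
        )

    rows.sort(key=lambda r: r[1])
    genes = [
        Gene(locus_tag=locus, start=start, end=end, strand=strand, index=i,
             protein=proteins[locus])
        for i, (locus, start, end, strand) in enumerate(rows)
    ]
    return Genome(genome_id=genome_id or seqid or str(path), genes=genes)


def write_gff(path: str | Path, genome: Genome, source: str = "phosphatome") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in genome:
            fh.write(
                "\t".join(
                    [
                        genome.genome_id,
                        source,
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        f"ID={g.locus_tag};locus_tag={g.locus_tag}",
                    ]
                )
                + "\n"
            )


def write_genome(directory: str | Path, genome: Genome) -> tuple[Path, Path]:
    """Write ``<id>.faa`` and ``<id>.gff`` for a genome; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    faa = directory / f"{genome.genome_id}.faa"
    gff = directory / f"{genome.genome_id}.gff"
    write_fasta(faa, [(g.locus_tag, g.protein) for g in genome])
    write_gff(gff, genome)
    return faa, gff


def read_genome(directory: str | Path, genome_id: str) -> Genome:
    directory = Path(directory)
    records = read_fasta(directory / f"{genome_id}.faa")
    return read_gff(directory / f"{genome_id}.gff", records, genome_id=genome_id)


# ---------------------------------------------------------------------------
# Domain table


DOMAIN_TABLE_COLUMNS = ("locus_tag", "pfam", "cog", "dom_start", "dom_end")


def read_domain_table(
    path: str | Path,
    proteins: Mapping[str, str] | Genome | None = None,
) -> list[DomainCall]:
    """Read a TSV of domain calls; one :class:`DomainCall` per row.

    Accessions are normalized (see :func:`normalize_accession`).  When
    ``proteins`` is supplied (a mapping locus->sequence or a Genome) domain
    coordinates are validated against protein lengths.
    """
    if isinstance(proteins, Genome):
        proteins = proteins.proteins()
    calls: list[DomainCall] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != DOMAIN_TABLE_COLUMNS:
            raise ParseError(
                f"{path}: expected header {list(DOMAIN_TABLE_COLUMNS)}, got {header}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns")
            locus, pfam, cog, s, e = fields
            try:
                call = DomainCall(
                    locus_tag=locus,
                    pfam=normalize_accession(pfam),
                    cog=normalize_accession(cog),
                    dom_start=int(s),
                    dom_end=int(e),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if proteins is not None:
                if locus not in proteins:
                    raise CrossReferenceError(
                        f"{path}: line {lineno}: locus {locus} has no protein"
                    )
                plen = len(proteins[locus])
                if call.dom_end > plen:
                    raise ParseError(
                        f"{path}: line {lineno}: domain end {call.dom_end} exceeds "
                        f"protein length {plen} for {locus}"
                    )
            calls.append(call)
    return calls


def write_domain_table(path: str | Path, calls: Iterable[DomainCall]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(DOMAIN_TABLE_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.locus_tag}\t{c.pfam}\t{c.cog}\t{c.dom_start}\t{c.dom_end}\n"
            )


def calls_by_locus(calls: Iterable[DomainCall]) -> dict[str, list[DomainCall]]:
    """Group domain calls by locus tag, preserving row order within a locus."""
    grouped: dict[str, list[DomainCall]] = {}
    for c in calls:
        grouped.setdefault(c.locus_tag, []).append(c)
    return grouped
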