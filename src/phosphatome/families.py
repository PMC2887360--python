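"""Kinase/phosphatase family classification from pfam + COG evidence.

Families and their evidence requirements (the shipped default schema):

========================  ==========  ===========
family                    pfam        COG
========================  ==========  ===========
PP2C (PP2c-type PP)       PF00481     COG0631
SPOIIE (SpoIIE-like PP)   PF07228     COG2208
PPP_CANDIDATE             PF00149     COG0639
PTP                       --          COG2453
LOW_MW_PTP                --          COG0394
DSP_PTP                   --          COG2365
PTP_OTHER                 --          COG4551 or COG5350
PTPZ (PHP family)         --          COG4464
ELK                       --          COG0515
NON_ELK_KINASE            --          COG2172
ANTI_ANTI_SIGMA           --          COG1366
RHODANESE                 --          COG0607
========================  ==========  ===========

A schema row matches when its pfam requirements AND its COG requirements
are both subsets of the locus's evidence; rows are evaluated in priority
order and the first match wins.  PF00149 without COG0639 marks a
calcineurin-like protein that is *not* a phosphatase (nucleotidases,
phosphodiesterases, nucleases share the fold) and classifies as OTHER.

PPP candidates (PF00149 + COG0639) are subtyped by motif content: the
(I/L/V)D(S/T)G motif confirms a genuine PPP (APAH_CANDIDATE otherwise,
i.e. a putative diadenosine tetraphosphatase), and a protein carrying all
four signature motifs is CONSENSUS_COMPLETE.  Rhodanese proteins are
additionally screened for the Cdc25 active-site motif and flagged
CDC25_NEGATIVE when it is absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_io import DomainCall, Gene, Genome, calls_by_locus, normalize_accession
from .motifs import CDC25_MOTIF, PppMotifFlags, check_ppp_motifs, contains

# Family labels
PP2C = "PP2C"
SPOIIE = "SPOIIE"
PPP_CANDIDATE = "PPP_CANDIDATE"
PTP = "PTP"
LOW_MW_PTP = "LOW_MW_PTP"
DSP_PTP = "DSP_PTP"
PTP_OTHER = "PTP_OTHER"
PTPZ = "PTPZ"
ELK = "ELK"
NON_ELK_KINASE = "NON_ELK_KINASE"
ANTI_ANTI_SIGMA = "ANTI_ANTI_SIGMA"
RHODANESE = "RHODANESE"
OTHER = "OTHER"

#: protein phosphatase families (PTPZ included; analyses that follow the
#: convention of excluding PtpZ-like proteins do so explicitly)
PP_FAMILIES = frozenset(
    {PP2C, SPOIIE, PPP_CANDIDATE, PTP, LOW_MW_PTP, DSP_PTP, PTP_OTHER, PTPZ}
)
#: the PTP class summed in summary tables (PtpZ-like excluded by convention)
PTP_CLASS_FAMILIES = frozenset({PTP, LOW_MW_PTP, DSP_PTP, PTP_OTHER})
KINASE_FAMILIES = frozenset({ELK, NON_ELK_KINASE})

# Subtype flags
PPP_CONFIRMED = "PPP_CONFIRMED"
APAH_CANDIDATE = "APAH_CANDIDATE"
CDC25_NEGATIVE = "CDC25_NEGATIVE"
CONSENSUS_COMPLETE = "CONSENSUS_COMPLETE"

# Fusion (accessory-domain) flags and their accessions
FUSION_ACCESSIONS: dict[str, str] = {
    "PF00027": "cNMP",  # cyclic nucleotide-monophosphate binding
    "SM00100": "cNMP",  # SMART accession for the same domain
    "PF00672": "HAMP",
    "PF00498": "FHA",
    "PF01590": "GAF",
    "PF00532": "PBD",  # periplasmic binding domain
    "PF01740": "STAS",  # anti-anti-sigma factor domain (COG1366-associated)
}

#: catalytic phosphatase evidence: a fusion flag is only meaningful when one
#: of these co-occurs on the same locus
CATALYTIC_PHOSPHATASE_ACCESSIONS = frozenset(
    {
        "PF00481", "PF07228", "PF00149",
        "COG0631", "COG2208", "COG0639",
        "COG2453", "COG0394", "COG2365", "COG4551", "COG5350", "COG4464",
    }
)

_CALCINEURIN_PFAM = "PF00149"
_PPP_COG = "COG0639"


@dataclass(frozen=True)
class SchemaRow:
    family: str
    pfam: frozenset[str]
    cog: frozenset[str]

    def matches(self, pfams: frozenset[str], cogs: frozenset[str]) -> bool:
        return self.pfam <= pfams and self.cog <= cogs


@dataclass
class FamilySchema:
    """Ordered classification rules; earlier rows take priority."""

    rows: list[SchemaRow]

    def __post_init__(self) -> None:
        labels = [r.family for r in self.rows]
        # PTP_OTHER legitimately has two rows (COG4551 / COG5350)
        for label in set(labels):
            dup = [r for r in self.rows if r.family == label]
            if len(dup) > 1 and {frozenset(r.cog) for r in dup} == {dup[0].cog}:
                raise ValueError(f"duplicate identical schema rows for {label}")

    @classmethod
    def default(cls) -> "FamilySchema":
        f = frozenset
        return cls(
            rows=[
                SchemaRow(PP2C, f({"PF00481"}), f({"COG0631"})),
                SchemaRow(SPOIIE, f({"PF07228"}), f({"COG2208"})),
                SchemaRow(PPP_CANDIDATE, f({"PF00149"}), f({"COG0639"})),
                SchemaRow(PTP, f(), f({"COG2453"})),
                SchemaRow(LOW_MW_PTP, f(), f({"COG0394"})),
                SchemaRow(DSP_PTP, f(), f({"COG2365"})),
                SchemaRow(PTP_OTHER, f(), f({"COG4551"})),
                SchemaRow(PTP_OTHER, f(), f({"COG5350"})),
                SchemaRow(PTPZ, f(), f({"COG4464"})),
                SchemaRow(ELK, f(), f({"COG0515"})),
                SchemaRow(NON_ELK_KINASE, f(), f({"COG2172"})),
                SchemaRow(ANTI_ANTI_SIGMA, f(), f({"COG1366"})),
                SchemaRow(RHODANESE, f(), f({"COG0607"})),
            ]
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilySchema":
        rows: list[SchemaRow] = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["family", "pfam_csv", "cog_csv", "priority"]:
                raise ValueError(
                    f"{path}: expected header family, pfam_csv, cog_csv, priority"
                )
            parsed = []
            for raw in fh:
                line = raw.rstrip("\n")
                if not line:
                    continue
                family, pfam_csv, cog_csv, priority = line.split("\t")
                parsed.append(
                    (
                        int(priority),
                        SchemaRow(
                            family,
                            frozenset(
                                normalize_accession(a)
                                for a in pfam_csv.split(",")
                                if a.strip()
                            ),
                            frozenset(
                                normalize_accession(a)
                                for a in cog_csv.split(",")
                                if a.strip()
                            ),
                        ),
                    )
                )
        parsed.sort(key=lambda t: t[0])
        rows = [r for _, r in parsed]
        return cls(rows=rows)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("family\tpfam_csv\tcog_csv\tpriority\n")
            for i, r in enumerate(self.rows):
                fh.write(
                    f"{r.family}\t{','.join(sorted(r.pfam))}\t"
                    f"{','.join(sorted(r.cog))}\t{i}\n"
                )


@dataclass
class FamilyAssignment:
    """Classification result for one locus."""

    locus_tag: str
    family: str
    evidence: list[SchemaRow] = field(default_factory=list)
    motif_flags: PppMotifFlags | None = None
    fusion_flags: frozenset[str] = frozenset()
    subtype_flags: frozenset[str] = frozenset()
    note: str = ""

    @property
    def is_phosphatase(self) -> bool:
        return self.family in PP_FAMILIES

    @property
    def is_kinase(self) -> bool:
        return self.family in KINASE_FAMILIES


def _evidence_sets(
    calls: Sequence[DomainCall],
) -> tuple[frozenset[str], frozenset[str]]:
    pfams = frozenset(c.pfam for c in calls if c.pfam)
    cogs = frozenset(c.cog for c in calls if c.cog)
    return pfams, cogs


def detect_fusions(calls: Sequence[DomainCall]) -> frozenset[str]:
    """Accessory-domain fusion flags for one locus.

    A flag is raised only when the accessory domain co-occurs with catalytic
    phosphatase evidence on the same locus — an accessory domain alone does
    not make a fusion protein.
    """
    pfams, cogs = _evidence_sets(calls)
    accessions = pfams | cogs
    if not accessions & CATALYTIC_PHOSPHATASE_ACCESSIONS:
        return frozenset()
    return frozenset(
        flag for acc, flag in FUSION_ACCESSIONS.items() if acc in accessions
    )


def assign_family(
    gene: Gene,
    calls: Sequence[DomainCall],
    schema: FamilySchema | None = None,
) -> FamilyAssignment:
    """Classify one gene product from its domain calls.

    The first schema row whose pfam and COG requirements are both present
    wins.  See module docstring for the PF00149, PPP-subtype and rhodanese
    special rules.
    """
    schema = schema or FamilySchema.default()
    for c in calls:
        if c.locus_tag != gene.locus_tag:
            raise ValueError(
                f"call for {c.locus_tag} passed with gene {gene.locus_tag}"
            )
    pfams, cogs = _evidence_sets(calls)
    matched = [row for row in schema.rows if row.matches(pfams, cogs)]

    fusion = detect_fusions(calls)
    if not matched:
        note = ""
        if _CALCINEURIN_PFAM in pfams and _PPP_COG not in cogs:
            note = "calcineurin-like non-phosphatase"
        return FamilyAssignment(
            locus_tag=gene.locus_tag,
            family=OTHER,
            evidence=[],
            fusion_flags=fusion,
            note=note,
        )

    family = matched[0].family
    motif_flags: PppMotifFlags | None = None
    subtype: set[str] = set()
    note = ""

    if family == PPP_CANDIDATE:
        motif_flags = check_ppp_motifs(gene.protein)
        if motif_flags.consensus_complete:
            subtype.add(CONSENSUS_COMPLETE)
        elif motif_flags.ILV_DST_G:
            subtype.add(PPP_CONFIRMED)
        else:
            subtype.add(APAH_CANDIDATE)
    elif family == RHODANESE:
        if not contains(gene.protein, CDC25_MOTIF):
            subtype.add(CDC25_NEGATIVE)
    elif family == LOW_MW_PTP:
        # arsenate reductase (ArsC) shares fold and COG with low-MW PTPs;
        # phosphatase activity is not certain without experimental evidence
        note = "ArsC-like ambiguity: low-MW PTP call is provisional"

    return FamilyAssignment(
        locus_tag=gene.locus_tag,
        family=family,
        evidence=matched[:1],
        motif_flags=motif_flags,
        fusion_flags=fusion,
        subtype_flags=frozenset(subtype),
        note=note,
    )


def classify_genome(
    genome: Genome,
    calls: Iterable[DomainCall] | Mapping[str, Sequence[DomainCall]],
    schema: FamilySchema | None = None,
) -> list[FamilyAssignment]:
    """Classify every gene in a genome; genes with no calls become OTHER."""
    schema = schema or FamilySchema.default()
    if isinstance(calls, Mapping):
        grouped = {k: list(v) for k, v in calls.items()}
    else:
        grouped = calls_by_locus(calls)
    return [
        assign_family(gene, grouped.get(gene.locus_tag, []), schema)
        for gene in genome
    ]


def assignments_by_locus(
    assignments: Iterable[FamilyAssignment],
) -> dict[str, FamilyAssignment]:
    return {a.locus_tag: a for a in assignments}


def family_counts(assignments: Iterable[FamilyAssignment]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.family] = counts.get(a.family, 0) + 1
    return counts


ASSIGNMENT_TABLE_COLUMNS = (
    "locus_tag", "family", "evidence", "fusion_flags", "subtype_flags", "note",
)


def write_assignments(path: str | Path, assignments: Iterable[FamilyAssignment]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ASSIGNMENT_TABLE_COLUMNS) + "\n")
        for a in assignments:
            evidence = ";".join(
                ",".join(sorted(r.pfam | r.cog)) for r in a.evidence
            )
            fh.write(
                f"{a.locus_tag}\t{a.family}\t{evidence}\t"
                f"{','.join(sorted(a.fusion_flags))}\t"
                f"{','.join(sorted(a.subtype_flags))}\t{a.note}\n"
            )
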