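"""V-gene germline reference sets: reading, filtering, trimming, collapsing.

A germline reference set is the catalog of known V allele sequences used to
annotate rearranged receptor reads.  Sequences are handled in IMGT unique
numbering: a fixed, 1-based gapped coordinate system in which '.' marks an
alignment gap.  All position arguments (e.g. the 3' trim point 318) refer to
gapped coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, DuplicateAlleleError, EmptyReferenceError

#: IMGT position through which full-length V amplicons are compared.  Allelic
#: variation beyond this point cannot be observed reliably in repertoire reads
#: because the 3' end of the V is trimmed during V(D)J recombination.
DEFAULT_TRIM_END = 318

FUNCTIONAL = "functional"
ORF = "ORF"
PSEUDOGENE = "pseudogene"
UNKNOWN = "unknown"

_ALLELE_RE = re.compile(r"^(IG[HKL][VDJ]|TR[ABGD][VDJ])[\w.\-/()]*\*\d+", re.I)
_SUBGROUP_RE = re.compile(r"^([A-Za-z]+\d*)")

# IMGT FASTA functionality tokens, with the "(F)"/"[F]" bracket variants that
# mark in-frame pseudogene calls etc.
_FUNC_TOKENS = {
    "F": FUNCTIONAL,
    "(F)": FUNCTIONAL,
    "[F]": FUNCTIONAL,
    "ORF": ORF,
    "(ORF)": ORF,
    "[ORF]": ORF,
    "P": PSEUDOGENE,
    "(P)": PSEUDOGENE,
    "[P]": PSEUDOGENE,
}


def natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically ('IGHV3-9' < 'IGHV3-64')."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", name)
    )


@dataclass(frozen=True)
class GermlineAllele:
    """One named germline V allele.

    ``gapped_sequence`` is the sequence in IMGT unique numbering ('.' = gap);
    ``sequence`` is the same sequence with gaps removed.  ``gene`` and
    ``subgroup`` are derived from the IUIS name (``IGHV3-64*02`` -> gene
    ``IGHV3-64``, subgroup ``IGHV3``).
    """

    iuis_name: str
    sequence: str
    gapped_sequence: str | None = None
    functionality: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for allele {self.iuis_name!r}")
        if self.gapped_sequence is not None:
            ungapped = self.gapped_sequence.replace(".", "")
            if ungapped.upper() != self.sequence.upper():
                raise ValueError(
                    f"{self.iuis_name}: sequence does not equal "
                    "gapped_sequence with gaps removed"
                )

    @property
    def gene(self) -> str:
        return self.iuis_name.split("*")[0]

    @property
    def subgroup(self) -> str:
        m = _SUBGROUP_RE.match(self.gene)
        return m.group(1) if m else self.gene

    @property
    def coverage_start(self) -> int | None:
        """First covered IMGT position (1-based), or None if ungapped."""
        if self.gapped_sequence is None:
            return None
        stripped = self.gapped_sequence.lstrip(".")
        return len(self.gapped_sequence) - len(stripped) + 1

    @property
    def coverage_end(self) -> int | None:
        """Last covered IMGT position, ignoring trailing gap padding."""
        if self.gapped_sequence is None:
            return None
        return len(self.gapped_sequence.rstrip("."))


@dataclass
class GermlineReference:
    """An ordered, uniquely named collection of germline alleles."""

    alleles: list[GermlineAllele]
    amplicon_class: str = "custom"
    trim_end: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [a.iuis_name for a in self.alleles]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DuplicateAlleleError(
                f"duplicate allele names: {sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)

    def __getitem__(self, name: str) -> GermlineAllele:
        for a in self.alleles:
            if a.iuis_name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.iuis_name for a in self.alleles]

    @property
    def is_gapped(self) -> bool:
        return all(a.gapped_sequence is not None for a in self.alleles)

    def _with(self, alleles: list[GermlineAllele], **kw) -> "GermlineReference":
        new = replace(self, alleles=alleles)
        for k, v in kw.items():
            setattr(new, k, v)
        return new


@dataclass(frozen=True)
class AmpliconSpec:
    """A sequencing-protocol window on the V region, in IMGT positions.

    ``S1`` is the full-length amplicon (positions 1-318).  5'-partial
    protocols (BIOMED-2-style FW1/FW2 priming, ImmunoSeq-style minimal V
    coverage) are modelled as later ``five_prime_start`` values; the exact
    primer coordinates are protocol- and kit-specific, so the bundled S2/S3
    starts are documented approximations meant to be overridden.
    """

    name: str
    five_prime_start: int = 1
    three_prime_end: int = DEFAULT_TRIM_END

    def __post_init__(self) -> None:
        if not 1 <= self.five_prime_start < self.three_prime_end:
            raise ValueError(
                f"invalid amplicon window [{self.five_prime_start}, "
                f"{self.three_prime_end}]"
            )


#: Full-length amplicon.
S1 = AmpliconSpec("S1", 1, DEFAULT_TRIM_END)
#: BIOMED-2-style FW2-primed coverage (approximate start; override per assay).
S2 = AmpliconSpec("S2", 115, DEFAULT_TRIM_END)
#: ImmunoSeq-style minimal 3' V coverage (approximate start).
S3 = AmpliconSpec("S3", 280, DEFAULT_TRIM_END)


def _parse_header(description: str) -> tuple[str, str]:
    """Extract (iuis_name, functionality) from a FASTA header.

    Supports both plain headers (``>IGHV3-64*02``) and IMGT pipe-delimited
    headers, in which the allele name and the functionality token each occupy
    one of the 16 fields.
    """
    if "|" in description:
        fields = [f.strip() for f in description.split("|")]
        name = next((f for f in fields if _ALLELE_RE.match(f)), fields[0])
        func = next(
            (_FUNC_TOKENS[f] for f in fields if f in _FUNC_TOKENS), UNKNOWN
        )
        return name, func
    return description.split()[0], UNKNOWN


def read_functionality_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of allele name -> functionality."""
    table: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, func = line.split("\t")[:2]
        func = func.strip()
        table[name.strip()] = _FUNC_TOKENS.get(func, func)
    return table


def read_germline_fasta(
    path: str | Path,
    functionality_table: str | Path | Mapping[str, str] | None = None,
    aligned_from_position_1: bool = False,
    amplicon_class: str = "custom",
) -> GermlineReference:
    """Read a V germline reference set from FASTA.

    Gapped (IMGT '.'-containing) input is auto-detected.  Ungapped input
    carries no IMGT coordinates; pass ``aligned_from_position_1=True`` to
    declare that every sequence starts at IMGT position 1 with no internal
    gaps, which makes position-based operations meaningful.

    Parameters
    ----------
    functionality_table
        Optional TSV path or mapping of allele name -> functionality used
        when the FASTA headers carry no IMGT functionality field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    if functionality_table is not None and not isinstance(
        functionality_table, Mapping
    ):
        functionality_table = read_functionality_table(functionality_table)

    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        name, func = _parse_header(rec.description)
        if functionality_table and name in functionality_table:
            func = functionality_table[name]
        gapped = raw if ("." in raw or aligned_from_position_1) else None
        alleles.append(
            GermlineAllele(
                iuis_name=name,
                sequence=raw.replace(".", ""),
                gapped_sequence=gapped,
                functionality=func,
            )
        )
    if not alleles:
        raise EmptyReferenceError(f"no FASTA records in {path}")
    return GermlineReference(
        alleles=alleles, amplicon_class=amplicon_class, provenance=str(path)
    )


def write_germline_fasta(
    ref: GermlineReference, path: str | Path, gapped: bool = False
) -> None:
    records = [
        SeqRecord(
            Seq(a.gapped_sequence if gapped and a.gapped_sequence else a.sequence),
            id=a.iuis_name,
            description="",
        )
        for a in ref
    ]
    SeqIO.write(records, str(path), "fasta")


def filter_functional(
    ref: GermlineReference, strict: bool = False
) -> tuple[GermlineReference, list[str]]:
    """Keep functional alleles; return (filtered reference, removed names).

    Pseudogenes and ORFs are discarded.  Alleles of ``unknown`` functionality
    are kept by default and discarded only under ``strict=True``.
    """
    keep_unknown = not strict
    kept, removed = [], []
    for a in ref:
        if a.functionality == FUNCTIONAL or (
            a.functionality == UNKNOWN and keep_unknown
        ):
            kept.append(a)
        else:
            removed.append(a.iuis_name)
    return ref._with(kept), removed


def _require_gapped(ref: GermlineReference, op: str) -> None:
    if not ref.is_gapped:
        raise CoordinateError(
            f"{op} needs IMGT numbering: input is ungapped and was not "
            "declared aligned from position 1 "
            "(read_germline_fasta(..., aligned_from_position_1=True))"
        )


def filter_complete_v(
    ref: GermlineReference, end: int = DEFAULT_TRIM_END
) -> GermlineReference:
    """Keep alleles covering IMGT position 1 through at least ``end``.

    5'-truncated records and records too short at the 3' end are dropped so
    that every retained sequence carries equivalent sequence content for the
    pairwise comparisons downstream.
    """
    _require_gapped(ref, "filter_complete_v")
    kept = [
        a
        for a in ref
        if a.coverage_start == 1 and (a.coverage_end or 0) >= end
    ]
    return ref._with(kept)


def trim_three_prime(
    ref: GermlineReference, end: int = DEFAULT_TRIM_END
) -> GermlineReference:
    """Truncate every sequence at IMGT position ``end`` (inclusive)."""
    _require_gapped(ref, "trim_three_prime")
    trimmed = []
    for a in ref:
        if (a.coverage_end or 0) < end:
            raise CoordinateError(
                f"{a.iuis_name} covers only through position "
                f"{a.coverage_end}; cannot trim at {end}"
            )
        g = a.gapped_sequence[:end]
        trimmed.append(replace(a, gapped_sequence=g, sequence=g.replace(".", "")))
    return ref._with(trimmed, trim_end=end)


def make_amplicon_variant(
    ref: GermlineReference, spec: AmpliconSpec
) -> GermlineReference:
    """Restrict sequences to the amplicon window [start, end] of ``spec``.

    Emulates a partial-coverage sequencing protocol by discarding germline
    content outside the window; distinct alleles whose differences lie
    outside the window become identical, which is exactly the ambiguity such
    protocols impose.
    """
    _require_gapped(ref, "make_amplicon_variant")
    out = []
    for a in ref:
        if (a.coverage_end or 0) < spec.three_prime_end:
            raise CoordinateError(
                f"{a.iuis_name}: window end {spec.three_prime_end} exceeds "
                f"coverage ({a.coverage_end})"
            )
        g = a.gapped_sequence[spec.five_prime_start - 1 : spec.three_prime_end]
        seq = g.replace(".", "")
        if not seq:
            raise CoordinateError(
                f"{a.iuis_name}: amplicon window contains no nucleotides"
            )
        out.append(replace(a, gapped_sequence=g, sequence=seq))
    new = ref._with(out, trim_end=spec.three_prime_end)
    new.amplicon_class = spec.name
    return new


def collapse_identical(
    ref: GermlineReference,
) -> tuple[GermlineReference, dict[str, list[str]]]:
    """Collapse alleles with identical (ungapped) sequences.

    Identical sequences arise from gene duplications in the locus: the same
    allele sequence can reside at more than one chromosomal position and so
    carries several IUIS names.  One record is kept per unique sequence; the
    representative is the natural-sort-smallest IUIS name, and the returned
    mapping lists every merged name per representative.
    """
    groups: dict[str, list[GermlineAllele]] = {}
    order: list[str] = []
    for a in ref:
        key = a.sequence.upper()
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)

    kept, mapping = [], {}
    for key in order:
        members = sorted(groups[key], key=lambda a: natural_key(a.iuis_name))
        rep = members[0]
        kept.append(rep)
        mapping[rep.iuis_name] = [m.iuis_name for m in members]
    return ref._with(kept), mapping


def expand_mapping(mapping: Mapping[str, list[str]]) -> list[str]:
    """All input names covered by a collapse mapping (for round trips)."""
    return [name for merged in mapping.values() for name in merged]


def extend_to_full_length(
    asc_ref: GermlineReference,
    original: GermlineReference,
    names: Mapping[str, str] | None = None,
) -> GermlineReference:
    """Restore original 3' ends on a trimmed (and possibly renamed) reference.

    The reference exported for aligners must carry full-length sequences even
    though clustering was done on 3'-trimmed ones.  Each trimmed sequence is
    traced to the original alleles whose trimmed form matches it.  When a
    collapsed group contains originals that differ beyond the trim point
    (e.g. the IGHV3-66*01/*04 pair, distinct only at position 319), every
    distinct full-length sequence is emitted under the same exported name
    with a numeric suffix, flagged as 3'-ambiguous in the provenance.
    """
    if asc_ref.trim_end is None:
        raise CoordinateError("asc_ref has no recorded trim_end to extend from")
    _require_gapped(original, "extend_to_full_length")
    end = asc_ref.trim_end

    by_trimmed: dict[str, list[GermlineAllele]] = {}
    for a in original:
        by_trimmed.setdefault(
            a.gapped_sequence[:end].replace(".", "").upper(), []
        ).append(a)

    out, flagged = [], []
    for a in asc_ref:
        sources = by_trimmed.get(a.sequence.upper())
        if not sources:
            raise KeyError(
                f"{a.iuis_name}: trimmed sequence not traceable to any "
                "original allele"
            )
        exported_name = names.get(a.iuis_name, a.iuis_name) if names else a.iuis_name
        # unique full-length sequences among the sources, original order
        full_seqs: list[str] = []
        for s in sources:
            if s.sequence.upper() not in [f.upper() for f in full_seqs]:
                full_seqs.append(s.sequence)
        if len(full_seqs) == 1:
            # prefer the source carrying the same name (plain trim round trip)
            src = next(
                (s for s in sources if s.iuis_name == a.iuis_name), sources[0]
            )
            out.append(replace(src, iuis_name=exported_name))
        else:
            flagged.append(exported_name)
            seen: list[str] = []
            distinct: list[GermlineAllele] = []
            for s in sorted(sources, key=lambda x: natural_key(x.iuis_name)):
                if s.sequence.upper() not in seen:
                    seen.append(s.sequence.upper())
                    distinct.append(s)
            for i, s in enumerate(distinct, start=1):
                out.append(replace(s, iuis_name=f"{exported_name}_{i}"))
    prov = (original.provenance + "; extended to full length").strip("; ")
    if flagged:
        prov += "; 3'-ambiguous: " + ",".join(flagged)
    new = asc_ref._with(out, trim_end=None)
    new.provenance = prov
    return new


def write_collapse_mapping(
    mapping: Mapping[str, list[str]],
    ref: GermlineReference,
    path: str | Path,
) -> None:
    """Write the collapse mapping as TSV (representative, merged, sequence)."""
    seqs = {a.iuis_name: a.sequence for a in ref}
    lines = ["asc_representative\tmerged_iuis_names\tsequence"]
    for rep, merged in mapping.items():
        lines.append(f"{rep}\t{';'.join(merged)}\t{seqs[rep]}")
    Path(path).write_text("\n".join(lines) + "\n")
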