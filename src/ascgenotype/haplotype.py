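"""Haplotype evidence and allele-specific threshold tuning.

A subject heterozygous at an anchor gene (typically IGHJ6) lets V alleles be
attributed to chromosomes: each read rearranges one V with one J, so V
usage can be partitioned by the J allele it co-occurs with.  Finding two
alleles of the same gene on opposite chromosomes is strong evidence both
are real, even when one is expressed near the detection limit.

The module also implements a dominance sanity check (is it plausible that
the population-rare allele of a cluster outnumbers the population-dominant
one in a sample?) and the advisory three-case procedure for tuning
allele-specific absolute-usage thresholds against population usage and
haplotype evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import binom

from .clustering import ASCReference, KeyTable, translate_call
from .errors import AscGenotypeError, NotHaplotypableError
from .genotype import (
    AlleleUsage,
    NearestAllele,
    ThresholdTable,
    novel_allele_threshold,
)
from .repertoire import RearrangementTable, parse_call

DEFAULT_ANCHOR_GENE = "IGHJ6"

#: An allele is "expressed at levels significantly higher than threshold"
#: (raise case) when every carrier's frequency exceeds this multiple of it.
CASE1_RATIO = 10.0
#: Raised thresholds target this fraction of the lowest carrier frequency,
#: staying strictly below the lowest expression level observed.
CASE1_RAISE_FACTOR = 0.9


@dataclass
class HaplotypeCounts:
    """V-allele fractional counts split by anchor allele (chromosome)."""

    subject_id: str
    anchor_gene: str
    anchor_alleles: tuple[str, str]
    matrix: pd.DataFrame  # index: V allele; columns: the two anchor alleles
    n_ambiguous_anchor: int = 0

    def to_tsv(self, path: str | Path) -> None:
        out = self.matrix.copy()
        out.insert(0, "subject_id", self.subject_id)
        out.to_csv(path, sep="\t")


def partition_by_anchor(
    table: RearrangementTable,
    key_table: KeyTable | None = None,
    anchor_gene: str = DEFAULT_ANCHOR_GENE,
) -> HaplotypeCounts:
    """Split V allele usage by the anchor allele each read rearranged with.

    Requires heterozygosity: exactly two anchor alleles among the
    unambiguous j_calls.  Reads with ambiguous or missing anchor calls are
    excluded from the matrix and tallied.  V multi-assignments contribute
    1/k per allele, as in usage computation.
    """
    table.require("j_call")
    rows: list[tuple[list[str], str]] = []
    n_ambiguous = 0
    anchor_seen: set[str] = set()
    for _, rec in table.df.iterrows():
        j_names = [
            n for n in parse_call(rec["j_call"])
            if n.split("*")[0] == anchor_gene
        ]
        v_names = parse_call(rec["v_call"])
        if key_table is not None and v_names:
            v_names = parse_call(
                translate_call(",".join(v_names), key_table, "iuis_to_asc")
            )
        if len(j_names) != 1 or not v_names:
            n_ambiguous += 1
            continue
        anchor_seen.add(j_names[0])
        rows.append((v_names, j_names[0]))

    if len(anchor_seen) != 2:
        raise NotHaplotypableError(
            f"{table.subject_id or 'subject'}: need exactly 2 {anchor_gene} "
            f"alleles among unambiguous calls, found {sorted(anchor_seen)}"
        )
    anchors = tuple(sorted(anchor_seen))
    counts: dict[str, dict[str, float]] = {}
    for v_names, anchor in rows:
        w = 1.0 / len(v_names)
        for v in v_names:
            counts.setdefault(v, {a: 0.0 for a in anchors})[anchor] += w
    matrix = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    matrix = matrix[list(anchors)]
    matrix.index.name = "v_allele"
    return HaplotypeCounts(
        subject_id=table.subject_id,
        anchor_gene=anchor_gene,
        anchor_alleles=anchors,  # type: ignore[arg-type]
        matrix=matrix,
        n_ambiguous_anchor=n_ambiguous,
    )


def binomial_dominance_test(
    count_minor: int,
    count_major: int,
    usage_ratio: float,
    parameterization: str = "odds",
) -> float:
    """Probability that the population-minor allele shows >= its observed
    count, given population usage of the major allele ``usage_ratio`` times
    the minor's.

    Under the null, each of the n = minor + major reads is the minor allele
    with probability p = 1/(1 + usage_ratio) (``"odds"``; with ``"rate"``,
    p = 1/usage_ratio).  Returns the exact upper tail P(X >= count_minor)
    for X ~ Binomial(n, p).  A tiny p-value flags the observed dominance of
    the minor allele as implausible — likely mutation or PCR/sequencing
    error rather than genotype.
    """
    if count_minor < 0 or count_major < 0 or count_minor + count_major == 0:
        raise AscGenotypeError("counts must be non-negative, not both zero")
    if usage_ratio <= 0:
        raise AscGenotypeError("usage_ratio must be positive")
    if parameterization == "odds":
        p = 1.0 / (1.0 + usage_ratio)
    elif parameterization == "rate":
        p = 1.0 / usage_ratio
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    n = count_minor + count_major
    # exact tail: sf(k-1) = P(X >= k)
    return float(binom.sf(count_minor - 1, n, p))


@dataclass
class ThresholdSuggestion:
    """One advisory adjustment of an allele-specific threshold."""

    allele: str
    current: float
    suggested: float
    case: int  # 1 raise, 2 lower, 3 undocumented allele (then 1/2 logic)
    evidence: str
    contradiction: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.suggested <= 1:
            raise AscGenotypeError(
                f"suggested threshold {self.suggested} not in (0, 1]"
            )


def _haplotype_support(
    allele: str,
    subject_id: str,
    haplotypes: Sequence[HaplotypeCounts],
    key_table: KeyTable | None,
) -> tuple[bool, bool]:
    """(supported, contradiction) for one allele in one subject.

    Supported: the allele has reads attributed to at least one chromosome.
    Contradiction: another allele of the same IUIS gene sits on the same
    chromosome — two alleles of one gene cannot share a chromosome, so the
    evidence is untrustworthy (possible duplication; leave threshold alone).
    """
    hap = next((h for h in haplotypes if h.subject_id == subject_id), None)
    if hap is None or allele not in hap.matrix.index:
        return False, False
    row = hap.matrix.loc[allele]
    present_cols = [c for c in hap.matrix.columns if row[c] > 0]
    if not present_cols:
        return False, False
    if key_table is None:
        return True, False
    genes = {n.split("*")[0] for n in key_table.asc_to_iuis.get(allele, [])}
    for other in hap.matrix.index:
        if other == allele:
            continue
        other_genes = {
            n.split("*")[0] for n in key_table.asc_to_iuis.get(other, [])
        }
        if genes & other_genes:
            for c in present_cols:
                if hap.matrix.loc[other, c] > 0:
                    return True, True
    return True, False


def suggest_threshold_adjustments(
    usages: Sequence[AlleleUsage],
    haplotypes: Sequence[HaplotypeCounts] | None,
    thresholds: ThresholdTable,
    key_table: KeyTable | None = None,
    novel_sequences: Mapping[str, str] | None = None,
    asc_ref: ASCReference | None = None,
    case1_ratio: float = CASE1_RATIO,
    raise_factor: float = CASE1_RAISE_FACTOR,
) -> list[ThresholdSuggestion]:
    """The three-case advisory procedure for tuning allele thresholds.

    Case 1 (raise): every carrier expresses the allele far above its
    threshold (minimum carrier frequency > ``case1_ratio`` x threshold);
    suggest raising to ``raise_factor`` x the minimum carrier frequency,
    i.e. just below the lowest expression level among studied subjects.

    Case 2 (lower): a subject expresses the allele below threshold but
    haplotype evidence places it on a chromosome with no same-gene
    conflict; suggest lowering to the lowest supported carrier's frequency
    so those subjects are included.  A same-gene conflict on one chromosome
    flags a contradiction and leaves the threshold unchanged.

    Case 3 (undocumented): novel alleles are first given the threshold of
    their nearest reference allele, then re-evaluated under cases 1-2.

    Suggestions are advisory and never auto-applied; genotype curation is a
    manual step.  The procedure is idempotent: applying the suggested
    thresholds and re-running produces no further case-1/2 suggestions.
    """
    if not usages:
        raise AscGenotypeError("need at least one subject's usage")
    haplotypes = haplotypes or []
    suggestions: list[ThresholdSuggestion] = []

    seeded: dict[str, tuple[float, str]] = {}
    if novel_sequences:
        if asc_ref is None:
            raise AscGenotypeError(
                "novel sequences require asc_ref for nearest-allele lookup"
            )
        for name, seq in novel_sequences.items():
            near: NearestAllele = novel_allele_threshold(
                seq, thresholds, asc_ref
            )
            seeded[name] = (
                near.threshold,
                f"seeded from nearest allele {','.join(near.nearest)}"
                + (" (tie)" if near.tie else ""),
            )

    alleles = sorted(
        {a for u in usages for a in u.fractional_counts}
        | set(seeded)
    )
    for allele in alleles:
        if allele in seeded:
            current, seed_note = seeded[allele]
            case = 3
        else:
            current, seed_note = thresholds.get(allele), ""
            case = None

        freqs = {
            u.subject_id: u.frequency(allele)
            for u in usages
            if u.frequency(allele) > 0
        }
        carriers = {s: f for s, f in freqs.items() if f >= current}
        below = {s: f for s, f in freqs.items() if f < current}

        # Case 1: all expressing subjects are far above the threshold.
        if carriers and not below and min(carriers.values()) > case1_ratio * current:
            suggested = min(carriers.values()) * raise_factor
            suggestions.append(
                ThresholdSuggestion(
                    allele=allele,
                    current=current,
                    suggested=suggested,
                    case=case or 1,
                    evidence=(
                        f"{len(carriers)} carriers, min frequency "
                        f"{min(carriers.values()):.3g} > {case1_ratio:g}x "
                        f"threshold {current:.3g}; " + seed_note
                    ).strip("; "),
                )
            )
            continue

        # Case 2: below-threshold expression backed by haplotype evidence.
        supported: dict[str, float] = {}
        contradiction = False
        for s, f in below.items():
            ok, conflict = _haplotype_support(allele, s, haplotypes, key_table)
            if conflict:
                contradiction = True
            elif ok:
                supported[s] = f
        if contradiction:
            suggestions.append(
                ThresholdSuggestion(
                    allele=allele,
                    current=current,
                    suggested=current,
                    case=case or 2,
                    evidence=(
                        "same-gene alleles co-occur on one chromosome; "
                        "threshold unchanged pending more information; "
                        + seed_note
                    ).strip("; "),
                    contradiction=True,
                )
            )
        elif supported:
            suggestions.append(
                ThresholdSuggestion(
                    allele=allele,
                    current=current,
                    suggested=min(supported.values()),
                    case=case or 2,
                    evidence=(
                        f"haplotype support in {len(supported)} subject(s) "
                        f"below threshold {current:.3g}; " + seed_note
                    ).strip("; "),
                )
            )
        elif case == 3:
            # undocumented allele with no further adjustment triggered:
            # still report the seeded threshold.
            suggestions.append(
                ThresholdSuggestion(
                    allele=allele,
                    current=thresholds.default,
                    suggested=current,
                    case=3,
                    evidence=seed_note,
                )
            )
    return suggestions


def suggestions_to_tsv(
    suggestions: Sequence[ThresholdSuggestion], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "allele": s.allele,
                "current_threshold": s.current,
                "suggested_threshold": s.suggested,
                "case": s.case,
                "contradiction": s.contradiction,
                "evidence": s.evidence,
            }
            for s in suggestions
        ]
    ).to_csv(path, sep="\t", index=False)
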