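"""Absolute-usage genotype inference over ASC alleles.

The genotype of a subject is the set of germline alleles they carry,
inferred from annotated repertoire reads.  Instead of the conventional
gene-based rule (an allele enters if its share of reads *within its gene*
exceeds 12.5% or 5%), each allele's *absolute* usage — fractional read
count divided by the total number of reads in the repertoire — is compared
to an allele-specific threshold (default 1e-4, matched to typical 10-20K
read depths).  Reads with multiple allele assignments contribute 1/k to
each of their k distinct alleles, so total weight is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import ASCReference, KeyTable, normalized_levenshtein, translate_call
from .errors import AscGenotypeError, TranslationError
from .repertoire import RearrangementTable, parse_call

logger = logging.getLogger(__name__)

#: Default absolute-usage threshold: at 10-20K reads this admits alleles
#: supported by roughly one or two reads.
DEFAULT_THRESHOLD = 1e-4

#: Conventional gene-based relative-usage thresholds.
GENE_FRACTION_STRICT = 0.125
GENE_FRACTION_LENIENT = 0.05


@dataclass
class AlleleUsage:
    """Per-subject fractional counts and absolute frequencies per allele."""

    subject_id: str
    fractional_counts: dict[str, float]
    total_sequences: int
    n_untranslatable: int = 0

    @property
    def absolute_frequencies(self) -> dict[str, float]:
        if self.total_sequences == 0:
            return {a: 0.0 for a in self.fractional_counts}
        return {
            a: c / self.total_sequences
            for a, c in self.fractional_counts.items()
        }

    def frequency(self, allele: str) -> float:
        return self.absolute_frequencies.get(allele, 0.0)


def compute_allele_usage(
    table: RearrangementTable,
    key_table: KeyTable | None = None,
    strict: bool = False,
) -> AlleleUsage:
    """Fractional allele counts with 1/k splitting of multi-assignments.

    Each record carries total weight 1; a record whose call resolves to k
    distinct (ASC-translated) alleles contributes 1/k to each.  Frequencies
    are normalized by the number of records with a translatable call;
    records with no usable call are excluded and their count logged.
    """
    if len(table) == 0:
        raise AscGenotypeError("cannot compute usage of an empty table")
    counts: dict[str, float] = {}
    n_used = 0
    n_untranslatable = 0
    for call in table.df["v_call"]:
        names = parse_call(call)
        if key_table is not None and names:
            translated = translate_call(
                ",".join(names), key_table, "iuis_to_asc", strict=strict
            )
            # drop names the key table does not know (logged below)
            names = [
                n
                for n in parse_call(translated)
                if n in key_table.asc_to_iuis
            ]
        if not names:
            n_untranslatable += 1
            continue
        n_used += 1
        w = 1.0 / len(names)
        for n in names:
            counts[n] = counts.get(n, 0.0) + w
    if n_untranslatable:
        logger.info(
            "%s: %d records had no translatable call and were excluded",
            table.subject_id,
            n_untranslatable,
        )
    return AlleleUsage(
        subject_id=table.subject_id,
        fractional_counts=counts,
        total_sequences=n_used,
        n_untranslatable=n_untranslatable,
    )


class ThresholdTable:
    """Allele-specific absolute-usage thresholds with a default fallback."""

    def __init__(
        self,
        thresholds: Mapping[str, float] | None = None,
        default: float = DEFAULT_THRESHOLD,
    ):
        if not 0 < default <= 1:
            raise AscGenotypeError(f"default threshold {default} not in (0, 1]")
        self.thresholds: dict[str, float] = dict(thresholds or {})
        for a, t in self.thresholds.items():
            if not 0 < t <= 1:
                raise AscGenotypeError(f"threshold {t} for {a} not in (0, 1]")
        self.default = default

    def get(self, allele: str) -> float:
        return self.thresholds.get(allele, self.default)

    def n_adjusted(self) -> int:
        """Number of listed alleles whose threshold deviates from default."""
        return sum(1 for t in self.thresholds.values() if t != self.default)

    def with_updates(self, updates: Mapping[str, float]) -> "ThresholdTable":
        merged = dict(self.thresholds)
        merged.update(updates)
        return ThresholdTable(merged, default=self.default)

    @classmethod
    def read_tsv(
        cls, path: str | Path, default: float = DEFAULT_THRESHOLD
    ) -> "ThresholdTable":
        df = pd.read_csv(path, sep="\t")
        allele_col = next(
            c for c in df.columns if c.lower() in ("allele", "asc_name", "name")
        )
        thr_col = next(
            c for c in df.columns if c.lower() in ("threshold", "thresh")
        )
        return cls(
            dict(zip(df[allele_col].astype(str), df[thr_col].astype(float))),
            default=default,
        )

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"allele": list(self.thresholds), "threshold": list(self.thresholds.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class Genotype:
    """The inferred allele set of one subject, with its audit trail."""

    subject_id: str
    table: pd.DataFrame  # allele, fractional_count, absolute_frequency,
    #                      threshold, in_genotype

    @property
    def alleles(self) -> set[str]:
        return set(self.table.loc[self.table["in_genotype"], "allele"])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "subject_id", self.subject_id)
        out.to_csv(path, sep="\t", index=False)


def infer_genotype_asc(
    usage: AlleleUsage, thresholds: ThresholdTable
) -> Genotype:
    """An allele enters the genotype iff absolute frequency >= its threshold.

    The comparison is inclusive: a frequency exactly at threshold passes.
    """
    freqs = usage.absolute_frequencies
    rows = []
    for allele in sorted(usage.fractional_counts):
        t = thresholds.get(allele)
        f = freqs[allele]
        rows.append(
            {
                "allele": allele,
                "fractional_count": usage.fractional_counts[allele],
                "absolute_frequency": f,
                "threshold": t,
                "in_genotype": f >= t,
            }
        )
    return Genotype(subject_id=usage.subject_id, table=pd.DataFrame(rows))


def infer_genotype_gene_based(
    table: RearrangementTable, fraction: float = GENE_FRACTION_STRICT
) -> Genotype:
    """Gene-based relative-frequency baseline.

    An allele enters iff its fractional count divided by the total count of
    its IUIS gene is >= ``fraction`` (conventionally 12.5% or 5%).  This is
    the simple per-gene fraction rule, used here only as a comparison
    baseline for the absolute-usage method; it is a deliberate
    simplification of full gene-based genotyping tools.
    """
    if not 0 < fraction < 1:
        raise AscGenotypeError(f"fraction {fraction} not in (0, 1)")
    usage = compute_allele_usage(table, key_table=None)
    gene_totals: dict[str, float] = {}
    for allele, c in usage.fractional_counts.items():
        gene = allele.split("*")[0]
        gene_totals[gene] = gene_totals.get(gene, 0.0) + c
    rows = []
    for allele in sorted(usage.fractional_counts):
        gene = allele.split("*")[0]
        c = usage.fractional_counts[allele]
        rel = c / gene_totals[gene]
        rows.append(
            {
                "allele": allele,
                "fractional_count": c,
                "relative_frequency": rel,
                "threshold": fraction,
                "in_genotype": rel >= fraction,
            }
        )
    return Genotype(subject_id=table.subject_id, table=pd.DataFrame(rows))


@dataclass(frozen=True)
class NearestAllele:
    """Result of attributing a novel sequence to its closest known allele."""

    threshold: float
    nearest: tuple[str, ...]
    distance: float
    tie: bool


def novel_allele_threshold(
    novel_sequence: str,
    thresholds: ThresholdTable,
    asc_ref: ASCReference,
) -> NearestAllele:
    """Threshold for an undocumented allele: that of its closest reference
    allele by normalized Levenshtein distance.

    Ties take the smallest threshold among equidistant alleles (conservative
    inclusion) and are flagged.
    """
    if len(asc_ref) == 0:
        raise AscGenotypeError("empty reference")
    dists = {
        e.asc_name: normalized_levenshtein(novel_sequence, e.sequence)
        for e in asc_ref
    }
    dmin = min(dists.values())
    nearest = sorted(a for a, d in dists.items() if d == dmin)
    thrs = [thresholds.get(a) for a in nearest]
    return NearestAllele(
        threshold=min(thrs),
        nearest=tuple(nearest),
        distance=dmin,
        tie=len(nearest) > 1,
    )


def multiple_assignment_fraction(
    table: RearrangementTable,
    key_table: KeyTable | None = None,
    level: str = "asc",
) -> float:
    """Fraction of records assigned to more than one gene-level unit.

    ``level="gene"`` counts records whose call spans more than one distinct
    IUIS gene; ``level="asc"`` first translates the call through the key
    table and counts records spanning more than one ASC (the cluster part
    of the name).  Identical sequences share one ASC, and near-identical
    same-gene alleles share one cluster, so the ASC-level fraction is what
    shrinks when the collapsed naming scheme replaces IUIS genes.
    """
    if len(table) == 0:
        raise AscGenotypeError("empty table")
    n_multi = 0
    for call in table.df["v_call"]:
        names = parse_call(call)
        if level == "asc":
            if key_table is not None:
                names = parse_call(
                    translate_call(",".join(names), key_table, "iuis_to_asc")
                )
            units = {n.split("*")[0] for n in names}
        elif level == "gene":
            units = {n.split("*")[0] for n in names}
        else:
            raise ValueError(f"unknown level {level!r}")
        if len(units) > 1:
            n_multi += 1
    return n_multi / len(table)


def usage_by_genotype_combination(
    usages: Sequence[AlleleUsage],
    genotypes: Sequence[Genotype],
    cluster: str,
) -> pd.DataFrame:
    """Per-subject summed cluster usage, grouped by genotype combination.

    Each subject is labelled by the sorted allele numbers of the cluster's
    alleles in their genotype (e.g. ``"04_05"``; ``"none"`` if the cluster
    is absent), and the summed absolute frequency over the cluster's
    alleles is reported.  Combinations are ordered by carrier count.
    """
    prefix = cluster + "*"
    rows = []
    for usage, geno in zip(usages, genotypes):
        if usage.subject_id != geno.subject_id:
            raise AscGenotypeError(
                "usages and genotypes are not aligned by subject"
            )
        carried = sorted(
            a.split("*")[1] for a in geno.alleles if a.startswith(prefix)
        )
        combination = "_".join(carried) if carried else "none"
        freq = sum(
            f
            for a, f in usage.absolute_frequencies.items()
            if a.startswith(prefix)
        )
        rows.append(
            {
                "combination": combination,
                "subject_id": usage.subject_id,
                "frequency": freq,
            }
        )
    df = pd.DataFrame(rows)
    order = (
        df.groupby("combination").size().sort_values(ascending=False).index
    )
    df["combination"] = pd.Categorical(
        df["combination"], categories=list(order), ordered=True
    )
    return df.sort_values(["combination", "subject_id"]).reset_index(drop=True)


def genotype_comparison_matrix(
    asc_genotypes: Sequence[Genotype],
    gene_genotypes: Sequence[Genotype],
    key_table: KeyTable,
) -> pd.DataFrame:
    """Allele x subject concordance matrix between the two methods.

    Gene-based calls (IUIS names) are translated to ASC names before the
    comparison; cells are ``both`` / ``asc_only`` / ``gene_only`` /
    ``neither``.
    """
    rows = []
    for asc_g, gene_g in zip(asc_genotypes, gene_genotypes):
        asc_set = asc_g.alleles
        gene_set = {
            n
            for a in gene_g.alleles
            for n in parse_call(translate_call(a, key_table, "iuis_to_asc"))
        }
        for allele in sorted(asc_set | gene_set):
            in_a, in_g = allele in asc_set, allele in gene_set
            status = (
                "both"
                if in_a and in_g
                else "asc_only"
                if in_a
                else "gene_only"
            )
            rows.append(
                {
                    "subject_id": asc_g.subject_id,
                    "allele": allele,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)
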