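"""Deterministic synthetic germline sets and simulated repertoires.

The generator plants known structure so every pipeline stage can be tested
end to end: a toy germline set with controlled within-/between-cluster
similarity and duplicated identical alleles under distinct gene names, and
repertoires drawn from a planted genotype with specified per-allele
absolute frequencies, uniform per-base mutation injection, nearest-neighbor
multi-assignments, and heterozygous J-anchor labels for haplotype analysis.

Reads are represented as annotation records (calls, mutation counts,
coverage), not raw nucleotides, because the genotype machinery consumes
annotated AIRR tables.  All randomness flows from a single numpy Generator
keyed by ``cfg.seed``, with draws in a fixed order, so outputs are
byte-stable for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import AscGenotypeError
from .germline import (
    DEFAULT_TRIM_END,
    FUNCTIONAL,
    GermlineAllele,
    GermlineReference,
    write_germline_fasta,
)
from .clustering import normalized_levenshtein
from .repertoire import RearrangementTable

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Planted-structure parameters for germline and repertoire synthesis.

    Defaults reflect the study conditions the genotype method targets:
    repertoire depth of 10,000 reads (typical AIRR-seq depths run 10-20K,
    which is what the 1e-4 default threshold is calibrated to), a mostly
    unmutated naive-like repertoire, and a moderate rate of multi-allele
    assignments.
    """

    seed: int = 0
    # germline structure
    n_genes: int = 8
    alleles_per_gene: int = 3
    sequence_length: int = DEFAULT_TRIM_END
    within_cluster_similarity: float = 0.97
    between_cluster_similarity: float = 0.80
    duplicated_allele_pairs: int = 1
    # repertoire structure
    n_sequences: int = 10_000
    planted_frequencies: dict[str, float] | None = None
    mutation_rate: float = 0.001
    ambiguity_rate: float = 0.1
    anchor_gene: str = "IGHJ6"
    anchor_alleles: tuple[str, str] = ("IGHJ6*02", "IGHJ6*03")
    #: optional allele -> anchor allele assignment (chromosome phasing)
    planted_haplotype: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for r in (
            self.mutation_rate,
            self.ambiguity_rate,
            self.within_cluster_similarity,
            self.between_cluster_similarity,
        ):
            if not 0 <= r <= 1:
                raise AscGenotypeError(f"rate {r} outside [0, 1]")
        if self.planted_frequencies is not None:
            total = sum(self.planted_frequencies.values())
            if abs(total - 1.0) > 1e-9:
                raise AscGenotypeError(
                    f"planted frequencies sum to {total}, expected 1"
                )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["anchor_alleles"] = list(d["anchor_alleles"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    chars = list(seq)
    for p in positions:
        old = chars[p]
        choices = [b for b in "ACGT" if b != old]
        chars[p] = choices[rng.integers(0, 3)]
    return "".join(chars)


def make_toy_germline(cfg: SimulationConfig) -> GermlineReference:
    """Build a germline set with planted gene/cluster structure.

    Each gene gets a random base sequence; its alleles mutate the base at
    disjoint position sets small enough that within-gene pairwise
    similarity stays >= ``within_cluster_similarity``, while independently
    drawn gene bases keep cross-gene similarity <= the between bound (both
    verified by direct distance computation; infeasible bounds raise).
    ``duplicated_allele_pairs`` first alleles are copied verbatim under a
    'D'-suffixed gene name, mimicking locus duplications.
    """
    if cfg.within_cluster_similarity <= cfg.between_cluster_similarity:
        raise AscGenotypeError(
            "infeasible similarity constraints: within <= between"
        )
    rng = np.random.default_rng(cfg.seed)
    L = cfg.sequence_length
    # substitutions per allele so any within-gene pair differs by <= 2k
    k = int(L * (1 - cfg.within_cluster_similarity) / 2)
    if k < 1 and cfg.alleles_per_gene > 1:
        raise AscGenotypeError(
            "within_cluster_similarity too tight for distinct alleles at "
            f"length {L}"
        )

    alleles: list[GermlineAllele] = []
    gene_bases: list[str] = []
    for g in range(cfg.n_genes):
        for _ in range(50):  # redraw until the between bound holds
            base = "".join(rng.choice(_BASES, size=L))
            if all(
                normalized_levenshtein(base, other)
                >= 1 - cfg.between_cluster_similarity
                for other in gene_bases
            ):
                break
        else:
            raise AscGenotypeError(
                "could not satisfy between_cluster_similarity bound"
            )
        gene_bases.append(base)
        gene = f"IGHV{g % 7 + 1}-{g + 1}"
        for a in range(cfg.alleles_per_gene):
            if a == 0:
                seq = base
            else:
                pos = rng.choice(L, size=k, replace=False)
                seq = _mutate(rng, base, pos)
            alleles.append(
                GermlineAllele(
                    iuis_name=f"{gene}*{a + 1:02d}",
                    sequence=seq,
                    gapped_sequence=seq,
                    functionality=FUNCTIONAL,
                )
            )

    # duplicated identical sequences under distinct gene names
    for d in range(cfg.duplicated_allele_pairs):
        src = alleles[d * cfg.alleles_per_gene]
        dup_gene = src.gene + "D"
        alleles.append(
            GermlineAllele(
                iuis_name=f"{dup_gene}*01",
                sequence=src.sequence,
                gapped_sequence=src.gapped_sequence,
                functionality=FUNCTIONAL,
            )
        )

    ref = GermlineReference(
        alleles=alleles,
        amplicon_class="S1",
        trim_end=L,
        provenance=f"synthetic toy germline, seed={cfg.seed}",
    )
    _verify_planted_structure(ref, cfg)
    return ref


def _verify_planted_structure(
    ref: GermlineReference, cfg: SimulationConfig
) -> None:
    by_gene: dict[str, list[str]] = {}
    for a in ref:
        by_gene.setdefault(a.gene.rstrip("D"), []).append(a.sequence)
    genes = list(by_gene)
    for g in genes:
        seqs = by_gene[g]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                if (
                    1 - normalized_levenshtein(seqs[i], seqs[j])
                    < cfg.within_cluster_similarity
                ):
                    raise AscGenotypeError(
                        f"planted within-cluster similarity violated in {g}"
                    )


def _nearest_neighbor(ref: GermlineReference) -> dict[str, str]:
    """Closest other allele (by name) for each allele, ties to smallest name."""
    out = {}
    for a in ref:
        best = None
        for b in ref:
            if b.iuis_name == a.iuis_name:
                continue
            d = normalized_levenshtein(a.sequence, b.sequence)
            key = (d, b.iuis_name)
            if best is None or key < best:
                best = key
                out[a.iuis_name] = b.iuis_name
    return out


def default_planted_frequencies(
    ref: GermlineReference, n_alleles: int = 8, seed: int = 0
) -> dict[str, float]:
    """A realistic skewed genotype: log-uniform usage over a subset of alleles.

    Allele usage in real repertoires spans orders of magnitude; frequencies
    are drawn log-uniformly over [1e-3, 1e-1] and normalized to 1.
    """
    rng = np.random.default_rng(seed)
    names = list(ref.names)[:n_alleles]
    raw = 10 ** rng.uniform(-3, -1, size=len(names))
    raw /= raw.sum()
    return dict(zip(names, raw))


def simulate_repertoire(
    cfg: SimulationConfig, ref: GermlineReference, subject_id: str = "sim"
) -> RearrangementTable:
    """Draw an annotated repertoire from the planted genotype.

    Each read samples its true allele from ``planted_frequencies``; with
    probability ``ambiguity_rate`` the v_call also lists the allele's
    nearest neighbor in the reference, emulating alignment ties.  A tie is
    only physically possible when the neighbor is indistinguishable from
    the true allele over the read: either an identical duplicated sequence
    (distance 0), or any nearest neighbor once the read carries mutations.
    An unmutated read of a twin-less allele therefore stays unambiguous
    even when selected for ambiguity.  Mutation counts are
    Binomial(L, mutation_rate) with uniformly drawn positions recorded in
    ``v_mutation_positions``.  The j_call is the chromosome's anchor allele
    when ``planted_haplotype`` assigns one, else a fair draw between the
    two anchor alleles.
    """
    freqs = cfg.planted_frequencies or default_planted_frequencies(
        ref, seed=cfg.seed
    )
    missing = [a for a in freqs if a not in ref.names]
    if missing:
        raise AscGenotypeError(
            f"planted alleles missing from reference: {missing}"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    names = sorted(freqs)
    probs = np.array([freqs[n] for n in names])
    probs = probs / probs.sum()
    nearest = _nearest_neighbor(ref)
    L = len(ref[names[0]].sequence)

    draws = rng.choice(len(names), size=cfg.n_sequences, p=probs)
    ambiguous = rng.random(cfg.n_sequences) < cfg.ambiguity_rate
    n_mut = rng.binomial(L, cfg.mutation_rate, size=cfg.n_sequences)
    anchor_draw = rng.integers(0, 2, size=cfg.n_sequences)

    dist_to_nearest = {
        a.iuis_name: normalized_levenshtein(
            a.sequence, ref[nearest[a.iuis_name]].sequence
        )
        for a in ref
    }

    records = []
    for i in range(cfg.n_sequences):
        true = names[draws[i]]
        call = true
        if ambiguous[i] and (dist_to_nearest[true] == 0.0 or n_mut[i] > 0):
            call = ",".join([true, nearest[true]])
        if cfg.planted_haplotype and true in cfg.planted_haplotype:
            j_call = cfg.planted_haplotype[true]
        else:
            j_call = cfg.anchor_alleles[anchor_draw[i]]
        k = int(n_mut[i])
        pos = (
            np.sort(rng.choice(L, size=k, replace=False)) + 1 if k else []
        )
        records.append(
            {
                "sequence_id": f"S{i:06d}",
                "v_call": call,
                "j_call": j_call,
                "clone_id": f"C{i:06d}",
                "v_mutation_count": k,
                "v_mutation_positions": ",".join(str(p) for p in pos),
                "v_germline_start": 1,
                "v_alignment_length": L,
            }
        )
    return RearrangementTable(
        df=pd.DataFrame(records),
        subject_id=subject_id,
        provenance=f"simulated repertoire, seed={cfg.seed}",
    )


def write_simulation(
    cfg: SimulationConfig,
    ref: GermlineReference,
    table: RearrangementTable,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + AIRR TSV + config YAML snapshot for provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "germline.fasta",
        "airr": outdir / "repertoire.tsv",
        "config": outdir / "config.yaml",
    }
    write_germline_fasta(ref, paths["fasta"])
    table.df.to_csv(paths["airr"], sep="\t", index=False)
    cfg.to_yaml(paths["config"])
    return paths
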