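"""Synthetic data with ground truth for both analysis arms.

Two generators live here:

* :func:`simulate_genome` writes an annotated genome (FASTA + GFF3) whose
  background sequence is guaranteed free of detectable SSRs, then plants
  perfect repeats of chosen motifs into chosen positional categories.  The
  returned truth table gives exact coordinates, motifs, copy numbers and
  categories, so detector and classifier can be scored for perfect recall
  and precision.

* :func:`simulate_populations` builds a two-species haploid microsatellite
  dataset under a bounded strict stepwise mutation model (SMM): each
  lineage's repeat count takes ``Poisson(mu * t)`` steps of +-1 repeat,
  reflecting at the allele-range bounds ``[r_min, r_max]``.  The lineage
  tree is: one ancestral allele per locus; species lineages diverge
  ``t_species`` generations ago; within each species a founder pool of
  lineages diverges at ``t_populations`` (the pool size is the founder
  count, small for an invasive/bottlenecked species); each population
  carries its own with-replacement subsample of the pool (founder drift,
  the source of among-population differentiation); individuals draw their
  ancestor from that subsample at ``t_individuals`` and then evolve
  independently (a star genealogy within populations).  Genealogies are
  drawn independently per locus, i.e. loci recombine freely across sexual
  generations.  Narrow bounds model the length
  constraint acting on exonic/upstream loci; the founder pool models the
  introduction bottleneck of an invasive species.  Allele sizes are
  emitted as ``repeat_count * unit_length + flank`` (bp), as produced by
  fragment-size genotyping.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ssrscape.popgen import GenotypeMatrix
from ssrscape.regions import (RegionCategory, RegionModel, Transcript,
                              build_region_model)
from ssrscape.ssr import ThresholdProfile, canonical_motif, find_ssrs

__all__ = [
    "GeneTemplate",
    "GenomeSimSpec",
    "PlantedSSR",
    "PopSimSpec",
    "LocusSpec",
    "simulate_genome",
    "simulate_populations",
]


# ---------------------------------------------------------------------------
# genome simulation


@dataclasses.dataclass(frozen=True)
class GeneTemplate:
    """Structural template for simulated gene models (lengths in bp)."""

    utr5_len: int = 200
    utr3_len: int = 200
    cds_exon_len: int = 600
    intron_len: int = 120
    n_cds_exons: int = 2
    p_forward: float = 0.5

    @property
    def span(self) -> int:
        return (self.utr5_len + self.utr3_len
                + self.n_cds_exons * self.cds_exon_len
                + (self.n_cds_exons - 1) * self.intron_len)


@dataclasses.dataclass(frozen=True)
class GenomeSimSpec:
    """Recipe for a synthetic annotated genome with planted SSRs.

    ``planting`` rows are (category, motif, repeat_count, count); planted
    repeat counts must meet the detection thresholds, and every locus is
    placed wholly inside an interval of its target category.
    """

    scaffold_lengths: Mapping[str, int]
    genes_per_scaffold: int = 3
    gene_template: GeneTemplate = GeneTemplate()
    planting: Sequence[tuple[str, str, int, int]] = ()
    gc_content: float = 0.5
    seed: int = 0
    thresholds: ThresholdProfile = ThresholdProfile()

    def __post_init__(self) -> None:
        for category, motif, copies, count in self.planting:
            RegionCategory(category)
            if copies < self.thresholds.minimum(len(motif)):
                raise ValueError(
                    f"planted {motif} x{copies} below detection threshold "
                    f"{self.thresholds.minimum(len(motif))}")
            if count < 0:
                raise ValueError("planting count must be non-negative")


@dataclasses.dataclass(frozen=True)
class PlantedSSR:
    scaffold_id: str
    start: int
    end: int
    motif: str
    canonical: str
    unit_length: int
    repeat_count: int
    category: str


class PlantingError(RuntimeError):
    """Raised when a planting request cannot be satisfied."""


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)


def _scrub_background(rng: np.random.Generator, arr: np.ndarray, scaffold: str,
                      gc: float, thresholds: ThresholdProfile,
                      max_rounds: int = 50) -> None:
    """Re-randomize spans of accidental SSRs until the scan comes back empty."""
    for _ in range(max_rounds):
        hits = find_ssrs(arr.tobytes().decode("ascii"), scaffold, thresholds)
        if not hits:
            return
        for h in hits:
            lo, hi = max(0, h.start - 2), min(arr.size, h.end + 1)
            arr[lo:hi] = _random_sequence(rng, hi - lo, gc)
    raise PlantingError(f"could not scrub accidental SSRs from {scaffold}")


def _place_genes(spec: GenomeSimSpec, rng: np.random.Generator
                 ) -> list[Transcript]:
    """Lay out evenly spaced gene models leaving >500 bp distal gaps."""
    tmpl = spec.gene_template
    transcripts = []
    counter = 0
    for scaf, length in spec.scaffold_lengths.items():
        n = spec.genes_per_scaffold
        if n == 0:
            continue
        slot = length // n
        if slot < tmpl.span + 2 * 600:
            raise ValueError(
                f"scaffold {scaf} too short for {n} genes of span {tmpl.span} "
                "with 600 bp margins")
        for k in range(n):
            counter += 1
            start = k * slot + 601
            strand = "+" if rng.random() < tmpl.p_forward else "-"
            # build sub-features left to right, then orient by strand
            pos = start
            left_utr = (pos, pos + tmpl.utr5_len - 1)
            pos = left_utr[1] + 1
            cds = []
            for e in range(tmpl.n_cds_exons):
                cds.append((pos, pos + tmpl.cds_exon_len - 1))
                pos = cds[-1][1] + 1
                if e < tmpl.n_cds_exons - 1:
                    pos += tmpl.intron_len
            right_utr = (pos, pos + tmpl.utr3_len - 1)
            end = right_utr[1]
            utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
            exons = sorted([left_utr, right_utr] + cds)
            tx = Transcript(f"tx{counter:04d}", scaf, start, end, strand,
                            exons=exons, cds=cds, utr5=[utr5], utr3=[utr3])
            transcripts.append(tx)
    return transcripts


def _write_gff3(transcripts: Sequence[Transcript], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in transcripts:
            gene_id = tx.transcript_id.replace("tx", "gene")
            base = f"{tx.scaffold_id}\tssrscape_sim"
            fh.write(f"{base}\tgene\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\t"
                     f"ID={gene_id}\n")
            fh.write(f"{base}\tmRNA\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\t"
                     f"ID={tx.transcript_id};Parent={gene_id}\n")
            rows = ([("exon", s, e) for s, e in tx.exons]
                    + [("CDS", s, e) for s, e in tx.cds]
                    + [("five_prime_UTR", s, e) for s, e in tx.utr5]
                    + [("three_prime_UTR", s, e) for s, e in tx.utr3])
            for i, (ftype, s, e) in enumerate(rows, 1):
                fh.write(f"{base}\t{ftype}\t{s}\t{e}\t.\t{tx.strand}\t.\t"
                         f"ID={tx.transcript_id}.{ftype}{i};Parent={tx.transcript_id}\n")


def simulate_genome(spec: GenomeSimSpec, out_dir: str | Path
                    ) -> tuple[Path, Path, Path]:
    """Write genome.fasta, annotation.gff3 and truth.tsv into ``out_dir``.

    The truth table lists every planted SSR with exact 1-based coordinates,
    motif, copy number and target category.  Backgrounds are rejection-
    scanned so the only detectable SSRs are the planted ones; generation is
    deterministic for a given spec (seed included).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    transcripts = _place_genes(spec, rng)
    model = build_region_model(transcripts, spec.scaffold_lengths)

    seqs = {scaf: _random_sequence(rng, length, spec.gc_content)
            for scaf, length in spec.scaffold_lengths.items()}
    for scaf, arr in seqs.items():
        _scrub_background(rng, arr, scaf, spec.gc_content, spec.thresholds)

    # candidate intervals per category, large enough to host a locus + guards
    intervals = {scaf: model.intervals(scaf) for scaf in seqs}
    used: dict[str, list[tuple[int, int]]] = {scaf: [] for scaf in seqs}
    planted: list[PlantedSSR] = []
    for category, motif, copies, count in spec.planting:
        cat = RegionCategory(category)
        span = len(motif) * copies
        candidates = [(scaf, s, e) for scaf in seqs
                      for s, e in intervals[scaf][cat] if e - s + 1 >= span + 4]
        rng.shuffle(candidates)
        placed = 0
        for scaf, s, e in candidates * 4:  # allow several loci per interval
            if placed == count:
                break
            lo = s + 2 + int(rng.integers(0, max(1, e - s + 1 - span - 4)))
            hi = lo + span - 1
            if any(not (hi + 2 < us or lo - 2 > ue) for us, ue in used[scaf]):
                continue
            if hi > e - 2:
                continue
            arr = seqs[scaf]
            unit = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
            arr[lo - 1 : hi] = np.tile(unit, copies)
            # guard bases prevent run extension beyond the planted span
            arr[lo - 2] = _guard_base(motif[-1], motif[(span - 1) % len(motif)])
            arr[hi] = _guard_base(motif[0], motif[span % len(motif)])
            used[scaf].append((lo, hi))
            planted.append(PlantedSSR(scaf, lo, hi, motif, canonical_motif(motif),
                                      len(motif), copies, category))
            placed += 1
        if placed < count:
            raise PlantingError(
                f"could only place {placed}/{count} loci in category {category}")

    # verify: detected loci must match planted loci exactly; rescrub leftovers
    truth_spans = {(p.scaffold_id, p.start, p.end) for p in planted}
    for attempt in range(50):
        extras = []
        for scaf, arr in seqs.items():
            for hit in find_ssrs(arr.tobytes().decode("ascii"), scaf, spec.thresholds):
                if (scaf, hit.start, hit.end) not in truth_spans:
                    extras.append(hit)
        if not extras:
            break
        for h in extras:
            # incidental run created by guard/plant juxtaposition: rewrite
            # only its bases lying outside every planted span
            protected = used[h.scaffold_id]
            arr = seqs[h.scaffold_id]
            for pos in range(h.start, h.end + 1):  # 1-based
                if any(us <= pos <= ue for us, ue in protected):
                    continue
                arr[pos - 1] = _random_sequence(rng, 1, spec.gc_content)[0]
    else:
        raise PlantingError("could not remove incidental SSRs after planting")

    fasta_path = out_dir / "genome.fasta"
    with open(fasta_path, "w") as fh:
        for scaf, arr in seqs.items():
            fh.write(f">{scaf}\n")
            text = arr.tobytes().decode("ascii")
            for i in range(0, len(text), 80):
                fh.write(text[i : i + 80] + "\n")
    gff_path = out_dir / "annotation.gff3"
    _write_gff3(transcripts, gff_path)
    truth_path = out_dir / "truth.tsv"
    columns = [f.name for f in dataclasses.fields(PlantedSSR)]
    table = pd.DataFrame([dataclasses.asdict(p) for p in planted], columns=columns)
    table.sort_values(["scaffold_id", "start"]).to_csv(
        truth_path, sep="\t", index=False)
    return fasta_path, gff_path, truth_path


def _guard_base(*avoid: str) -> np.uint8:
    for base in "ACGT":
        if base not in avoid:
            return np.uint8(ord(base))
    raise AssertionError("unreachable: four bases, at most two to avoid")


# ---------------------------------------------------------------------------
# population simulation


@dataclasses.dataclass(frozen=True)
class LocusSpec:
    """Mutation model for one category of loci.

    ``bounds`` is the permitted repeat-count range (inclusive); narrow
    bounds emulate length constraint, e.g. on exonic repeats.
    """

    n_loci: int
    ancestral_repeats: int
    mu: float                      # +-1-step mutations per generation
    bounds: tuple[int, int]
    unit_length: int = 3
    flank: int = 90                # bp added by the amplified flanks

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")
        if not self.bounds[0] <= self.ancestral_repeats <= self.bounds[1]:
            raise ValueError("ancestral repeat count outside allele bounds")


DEFAULT_LOCI: dict[str, LocusSpec] = {
    # Mirrors the marker panel design: 39 trinucleotide loci across four
    # positional categories.  Exonic (IN) and upstream-proximal (UP) loci
    # get narrower repeat-count bounds than loci away from genes.
    "OUT": LocusSpec(n_loci=11, ancestral_repeats=25, mu=1e-3, bounds=(5, 45)),
    "UP": LocusSpec(n_loci=9, ancestral_repeats=15, mu=1e-3, bounds=(8, 22)),
    "IN": LocusSpec(n_loci=13, ancestral_repeats=10, mu=1e-3, bounds=(8, 12)),
    "DOWN": LocusSpec(n_loci=6, ancestral_repeats=25, mu=1e-3, bounds=(5, 45)),
}


@dataclasses.dataclass(frozen=True)
class PopSimSpec:
    """Recipe for the two-species microsatellite dataset.

    Defaults emulate the study design behind the real marker panel: an
    invasive species (2 populations, 20 individuals, founded by few
    genotypes) and a native species (3 populations, 31 individuals), typed
    at 39 trinucleotide loci in four positional categories.
    """

    loci: Mapping[str, LocusSpec] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LOCI))
    species_names: tuple[str, str] = ("invasive", "native")
    populations: tuple[tuple[int, ...], tuple[int, ...]] = ((10, 10), (10, 10, 11))
    founders: tuple[int, int] = (2, 20)   # founder-pool size per species
    pop_founders: int = 10                # lineages per population drawn from the pool
    t_species: int = 30000                # generations since species divergence
    t_populations: int = 4000             # generations since the founder pool split
    t_individuals: int = 150              # generations of star-shaped individual branches
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_species >= self.t_populations >= self.t_individuals >= 0:
            raise ValueError("need t_species >= t_populations >= t_individuals >= 0")
        if any(f < 1 for f in self.founders):
            raise ValueError("founder-pool sizes must be >= 1")

    @property
    def n_individuals(self) -> int:
        return sum(sum(p) for p in self.populations)


def _evolve(rng: np.random.Generator, repeats: int, mu: float, t: float,
            bounds: tuple[int, int]) -> tuple[int, int]:
    """Bounded strict SMM: Poisson(mu*t) steps of +-1, reflecting at bounds.

    Returns (new repeat count, number of mutation events).
    """
    n_mut = int(rng.poisson(mu * t))
    r = repeats
    lo, hi = bounds
    for _ in range(n_mut):
        step = 1 if rng.random() < 0.5 else -1
        r += step
        if r > hi:
            r = hi - 1
        elif r < lo:
            r = lo + 1
    return r, n_mut


def simulate_populations(spec: PopSimSpec
                         ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the two-species dataset; returns genotypes and a truth table.

    The truth table has one row per individual x locus with the repeat
    count, the founder-pool lineage the individual descends from, and the
    number of mutation events on its post-pool path — enough to tell
    identity-by-descent from size homoplasy.
    """
    rng = np.random.default_rng(spec.seed)
    locus_ids, locus_cats, locus_specs = [], [], []
    for cat in ("OUT", "UP", "IN", "DOWN"):
        if cat not in spec.loci:
            continue
        ls = spec.loci[cat]
        for i in range(ls.n_loci):
            locus_ids.append(f"{cat}{i+1:02d}")
            locus_cats.append(cat)
            locus_specs.append(ls)

    individuals, pops, specs_col = [], [], []
    for s_idx, (sp_name, pop_sizes) in enumerate(
            zip(spec.species_names, spec.populations)):
        for p_idx, size in enumerate(pop_sizes):
            pop_name = f"{sp_name}_pop{p_idx+1}"
            for k in range(size):
                individuals.append(f"{pop_name}_ind{k+1:02d}")
                pops.append(pop_name)
                specs_col.append(sp_name)

    alleles = np.zeros((len(individuals), len(locus_ids)), dtype=float)
    truth_rows = []
    for j, (locus, ls) in enumerate(zip(locus_ids, locus_specs)):
        ancestral = ls.ancestral_repeats
        row = 0
        for s_idx, (sp_name, pop_sizes) in enumerate(
                zip(spec.species_names, spec.populations)):
            sp_state, _ = _evolve(rng, ancestral, ls.mu,
                                  spec.t_species - spec.t_populations, ls.bounds)
            pool_size = spec.founders[s_idx]
            pool = [_evolve(rng, sp_state, ls.mu,
                            spec.t_populations - spec.t_individuals, ls.bounds)
                    for _ in range(pool_size)]
            for p_idx, size in enumerate(pop_sizes):
                # founder drift: each population carries its own (with-
                # replacement) subsample of the species pool at this locus
                subset = rng.integers(0, pool_size,
                                      size=min(spec.pop_founders, pool_size))
                draws = subset[rng.integers(0, subset.size, size=size)]
                for k in range(size):
                    lineage = int(draws[k])
                    state, n_pool_mut = pool[lineage]
                    repeats, n_mut = _evolve(rng, state, ls.mu,
                                             spec.t_individuals, ls.bounds)
                    alleles[row, j] = repeats * ls.unit_length + ls.flank
                    truth_rows.append({
                        "individual_id": individuals[row], "locus": locus,
                        "repeats": repeats, "lineage": lineage,
                        "n_mutations": n_mut + n_pool_mut,
                    })
                    row += 1
    g = GenotypeMatrix(
        alleles=pd.DataFrame(alleles, index=pd.Index(individuals,
                                                     name="individual_id"),
                             columns=locus_ids),
        population=pd.Series(pops, index=individuals),
        species=pd.Series(specs_col, index=individuals),
        locus_category=pd.Series(locus_cats, index=locus_ids),
    )
    return g, pd.DataFrame(truth_rows)
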