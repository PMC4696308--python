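"""Positional classification of the genome and of SSRs relative to gene models.

Every scaffold position is assigned to exactly one of nine categories:

===========  ===========================================================
EXON         overlapping coding sequence (CDS)
UTR5         5' untranslated region
UTR3         3' untranslated region
INTRON       inside the transcript span but in none of the above
UP_0_50      1-50 bp upstream (5' direction) of the transcript
UP_50_500    51-500 bp upstream
DOWN_0_50    1-50 bp downstream (3' direction)
DOWN_50_500  51-500 bp downstream
DISTAL       further than 500 bp from any transcript
===========  ===========================================================

Genic categories always win over a neighbouring gene's flank.  Where the
flanks of two genes overlap, the position goes to the nearer gene; at
equal distance the upstream bin wins.  The nine categories tile every
scaffold exactly, so category sizes can serve as denominators for
size-standardized SSR densities (loci per Mbp) and as expected proportions
in a chi-square test of random placement.

The gene-term over-representation test (one-sided Fisher's exact with
Benjamini-Hochberg FDR) for SSR-bearing coding genes also lives here.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ssrscape.ssr import SSRLocus

__all__ = [
    "RegionCategory",
    "Transcript",
    "RegionModel",
    "parse_gff3",
    "build_region_model",
    "classify_ssrs",
    "compute_densities",
    "chi_square_uniformity",
    "term_enrichment",
]


class RegionCategory(enum.Enum):
    EXON = "EXON"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRON = "INTRON"
    UP_0_50 = "UP_0_50"
    UP_50_500 = "UP_50_500"
    DOWN_0_50 = "DOWN_0_50"
    DOWN_50_500 = "DOWN_50_500"
    DISTAL = "DISTAL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


GENIC = frozenset({RegionCategory.EXON, RegionCategory.UTR5,
                   RegionCategory.UTR3, RegionCategory.INTRON})

# integer codes used in the per-position label arrays; genic codes are
# ordered by painting precedence (higher paints later, i.e. wins)
_CODE = {
    RegionCategory.DISTAL: 0,
    RegionCategory.DOWN_50_500: 1,
    RegionCategory.UP_50_500: 2,
    RegionCategory.DOWN_0_50: 3,
    RegionCategory.UP_0_50: 4,
    RegionCategory.INTRON: 5,
    RegionCategory.UTR3: 6,
    RegionCategory.UTR5: 7,
    RegionCategory.EXON: 8,
}
_CATEGORY = {code: cat for cat, code in _CODE.items()}


@dataclasses.dataclass
class Transcript:
    """A gene model: transcript span plus exon/CDS/UTR sub-features.

    All coordinates are 1-based inclusive; ``strand`` is ``+`` or ``-``.
    """

    transcript_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    cds: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    utr5: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    utr3: list[tuple[int, int]] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class RegionModel:
    """Complete, non-overlapping partition of every scaffold into categories."""

    labels: dict[str, np.ndarray]  # scaffold -> int8 array, index 0 = position 1
    category_bp: dict[RegionCategory, int]
    genome_bp: int

    def category_at(self, scaffold_id: str, position: int) -> RegionCategory:
        """Category of a single 1-based position."""
        arr = self.labels[scaffold_id]
        if not 1 <= position <= arr.size:
            raise IndexError(
                f"position {position} outside scaffold {scaffold_id!r} (1-{arr.size})"
            )
        return _CATEGORY[int(arr[position - 1])]

    def intervals(self, scaffold_id: str) -> dict[RegionCategory, list[tuple[int, int]]]:
        """Sorted 1-based inclusive intervals per category for one scaffold."""
        arr = self.labels[scaffold_id]
        out: dict[RegionCategory, list[tuple[int, int]]] = {c: [] for c in RegionCategory}
        if arr.size == 0:
            return out
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        for s, e in zip(starts.tolist(), ends.tolist()):
            out[_CATEGORY[int(arr[s])]].append((s + 1, e))
        return out


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.split(";"):
        item = item.strip()
        if item:
            key, _, value = item.partition("=")
            attrs[key] = value
    return attrs


def parse_gff3(path: str | Path) -> list[Transcript]:
    """Read gene models from a GFF3 file.

    Transcripts are taken from ``mRNA``/``transcript`` features (or from
    ``gene`` features that have no mRNA children).  ``exon``, ``CDS``,
    ``five_prime_UTR`` and ``three_prime_UTR`` children are attached via
    their ``Parent`` attribute.  A transcript lacking explicit exons gets a
    single exon covering its span.
    """
    import gffutils

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                merge_strategy="create_unique", keep_order=True)
    transcripts: dict[str, Transcript] = {}
    parents: set[str] = set()
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            transcripts[feat.id] = Transcript(feat.id, feat.seqid, feat.start,
                                              feat.end, feat.strand)
            parents.update(feat.attributes.get("Parent", []))
    for feat in db.features_of_type("gene"):
        has_mrna_child = any(True for _ in db.children(feat, featuretype=("mRNA", "transcript")))
        if not has_mrna_child and feat.id not in transcripts:
            transcripts[feat.id] = Transcript(feat.id, feat.seqid, feat.start,
                                              feat.end, feat.strand)
    kind_map = {"exon": "exons", "CDS": "cds",
                "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}
    for ftype, attr in kind_map.items():
        for feat in db.features_of_type(ftype):
            for parent_id in feat.attributes.get("Parent", []):
                if parent_id in transcripts:
                    getattr(transcripts[parent_id], attr).append((feat.start, feat.end))
    out = []
    for tx in transcripts.values():
        if not tx.exons:
            tx.exons = [(tx.start, tx.end)]
        for attr in ("exons", "cds", "utr5", "utr3"):
            getattr(tx, attr).sort()
        out.append(tx)
    out.sort(key=lambda t: (t.scaffold_id, t.start, t.transcript_id))
    return out


def _derive_utrs(tx: Transcript) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """UTRs for a transcript: explicit features, else exon-minus-CDS by strand."""
    if tx.utr5 or tx.utr3:
        return tx.utr5, tx.utr3
    if not tx.cds:
        return [], []
    cds_lo = min(s for s, _ in tx.cds)
    cds_hi = max(e for _, e in tx.cds)
    left: list[tuple[int, int]] = []   # exon bp numerically left of the CDS span
    right: list[tuple[int, int]] = []
    for s, e in tx.exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo - 1)))
        if e > cds_hi:
            right.append((max(s, cds_hi + 1), e))
    return (left, right) if tx.strand == "+" else (right, left)


def build_region_model(transcripts: Sequence[Transcript] | str | Path,
                       scaffold_lengths: Mapping[str, int],
                       flank_near: int = 50,
                       flank_far: int = 500) -> RegionModel:
    """Assign every scaffold position to exactly one positional category.

    Parameters
    ----------
    transcripts
        Parsed gene models, or a path to a GFF3 file.
    scaffold_lengths
        Mapping of scaffold id to length in bp; scaffolds absent from the
        annotation become entirely DISTAL.
    flank_near, flank_far
        Flank bin edges (closed bins, measured in bp from the transcript's
        outermost coordinate in the transcription direction): distances
        1..flank_near are the near bin, flank_near+1..flank_far the far
        bin, anything further is DISTAL.
    """
    if isinstance(transcripts, (str, Path)):
        transcripts = parse_gff3(transcripts)

    labels = {scaf: np.zeros(length, dtype=np.int8)
              for scaf, length in scaffold_lengths.items()}
    # flank bookkeeping: distance of the best flank claim so far, and
    # whether it was an upstream claim (upstream wins distance ties)
    INF = np.iinfo(np.int16).max
    dist = {scaf: np.full(length, INF, dtype=np.int16)
            for scaf, length in scaffold_lengths.items()}
    is_up = {scaf: np.zeros(length, dtype=bool)
             for scaf, length in scaffold_lengths.items()}

    def paint(arr: np.ndarray, span: tuple[int, int], code: int) -> None:
        s, e = span
        if s < 1 or e > arr.size or s > e:
            raise ValueError(f"feature span {s}-{e} out of scaffold bounds (1-{arr.size})")
        region = arr[s - 1 : e]
        np.maximum(region, np.int8(code), out=region)

    genic_order = (RegionCategory.INTRON, RegionCategory.UTR3,
                   RegionCategory.UTR5, RegionCategory.EXON)
    for tx in transcripts:
        if tx.scaffold_id not in labels:
            raise KeyError(f"transcript {tx.transcript_id} on unknown scaffold "
                           f"{tx.scaffold_id!r}")
        if not tx.exons:
            warnings.warn(f"transcript {tx.transcript_id} has no exons; skipped")
            continue
        arr = labels[tx.scaffold_id]
        utr5, utr3 = _derive_utrs(tx)
        spans = {
            RegionCategory.INTRON: [(tx.start, tx.end)],
            RegionCategory.UTR3: utr3,
            RegionCategory.UTR5: utr5,
            RegionCategory.EXON: tx.cds if tx.cds else tx.exons,
        }
        for cat in genic_order:
            for span in spans[cat]:
                paint(arr, span, _CODE[cat])

    # flanks in a second pass so genic paint from any gene is already final
    for tx in transcripts:
        arr = labels[tx.scaffold_id]
        d = dist[tx.scaffold_id]
        up = is_up[tx.scaffold_id]
        n = arr.size
        # (side, upstream?) -> positions numerically left or right of the span
        left_is_upstream = tx.strand == "+"
        for left_side, upstream in ((True, left_is_upstream), (False, not left_is_upstream)):
            if left_side:
                lo = max(1, tx.start - flank_far)
                hi = tx.start - 1
                if hi < lo:
                    continue
                idx = np.arange(lo - 1, hi)
                cand = tx.start - (idx + 1)  # distance in bp
            else:
                lo = tx.end + 1
                hi = min(n, tx.end + flank_far)
                if hi < lo:
                    continue
                idx = np.arange(lo - 1, hi)
                cand = (idx + 1) - tx.end
            cand = cand.astype(np.int16)
            free = arr[idx] < _CODE[RegionCategory.INTRON]  # not genic
            better = cand < d[idx]
            tie = (cand == d[idx]) & upstream & ~up[idx]
            take = free & (better | tie)
            sel = idx[take]
            d[sel] = cand[take]
            up[sel] = upstream

    for scaf, arr in labels.items():
        d = dist[scaf]
        up = is_up[scaf]
        claimed = d < INF
        near = claimed & (d <= flank_near)
        far = claimed & (d > flank_near)
        arr[near & up] = _CODE[RegionCategory.UP_0_50]
        arr[near & ~up] = _CODE[RegionCategory.DOWN_0_50]
        arr[far & up] = _CODE[RegionCategory.UP_50_500]
        arr[far & ~up] = _CODE[RegionCategory.DOWN_50_500]

    category_bp = {cat: 0 for cat in RegionCategory}
    genome_bp = 0
    for arr in labels.values():
        genome_bp += arr.size
        counts = np.bincount(arr, minlength=9)
        for code, count in enumerate(counts.tolist()):
            category_bp[_CATEGORY[code]] += count
    assert sum(category_bp.values()) == genome_bp
    return RegionModel(labels=labels, category_bp=category_bp, genome_bp=genome_bp)


def classify_ssrs(ssrs: Sequence[SSRLocus], model: RegionModel
                  ) -> tuple[list[RegionCategory], dict[str, int]]:
    """Assign each SSR the category containing its midpoint.

    Returns the per-locus category list (aligned with ``ssrs``) and an
    intergenic/intragenic tally; intragenic means EXON, INTRON, UTR5 or
    UTR3, intergenic everything else.
    """
    categories = []
    tally = {"intragenic": 0, "intergenic": 0}
    for locus in ssrs:
        if locus.scaffold_id not in model.labels:
            raise KeyError(f"SSR on unknown scaffold {locus.scaffold_id!r}")
        cat = model.category_at(locus.scaffold_id, locus.midpoint)
        categories.append(cat)
        tally["intragenic" if cat in GENIC else "intergenic"] += 1
    return categories, tally


def compute_densities(ssrs: Sequence[SSRLocus],
                      categories: Sequence[RegionCategory],
                      model: RegionModel) -> pd.DataFrame:
    """Size-standardized SSR density table.

    One row per category with the region size, SSR count, SSRs per Mbp and
    total SSR bp per Mbp of region; per-unit-length counts and per
    canonical-motif bp/Mbp are included as extra columns.
    """
    rows = {}
    for cat in RegionCategory:
        bp = model.category_bp[cat]
        rows[cat.value] = {
            "category_bp": bp, "ssr_count": 0, "ssr_bp": 0,
            **{f"n_unit{u}": 0 for u in range(1, 7)},
        }
    motif_bp: dict[str, dict[str, int]] = {}
    for locus, cat in zip(ssrs, categories):
        row = rows[cat.value]
        if row["category_bp"] == 0:
            raise ValueError(f"SSRs assigned to zero-length category {cat}")
        row["ssr_count"] += 1
        row["ssr_bp"] += locus.length
        row[f"n_unit{locus.unit_length}"] += 1
        motif_bp.setdefault(locus.canonical, {}).setdefault(cat.value, 0)
        motif_bp[locus.canonical][cat.value] += locus.length
    table = pd.DataFrame.from_dict(rows, orient="index")
    mbp = table["category_bp"] / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        table["ssr_per_mbp"] = np.where(mbp > 0, table["ssr_count"] / mbp, 0.0)
        table["ssr_bp_per_mbp"] = np.where(mbp > 0, table["ssr_bp"] / mbp, 0.0)
    for motif in sorted(motif_bp):
        col = pd.Series({cat: bp for cat, bp in motif_bp[motif].items()},
                        dtype=float).reindex(table.index).fillna(0.0)
        table[f"bp_per_mbp_{motif}"] = np.where(mbp > 0, col / mbp, 0.0)
    table.index.name = "category"
    return table


@dataclasses.dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_uniformity(counts: Mapping[RegionCategory, int] | Mapping[str, int],
                          category_bp: Mapping[RegionCategory, int] | Mapping[str, int]
                          ) -> ChiSquareResult:
    """Chi-square test of SSR placement against region-size expectation.

    Under the null of random placement the expected count in category *i*
    is ``total * bp_i / genome_bp``.
    """
    keys = [k for k in category_bp if category_bp[k] > 0]
    if len(keys) < 2:
        raise ValueError("need at least two non-empty categories")
    obs = np.array([counts.get(k, 0) for k in keys], dtype=float)
    sizes = np.array([category_bp[k] for k in keys], dtype=float)
    total = obs.sum()
    if total == 0:
        raise ValueError("no SSRs to test")
    expected = total * sizes / sizes.sum()
    if np.any(expected == 0):
        raise ValueError("expected count of zero; merge zero-size categories first")
    stat, p = stats.chisquare(obs, expected)
    return ChiSquareResult(statistic=float(stat), df=len(keys) - 1, p_value=float(p))


def term_enrichment(ssr_gene_ids: Iterable[str], all_gene_ids: Iterable[str],
                    gene_to_terms: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Gene-term over-representation among SSR-bearing genes.

    One-sided Fisher's exact test (hypergeometric upper tail) per term on
    the 2x2 table of term membership inside/outside the SSR gene set, with
    Benjamini-Hochberg adjustment across terms.  Genes in the mapping that
    are absent from the background are skipped with a warning.
    """
    study = set(ssr_gene_ids)
    background = set(all_gene_ids)
    if not study:
        raise ValueError("empty SSR gene set")
    if not study <= background:
        raise ValueError("SSR gene set must be a subset of the background")
    term_members: dict[str, set[str]] = {}
    for gene, terms in gene_to_terms.items():
        if gene not in background:
            warnings.warn(f"gene {gene!r} in term mapping but not in background; skipped")
            continue
        for term in terms:
            term_members.setdefault(term, set()).add(gene)
    rows = []
    n_bg, n_study = len(background), len(study)
    for term, members in sorted(term_members.items()):
        k = len(members & study)
        m = len(members)
        # P(X >= k), X ~ Hypergeom(N=n_bg, K=m, n=n_study)
        p = float(stats.hypergeom.sf(k - 1, n_bg, m, n_study))
        rows.append({"term_id": term, "count_in_set": k,
                     "count_in_background": m, "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    return table
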