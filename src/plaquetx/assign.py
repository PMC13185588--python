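"""Seed-and-extend read assignment restricted to unique gene regions.

Reads are aligned with a seeded strategy: fixed-length seeds sampled at a
regular interval along each reference gene are indexed; a read triggers a
full ungapped alignment against a candidate gene only when at least
``min_seed_hits`` of its seeds hit that gene on a consistent diagonal. The
best alignment by identity is kept if it clears ``min_identity``; ties across
targets make the read ambiguous. A kept alignment is counted only if it
overlaps the target gene's unique regions by at least ``min_unique_overlap``
bases — alignments confined to sequence shared between genes are recorded
but never counted, which is what prevents cross-species misassignment.

Defaults follow the seeded-alignment parameters of the upstream taxonomic
classifier: 14 bp seeds every 2 bp, 4 seed hits to trigger an alignment.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .refdb import GeneCatalog, UniqueMaskSet, revcomp

#: diagonal tolerance when chaining seed hits (bp)
DIAG_TOL = 2


@dataclass(frozen=True)
class AlignParams:
    seed_len: int = 14
    seed_interval: int = 2
    min_seed_hits: int = 4
    min_identity: float = 0.9
    min_unique_overlap: int = 1

    def __post_init__(self):
        if self.seed_len < 1 or self.seed_interval < 1 or self.min_seed_hits < 1:
            raise ValueError("seed_len, seed_interval, min_seed_hits must be >= 1")
        if not (0 <= self.min_identity <= 1):
            raise ValueError("min_identity must be in [0,1]")


@dataclass
class ReadAssignment:
    read_id: str
    status: str  # assigned | ambiguous | aligned_nonunique | unassigned
    species_id: str | None = None
    gene_id: str | None = None
    start: int | None = None  # alignment interval on the gene, half-open
    end: int | None = None
    strand: str | None = None
    identity: float | None = None
    reason: str | None = None


class SeedIndex:
    """Forward seeds of every gene at positions 0, interval, 2*interval, ...

    Lookups are done with the read's k-mers as-is and reverse-complemented,
    so both strands are searched without canonicalizing the index.
    """

    def __init__(self, catalog: GeneCatalog, params: AlignParams):
        self.params = params
        self.genes: list[tuple[str, str]] = []
        self.seqs: list[str] = []
        self.seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
        k, step = params.seed_len, params.seed_interval
        for row in catalog.records.itertuples():
            gi = len(self.genes)
            self.genes.append((row.species_id, row.gene_id))
            self.seqs.append(row.sequence)
            for p in range(0, len(row.sequence) - k + 1, step):
                self.seeds[row.sequence[p:p + k]].append((gi, p))
        self.seeds = dict(self.seeds)

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self.seeds.get(kmer, [])


def build_seed_index(catalog: GeneCatalog, params: AlignParams | None = None) -> SeedIndex:
    return SeedIndex(catalog, params or AlignParams())


def _ungapped_identity(read: str, gene: str, offset: int) -> tuple[float, int, int]:
    """Identity of the read laid on the gene at ``offset``.

    Overhang outside the gene counts as mismatch (identity denominator is the
    full read length); the reported interval is clipped to the gene.
    """
    L = len(read)
    a = max(0, offset)
    b = min(len(gene), offset + L)
    if b <= a:
        return 0.0, 0, 0
    matches = sum(1 for i in range(a, b) if gene[i] == read[i - offset])
    return matches / L, a, b


def assign_read(read_id: str, seq: str, index: SeedIndex,
                masks: UniqueMaskSet | None, params: AlignParams | None = None) -> ReadAssignment:
    """Assign one read. See module docstring for the decision sequence."""
    params = params or index.params
    k, step = params.seed_len, params.seed_interval
    if len(seq) < k:
        return ReadAssignment(read_id, "unassigned", reason="read shorter than seed")

    # candidate diagonals per (gene, strand): seed hits voting on an offset.
    # reference seeds sit every seed_interval bases, so the query is scanned
    # at every position to catch alignments at any offset parity
    votes: dict[tuple[int, str, int], int] = defaultdict(int)
    rc = revcomp(seq)
    for rp in range(0, len(seq) - k + 1):
        for gi, gp in index.lookup(seq[rp:rp + k]):
            votes[(gi, "+", gp - rp)] += 1
        for gi, gp in index.lookup(rc[rp:rp + k]):
            votes[(gi, "-", gp - rp)] += 1

    # merge votes within DIAG_TOL per (gene, strand)
    merged: dict[tuple[int, str], list[tuple[int, int]]] = defaultdict(list)
    for (gi, strand, diag), n in votes.items():
        merged[(gi, strand)].append((diag, n))
    candidates = []
    for (gi, strand), dv in merged.items():
        dv.sort()
        i = 0
        while i < len(dv):
            j = i
            total = 0
            while j < len(dv) and dv[j][0] - dv[i][0] <= DIAG_TOL:
                total += dv[j][1]
                j += 1
            if total >= params.min_seed_hits:
                # representative diagonal: the best-supported one in the window
                best_diag = max(dv[i:j], key=lambda t: t[1])[0]
                candidates.append((gi, strand, best_diag))
            i += 1
    if not candidates:
        return ReadAssignment(read_id, "unassigned", reason="insufficient seed hits")

    # full ungapped extension on each candidate; keep the best identity
    best = None
    tied = False
    seen = set()
    for gi, strand, diag in candidates:
        if (gi, strand, diag) in seen:
            continue
        seen.add((gi, strand, diag))
        query = seq if strand == "+" else rc
        ident, a, b = _ungapped_identity(query, index.seqs[gi], diag)
        if best is None or ident > best[0] + 1e-12:
            best = (ident, gi, strand, a, b)
            tied = False
        elif abs(ident - best[0]) <= 1e-12 and gi != best[1]:
            tied = True
    ident, gi, strand, a, b = best
    if ident < params.min_identity:
        return ReadAssignment(read_id, "unassigned", reason="best identity below threshold")
    if tied:
        return ReadAssignment(read_id, "ambiguous", identity=ident)
    sp, gene = index.genes[gi]
    if masks is not None:
        ov = masks.overlap(sp, gene, a, b)
        if ov < params.min_unique_overlap:
            return ReadAssignment(read_id, "aligned_nonunique", species_id=sp,
                                  gene_id=gene, start=a, end=b, strand=strand,
                                  identity=ident)
    return ReadAssignment(read_id, "assigned", species_id=sp, gene_id=gene,
                          start=a, end=b, strand=strand, identity=ident)


def assign_reads(reads, index: SeedIndex, masks: UniqueMaskSet | None,
                 params: AlignParams | None = None) -> list[ReadAssignment]:
    """Assign an iterable of ``(read_id, sequence)`` pairs."""
    return [assign_read(rid, seq, index, masks, params) for rid, seq in reads]


def count_assignments(assignments_by_sample: dict[str, list[ReadAssignment]],
                      sample_sheet: pd.DataFrame,
                      catalog: GeneCatalog) -> pd.DataFrame:
    """Tally status=assigned reads into a features x samples count table.

    Every catalog feature appears (zero-filled); columns follow the sample
    sheet order. Samples present in the assignments but absent from the sheet
    abort the run.
    """
    sheet_samples = list(sample_sheet["sample_id"])
    unknown = set(assignments_by_sample) - set(sheet_samples)
    if unknown:
        raise ValueError(f"assignments for samples not in sample sheet: {sorted(unknown)}")
    ann = catalog.annotations()
    idx = pd.MultiIndex.from_frame(ann)
    counts = pd.DataFrame(0, index=idx, columns=sheet_samples, dtype=np.int64)
    ko_of = {(r.species_id, r.gene_id): r.ko_id for r in ann.itertuples()}
    for sample, assignments in assignments_by_sample.items():
        for a in assignments:
            if a.status != "assigned":
                continue
            key = (a.species_id, a.gene_id, ko_of[(a.species_id, a.gene_id)])
            counts.loc[key, sample] += 1
    return counts


def assignment_summary(assignments: list[ReadAssignment]) -> dict[str, int]:
    out = {"assigned": 0, "ambiguous": 0, "aligned_nonunique": 0, "unassigned": 0}
    for a in assignments:
        out[a.status] += 1
    return out
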