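"""Species-resolved gene reference and unique-region masks.

A pan-species gene catalog maps (species, gene) pairs to annotated DNA
sequences. Because closely related species carry near-identical genes, read
counting is restricted to regions of each gene whose k-mers occur nowhere
else in the catalog — the "unique regions". This module builds the catalog
(including the prevalence-based species selection and the genus-level
annotation substitution used when a species has no gene records of its own)
and computes the unique-region masks.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

HEADER_DELIM = "|"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Strand-collapsed representative: the lexicographic min of a k-mer and
    its reverse complement, so reverse-complement duplicates are not unique."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


class GeneCatalog:
    """Annotated reference gene sequences keyed by (species_id, gene_id).

    Wraps a DataFrame with columns ``species_id, gene_id, ko_id, sequence``.
    Sequences are uppercased and must use the {A,C,G,T} alphabet; the
    (species_id, gene_id) pairs must be unique. An optional ``genus_map``
    (species_id -> genus label) supports annotation substitution.
    """

    COLUMNS = ("species_id", "gene_id", "ko_id", "sequence")

    def __init__(self, records: pd.DataFrame, genus_map: dict[str, str] | None = None):
        records = records.copy().reset_index(drop=True)
        if "ko_id" not in records.columns:
            records["ko_id"] = ""
        records["ko_id"] = records["ko_id"].fillna("")
        missing = [c for c in self.COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        records["sequence"] = records["sequence"].str.upper()
        if (records["sequence"].str.len() == 0).any():
            raise ValueError("catalog contains empty sequences")
        bad = records["sequence"].str.contains("[^ACGT]", regex=True)
        if bad.any():
            raise ValueError("sequences must be over the alphabet {A,C,G,T}")
        if records.duplicated(["species_id", "gene_id"]).any():
            raise ValueError("(species_id, gene_id) pairs must be unique")
        self.records = records[list(self.COLUMNS)]
        self.genus_map = dict(genus_map) if genus_map else None

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> list[tuple[str, str]]:
        return list(zip(self.records.species_id, self.records.gene_id))

    @property
    def species(self) -> list[str]:
        return sorted(self.records.species_id.unique())

    def sequence(self, species_id: str, gene_id: str) -> str:
        m = self.records[(self.records.species_id == species_id)
                         & (self.records.gene_id == gene_id)]
        if m.empty:
            raise KeyError((species_id, gene_id))
        return m.iloc[0].sequence

    def annotations(self) -> pd.DataFrame:
        return self.records[["species_id", "gene_id", "ko_id"]].copy()

    # ---- FASTA round trip (header dialect: >species|gene|ko) ----

    def to_fasta(self, path, delim: str = HEADER_DELIM) -> None:
        recs = [SeqRecord(Seq(r.sequence),
                          id=delim.join([r.species_id, r.gene_id, r.ko_id]),
                          description="")
                for r in self.records.itertuples()]
        SeqIO.write(recs, path, "fasta")

    @classmethod
    def from_fasta(cls, path, delim: str = HEADER_DELIM,
                   genus_map: dict[str, str] | None = None) -> "GeneCatalog":
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split(delim)
            if len(parts) < 2:
                raise ValueError(f"cannot parse header {rec.id!r}; expected species{delim}gene[{delim}ko]")
            sp, gene = parts[0], parts[1]
            ko = parts[2] if len(parts) > 2 else ""
            rows.append({"species_id": sp, "gene_id": gene, "ko_id": ko,
                         "sequence": str(rec.seq)})
        return cls(pd.DataFrame(rows), genus_map=genus_map)


@dataclass
class PrevalenceSelection:
    """Outcome of the top-N / minimum-read species prevalence rule."""
    selected: set[str]
    top_n: int
    min_reads: int
    pooled: bool = False


def select_prevalent_species(per_sample_species_counts: pd.DataFrame,
                             top_n: int = 150, min_reads: int = 1000,
                             pooled: bool = False) -> PrevalenceSelection:
    """Select prevalent species: the union over samples of each sample's
    top ``top_n`` species having at least ``min_reads`` assigned reads.

    ``per_sample_species_counts``: DataFrame indexed by species_id with one
    column per sample (nonnegative integer read counts). Ties in the ranking
    are broken by lexicographic species_id. With ``pooled=True`` the rule is
    instead applied once to the row sums (the alternative reading).
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if min_reads < 0:
        raise ValueError("min_reads must be nonnegative")
    counts = per_sample_species_counts
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    if pooled:
        counts = counts.sum(axis=1).to_frame("pooled")
    selected: set[str] = set()
    for col in counts.columns:
        s = counts[col]
        s = s[s >= min_reads]
        # rank by count desc, species_id asc for ties
        ranked = s.sort_index().sort_values(ascending=False, kind="stable")
        selected.update(ranked.index[:top_n])
    return PrevalenceSelection(selected=selected, top_n=top_n,
                               min_reads=min_reads, pooled=pooled)


def substitute_genus_annotations(catalog: GeneCatalog,
                                 species_missing_genes: list[str]):
    """For species without gene records, borrow the gene set of the
    lexicographically nearest species in the same genus.

    Requires ``catalog.genus_map`` to cover the affected species. Species
    whose genus has no member with genes remain absent. Returns
    ``(new_catalog, report)`` where report maps each missing species to its
    donor (or None).
    """
    gm = catalog.genus_map or {}
    have = set(catalog.records.species_id.unique())
    report: dict[str, str | None] = {}
    new_rows = []
    for sp in species_missing_genes:
        if sp in have:
            report[sp] = sp  # already present, nothing to do
            continue
        genus = gm.get(sp)
        if genus is None:
            raise ValueError(f"no genus annotation for missing species {sp!r}")
        congeners = sorted(s for s in have if gm.get(s) == genus)
        if not congeners:
            report[sp] = None
            continue
        donor = min(congeners, key=lambda s: (abs_lex_distance(s, sp), s))
        rows = catalog.records[catalog.records.species_id == donor].copy()
        rows["species_id"] = sp
        new_rows.append(rows)
        report[sp] = donor
    if not new_rows:
        return catalog, report
    merged = pd.concat([catalog.records] + new_rows, ignore_index=True)
    return GeneCatalog(merged, genus_map=gm), report


def abs_lex_distance(a: str, b: str) -> tuple:
    """Deterministic 'closeness' surrogate for species names: shared-prefix
    length (negated) then the pair sorted lexicographically."""
    n = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            break
        n += 1
    return (-n, a)


class UniqueMaskSet:
    """Per-gene sorted, disjoint half-open intervals of UNIQUE positions.

    A position p of gene g is unique iff every k-mer of g overlapping p has
    its canonical form occurring in exactly one (species, gene) of the
    catalog — namely g itself. ``masks`` maps (species_id, gene_id) to a list
    of [start, end) intervals in 0-based gene coordinates.
    """

    def __init__(self, masks: dict[tuple[str, str], list[tuple[int, int]]], k: int):
        self.k = k
        self.masks = {}
        for key, ivals in masks.items():
            ivals = sorted((int(a), int(b)) for a, b in ivals)
            for (a, b), (c, d) in zip(ivals, ivals[1:]):
                if c < b:
                    raise ValueError(f"overlapping intervals for {key}")
            if any(a >= b for a, b in ivals):
                raise ValueError(f"empty/inverted interval for {key}")
            self.masks[key] = ivals

    def intervals(self, species_id: str, gene_id: str) -> list[tuple[int, int]]:
        return self.masks.get((species_id, gene_id), [])

    def unique_bases(self, species_id: str, gene_id: str) -> int:
        return sum(b - a for a, b in self.intervals(species_id, gene_id))

    def overlap(self, species_id: str, gene_id: str, start: int, end: int) -> int:
        """Bases of [start, end) covered by the gene's unique intervals."""
        return sum(max(0, min(end, b) - max(start, a))
                   for a, b in self.intervals(species_id, gene_id))

    # ---- BED-like TSV round trip (gene as "chromosome", 0-based half-open) ----

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            for (sp, g), ivals in sorted(self.masks.items()):
                for a, b in ivals:
                    fh.write(f"{sp}{HEADER_DELIM}{g}\t{a}\t{b}\n")

    @classmethod
    def from_bed(cls, path) -> "UniqueMaskSet":
        masks: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
        k = 14
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#k="):
                    k = int(line[3:])
                    continue
                chrom, a, b = line.split("\t")
                sp, g = chrom.split(HEADER_DELIM)
                masks[(sp, g)].append((int(a), int(b)))
        return cls(dict(masks), k=k)


def compute_unique_regions(catalog: GeneCatalog, k: int = 14,
                           mode: str = "all") -> UniqueMaskSet:
    """Compute per-gene unique-region masks from a whole-catalog k-mer census.

    Canonical (strand-collapsed) k-mers are used, so a sequence and its
    reverse complement collide. With ``mode="all"`` (default, conservative) a
    position is unique only if ALL k-mers covering it are unique to its gene;
    ``mode="any"`` requires at least one covering k-mer to be unique.

    Genes shorter than k get an empty mask and a warning. Masks are empty for
    genes every k-mer of which occurs in another gene; a singleton catalog
    gene is unique over its full length.
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    # census: canonical k-mer -> set of gene indices (capped at 2: we only
    # need to know whether it is private to one gene)
    owner: dict[str, int] = {}
    AMBIG = -1
    recs = catalog.records
    short = []
    for gi, seq in enumerate(recs.sequence):
        if len(seq) < k:
            short.append(gi)
            continue
        for p in range(len(seq) - k + 1):
            km = canonical(seq[p:p + k])
            cur = owner.get(km)
            if cur is None:
                owner[km] = gi
            elif cur != gi:
                owner[km] = AMBIG
    if short:
        names = [tuple(recs.iloc[gi][["species_id", "gene_id"]]) for gi in short]
        warnings.warn(f"{len(short)} gene(s) shorter than k={k} get empty masks: {names[:5]}")

    masks: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for gi, row in enumerate(recs.itertuples()):
        key = (row.species_id, row.gene_id)
        seq = row.sequence
        L = len(seq)
        if L < k:
            masks[key] = []
            continue
        uniq_kmer = [owner[canonical(seq[p:p + k])] == gi for p in range(L - k + 1)]
        unique_pos = _positions_from_kmers(uniq_kmer, L, k, mode)
        masks[key] = _runs_to_intervals(unique_pos)
    return UniqueMaskSet(masks, k=k)


def _positions_from_kmers(uniq_kmer: list[bool], L: int, k: int, mode: str) -> list[bool]:
    """Lift per-k-mer uniqueness to per-position uniqueness."""
    n_kmers = L - k + 1
    out = [False] * L
    for p in range(L):
        lo = max(0, p - k + 1)
        hi = min(p, n_kmers - 1)
        covering = uniq_kmer[lo:hi + 1]
        out[p] = all(covering) if mode == "all" else any(covering)
    return out


def _runs_to_intervals(flags: list[bool]) -> list[tuple[int, int]]:
    ivals = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            ivals.append((start, i))
            start = None
    if start is not None:
        ivals.append((start, len(flags)))
    return ivals
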