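"""Synthetic metatranscriptome generator with planted ground truth.

Everything downstream of this module (reference building, read assignment,
differential expression, labeling, convergence analysis) can be exercised on
data whose true structure is known exactly: which genes share sequence blocks
across species, which features are differentially expressed in which cohort
and in which direction, and which gene each simulated read came from.

The default design mirrors a paired caries / non-caries study with two
cohorts of 12 and 7 subjects, two plaque samples per subject, and
negative-binomial counts with multiplicative subject and library-size
effects.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refdb import GeneCatalog

TRUTH_CLASSES = ("null", "shared_up", "shared_down", "groupA_only", "groupB_only", "opposite")

#: read-name truth encoding: ``<species>|<gene>|<start>|<strand>|<serial>``
READ_NAME_DELIM = "|"

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimDesign:
    """Parameters of a simulated paired two-cohort study.

    Counts for sample j of subject i are drawn NB with mean

        baseline_i * sizefactor_j * subject_i * 2**(effect_g(i) * caries_j)

    and variance mu + alpha * mu**2 (``dispersion`` is the NB alpha; 0 gives
    the Poisson limit). Per-group log2 effects follow the planted class of
    each feature.
    """

    groups: tuple[str, str] = ("AA", "LAH")
    n_subjects_per_group: tuple[int, int] = (12, 7)
    n_species: int = 12
    genes_per_species: int = 50
    n_kos: int = 40
    frac_shared_de: float = 0.10
    frac_groupA_de: float = 0.05
    frac_groupB_de: float = 0.05
    frac_opposite_de: float = 0.02
    planted_lfc: float = 1.5
    dispersion: float = 0.1
    baseline_mean: float = 200.0
    libsize_spread: tuple[float, float] = (0.5, 2.0)
    gene_length: int = 600
    shared_block_fraction: float = 0.10
    shared_block_len: int = 100
    reads_per_sample: int = 2000
    read_length: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_shared_de, self.frac_groupA_de, self.frac_groupB_de, self.frac_opposite_de)
        if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1 + 1e-12:
            raise ValueError("DE fractions must lie in [0,1] and sum to <= 1")
        if self.n_species < 2 or self.genes_per_species < 1:
            raise ValueError("need at least 2 species and 1 gene per species")
        if self.gene_length <= 0:
            raise ValueError("gene_length must be positive")
        if self.baseline_mean < 0 or self.dispersion < 0:
            raise ValueError("baseline_mean and dispersion must be nonnegative")
        if self.planted_lfc == 0:
            raise ValueError("planted_lfc must be nonzero")
        lo, hi = self.libsize_spread
        if not (0 < lo <= hi):
            raise ValueError("libsize_spread must be 0 < lo <= hi")
        if len(self.groups) != 2 or len(self.n_subjects_per_group) != 2:
            raise ValueError("exactly two groups are supported")

    @classmethod
    def from_json(cls, path) -> "SimDesign":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("groups", "n_subjects_per_group", "libsize_spread"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def generate_catalog(design: SimDesign, rng: np.random.Generator | None = None) -> GeneCatalog:
    """Random gene catalog with planted cross-species shared blocks.

    KO identifiers cycle over genes so that the same KO is carried by genes
    of every species (gene j of each species gets KO ``j % n_kos``), which
    makes species-attribution convergence analysis non-trivial. A fraction
    ``shared_block_fraction`` of gene slots receive a sequence block copied
    verbatim into the homologous gene of one other species, creating
    non-unique regions.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    L = design.gene_length
    species = [f"sp{s:03d}" for s in range(design.n_species)]
    rows = []
    seqs: dict[tuple[str, str], list] = {}
    for sp in species:
        for j in range(design.genes_per_species):
            seq = rng.choice(_BASES, size=L)
            key = (sp, f"g{j:04d}")
            seqs[key] = seq
            rows.append({"species_id": sp, "gene_id": f"g{j:04d}",
                         "ko_id": f"K{j % design.n_kos:05d}"})

    # plant shared blocks: copy a block from one species' gene into another
    # species' gene with the same gene_id
    n_shared_slots = int(round(design.shared_block_fraction * design.genes_per_species))
    blen = min(design.shared_block_len, L)
    if n_shared_slots and blen > 0:
        slots = rng.choice(design.genes_per_species, size=n_shared_slots, replace=False)
        for j in slots:
            a, b = rng.choice(design.n_species, size=2, replace=False)
            start = int(rng.integers(0, L - blen + 1))
            gid = f"g{j:04d}"
            seqs[(species[b], gid)][start:start + blen] = seqs[(species[a], gid)][start:start + blen]

    for r in rows:
        r["sequence"] = "".join(seqs[(r["species_id"], r["gene_id"])])
    return GeneCatalog(pd.DataFrame(rows))


def make_sample_sheet(design: SimDesign) -> pd.DataFrame:
    """Two samples (caries, non_caries) per subject, subjects nested in groups."""
    rows = []
    sidx = 0
    for g, n in zip(design.groups, design.n_subjects_per_group):
        for _ in range(n):
            subj = f"subj{sidx:03d}"
            for cond in ("caries", "non_caries"):
                rows.append({"sample_id": f"{subj}_{cond}", "subject_id": subj,
                             "group": g, "condition": cond})
            sidx += 1
    return pd.DataFrame(rows)


def make_truth(design: SimDesign, catalog: GeneCatalog,
               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign each catalog feature a planted DE class and per-group log2 effects.

    Classes partition features; shared features split evenly between up and
    down. Returns a frame indexed like the catalog with columns
    ``klass, lfc_<groupA>, lfc_<groupB>``.
    """
    rng = np.random.default_rng(design.seed + 1) if rng is None else rng
    feats = catalog.records[["species_id", "gene_id", "ko_id"]].copy()
    n = len(feats)
    perm = rng.permutation(n)
    n_shared = int(round(design.frac_shared_de * n))
    n_a = int(round(design.frac_groupA_de * n))
    n_b = int(round(design.frac_groupB_de * n))
    n_opp = int(round(design.frac_opposite_de * n))
    klass = np.array(["null"] * n, dtype=object)
    pos = 0
    klass[perm[pos:pos + n_shared - n_shared // 2]] = "shared_up"
    pos += n_shared - n_shared // 2
    klass[perm[pos:pos + n_shared // 2]] = "shared_down"
    pos += n_shared // 2
    klass[perm[pos:pos + n_a]] = "groupA_only"
    pos += n_a
    klass[perm[pos:pos + n_b]] = "groupB_only"
    pos += n_b
    klass[perm[pos:pos + n_opp]] = "opposite"

    lfc = design.planted_lfc
    ga, gb = design.groups
    eff_a = np.zeros(n)
    eff_b = np.zeros(n)
    eff_a[klass == "shared_up"] = lfc
    eff_b[klass == "shared_up"] = lfc
    eff_a[klass == "shared_down"] = -lfc
    eff_b[klass == "shared_down"] = -lfc
    eff_a[klass == "groupA_only"] = lfc
    eff_b[klass == "groupB_only"] = lfc
    eff_a[klass == "opposite"] = lfc
    eff_b[klass == "opposite"] = -lfc
    feats["klass"] = klass
    feats[f"lfc_{ga}"] = eff_a
    feats[f"lfc_{gb}"] = eff_b
    return feats


def make_convergent_truth(design: SimDesign, catalog: GeneCatalog,
                          n_convergent_kos: int, n_identical_kos: int = 0,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Truth table planting KO-level functional convergence.

    For each of ``n_convergent_kos`` KOs, the KO's genes in one species are
    made DE (upregulated) only in group A and its genes in a second, disjoint
    species only in group B — the same function carried by different taxa in
    the two cohorts. ``n_identical_kos`` further KOs get the same species DE
    in both groups (identical attribution). Everything else is null.

    Requires each planted KO to be carried by at least two species.
    """
    rng = np.random.default_rng(design.seed + 3) if rng is None else rng
    feats = catalog.records[["species_id", "gene_id", "ko_id"]].copy()
    ga, gb = design.groups
    feats["klass"] = "null"
    feats[f"lfc_{ga}"] = 0.0
    feats[f"lfc_{gb}"] = 0.0
    by_ko = feats.groupby("ko_id")["species_id"].agg(lambda s: sorted(set(s)))
    eligible = [ko for ko, sps in by_ko.items() if len(sps) >= 2]
    want = n_convergent_kos + n_identical_kos
    if len(eligible) < want:
        raise ValueError(f"only {len(eligible)} KOs span >= 2 species; need {want}")
    chosen = list(rng.choice(eligible, size=want, replace=False))
    lfc = abs(design.planted_lfc)
    convergent = set(chosen[:n_convergent_kos])
    identical = set(chosen[n_convergent_kos:])
    for ko in chosen:
        sps = by_ko[ko]
        if ko in convergent:
            sp_a, sp_b = rng.choice(sps, size=2, replace=False)
            in_a = (feats["ko_id"] == ko) & (feats["species_id"] == sp_a)
            in_b = (feats["ko_id"] == ko) & (feats["species_id"] == sp_b)
            feats.loc[in_a, ["klass", f"lfc_{ga}"]] = ["groupA_only", lfc]
            feats.loc[in_b, ["klass", f"lfc_{gb}"]] = ["groupB_only", lfc]
        else:
            sp = rng.choice(sps)
            m = (feats["ko_id"] == ko) & (feats["species_id"] == sp)
            feats.loc[m, ["klass", f"lfc_{ga}", f"lfc_{gb}"]] = ["shared_up", lfc, lfc]
    feats.attrs["convergent_kos"] = sorted(convergent)
    feats.attrs["identical_kos"] = sorted(identical)
    return feats


def generate_counts(design: SimDesign, catalog: GeneCatalog,
                    truth: pd.DataFrame | None = None):
    """Draw the paired NB count matrix.

    Returns ``(counts, sample_sheet, truth)`` where counts is a DataFrame of
    nonnegative integers indexed by (species_id, gene_id, ko_id) with one
    column per sample. Per-feature dispersions are drawn log-normally around
    the design dispersion (sigma 0.3) so that dispersion estimation is
    exercised; ``dispersion = 0`` gives exact Poisson sampling. Subject
    effects are log-normal (sigma 0.3) and shared between a subject's two
    samples; size factors are log-uniform over ``libsize_spread``.
    """
    if len(catalog.records) == 0:
        raise ValueError("catalog is empty")
    rng = np.random.default_rng(design.seed + 2)
    sheet = make_sample_sheet(design)
    if truth is None:
        truth = make_truth(design, catalog, rng=np.random.default_rng(design.seed + 1))
    ga, gb = design.groups
    n_feat = len(truth)
    n_samp = len(sheet)

    base = design.baseline_mean * rng.lognormal(mean=0.0, sigma=0.3, size=n_feat)
    if design.dispersion > 0:
        alpha = rng.lognormal(mean=math.log(design.dispersion), sigma=0.3, size=n_feat)
    else:
        alpha = np.zeros(n_feat)

    subjects = sheet["subject_id"].unique()
    subj_eff = dict(zip(subjects, rng.lognormal(0.0, 0.3, size=len(subjects))))
    lo, hi = design.libsize_spread
    sf = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_samp))

    eff = np.where(sheet["group"].values[None, :] == ga,
                   truth[f"lfc_{ga}"].values[:, None],
                   truth[f"lfc_{gb}"].values[:, None])
    caries = (sheet["condition"].values == "caries").astype(float)[None, :]
    subj = np.array([subj_eff[s] for s in sheet["subject_id"]])[None, :]
    mu = base[:, None] * sf[None, :] * subj * np.power(2.0, eff * caries)

    counts = np.empty((n_feat, n_samp), dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        a = alpha[~pois][:, None]
        r = 1.0 / a
        p = r / (r + mu[~pois])
        counts[~pois] = rng.negative_binomial(np.broadcast_to(r, p.shape), p)

    idx = pd.MultiIndex.from_frame(truth[["species_id", "gene_id", "ko_id"]])
    cdf = pd.DataFrame(counts, index=idx, columns=sheet["sample_id"].tolist())
    tdf = truth.set_index(["species_id", "gene_id", "ko_id"])
    return cdf, sheet, tdf


def generate_reads(catalog: GeneCatalog, abundances, n_reads: int,
                   read_length: int = 150, error_rate: float = 0.0,
                   seed: int = 0, rc_fraction: float = 0.5):
    """Sample error-prone single-end reads from catalog genes.

    ``abundances`` maps (species_id, gene_id) -> nonnegative weight; reads are
    drawn from genes proportional to weight, uniformly positioned, reverse-
    complemented with probability ``rc_fraction``, and substituted per base at
    ``error_rate``. Read names encode the truth as
    ``species|gene|start|strand|serial`` (see :data:`READ_NAME_DELIM`).

    Returns a list of ``(name, sequence)`` tuples. Genes shorter than
    ``read_length`` are dropped with a warning; if all are too short a
    ValueError is raised.
    """
    rng = np.random.default_rng(seed)
    recs = catalog.records
    keys, weights, seqs = [], [], []
    skipped = []
    for _, r in recs.iterrows():
        w = float(abundances.get((r.species_id, r.gene_id), 0.0))
        if w < 0:
            raise ValueError("abundances must be nonnegative")
        if w == 0:
            continue
        if len(r.sequence) < read_length:
            skipped.append((r.species_id, r.gene_id))
            continue
        keys.append((r.species_id, r.gene_id))
        weights.append(w)
        seqs.append(r.sequence)
    if skipped:
        import warnings
        warnings.warn(f"{len(skipped)} genes shorter than read_length skipped")
    if not keys:
        if skipped:
            raise ValueError("all genes with nonzero abundance are shorter than read_length")
        return []
    w = np.asarray(weights, dtype=float)
    gene_idx = rng.choice(len(keys), size=n_reads, p=w / w.sum())
    reads = []
    for serial, gi in enumerate(gene_idx):
        seq = seqs[gi]
        start = int(rng.integers(0, len(seq) - read_length + 1))
        frag = seq[start:start + read_length]
        strand = "-" if rng.random() < rc_fraction else "+"
        if strand == "-":
            frag = _revcomp(frag)
        if error_rate > 0:
            arr = np.frombuffer(frag.encode(), dtype="S1").astype("U1")
            hit = rng.random(read_length) < error_rate
            if hit.any():
                for i in np.flatnonzero(hit):
                    arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
                frag = "".join(arr)
        sp, g = keys[gi]
        name = READ_NAME_DELIM.join([sp, g, str(start), strand, str(serial)])
        reads.append((name, frag))
    return reads


def reads_for_samples(design: SimDesign, catalog: GeneCatalog, counts: pd.DataFrame):
    """Per-sample read sets drawn proportional to each sample's count column.

    Yields ``(sample_id, reads)`` where reads follow :func:`generate_reads`.
    """
    for i, sample in enumerate(counts.columns):
        ab = {(sp, g): float(c) for (sp, g, _), c in counts[sample].items()}
        yield sample, generate_reads(
            catalog, ab, n_reads=design.reads_per_sample,
            read_length=design.read_length, error_rate=design.error_rate,
            seed=design.seed + 1000 + i)


def parse_read_name(name: str) -> dict:
    sp, gene, start, strand, serial = name.split(READ_NAME_DELIM)
    return {"species_id": sp, "gene_id": gene, "start": int(start),
            "strand": strand, "serial": int(serial)}
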