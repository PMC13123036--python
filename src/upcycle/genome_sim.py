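"""Forward-in-time genome simulation for a closed pig breeding population.

The genome model is deliberately simple: a fixed number of autosomes with
loci at random centimorgan positions, biallelic alleles, purely additive
QTL, and crossovers from a Poisson (no-interference, Haldane) process.
Founder genomes are produced by a neutral Wright-Fisher history that builds
up drift-shaped allele frequencies and within-chromosome linkage
disequilibrium.  Every haplotype carries, per locus, the identity of the
founder haplotype it descends from, so identity-by-descent can be measured
exactly downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "GeneticMap",
    "HaplotypePanel",
    "TraitArchitecture",
    "PEDIGREE_COLUMNS",
    "MALE",
    "FEMALE",
    "build_genetic_map",
    "place_qtl",
    "simulate_founder_history",
    "select_chip_snps",
    "assign_trait_architecture",
    "meiosis",
    "gametes_batch",
    "breed_offspring",
    "make_pedigree",
]

MALE = 1
FEMALE = 2

#: columns of the pedigree table used throughout the package
PEDIGREE_COLUMNS = ("id", "sire", "dam", "sex", "generation", "component", "tbv", "phenotype", "gebv")


# ---------------------------------------------------------------------------
# genetic map


@dataclass
class GeneticMap:
    """Chromosome assignment and cM position per locus, plus chip/QTL masks.

    Loci are stored in genome order (by chromosome, then position).  The
    chip mask and QTL mask are disjoint: the genotyping array never includes
    QTL positions.
    """

    chrom: np.ndarray            # int32 [n_loci], 0-based chromosome index
    cm: np.ndarray               # float64 [n_loci], position in cM
    chip_mask: np.ndarray        # bool [n_loci]
    qtl_mask: np.ndarray         # bool [n_loci]
    n_chromosomes: int
    chrom_length_cm: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if np.any(self.chip_mask & self.qtl_mask):
            raise ValueError("chip and QTL masks overlap")
        for sl in self.chrom_slices():
            if np.any(np.diff(self.cm[sl]) < 0):
                raise ValueError("cM positions not sorted within chromosome")

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    @property
    def chip_idx(self) -> np.ndarray:
        return np.flatnonzero(self.chip_mask)

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(self.qtl_mask)

    def chrom_slices(self) -> list[slice]:
        bounds = np.searchsorted(self.chrom, np.arange(self.n_chromosomes + 1))
        return [slice(bounds[c], bounds[c + 1]) for c in range(self.n_chromosomes)]

    def subset_slices(self, loci: np.ndarray) -> list[slice]:
        """Chromosome slices of an ordered locus-index subset (e.g. the chip)."""
        sub = self.chrom[loci]
        bounds = np.searchsorted(sub, np.arange(self.n_chromosomes + 1))
        return [slice(bounds[c], bounds[c + 1]) for c in range(self.n_chromosomes)]

    def locus_weights(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Midpoint-rule cM weight per locus, normalised to sum to one.

        Used for length-weighted genome averages (e.g. founder-IBD kinship).
        """
        idx = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        cm, chrom = self.cm[idx], self.chrom[idx]
        w = np.zeros(idx.size)
        sub = self.subset_slices(idx) if loci is not None else self.chrom_slices()
        for sl in sub:
            c = cm[sl]
            if c.size == 0:
                continue
            if c.size == 1:
                w[sl] = 1.0  # lone locus: nominal weight
                continue
            mid = np.empty(c.size + 1)
            mid[0], mid[-1] = c[0], c[-1]
            mid[1:-1] = 0.5 * (c[:-1] + c[1:])
            w[sl.start:sl.stop] = np.diff(mid)
            # end loci get half-intervals only; extend by mean spacing so
            # chromosome ends are not systematically down-weighted
            w[sl.start] += 0.5 * np.mean(np.diff(c))
            w[sl.stop - 1] += 0.5 * np.mean(np.diff(c))
        s = w.sum()
        return w / s if s > 0 else np.full(idx.size, 1.0 / max(idx.size, 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "cm": self.cm, "is_chip": self.chip_mask, "is_qtl": self.qtl_mask}
        )


def build_genetic_map(
    n_chrom: int, n_loci: int, chrom_length_cm: float = 100.0, seed: int | np.random.Generator = 0
) -> GeneticMap:
    """Place ``n_loci`` loci uniformly at random on ``n_chrom`` chromosomes.

    Loci are split as evenly as possible across chromosomes and sorted by
    position.  Fails if any chromosome would receive fewer than two loci.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "genetic-map")
    per = np.full(n_chrom, n_loci // n_chrom, dtype=int)
    per[: n_loci % n_chrom] += 1
    if per.min() < 2:
        raise ValueError("each chromosome needs at least 2 loci")
    chrom = np.repeat(np.arange(n_chrom, dtype=np.int32), per)
    cm = np.concatenate([np.sort(rng.uniform(0.0, chrom_length_cm, k)) for k in per])
    zeros = np.zeros(n_loci, dtype=bool)
    return GeneticMap(chrom, cm, zeros.copy(), zeros.copy(), n_chrom, float(chrom_length_cm))


def place_qtl(gmap: GeneticMap, n_qtl: int, seed: int | np.random.Generator = 0) -> GeneticMap:
    """Flag ``n_qtl`` loci, chosen uniformly at random, as QTL."""
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "qtl-placement")
    if n_qtl > gmap.n_loci:
        raise ValueError("more QTL than loci")
    idx = rng.choice(gmap.n_loci, size=n_qtl, replace=False)
    qtl = np.zeros(gmap.n_loci, dtype=bool)
    qtl[idx] = True
    return replace(gmap, qtl_mask=qtl, chip_mask=gmap.chip_mask & ~qtl)


# ---------------------------------------------------------------------------
# haplotype storage


@dataclass
class HaplotypePanel:
    """Phased binary alleles with per-locus founder-haplotype labels.

    ``alleles`` and ``founder_label`` are shaped [2, n_animals, n_loci];
    axis 0 indexes the two haplotypes of each animal.
    """

    alleles: np.ndarray        # uint8 [2, n, L]
    founder_label: np.ndarray  # int32 [2, n, L]
    ids: np.ndarray            # int64 [n]
    _row_of: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self._row_of = {int(i): r for r, i in enumerate(self.ids)}

    @property
    def n_animals(self) -> int:
        return self.ids.size

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[2]

    def rows(self, ids: np.ndarray | list) -> np.ndarray:
        return np.array([self._row_of[int(i)] for i in ids], dtype=np.intp)

    def genotypes(self, loci: np.ndarray | None = None, rows: np.ndarray | None = None) -> np.ndarray:
        """Allele counts in {0,1,2}, shape [n_animals, n_loci_selected]."""
        a = self.alleles if rows is None else self.alleles[:, rows, :]
        if loci is not None:
            a = a[:, :, loci]
        return a.sum(axis=0, dtype=np.int16).astype(np.uint8)

    def haplotypes(self, loci: np.ndarray | None = None, rows: np.ndarray | None = None) -> np.ndarray:
        """Haplotypes stacked as [n_animals, 2, n_loci_selected]."""
        a = self.alleles if rows is None else self.alleles[:, rows, :]
        if loci is not None:
            a = a[:, :, loci]
        return np.ascontiguousarray(np.moveaxis(a, 0, 1))

    def allele_freq(self, loci: np.ndarray | None = None, rows: np.ndarray | None = None) -> np.ndarray:
        a = self.alleles if rows is None else self.alleles[:, rows, :]
        if loci is not None:
            a = a[:, :, loci]
        return a.mean(axis=(0, 1))

    def subset(self, rows: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(self.alleles[:, rows], self.founder_label[:, rows], self.ids[rows])

    @classmethod
    def from_parts(cls, alleles: np.ndarray, labels: np.ndarray, ids: np.ndarray) -> "HaplotypePanel":
        return cls(np.asarray(alleles, dtype=np.uint8), np.asarray(labels, dtype=np.int32), ids)


# ---------------------------------------------------------------------------
# founder history


def simulate_founder_history(
    gmap: GeneticMap,
    n_founders: int,
    n_history_generations: int = 150,
    history_ne: int = 100,
    seed: int | np.random.Generator = 0,
    init_freq: np.ndarray | tuple[float, float] = (0.1, 0.9),
) -> HaplotypePanel:
    """Neutral Wright-Fisher history producing the founder haplotype panel.

    A population of ``history_ne`` diploids mates at random for
    ``n_history_generations`` generations; the final generation breeds the
    ``n_founders`` founder animals.  Initial allele frequencies per locus
    are drawn uniformly from ``init_freq`` (or taken as given when an array
    is passed).  Drift shapes the allele-frequency spectrum and
    recombination-limited coancestry creates within-chromosome LD.  Founder
    haplotypes receive the labels ``0 .. 2*n_founders-1``.
    """
    if n_founders % 2:
        raise ValueError("n_founders must be even")
    if history_ne < 2:
        raise ValueError("history_ne must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "founder-history")
    L = gmap.n_loci
    if isinstance(init_freq, tuple):
        p0 = rng.uniform(init_freq[0], init_freq[1], L)
    else:
        p0 = np.asarray(init_freq, dtype=float)
    pop = (rng.random((2, history_ne, L)) < p0).astype(np.uint8)
    dummy_labels = np.zeros_like(pop, dtype=np.int32)

    for _ in range(n_history_generations):
        sires = rng.integers(0, history_ne, history_ne)
        dams = (sires + 1 + rng.integers(0, history_ne - 1, history_ne)) % history_ne
        g1, _ = gametes_batch(pop, dummy_labels, sires, gmap, rng)
        g2, _ = gametes_batch(pop, dummy_labels, dams, gmap, rng)
        pop = np.stack([g1, g2])

    sires = rng.integers(0, history_ne, n_founders)
    dams = (sires + 1 + rng.integers(0, history_ne - 1, n_founders)) % history_ne
    g1, _ = gametes_batch(pop, dummy_labels, sires, gmap, rng)
    g2, _ = gametes_batch(pop, dummy_labels, dams, gmap, rng)
    alleles = np.stack([g1, g2])
    labels = (
        np.arange(2 * n_founders, dtype=np.int32).reshape(2, n_founders)[:, :, None]
        * np.ones(L, dtype=np.int32)
    )
    return HaplotypePanel(alleles, labels, np.arange(n_founders, dtype=np.int64))


def select_chip_snps(panel: HaplotypePanel, gmap: GeneticMap, n_chip: int) -> GeneticMap:
    """Mark the ``n_chip`` non-QTL loci with the highest founder MAF as chip SNPs.

    Mimics commercial array design: common variants only, QTL positions
    excluded.  Ties are broken by ascending locus index; if fewer than
    ``n_chip`` polymorphic non-QTL loci exist, monomorphic loci pad the chip
    (with a warning).
    """
    p = panel.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    eligible = ~gmap.qtl_mask
    if n_chip > int(eligible.sum()):
        raise ValueError("n_chip exceeds number of non-QTL loci")
    cand = np.flatnonzero(eligible)
    order = cand[np.lexsort((cand, -maf[cand]))]
    chosen = order[:n_chip]
    if maf[chosen].min() == 0.0:
        warnings.warn("chip padded with monomorphic loci", stacklevel=2)
    chip = np.zeros(gmap.n_loci, dtype=bool)
    chip[chosen] = True
    return replace(gmap, chip_mask=chip)


# ---------------------------------------------------------------------------
# trait architecture


@dataclass
class TraitArchitecture:
    """Additive QTL effects, oriented so alpha is the beneficial-allele effect."""

    qtl_effects: np.ndarray       # float64 [n_qtl], >= 0
    beneficial_allele: np.ndarray  # uint8 [n_qtl], 0 or 1
    h2_base: float
    sigma2_e: float
    sigma2_g_base: float
    qtl_idx: np.ndarray           # locus indices of the QTL in the map

    def tbv(self, panel: HaplotypePanel, rows: np.ndarray | None = None) -> np.ndarray:
        """True breeding value: beneficial-allele dose times effect, summed."""
        a = panel.alleles if rows is None else panel.alleles[:, rows, :]
        a = a[:, :, self.qtl_idx]
        dose = (a == self.beneficial_allele[None, None, :]).sum(axis=0)
        return dose.astype(np.float64) @ self.qtl_effects

    def beneficial_freq(self, panel: HaplotypePanel, rows: np.ndarray | None = None) -> np.ndarray:
        a = panel.alleles if rows is None else panel.alleles[:, rows, :]
        a = a[:, :, self.qtl_idx]
        return (a == self.beneficial_allele[None, None, :]).mean(axis=(0, 1))


def assign_trait_architecture(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    n_qtl: int,
    h2: float = 0.3,
    effect_seed: int | np.random.Generator = 0,
) -> TraitArchitecture:
    """Draw standard-normal QTL effects and solve the residual variance for h2.

    Effects are recorded for the beneficial allele (the direction that
    increases the trait), so all stored effects are non-negative.  The
    residual variance is set from the realised base-generation TBV variance:
    sigma2_e = Var(TBV) * (1 - h2) / h2.
    """
    qtl_idx = gmap.qtl_idx
    if qtl_idx.size != n_qtl:
        raise ValueError(f"map flags {qtl_idx.size} QTL, expected {n_qtl}")
    rng = effect_seed if isinstance(effect_seed, np.random.Generator) else substream(effect_seed, "qtl-effects")
    raw = rng.standard_normal(n_qtl)
    beneficial = (raw > 0).astype(np.uint8)  # allele 1 beneficial iff effect positive
    trait = TraitArchitecture(np.abs(raw), beneficial, float(h2), 0.0, 0.0, qtl_idx)
    v = float(np.var(trait.tbv(panel)))
    if v == 0.0:
        raise ValueError("base TBV variance is zero; cannot calibrate residual variance")
    trait.sigma2_g_base = v
    trait.sigma2_e = v * (1.0 - h2) / h2 if h2 > 0 else np.inf
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    return trait


# ---------------------------------------------------------------------------
# meiosis


def meiosis(
    parent_alleles: np.ndarray,
    parent_labels: np.ndarray,
    gmap: GeneticMap,
    seed: int | np.random.Generator = 0,
    return_crossovers: bool = False,
):
    """Single gamete from one parent via an explicit Poisson crossover process.

    Crossover counts per chromosome are Poisson with mean equal to the
    chromosome length in Morgan; positions are uniform; no interference.
    Founder labels travel with the alleles they annotate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "meiosis")
    L = parent_alleles.shape[1]
    out_a = np.empty(L, dtype=parent_alleles.dtype)
    out_l = np.empty(L, dtype=parent_labels.dtype)
    crossovers: list[np.ndarray] = []
    for sl in gmap.chrom_slices():
        cm = gmap.cm[sl]
        span = cm[-1] - cm[0] if cm.size else 0.0
        k = rng.poisson(span / 100.0)
        pos = np.sort(rng.uniform(cm[0], cm[-1], k)) if k else np.empty(0)
        crossovers.append(pos)
        start = rng.integers(2)
        source = (start + np.searchsorted(pos, cm, side="right")) % 2
        out_a[sl] = np.where(source == 0, parent_alleles[0, sl], parent_alleles[1, sl])
        out_l[sl] = np.where(source == 0, parent_labels[0, sl], parent_labels[1, sl])
    if return_crossovers:
        return out_a, out_l, crossovers
    return out_a, out_l


def _switch_probs(gmap: GeneticMap) -> list[np.ndarray]:
    probs = []
    for sl in gmap.chrom_slices():
        d = np.diff(gmap.cm[sl]) / 100.0  # Morgan
        probs.append(0.5 * (1.0 - np.exp(-2.0 * d)))  # Haldane
    return probs


def gametes_batch(
    alleles: np.ndarray,
    labels: np.ndarray,
    parent_rows: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised meiosis for a batch of gametes, one per entry of parent_rows.

    Uses the marker-transmission Markov chain equivalent to the Poisson
    crossover process (Haldane switch probability per marker interval),
    which yields exactly the same marker-level transmission law as
    :func:`meiosis` without per-gamete Python loops.
    """
    B = len(parent_rows)
    L = alleles.shape[2]
    out_a = np.empty((B, L), dtype=alleles.dtype)
    out_l = np.empty((B, L), dtype=labels.dtype)
    pa = alleles[:, parent_rows, :]  # [2, B, L]
    pl = labels[:, parent_rows, :]
    for sl, sp in zip(gmap.chrom_slices(), _switch_probs(gmap)):
        n = sl.stop - sl.start
        switches = rng.random((B, n)) < np.concatenate(([0.0], sp))[None, :]
        switches[:, 0] = rng.integers(0, 2, B)  # random start haplotype
        source = np.cumsum(switches, axis=1, dtype=np.int32) & 1
        take = source.astype(bool)
        seg_a = np.where(take, pa[1, :, sl.start:sl.stop], pa[0, :, sl.start:sl.stop])
        seg_l = np.where(take, pl[1, :, sl.start:sl.stop], pl[0, :, sl.start:sl.stop])
        out_a[:, sl.start:sl.stop] = seg_a
        out_l[:, sl.start:sl.stop] = seg_l
    return out_a, out_l


# ---------------------------------------------------------------------------
# breeding


def make_pedigree(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=list(PEDIGREE_COLUMNS))
    return df.astype({"id": np.int64, "sire": np.int64, "dam": np.int64, "sex": np.int8, "generation": np.int32})


def breed_offspring(
    panel: HaplotypePanel,
    pedigree: pd.DataFrame,
    matings: list[tuple[int, int]] | np.ndarray,
    litter_size: int,
    component_tag: str | list[str],
    gmap: GeneticMap,
    trait: TraitArchitecture,
    seed: int | np.random.Generator,
    generation: int,
    id_start: int,
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Produce litters for a list of (sire_id, dam_id) matings.

    Each mating yields ``litter_size`` offspring (sex Bernoulli(0.5)); TBV
    is computed from QTL genotypes and the phenotype adds Normal(0,
    sigma2_e) noise.  Selfing and sex-mismatched parents are rejected.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "breeding")
    matings = list(matings)
    sex_of = dict(zip(pedigree["id"].to_numpy(), pedigree["sex"].to_numpy()))
    for s, d in matings:
        if s == d:
            raise ValueError(f"selfing not allowed (animal {s})")
        if sex_of.get(int(s)) != MALE or sex_of.get(int(d)) != FEMALE:
            raise ValueError(f"sex mismatch in mating ({s}, {d})")
    tags = [component_tag] * len(matings) if isinstance(component_tag, str) else list(component_tag)

    sire_rows = panel.rows([s for s, _ in matings]).repeat(litter_size)
    dam_rows = panel.rows([d for _, d in matings]).repeat(litter_size)
    ga, gl = gametes_batch(panel.alleles, panel.founder_label, sire_rows, gmap, rng)
    ha, hl = gametes_batch(panel.alleles, panel.founder_label, dam_rows, gmap, rng)
    n = len(sire_rows)
    alleles = np.stack([ga, ha])
    labels = np.stack([gl, hl])
    ids = np.arange(id_start, id_start + n, dtype=np.int64)
    child = HaplotypePanel(alleles, labels, ids)

    tbv = trait.tbv(child)
    noise = rng.standard_normal(n) * np.sqrt(trait.sigma2_e) if trait.sigma2_e > 0 else 0.0
    pheno = tbv + noise
    sex = np.where(rng.random(n) < 0.5, MALE, FEMALE).astype(np.int8)
    recs = make_pedigree(
        [
            {
                "id": ids[k],
                "sire": matings[k // litter_size][0],
                "dam": matings[k // litter_size][1],
                "sex": sex[k],
                "generation": generation,
                "component": tags[k // litter_size],
                "tbv": tbv[k],
                "phenotype": float(np.asarray(pheno)[k]) if np.ndim(pheno) else tbv[k],
                "gebv": np.nan,
            }
            for k in range(n)
        ]
    )
    return child, recs
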