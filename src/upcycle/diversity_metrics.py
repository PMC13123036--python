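"""Diversity-donor criteria, diversity statistics and small theory utilities.

Three criteria rank candidate donors against an elite reference set:

* **rare beneficial haplotypes** — greedy selection of the donor whose
  haplotypes raise the sum over genome windows of the best per-window
  haplotype breeding value the most (windows of 44 chip SNPs, stepping by
  20% of the window length);
* **rare (unique) haplotypes** — greedy selection of the donor adding the
  most haplotype variants not yet seen per non-overlapping 1 cM segment;
* **low average kinship** — donors with the lowest mean segment-based IBD
  kinship to the elite, where two haplotypes count as sharing a segment
  only for runs of literally identical alleles of at least 4 cM and at
  least 20 consecutive SNPs.

The module also provides the summary statistics tracked per generation
(genic variance, selection limit, unique-haplotype counts, founder-IBD
kinship) and the classical single-locus drift formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_sim import GeneticMap, HaplotypePanel, TraitArchitecture

__all__ = [
    "WindowScheme",
    "SegmentKinshipSpec",
    "build_windows",
    "window_haplotype_ebvs",
    "select_donors_beneficial",
    "count_unique_haplotypes",
    "select_donors_unique",
    "segment_ibd_kinship",
    "segment_ibd_kinship_cross",
    "select_donors_low_kinship",
    "genic_variance",
    "selection_limit",
    "true_ibd_kinship",
    "mean_true_ibd_kinship",
    "allele_retention_probability",
    "expected_backcross_kinship",
    "elite_genome_fraction",
    "delta_f",
    "inbreeding_after",
]


@dataclass
class WindowScheme:
    """Sliding-window / fixed-segment geometry for haplotype statistics."""

    window_snps: int = 44
    step_fraction: float = 0.20
    fixed_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if not 0.0 < self.step_fraction <= 1.0:
            raise ValueError("step_fraction must be in (0, 1]")

    @property
    def step_snps(self) -> int:
        return max(1, round(self.step_fraction * self.window_snps))


@dataclass
class SegmentKinshipSpec:
    """Minimum length requirements for a shared run to count as IBD."""

    min_segment_cm: float = 4.0
    min_consecutive_snps: int = 20

    def __post_init__(self) -> None:
        if self.min_segment_cm <= 0 or self.min_consecutive_snps <= 0:
            raise ValueError("segment thresholds must be positive")


# ---------------------------------------------------------------------------
# windows and haplotype breeding values (rare beneficial haplotypes)


def build_windows(gmap: GeneticMap, scheme: WindowScheme, loci: np.ndarray | None = None) -> list[np.ndarray]:
    """Index windows (into the supplied locus subset) per chromosome.

    Windows hold ``window_snps`` consecutive loci and advance by
    ``step_snps``; they never span chromosome boundaries.  A trailing
    partial window is kept if it covers at least half a window, otherwise
    its loci are merged into the previous window.
    """
    loci = gmap.chip_idx if loci is None else np.asarray(loci)
    win, step = scheme.window_snps, scheme.step_snps
    windows: list[np.ndarray] = []
    for sl in gmap.subset_slices(loci):
        n = sl.stop - sl.start
        if n == 0:
            continue
        if n <= win:
            windows.append(np.arange(sl.start, sl.stop))
            continue
        starts = list(range(0, n - win + 1, step))
        chrom_windows = [np.arange(sl.start + s, sl.start + s + win) for s in starts]
        tail = starts[-1] + win
        if tail < n:
            rest = n - tail
            if rest >= win / 2:
                chrom_windows.append(np.arange(sl.start + tail, sl.stop))
            else:
                chrom_windows[-1] = np.arange(sl.start + starts[-1], sl.stop)
        windows.extend(chrom_windows)
    if not windows:
        raise ValueError("empty window set")
    return windows


def window_haplotype_ebvs(
    haplotypes: np.ndarray,
    gmap: GeneticMap,
    snp_effects: np.ndarray,
    scheme: WindowScheme | None = None,
    windows: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Per-haplotype, per-window estimated breeding values.

    ``haplotypes`` is [n_haplotypes, n_chip_loci]; the value of haplotype h
    in window w is the sum over the window's loci of effect * allele.
    """
    haplotypes = np.asarray(haplotypes)
    if windows is None:
        windows = build_windows(gmap, scheme or WindowScheme())
    weighted = haplotypes * np.asarray(snp_effects, dtype=float)[None, :]
    cs = np.concatenate([np.zeros((haplotypes.shape[0], 1)), np.cumsum(weighted, axis=1)], axis=1)
    out = np.empty((haplotypes.shape[0], len(windows)))
    for k, w in enumerate(windows):
        # windows are contiguous index ranges
        out[:, k] = cs[:, w[-1] + 1] - cs[:, w[0]]
    return out


def _tie_order(gains: np.ndarray, generations: np.ndarray, ids: np.ndarray) -> int:
    """Argmax of gains; ties broken by older generation, then lower id."""
    best = np.flatnonzero(gains == gains.max())
    sub = best[np.lexsort((ids[best], generations[best]))]
    return int(sub[0])


def select_donors_beneficial(
    candidate_haps: np.ndarray,
    candidate_ids: np.ndarray,
    candidate_generations: np.ndarray,
    elite_haps: np.ndarray,
    snp_effects: np.ndarray,
    gmap: GeneticMap,
    scheme: WindowScheme | None = None,
    n_donors: int = 1,
) -> tuple[list[int], list[float]]:
    """Greedy donor selection maximising the summed best-window EBV.

    ``candidate_haps`` is [n_candidates, 2, n_chip]; ``elite_haps`` is
    [n_elite_haplotypes, n_chip].  Each round picks the candidate whose two
    haplotypes raise ``sum_w max(haplotype EBV in window w)`` over the
    current reference (elite plus donors already chosen) the most; the
    winner's haplotypes then join the reference.  Zero-gain donors may be
    selected when no candidate improves any window.
    """
    scheme = scheme or WindowScheme()
    windows = build_windows(gmap, scheme)
    cand = np.asarray(candidate_haps)
    n_c = cand.shape[0]
    cand_flat = cand.reshape(2 * n_c, -1)
    cand_vals = window_haplotype_ebvs(cand_flat, gmap, snp_effects, windows=windows)
    # rows 2k and 2k+1 of cand_flat are the two haplotypes of candidate k
    cand_best = np.maximum(cand_vals[0::2], cand_vals[1::2])  # [n_c, W]
    elite_vals = window_haplotype_ebvs(np.asarray(elite_haps), gmap, snp_effects, windows=windows)
    ref_max = elite_vals.max(axis=0) if elite_vals.size else np.full(len(windows), -np.inf)

    ids = np.asarray(candidate_ids)
    gens = np.asarray(candidate_generations)
    chosen: list[int] = []
    gains: list[float] = []
    available = np.ones(n_c, dtype=bool)
    for _ in range(min(n_donors, n_c)):
        gain = np.where(available, np.maximum(cand_best - ref_max, 0.0).sum(axis=1), -np.inf)
        k = _tie_order(np.where(available, gain, -np.inf), gens, ids)
        chosen.append(int(ids[k]))
        gains.append(float(gain[k]))
        ref_max = np.maximum(ref_max, cand_best[k])
        available[k] = False
    return chosen, gains


# ---------------------------------------------------------------------------
# unique haplotypes (rare haplotypes)


def _segment_slices(gmap: GeneticMap, loci: np.ndarray, fixed_cm: float) -> list[tuple[int, int, np.ndarray]]:
    """Non-overlapping cM tiles; returns (chrom, tile index, locus positions in subset)."""
    out = []
    cm = gmap.cm[loci]
    for c, sl in enumerate(gmap.subset_slices(loci)):
        n_seg = int(np.ceil(gmap.chrom_length_cm / fixed_cm))
        pos = cm[sl]
        tile = np.minimum((pos / fixed_cm).astype(int), n_seg - 1)
        for t in range(n_seg):
            idx = sl.start + np.flatnonzero(tile == t)
            out.append((c, t, idx))
    return out


def _hap_keys(haps: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Hashable byte keys of the allele strings of every haplotype at idx."""
    block = np.ascontiguousarray(haps[:, idx])
    return block.view(np.dtype((np.void, block.shape[1]))).ravel()


def count_unique_haplotypes(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    fixed_cm: float = 1.0,
    use_all_loci: bool = True,
    rows: np.ndarray | None = None,
    warn_empty: bool = True,
) -> tuple[int, np.ndarray]:
    """Distinct haplotype count per non-overlapping cM segment, and the total.

    Chromosomes are tiled with half-open [k, k+1) cM segments; within each
    segment the number of distinct allele strings among the 2N haplotypes is
    counted.  Segments containing no loci contribute zero.
    """
    loci = np.arange(gmap.n_loci) if use_all_loci else gmap.chip_idx
    haps = panel.haplotypes(loci=loci, rows=rows).reshape(-1, loci.size)
    segs = _segment_slices(gmap, loci, fixed_cm)
    counts = np.zeros(len(segs), dtype=np.int64)
    n_empty = 0
    for k, (_, _, idx) in enumerate(segs):
        if idx.size == 0:
            n_empty += 1
            continue
        counts[k] = len(set(_hap_keys(haps, idx).tolist()))
    if n_empty and warn_empty:
        warnings.warn(f"{n_empty} segments contain no loci", stacklevel=2)
    return int(counts.sum()), counts


def select_donors_unique(
    candidate_haps: np.ndarray,
    candidate_ids: np.ndarray,
    candidate_generations: np.ndarray,
    elite_haps: np.ndarray,
    gmap: GeneticMap,
    n_donors: int = 1,
    fixed_cm: float = 1.0,
) -> tuple[list[int], list[int]]:
    """Greedy donor selection maximising added distinct segment haplotypes.

    Operates on chip loci (the operational genotype data).  Each round adds
    the candidate contributing the most allele strings not yet present in
    the reference per 1 cM segment; its haplotypes then join the reference.
    """
    loci = gmap.chip_idx
    segs = [idx for _, _, idx in _segment_slices(gmap, loci, fixed_cm) if idx.size]
    cand = np.asarray(candidate_haps)
    n_c = cand.shape[0]
    cand_flat = cand.reshape(2 * n_c, -1)
    seen: list[set] = []
    cand_keys: list[list] = []
    for idx in segs:
        seen.append(set(_hap_keys(np.asarray(elite_haps), idx).tolist()))
        cand_keys.append(_hap_keys(cand_flat, idx).reshape(n_c, 2).tolist())

    ids = np.asarray(candidate_ids)
    gens = np.asarray(candidate_generations)
    chosen: list[int] = []
    gains: list[int] = []
    available = np.ones(n_c, dtype=bool)
    for _ in range(min(n_donors, n_c)):
        gain = np.full(n_c, -np.inf)
        for k in np.flatnonzero(available):
            g = 0
            for s, keys in enumerate(cand_keys):
                a, b = keys[k]
                if a not in seen[s]:
                    g += 1
                if b != a and b not in seen[s]:
                    g += 1
            gain[k] = g
        k = _tie_order(gain, gens, ids)
        chosen.append(int(ids[k]))
        gains.append(int(gain[k]))
        for s, keys in enumerate(cand_keys):
            seen[s].add(keys[k][0])
            seen[s].add(keys[k][1])
        available[k] = False
    return chosen, gains


# ---------------------------------------------------------------------------
# segment-based IBD kinship (low average kinship)


def _run_share(
    eq: np.ndarray, cm: np.ndarray, chrom_slices: list[slice], spec: SegmentKinshipSpec
) -> np.ndarray:
    """Per row of the equality matrix: cM covered by qualifying identical runs.

    A qualifying run is a maximal stretch of equal alleles spanning at least
    ``min_segment_cm`` and containing at least ``min_consecutive_snps``
    markers.  Vectorised over all rows at once: a single zero column is
    inserted at every chromosome boundary (and the row ends), so one run
    detection pass over the flattened matrix handles the whole genome and
    runs can never bridge chromosomes or rows.
    """
    P, L = eq.shape
    n_seg = len(chrom_slices)
    width = L + n_seg + 1
    pad = np.zeros((P, width), dtype=np.int8)
    cm_pad = np.zeros(width)
    pos = 1
    for sl in chrom_slices:
        n = sl.stop - sl.start
        pad[:, pos:pos + n] = eq[:, sl]
        cm_pad[pos:pos + n] = cm[sl]
        pos += n + 1
    flat = pad.reshape(-1)
    d = flat[1:].astype(np.int8)
    d -= flat[:-1]
    nz = np.flatnonzero(d)
    starts = nz[d[nz] == 1]
    ends = nz[d[nz] == -1]
    # cheap SNP-count filter first: the vast majority of runs are short
    keep = (ends - starts) >= spec.min_consecutive_snps
    starts, ends = starts[keep], ends[keep]
    cs = (starts + 1) % width          # first equal position (padded coords)
    ce = ends % width                  # last equal position
    run_cm = cm_pad[ce] - cm_pad[cs]
    ok = run_cm >= spec.min_segment_cm
    row = starts[ok] // width
    return np.bincount(row, weights=run_cm[ok], minlength=P).astype(float)


def _genome_span(gmap: GeneticMap, loci: np.ndarray) -> float:
    spans = [gmap.cm[loci][sl][-1] - gmap.cm[loci][sl][0] for sl in gmap.subset_slices(loci) if sl.stop > sl.start]
    return float(sum(spans))


try:  # numba accelerates the pairwise run scan; numpy path kept as fallback
    from numba import njit

    @njit(cache=True)
    def _pair_share_kernel(A, B, cm, bounds, min_cm, min_snps):  # pragma: no cover - compiled
        na, nb = A.shape[0], B.shape[0]
        out = np.zeros((na, nb))
        for i in range(na):
            for j in range(nb):
                acc = 0.0
                for c in range(bounds.size - 1):
                    lo, hi = bounds[c], bounds[c + 1]
                    k = lo
                    while k < hi:
                        if A[i, k] == B[j, k]:
                            start = k
                            while k < hi and A[i, k] == B[j, k]:
                                k += 1
                            n_snps = k - start
                            run_cm = cm[k - 1] - cm[start]
                            if n_snps >= min_snps and run_cm >= min_cm:
                                acc += run_cm
                        else:
                            k += 1
                out[i, j] = acc
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _pair_share_numpy(A, B, cm, slices, spec):
    na2, nb2 = A.shape[0], B.shape[0]
    out = np.zeros((na2, nb2))
    rows_per_chunk = max(1, 16384 // max(nb2, 1))
    for lo in range(0, na2, rows_per_chunk):
        hi = min(lo + rows_per_chunk, na2)
        eq = (A[lo:hi, None, :] == B[None, :, :]).reshape((hi - lo) * nb2, A.shape[1])
        share = _run_share(eq.view(np.int8), cm, slices, spec)
        out[lo:hi] = share.reshape(hi - lo, nb2)
    return out


def segment_ibd_kinship_cross(
    haps_a: np.ndarray,
    haps_b: np.ndarray,
    gmap: GeneticMap,
    spec: SegmentKinshipSpec | None = None,
    loci: np.ndarray | None = None,
    use_numba: bool | None = None,
) -> np.ndarray:
    """Segment-based kinship between two animal sets; returns [n_a, n_b].

    f(i, j) averages, over the four haplotype pairs, the genome fraction
    covered by identical runs of at least ``min_segment_cm`` cM and
    ``min_consecutive_snps`` markers.
    """
    spec = spec or SegmentKinshipSpec()
    loci = gmap.chip_idx if loci is None else np.asarray(loci)
    A = np.ascontiguousarray(np.asarray(haps_a).reshape(-1, loci.size))  # [2*na, L]
    B = np.ascontiguousarray(np.asarray(haps_b).reshape(-1, loci.size))  # [2*nb, L]
    na, nb = A.shape[0] // 2, B.shape[0] // 2
    slices = gmap.subset_slices(loci)
    cm = gmap.cm[loci]
    total = _genome_span(gmap, loci)
    if use_numba is None:
        use_numba = _HAVE_NUMBA
    if use_numba and _HAVE_NUMBA:
        bounds = np.array([sl.start for sl in slices] + [loci.size], dtype=np.int64)
        out = _pair_share_kernel(
            A, B, np.ascontiguousarray(cm), bounds, float(spec.min_segment_cm), int(spec.min_consecutive_snps)
        )
    else:
        out = _pair_share_numpy(A, B, cm, slices, spec)
    # average the four haplotype-pair shares per animal pair
    f = out.reshape(na, 2, nb, 2).sum(axis=(1, 3))
    return f / (4.0 * total)


def segment_ibd_kinship(
    panel_or_haps,
    gmap: GeneticMap,
    spec: SegmentKinshipSpec | None = None,
    loci: np.ndarray | None = None,
) -> np.ndarray:
    """Segment-based kinship matrix of one animal set (symmetric, in [0,1])."""
    if isinstance(panel_or_haps, HaplotypePanel):
        haps = panel_or_haps.haplotypes(loci=gmap.chip_idx if loci is None else loci)
    else:
        haps = np.asarray(panel_or_haps)
        if haps.ndim != 3 or haps.shape[1] != 2:
            raise ValueError("expected phased haplotypes of shape [n, 2, L]")
    return segment_ibd_kinship_cross(haps, haps, gmap, spec, loci)


def select_donors_low_kinship(
    candidate_haps: np.ndarray,
    candidate_ids: np.ndarray,
    candidate_generations: np.ndarray,
    elite_haps: np.ndarray,
    gmap: GeneticMap,
    spec: SegmentKinshipSpec | None = None,
    n_donors: int = 1,
) -> tuple[list[int], list[float]]:
    """Donors with the lowest mean segment-IBD kinship to the elite set."""
    elite = np.asarray(elite_haps)
    if elite.shape[0] == 0:
        raise ValueError("empty elite set")
    f = segment_ibd_kinship_cross(np.asarray(candidate_haps), elite, gmap, spec)
    mean_f = f.mean(axis=1)
    ids = np.asarray(candidate_ids)
    gens = np.asarray(candidate_generations)
    order = np.lexsort((ids, gens, mean_f))
    take = order[: min(n_donors, ids.size)]
    return [int(i) for i in ids[take]], [float(v) for v in mean_f[take]]


# ---------------------------------------------------------------------------
# summary statistics


def genic_variance(qtl_freqs: np.ndarray, qtl_effects: np.ndarray) -> float:
    """Genic variance: sum of 2 p (1-p) alpha^2 over QTL.

    Free of linkage-disequilibrium contributions, hence comparable across
    generations regardless of selection-induced LD.
    """
    p = np.asarray(qtl_freqs, dtype=float)
    a = np.asarray(qtl_effects, dtype=float)
    if p.shape != a.shape:
        raise ValueError("frequency/effect length mismatch")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies outside [0,1]")
    return float(np.sum(2.0 * p * (1.0 - p) * a * a))


def selection_limit(panel: HaplotypePanel, trait: TraitArchitecture, rows: np.ndarray | None = None) -> float:
    """Hypothetical TBV if every beneficial allele still present were fixed.

    On the beneficial-allele dose coding a QTL contributes 2*alpha when its
    beneficial allele segregates (or is fixed) in the subset and 0 once it
    is lost; the result is on the same scale as raw TBV.
    """
    present = trait.beneficial_freq(panel, rows=rows) > 0.0
    return float(np.sum(2.0 * trait.qtl_effects[present]))


def true_ibd_kinship(panel: HaplotypePanel, gmap: GeneticMap, rows: np.ndarray | None = None) -> np.ndarray:
    """Founder-IBD kinship matrix from founder labels.

    f(i,j) is the probability that alleles sampled from i and j at a
    cM-length-weighted random genome position descend from the same founder
    haplotype, averaged over the four haplotype pairs.  A non-inbred founder
    has self-kinship 0.5.
    """
    lab = panel.founder_label if rows is None else panel.founder_label[:, rows, :]
    w = gmap.locus_weights()
    n = lab.shape[1]
    out = np.zeros((n, n))
    for a in range(2):
        for b in range(2):
            La = lab[a]
            Lb = lab[b]
            for i in range(n):
                out[i] += ((La[i][None, :] == Lb) * w[None, :]).sum(axis=1)
    return out / 4.0


def mean_true_ibd_kinship(panel: HaplotypePanel, gmap: GeneticMap, rows: np.ndarray | None = None) -> float:
    """Mean founder-IBD kinship over all ordered animal pairs (incl. self).

    Computed from per-locus founder-label frequency spectra, which is
    algebraically identical to averaging :func:`true_ibd_kinship` but linear
    in the number of haplotypes.
    """
    lab = panel.founder_label if rows is None else panel.founder_label[:, rows, :]
    H = lab.shape[1] * 2
    flat = lab.reshape(H, -1)
    w = gmap.locus_weights()
    total = 0.0
    for l in range(flat.shape[1]):
        counts = np.bincount(flat[:, l])
        total += w[l] * float(np.sum((counts / H) ** 2))
    return float(total)


# ---------------------------------------------------------------------------
# theory utilities


def delta_f(ne: float) -> float:
    """Per-generation inbreeding rate for effective population size Ne."""
    return 1.0 / (2.0 * ne)


def inbreeding_after(ne: float, n_generations: int) -> float:
    """Expected inbreeding level after n generations at constant Ne."""
    return 1.0 - (1.0 - delta_f(ne)) ** n_generations


def allele_retention_probability(p: float, ne: float, n_generations: int, n_loci: int = 1) -> float:
    """Probability of keeping the allele at every one of ``n_loci`` independent
    loci, all at starting frequency ``p``, for ``n_generations`` generations:

        [(1 - (1-p)^(2 Ne))^n_generations]^n_loci

    The per-generation loss probability treats each generation as a fresh
    binomial sample of 2 Ne gene copies at the starting frequency.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    keep_one_gen = 1.0 - (1.0 - p) ** (2.0 * ne)
    return float((keep_one_gen ** n_generations) ** n_loci)


def expected_backcross_kinship(f_donor: float, f_elite: float, n_elite_crosses: int) -> float:
    """Expected kinship to the elite after ``n`` successive crosses to elite:

        (1 - 2^-n) * f_elite + 2^-n * f_donor
    """
    for v in (f_donor, f_elite):
        if not 0.0 <= v <= 1.0:
            raise ValueError("kinships must be in [0, 1]")
    wt = 2.0 ** (-n_elite_crosses)
    return (1.0 - wt) * f_elite + wt * f_donor


def elite_genome_fraction(n_elite_crosses: int) -> float:
    """Expected elite-derived genome fraction after ``n`` crosses to elite."""
    return 1.0 - 2.0 ** (-n_elite_crosses)
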