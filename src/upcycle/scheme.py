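"""Orchestration of the layered ("upcycling") breeding program.

A closed nucleus of 400 sows x litter size 6 is simulated generation by
generation: ten burn-in generations of GEBV truncation selection establish a
realistic selected population, after which one of 13 selection strategies
runs.  Upcycling strategies divert part of the sow capacity into layers:
archived boars chosen as diversity donors are mated to layer-1 sows, and
their descendants are backcrossed towards elite performance through up to
four layers before competing for elite selection.  Elite sires are always
chosen by optimum contribution selection with a 1% kinship-rate constraint.

Selection order within a generation follows the program design: elite dams,
elite sires (OCS), layer-1 dams, then layer dams from the highest layer
down, and finally the diversity donors, so that donor choice can avoid
genetics already covered by the selected parents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream
from . import diversity_metrics as dm
from . import genetic_eval as ge
from . import ocs as ocs_mod
from .genome_sim import (
    FEMALE,
    MALE,
    GeneticMap,
    HaplotypePanel,
    TraitArchitecture,
    assign_trait_architecture,
    breed_offspring,
    build_genetic_map,
    make_pedigree,
    place_qtl,
    select_chip_snps,
    simulate_founder_history,
)

__all__ = [
    "SimConfig",
    "LayerSpec",
    "DonorSpec",
    "StrategyConfig",
    "STRATEGIES",
    "strategy_config",
    "GenerationState",
    "run_burnin",
    "select_cohort",
    "select_diversity_donors",
    "advance_generation",
    "run_scenario",
    "run_paired_scenarios",
]

COMPONENTS = ("elite", "layer1", "layer2", "layer3", "layer4")
ANY = COMPONENTS

ROLE_ORDER = ("elite_dams", "elite_sires", "L1_dams", "L4_dams", "L3_dams", "L2_dams", "donors")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Genome and program sizes plus evaluation/OCS policy knobs."""

    n_chromosomes: int = 18
    chrom_length_cm: float = 100.0
    n_loci: int = 65000
    n_qtl: int = 6000
    chip_size: int = 20000
    n_dams: int = 400
    litter_size: int = 6
    n_burnin: int = 10
    burnin_sires: int = 40
    h2: float = 0.3
    training_window: int = 5
    vce_interval: int = 3
    vce_sample: int = 3000
    vce_depth: int = 3
    archive_depth: int = 10
    ocs_ref_lag: int = 5
    kinship_rate: float = 0.01
    max_doses: int = 30
    min_doses: int = 1
    full_metrics_from: int = 0  # haplotype/kinship diversity metrics recorded from this generation on
    n_founders: int = 2400
    history_ne: int = 175
    history_generations: int = 30
    init_freq: tuple[float, float] = (0.13, 0.87)

    @classmethod
    def full(cls) -> "SimConfig":
        return cls()

    @classmethod
    def desk(cls) -> "SimConfig":
        """Quarter-size population with a proportionally reduced genome.

        100 dams, 5k loci, 1k QTL; the chip, dose cap, VCE sample and burn-in
        sire numbers scale with the same factors.
        """
        return cls(
            n_loci=5000,
            n_qtl=1000,
            chip_size=1500,
            n_dams=100,
            burnin_sires=10,
            vce_sample=750,
            max_doses=8,
            n_founders=600,
        )

    @property
    def cohort_size(self) -> int:
        return self.n_dams * self.litter_size


@dataclass(frozen=True)
class LayerSpec:
    """One upcycling layer: how many sows and how they are picked.

    ``parts`` lists (selector, count) pairs; the selector is ``"ebv"`` or a
    diversity criterion in {"kinship", "unique", "beneficial"}.  ``eligible``
    restricts the birth components sows may come from.
    """

    layer: int
    parts: tuple[tuple[str, int], ...]
    eligible: tuple[str, ...] = ANY

    @property
    def n_sows(self) -> int:
        return sum(n for _, n in self.parts)


@dataclass(frozen=True)
class DonorSpec:
    criterion: str  # 'kinship' | 'unique' | 'beneficial'
    n: int
    pool_depth: int = 10


@dataclass(frozen=True)
class StrategyConfig:
    """One row of the strategy table: donors, layers and elite dam count."""

    strategy_id: int
    label: str
    donors: tuple[DonorSpec, ...]
    layers: tuple[LayerSpec, ...]
    n_dams_total: int = 400

    def __post_init__(self) -> None:
        if self.layers and self.layers[0].layer == 1:
            if self.layers[0].n_sows != self.n_donors:
                raise ValueError("layer-1 sow count must equal the donor count (one sow per donor)")
        if self.elite_dams <= 0:
            raise ValueError("upcycling layers exceed total sow capacity")

    @property
    def n_donors(self) -> int:
        return sum(d.n for d in self.donors)

    @property
    def upcycling_sows(self) -> int:
        return sum(l.n_sows for l in self.layers)

    @property
    def elite_dams(self) -> int:
        return self.n_dams_total - self.upcycling_sows

    @property
    def upcycling_fraction(self) -> float:
        return self.upcycling_sows / self.n_dams_total

    def layer_by_number(self, k: int) -> LayerSpec | None:
        for l in self.layers:
            if l.layer == k:
                return l
        return None


def _standard_strategy(sid: int, label: str, criterion: str, d: int) -> StrategyConfig:
    no_l1 = ("elite", "layer2", "layer3", "layer4")
    upcycling = ("layer1", "layer2", "layer3")
    return StrategyConfig(
        sid,
        label,
        donors=(DonorSpec(criterion, d),),
        layers=(
            LayerSpec(1, (("ebv", d),), ANY),
            LayerSpec(2, ((criterion, d),), ANY),
            LayerSpec(3, ((criterion, d),), no_l1),
            LayerSpec(4, (("ebv", d),), upcycling),
        ),
    )


def _build_strategies() -> dict[int, StrategyConfig]:
    s: dict[int, StrategyConfig] = {}
    for k, (crit, name) in enumerate(
        [("beneficial", "rare beneficial haplotypes"), ("unique", "rare haplotypes"), ("kinship", "low kinship")]
    ):
        for j, d in enumerate([3, 10, 25]):
            sid = 3 * k + j + 1
            s[sid] = _standard_strategy(sid, f"{name} {d}/layer", crit, d)
    s[10] = StrategyConfig(
        10,
        "low kinship, 3 layers (7.5%)",
        donors=(DonorSpec("kinship", 10),),
        layers=(
            LayerSpec(1, (("ebv", 10),), ANY),
            LayerSpec(2, (("kinship", 10),), ANY),
            LayerSpec(3, (("ebv", 10),), ("layer1", "layer2")),
        ),
    )
    s[11] = StrategyConfig(
        11,
        "low kinship, 2 layers (5%)",
        donors=(DonorSpec("kinship", 10),),
        layers=(
            LayerSpec(1, (("ebv", 10),), ANY),
            LayerSpec(2, (("ebv", 10),), ("layer1",)),
        ),
    )
    s[12] = StrategyConfig(
        12,
        "all criteria, 3 layers (9.75%)",
        donors=(DonorSpec("kinship", 8), DonorSpec("unique", 4), DonorSpec("beneficial", 5, pool_depth=5)),
        layers=(
            LayerSpec(1, (("ebv", 17),), ANY),
            LayerSpec(2, (("kinship", 8), ("unique", 4), ("beneficial", 5)), ANY),
            LayerSpec(3, (("ebv", 5),), ("layer1", "layer2")),
        ),
    )
    s[13] = StrategyConfig(13, "control", donors=(), layers=())
    return s


#: the 13 selection strategies at full (400-sow) scale
STRATEGIES = _build_strategies()


def strategy_config(strategy_id: int, n_dams: int = 400) -> StrategyConfig:
    """Strategy scaled to a total of ``n_dams`` sows (counts rounded, min 1)."""
    base = STRATEGIES[strategy_id]
    if n_dams == base.n_dams_total:
        return base
    f = n_dams / base.n_dams_total

    def sc(n: int) -> int:
        return max(1, int(n * f + 0.5))  # half-up, avoids banker's rounding

    donors = tuple(replace(d, n=sc(d.n)) for d in base.donors)
    layers = tuple(
        replace(l, parts=tuple((sel, sc(n)) for sel, n in l.parts)) for l in base.layers
    )
    # keep the one-sow-per-donor identity after rounding
    if layers:
        layers = (replace(layers[0], parts=(("ebv", sum(d.n for d in donors)),),),) + layers[1:]
    return replace(base, donors=donors, layers=layers, n_dams_total=n_dams)


# ---------------------------------------------------------------------------
# generation state


@dataclass
class GenerationState:
    """Mutable state of one simulation run at a given generation."""

    config: SimConfig
    gmap: GeneticMap
    trait: TraitArchitecture
    master_seed: int
    generation: int
    panel: HaplotypePanel                     # current cohort haplotypes
    cohort: pd.DataFrame                      # current cohort pedigree rows
    training: ge.TrainingStore
    archive: list[dict] = field(default_factory=list)
    elite_freqs: dict[int, np.ndarray] = field(default_factory=dict)
    varcomp: tuple[float, float] = (1.0, 1.0)
    metrics: list[dict] = field(default_factory=list)
    ped_frames: list[pd.DataFrame] = field(default_factory=list)
    next_id: int = 0
    selection: dict = field(default_factory=dict)
    evaluation: ge.EvaluationResult | None = None

    @property
    def pedigree(self) -> pd.DataFrame:
        return pd.concat(self.ped_frames, ignore_index=True)

    def clone(self) -> "GenerationState":
        """Cheap copy for branching scenarios off a shared burn-in.

        Arrays inside cohorts/archives are never mutated in place, so
        container-level copies suffice.
        """
        ts = ge.TrainingStore(self.training.window)
        ts._cohorts = [dict(c) for c in self.training._cohorts]
        return GenerationState(
            config=self.config,
            gmap=self.gmap,
            trait=self.trait,
            master_seed=self.master_seed,
            generation=self.generation,
            panel=self.panel,
            cohort=self.cohort.copy(),
            training=ts,
            archive=list(self.archive),
            elite_freqs=dict(self.elite_freqs),
            varcomp=self.varcomp,
            metrics=[dict(m) for m in self.metrics],
            ped_frames=list(self.ped_frames),
            next_id=self.next_id,
            selection={},
            evaluation=self.evaluation,
        )

    def rng(self, *names) -> np.random.Generator:
        return substream(self.master_seed, "gen", self.generation, *names)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics)


# ---------------------------------------------------------------------------
# per-cohort bookkeeping


def _chip_M(state: GenerationState, panel: HaplotypePanel | None = None) -> np.ndarray:
    return (panel or state.panel).genotypes(loci=state.gmap.chip_idx)


def _register_cohort(state: GenerationState) -> None:
    """Metrics, allele-frequency history and training entry for the cohort."""
    cfg, gmap, trait = state.config, state.gmap, state.trait
    cohort = state.cohort
    elite_mask = (cohort["component"] == "elite").to_numpy()
    rows_elite = np.flatnonzero(elite_mask)
    M = _chip_M(state)
    state.training.add_cohort(
        state.generation,
        cohort["id"].to_numpy(),
        M,
        cohort["phenotype"].to_numpy(),
        elite_mask,
    )
    state.elite_freqs[state.generation] = M[elite_mask].mean(axis=0) / 2.0

    p_ben = trait.beneficial_freq(state.panel, rows=rows_elite)
    row = {
        "generation": state.generation,
        "n_cohort": len(cohort),
        "n_elite_born": int(elite_mask.sum()),
        "mean_tbv": float(cohort["tbv"].mean()),
        "mean_tbv_elite": float(cohort.loc[elite_mask, "tbv"].mean()),
        "genic_variance": dm.genic_variance(p_ben, trait.qtl_effects),
        "selection_limit": dm.selection_limit(state.panel, trait, rows=rows_elite),
        "pct_beneficial_lost": 100.0 * float(np.mean(p_ben == 0.0)),
    }
    if state.generation >= cfg.full_metrics_from:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            uniq_all, _ = dm.count_unique_haplotypes(state.panel, gmap, rows=rows_elite, use_all_loci=True)
            uniq_chip, _ = dm.count_unique_haplotypes(state.panel, gmap, rows=rows_elite, use_all_loci=False)
        row["mean_kinship_ibd"] = dm.mean_true_ibd_kinship(state.panel, gmap, rows=rows_elite)
        row["unique_haplotypes_all"] = uniq_all
        row["unique_haplotypes_chip"] = uniq_chip
    state.metrics.append(row)


def _maybe_vce(state: GenerationState) -> None:
    cfg = state.config
    if state.generation % cfg.vce_interval != 0:
        return
    rng = state.rng("vce")
    y, M = state.training.vce_sample(cfg.vce_sample, cfg.vce_depth, rng)
    if y.size < 20:
        return
    p = M.mean(axis=0) / 2.0
    G = ge.grm_vanraden1(M, p)
    try:
        sg, se = ge.estimate_variance_components(y, G)
        if np.isfinite(sg) and np.isfinite(se) and sg >= 0 and se > 0:
            state.varcomp = (sg, se)
        else:
            warnings.warn("variance-component estimation degenerate; keeping previous", stacklevel=2)
    except Exception:  # pragma: no cover - numerical safety net
        warnings.warn("variance-component estimation failed; keeping previous", stacklevel=2)


def _evaluate(state: GenerationState) -> None:
    _maybe_vce(state)
    res = state.training.evaluate(*state.varcomp)
    state.evaluation = res
    state.cohort = state.cohort.copy()
    state.cohort["gebv"] = res.gebv_of(state.cohort["id"].to_numpy())
    state.ped_frames[-1] = state.cohort


# ---------------------------------------------------------------------------
# selection


def _ranked_females(cohort: pd.DataFrame, exclude: set[int], eligible: tuple[str, ...]) -> pd.DataFrame:
    mask = (
        (cohort["sex"] == FEMALE)
        & ~cohort["id"].isin(exclude)
        & cohort["component"].isin(eligible)
    )
    sub = cohort[mask]
    order = np.lexsort((sub["id"].to_numpy(), -sub["gebv"].to_numpy()))
    return sub.iloc[order]


def _reference_haps(state: GenerationState) -> np.ndarray:
    """Chip haplotypes of every animal already selected this generation."""
    ids: list[int] = []
    for role, val in state.selection.items():
        if role == "elite_sires":
            ids.extend(int(i) for i in val.candidate_ids[val.contributions > 1e-12])
        elif role != "donors":
            ids.extend(int(i) for i in val)
    rows = state.panel.rows(ids)
    return state.panel.haplotypes(loci=state.gmap.chip_idx, rows=rows).reshape(-1, state.gmap.chip_idx.size)


def _criterion_rank(
    state: GenerationState,
    criterion: str,
    candidates: pd.DataFrame,
    n: int,
) -> list[int]:
    """Pick ``n`` females from ``candidates`` by a diversity criterion.

    The reference set is everything selected so far this generation, per the
    design goal of not duplicating genetics that already contribute.
    """
    if len(candidates) <= n:
        return [int(i) for i in candidates["id"]]
    gmap = state.gmap
    rows = state.panel.rows(candidates["id"].to_numpy())
    haps = state.panel.haplotypes(loci=gmap.chip_idx, rows=rows)
    ref = _reference_haps(state)
    ids = candidates["id"].to_numpy()
    gens = candidates["generation"].to_numpy()
    if criterion == "kinship":
        chosen, _ = dm.select_donors_low_kinship(haps, ids, gens, ref.reshape(-1, 2, ref.shape[1]), gmap, n_donors=n)
    elif criterion == "unique":
        chosen, _ = dm.select_donors_unique(haps, ids, gens, ref, gmap, n_donors=n)
    elif criterion == "beneficial":
        chosen, _ = dm.select_donors_beneficial(
            haps, ids, gens, ref, state.evaluation.snp_effects, gmap, n_donors=n
        )
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return chosen


def select_cohort(state: GenerationState, role: str, strategy: StrategyConfig) -> object:
    """Select one role of the current generation (in program order).

    Roles must be requested in the order elite_dams, elite_sires, L1_dams,
    L4_dams, L3_dams, L2_dams, donors; each result is cached on the state so
    later roles can exclude or reference earlier ones.  When an eligibility
    pool runs short, the shortfall is filled with the next-best remaining
    females regardless of component (with a warning).
    """
    if role in state.selection:
        return state.selection[role]
    for r in ROLE_ORDER:
        if r == role:
            break
        applies = (
            r in ("elite_dams", "elite_sires")
            or (r.startswith("L") and strategy.layer_by_number(int(r[1])) is not None)
            or (r == "donors" and bool(strategy.donors))
        )
        if applies and r not in state.selection:
            raise ValueError(f"role {r!r} must be selected before {role!r}")
    cohort = state.cohort
    taken: set[int] = set()
    for r, val in state.selection.items():
        if r == "elite_sires" or r == "donors":
            continue
        taken.update(int(i) for i in val)

    if role == "elite_dams":
        n = strategy.elite_dams
        out = [int(i) for i in _ranked_females(cohort, taken, ANY)["id"].head(n)]
        if len(out) < n:
            raise ValueError("not enough female candidates for elite dams")
    elif role == "elite_sires":
        out = _select_sires_ocs(state, strategy)
    elif role in ("L1_dams", "L2_dams", "L3_dams", "L4_dams"):
        spec = strategy.layer_by_number(int(role[1]))
        if spec is None:
            out = []
        else:
            out = []
            for selector, n in spec.parts:
                pool = _ranked_females(cohort, taken | set(out), spec.eligible)
                if selector == "ebv":
                    part = [int(i) for i in pool["id"].head(n)]
                else:
                    part = _criterion_rank(state, selector, pool, n)
                if len(part) < n:
                    fallback = _ranked_females(cohort, taken | set(out) | set(part), ANY)
                    extra = [int(i) for i in fallback["id"].head(n - len(part))]
                    if extra:
                        warnings.warn(
                            f"{role}: eligible pool exhausted; filled {len(extra)} from other components",
                            stacklevel=2,
                        )
                    part += extra
                out.extend(part)
    elif role == "donors":
        out = select_diversity_donors(state, strategy)
    else:
        raise ValueError(f"unknown role {role!r}")
    state.selection[role] = out
    return out


def _select_sires_ocs(state: GenerationState, strategy: StrategyConfig) -> ocs_mod.ContributionSolution:
    cfg = state.config
    cohort = state.cohort
    males = cohort[cohort["sex"] == MALE]
    dam_ids = np.asarray(state.selection["elite_dams"], dtype=np.int64)
    cand_ids = males["id"].to_numpy()
    ref_gen = state.generation - cfg.ocs_ref_lag
    avail = sorted(state.elite_freqs)
    ref_gen = ref_gen if ref_gen in state.elite_freqs else avail[0]
    p = state.elite_freqs[ref_gen]
    all_ids = np.concatenate([cand_ids, dam_ids])
    M = _chip_M(state)[state.panel.rows(all_ids)]
    K = ge.grm_vanraden1(M, p) / 2.0  # kinship scale
    n_serve = strategy.n_dams_total - (strategy.layer_by_number(1).n_sows if strategy.layers else 0)
    problem = ocs_mod.ContributionProblem(
        candidate_ids=cand_ids,
        gebv=males["gebv"].to_numpy(),
        K=K,
        n_dams=len(dam_ids),
        f_bar_t=float(K.mean()),
        n_matings=n_serve,
        max_doses=cfg.max_doses,
        min_doses=cfg.min_doses,
        rate=cfg.kinship_rate,
    )
    return ocs_mod.solve_contributions(problem)


def select_diversity_donors(state: GenerationState, strategy: StrategyConfig) -> list[int]:
    """Choose donors from the archived-sire pool by the strategy's criteria."""
    donors: list[int] = []
    gmap = state.gmap
    for spec in strategy.donors:
        pool = [
            a
            for a in state.archive
            if state.generation - spec.pool_depth <= a["generation"] <= state.generation - 1
            and a["id"] not in donors
        ]
        if not pool:
            continue
        n = min(spec.n, len(pool))
        if len(pool) < spec.n:
            warnings.warn("donor archive smaller than requested; taking all", stacklevel=2)
        haps = np.stack([a["chip_haps"] for a in pool])  # [n_pool, 2, Lc]
        ids = np.array([a["id"] for a in pool])
        gens = np.array([a["generation"] for a in pool])
        ref = _reference_haps(state)
        chosen_haps = [np.stack([a["chip_haps"] for a in state.archive if a["id"] in donors])] if donors else []
        if chosen_haps:
            ref = np.concatenate([ref, chosen_haps[0].reshape(-1, ref.shape[1])])
        if spec.criterion == "kinship":
            chosen, _ = dm.select_donors_low_kinship(haps, ids, gens, ref.reshape(-1, 2, ref.shape[1]), gmap, n_donors=n)
        elif spec.criterion == "unique":
            chosen, _ = dm.select_donors_unique(haps, ids, gens, ref, gmap, n_donors=n)
        elif spec.criterion == "beneficial":
            chosen, _ = dm.select_donors_beneficial(
                haps, ids, gens, ref, state.evaluation.snp_effects, gmap, n_donors=n
            )
        else:
            raise ValueError(f"unknown donor criterion {spec.criterion!r}")
        donors.extend(chosen)
    return donors


# ---------------------------------------------------------------------------
# generation advance


def _origin_counts(cohort: pd.DataFrame, ids: list[int] | np.ndarray, prefix: str) -> dict:
    comp = cohort.set_index("id")["component"]
    out = {f"{prefix}_{c}": 0 for c in COMPONENTS}
    for i in ids:
        out[f"{prefix}_{comp.loc[int(i)]}"] += 1
    return out


def advance_generation(state: GenerationState, strategy: StrategyConfig, seed=None) -> GenerationState:
    """Run one full selection-and-breeding cycle, mutating ``state``.

    Produces the next cohort of ``n_dams * litter_size`` animals, rolls the
    sire archive and allele-frequency history forward, and appends metric
    rows.  Offspring are tagged at birth with the component (elite or layer)
    they were bred for.
    """
    cfg, gmap, trait = state.config, state.gmap, state.trait
    state.selection = {}
    _evaluate(state)
    for role in ROLE_ORDER:
        if role.startswith("L") and strategy.layer_by_number(int(role[1])) is None:
            continue
        if role == "donors" and not strategy.donors:
            continue
        select_cohort(state, role, strategy)

    cohort = state.cohort
    sol: ocs_mod.ContributionSolution = state.selection["elite_sires"]
    donors: list[int] = state.selection.get("donors", [])

    # --- matings -----------------------------------------------------------
    elite_dams = list(state.selection["elite_dams"])
    layer_dams = {k: list(state.selection.get(f"L{k}_dams", [])) for k in (1, 2, 3, 4)}
    served_by_ocs = elite_dams + layer_dams[2] + layer_dams[3] + layer_dams[4]
    matings = ocs_mod.contributions_to_matings(
        sol, np.asarray(served_by_ocs), seed=state.rng("matings"), mating_share=0.5 / len(served_by_ocs)
    )
    tags = {int(d): "elite" for d in elite_dams}
    for k in (2, 3, 4):
        for d in layer_dams[k]:
            tags[int(d)] = f"layer{k}"
    mating_list = [(s, d) for s, d in matings]
    tag_list = [tags[int(d)] for _, d in mating_list]
    # donor x layer-1 sow matings: one sow per donor (donors recycled only if
    # the archive fell short of the requested donor count)
    l1 = layer_dams[1]
    perm = state.rng("l1-pairing").permutation(len(l1))
    if l1 and not donors:
        raise RuntimeError("layer-1 sows selected but no donors available")
    for k, dam_idx in enumerate(perm):
        mating_list.append((int(donors[k % len(donors)]), int(l1[dam_idx])))
        tag_list.append("layer1")

    # --- breeding ----------------------------------------------------------
    donor_panels = [a for a in state.archive if a["id"] in set(donors)]
    if donor_panels:
        breed_panel = HaplotypePanel(
            np.concatenate([state.panel.alleles] + [a["alleles"][:, None, :] for a in donor_panels], axis=1),
            np.concatenate([state.panel.founder_label] + [a["labels"][:, None, :] for a in donor_panels], axis=1),
            np.concatenate([state.panel.ids, np.array([a["id"] for a in donor_panels], dtype=np.int64)]),
        )
    else:
        breed_panel = state.panel
    new_panel, new_recs = breed_offspring(
        breed_panel,
        state.pedigree,
        mating_list,
        cfg.litter_size,
        tag_list,
        gmap,
        trait,
        state.rng("breeding"),
        state.generation + 1,
        state.next_id,
    )
    state.next_id += len(new_recs)

    # --- bookkeeping -------------------------------------------------------
    sire_ids = [int(i) for i in sol.candidate_ids[sol.contributions > 1e-12]]
    sel_counts = {
        **_origin_counts(cohort, sire_ids, "sires"),
        **_origin_counts(cohort, elite_dams, "elite_dams"),
        "n_ocs_sires": len(sire_ids),
        "ocs_xKx": sol.xKx,
        "ocs_bound": sol.bound,
        "ocs_status": sol.status,
        "updams_from_elite": sum(
            1 for k in (2, 3, 4) for d in layer_dams[k]
            if cohort.set_index("id")["component"].loc[int(d)] == "elite"
        ),
        "n_donors_used": len(donors),
        "donor_mean_generation": float(np.mean([
            a["generation"] for a in state.archive if a["id"] in set(donors)
        ])) if donors else np.nan,
        "gebv_accuracy": float(np.corrcoef(cohort["gebv"], cohort["tbv"])[0, 1]),
    }
    state.metrics[-1].update(sel_counts)

    _archive_sires(state, sire_ids)
    state.generation += 1
    state.panel = new_panel
    state.cohort = new_recs
    state.ped_frames.append(new_recs)
    state.selection = {}
    _register_cohort(state)
    return state


def _archive_sires(state: GenerationState, sire_ids: list[int]) -> None:
    rows = state.panel.rows(sire_ids)
    chip = state.gmap.chip_idx
    for sid, r in zip(sire_ids, rows):
        state.archive.append(
            {
                "id": int(sid),
                "generation": state.generation,
                "alleles": state.panel.alleles[:, r, :].copy(),
                "labels": state.panel.founder_label[:, r, :].copy(),
                "chip_haps": np.ascontiguousarray(state.panel.alleles[:, r, :][:, chip]),
            }
        )
    horizon = state.generation - state.config.archive_depth
    state.archive = [a for a in state.archive if a["generation"] > horizon]


# ---------------------------------------------------------------------------
# burn-in and scenarios


def run_burnin(config: SimConfig, seed: int) -> GenerationState:
    """Found the population and run truncation-selection burn-in.

    Founders (generation ``-n_burnin``) come from the neutral history; each
    burn-in generation selects ``burnin_sires`` males and ``n_dams`` females
    on GEBV and mates them at random.  The returned state sits at generation
    0 (the last burn-in cohort) with the sire archive and allele-frequency
    history populated.
    """
    gmap = build_genetic_map(config.n_chromosomes, config.n_loci, config.chrom_length_cm, substream(seed, "map"))
    gmap = place_qtl(gmap, config.n_qtl, substream(seed, "qtl"))
    panel = simulate_founder_history(
        gmap,
        config.n_founders,
        config.history_generations,
        config.history_ne,
        substream(seed, "history"),
        init_freq=config.init_freq,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gmap = select_chip_snps(panel, gmap, config.chip_size)
    trait = assign_trait_architecture(panel, gmap, config.n_qtl, config.h2, substream(seed, "effects"))

    g0 = -config.n_burnin
    rng = substream(seed, "founders")
    tbv = trait.tbv(panel)
    pheno = tbv + rng.standard_normal(panel.n_animals) * np.sqrt(trait.sigma2_e)
    sex = np.where(rng.random(panel.n_animals) < 0.5, MALE, FEMALE).astype(np.int8)
    founders = make_pedigree(
        [
            {
                "id": i,
                "sire": -1,
                "dam": -1,
                "sex": sex[k],
                "generation": g0,
                "component": "elite",
                "tbv": tbv[k],
                "phenotype": pheno[k],
                "gebv": np.nan,
            }
            for k, i in enumerate(panel.ids)
        ]
    )
    state = GenerationState(
        config=config,
        gmap=gmap,
        trait=trait,
        master_seed=seed,
        generation=g0,
        panel=panel,
        cohort=founders,
        training=ge.TrainingStore(config.training_window),
        varcomp=(trait.sigma2_g_base, trait.sigma2_e),
        next_id=int(panel.ids.max()) + 1,
    )
    state.ped_frames.append(founders)
    _register_cohort(state)

    for _ in range(config.n_burnin):
        _burnin_step(state)
    return state


def _burnin_step(state: GenerationState) -> None:
    cfg = state.config
    _evaluate(state)
    cohort = state.cohort
    males = _ranked_males(cohort)
    sires = [int(i) for i in males["id"].head(cfg.burnin_sires)]
    dams = [int(i) for i in _ranked_females(cohort, set(), ANY)["id"].head(cfg.n_dams)]
    rng = state.rng("burnin-mating")
    assign = rng.integers(0, len(sires), len(dams))
    matings = [(sires[a], d) for a, d in zip(assign, dams)]
    new_panel, new_recs = breed_offspring(
        state.panel, cohort, matings, cfg.litter_size, "elite", state.gmap, state.trait,
        state.rng("breeding"), state.generation + 1, state.next_id,
    )
    state.next_id += len(new_recs)
    state.metrics[-1].update(
        {"n_ocs_sires": len(sires), **_origin_counts(cohort, sires, "sires"), **_origin_counts(cohort, dams, "elite_dams")}
    )
    _archive_sires(state, sires)
    state.generation += 1
    state.panel = new_panel
    state.cohort = new_recs
    state.ped_frames.append(new_recs)
    _register_cohort(state)


def _ranked_males(cohort: pd.DataFrame) -> pd.DataFrame:
    sub = cohort[cohort["sex"] == MALE]
    order = np.lexsort((sub["id"].to_numpy(), -sub["gebv"].to_numpy()))
    return sub.iloc[order]


def run_scenario(
    strategy: int | StrategyConfig,
    n_generations: int,
    n_replicates: int,
    master_seed: int,
    config: SimConfig | None = None,
) -> list[pd.DataFrame]:
    """Independent replicates of one strategy; returns per-replicate metrics."""
    config = config or SimConfig.desk()
    if isinstance(strategy, int):
        strategy = strategy_config(strategy, config.n_dams)
    out = []
    for rep in range(n_replicates):
        seed = int(substream(master_seed, "replicate", rep).integers(0, 2**31 - 1))
        state = run_burnin(config, seed)
        for _ in range(n_generations):
            advance_generation(state, strategy)
        out.append(state.metrics_frame())
    return out


def run_paired_scenarios(
    strategy_ids: list[int],
    n_generations: int,
    n_replicates: int,
    master_seed: int,
    config: SimConfig | None = None,
) -> dict[int, list[pd.DataFrame]]:
    """Replicates paired by seed: strategies share each replicate's burn-in."""
    config = config or SimConfig.desk()
    out: dict[int, list[pd.DataFrame]] = {sid: [] for sid in strategy_ids}
    for rep in range(n_replicates):
        seed = int(substream(master_seed, "replicate", rep).integers(0, 2**31 - 1))
        base = run_burnin(config, seed)
        for sid in strategy_ids:
            strat = strategy_config(sid, config.n_dams)
            state = base.clone()
            for _ in range(n_generations):
                advance_generation(state, strat)
            out[sid].append(state.metrics_frame())
    return out
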