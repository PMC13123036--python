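"""Optimum contribution selection of sires under a kinship-rate constraint.

Sire contributions c (summing to 0.5, the dam half being fixed at equal
shares) maximise the expected genetic merit c'g subject to the expected
mean kinship of the offspring cohort,

    x'Kx,   x = [c; dam shares],

not exceeding the per-generation bound f_next = f + (1-f)*rate with
rate = 0.01 (an effective population size of at least 50).  A box
constraint caps each sire at ``max_doses`` matings, and an iterative
pruning rule zeroes sires whose optimised contribution is below one mating.

The optimiser is an exact active-set method for this convex, quadratically
constrained linear program: on the current free set the KKT conditions
reduce to a line in the Lagrange parameter, along which the quadratic
constraint is a scalar quadratic equation solved in closed form; bound
violators are clamped and KKT multipliers are checked for release.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream

__all__ = [
    "ContributionProblem",
    "ContributionSolution",
    "kinship_bound",
    "solve_contributions",
    "contributions_to_matings",
]


def kinship_bound(f_bar_t: float, rate: float = 0.01) -> float:
    """Maximum mean kinship of the next generation: f + (1-f)*rate."""
    if not 0.0 <= f_bar_t <= 1.0:
        raise ValueError("mean kinship must be in [0, 1]")
    return f_bar_t + (1.0 - f_bar_t) * rate


@dataclass
class ContributionProblem:
    """Inputs of one sire-contribution optimisation.

    ``K`` is the kinship matrix over candidates followed by the selected
    dams (kinship scale, i.e. half the VanRaden GRM).  Dams receive fixed
    equal contributions summing to 0.5; the male half is optimised.
    """

    candidate_ids: np.ndarray
    gebv: np.ndarray
    K: np.ndarray
    n_dams: int
    f_bar_t: float
    n_matings: int
    max_doses: int = 30
    min_doses: int = 1
    rate: float = 0.01

    def __post_init__(self) -> None:
        n = len(self.candidate_ids)
        if self.K.shape != (n + self.n_dams, n + self.n_dams):
            raise ValueError("K must cover candidates followed by dams")
        if n * self.max_doses < self.n_matings:
            raise ValueError("not enough candidates to serve all matings under the dose cap")

    @property
    def mating_share(self) -> float:
        return 0.5 / self.n_matings

    @property
    def cap(self) -> float:
        return self.max_doses * self.mating_share


@dataclass
class ContributionSolution:
    candidate_ids: np.ndarray
    contributions: np.ndarray
    objective: float
    xKx: float
    bound: float
    status: str  # 'optimal' | 'pruned-optimal' | 'infeasible-relaxed'
    n_positive: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_positive = int(np.sum(self.contributions > 1e-12))


# ---------------------------------------------------------------------------
# core solver


def _greedy_lp(g: np.ndarray, cap: float, total: float) -> np.ndarray:
    """Maximise g'c subject to sum c = total, 0 <= c <= cap (sort and fill)."""
    c = np.zeros_like(g)
    left = total
    for i in np.argsort(-g):
        take = min(cap, left)
        c[i] = take
        left -= take
        if left <= 1e-15:
            break
    return c


def _quad(Q: np.ndarray, q: np.ndarray, r: float, c: np.ndarray) -> float:
    return float(c @ Q @ c + 2.0 * q @ c + r)


def _solve_equality_qp(Q, q, total, cap, maximize_gain_dir=None):
    """min c'Qc + 2q'c s.t. 1'c = total, 0 <= c <= cap (clamping active set)."""
    n = len(q)
    lower = np.zeros(n, dtype=bool)
    upper = np.zeros(n, dtype=bool)
    for _ in range(3 * n + 10):
        free = ~lower & ~upper
        nf = int(free.sum())
        if nf == 0:
            break
        A = Q[np.ix_(free, free)] + 1e-10 * np.eye(nf)
        q_eff = q[free] + Q[np.ix_(free, upper)] @ np.full(int(upper.sum()), cap)
        S = total - cap * int(upper.sum())
        v = np.linalg.solve(A, np.ones(nf))
        w = np.linalg.solve(A, q_eff)
        mu_half = (S + w.sum()) / v.sum()
        cf = mu_half * v - w
        c = np.zeros(n)
        c[free] = cf
        c[upper] = cap
        if cf.min() < -1e-12:
            lower[np.flatnonzero(free)[cf < -1e-12]] = True
            continue
        if cf.max() > cap + 1e-12:
            upper[np.flatnonzero(free)[np.argmax(cf)]] = True
            continue
        return c
    c = np.zeros(n)
    c[upper] = cap
    free = ~lower & ~upper
    if free.sum():
        c[free] = max(total - c.sum(), 0.0) / free.sum()
    return c


def _solve_qclp(
    g: np.ndarray,
    Q: np.ndarray,
    q: np.ndarray,
    r: float,
    cap: float,
    total: float,
    bound: float,
    tol: float = 1e-10,
) -> tuple[np.ndarray, str]:
    """Maximise g'c s.t. c'Qc + 2q'c + r <= bound, 1'c = total, 0 <= c <= cap."""
    n = len(g)
    # 1. constraint slack at the LP optimum?
    c_lp = _greedy_lp(g, cap, total)
    if _quad(Q, q, r, c_lp) <= bound + tol:
        return c_lp, "optimal"
    # 2. feasibility: minimum achievable kinship
    c_min = _solve_equality_qp(Q, q, total, cap)
    if _quad(Q, q, r, c_min) > bound + 1e-9:
        return c_min, "infeasible-relaxed"
    # 3. active-set iteration with the constraint active
    lower = np.zeros(n, dtype=bool)
    upper = np.zeros(n, dtype=bool)
    best = c_min
    for _ in range(6 * n + 20):
        free = ~lower & ~upper
        nf = int(free.sum())
        if nf == 0:
            break
        A = Q[np.ix_(free, free)] + 1e-10 * np.eye(nf)
        q_eff = q[free] + Q[np.ix_(free, upper)] @ np.full(int(upper.sum()), cap)
        S = total - cap * int(upper.sum())
        u = np.linalg.solve(A, g[free])
        v = np.linalg.solve(A, np.ones(nf))
        w = np.linalg.solve(A, q_eff)
        sv = v.sum()
        # c_F(x) = c0 + x * p  (x = 1/(2 lambda) >= 0)
        p_dir = u - (u.sum() / sv) * v
        c0 = ((S + w.sum()) / sv) * v - w
        cp = np.zeros(n)
        cc = np.zeros(n)
        cp[free] = p_dir
        cc[free] = c0
        cc[upper] = cap
        a2 = float(cp @ Q @ cp)
        a1 = float(2.0 * cp @ (Q @ cc + q))
        a0 = _quad(Q, q, r, cc) - bound
        if a2 <= 1e-14:
            x = -a0 / a1 if abs(a1) > 1e-14 else 0.0
            x = max(x, 0.0)
        else:
            disc = a1 * a1 - 4.0 * a2 * a0
            if disc < 0:
                # constraint unreachable on this face; fall back to min-kinship face
                x = 0.0
            else:
                x = (-a1 + np.sqrt(disc)) / (2.0 * a2)
                x = max(x, 0.0)
        c = cc + x * cp
        cf = c[free]
        if cf.min() < -1e-10:
            # clamp all violators at once; the KKT release step below can
            # rescue any that were clamped too eagerly
            lower[np.flatnonzero(free)[cf < -1e-10]] = True
            continue
        if cf.max() > cap + 1e-10:
            upper[np.flatnonzero(free)[np.argmax(cf)]] = True
            continue
        best = np.clip(c, 0.0, cap)
        # KKT release check: grad of Lagrangian uses lambda = 1/(2x)
        if x <= 1e-14:
            break
        lam = 1.0 / (2.0 * x)
        grad = g - 2.0 * lam * (Q @ c + q)
        mu = float(grad[free].mean())
        released = False
        low_idx = np.flatnonzero(lower)
        if low_idx.size:
            viol = grad[low_idx] - mu
            k = np.argmax(viol)
            if viol[k] > 1e-9:
                lower[low_idx[k]] = False
                released = True
        up_idx = np.flatnonzero(upper)
        if not released and up_idx.size:
            viol = mu - grad[up_idx]
            k = np.argmax(viol)
            if viol[k] > 1e-9:
                upper[up_idx[k]] = False
                released = True
        if not released:
            break
    # exact constraint satisfaction: shrink towards c_min if needed
    c = best
    if _quad(Q, q, r, c) > bound + tol:
        loq, hiq = 0.0, 1.0
        for _ in range(80):
            mid = 0.5 * (loq + hiq)
            trial = c_min + mid * (c - c_min)
            if _quad(Q, q, r, trial) <= bound:
                loq = mid
            else:
                hiq = mid
        c = c_min + loq * (c - c_min)
    return c, "optimal"


def solve_contributions(problem: ContributionProblem) -> ContributionSolution:
    """Solve the OCS problem, then prune sub-one-mating contributions.

    After the initial solve, while the smallest positive contribution is
    below one mating's share, that sire is fixed at zero and the problem is
    re-solved (mirroring iterative pruning of the lowest-contribution boar).
    If the kinship bound is unattainable the kinship-minimising feasible
    contribution vector is returned with status ``infeasible-relaxed``.
    """
    n = len(problem.candidate_ids)
    g = np.asarray(problem.gebv, dtype=float)
    K = np.asarray(problem.K, dtype=float)
    d = np.full(problem.n_dams, 0.5 / problem.n_dams)
    Kmm = K[:n, :n]
    Kmd = K[:n, n:]
    q_vec = Kmd @ d
    r_const = float(d @ K[n:, n:] @ d)
    bound = kinship_bound(problem.f_bar_t, problem.rate)
    cap, share = problem.cap, problem.mating_share

    active = np.ones(n, dtype=bool)
    pruned = False
    for _ in range(n):
        idx = np.flatnonzero(active)
        c_sub, status = _solve_qclp(g[idx], Kmm[np.ix_(idx, idx)], q_vec[idx], r_const, cap, 0.5, bound)
        c = np.zeros(n)
        c[idx] = c_sub
        if status == "infeasible-relaxed":
            break
        pos = idx[c_sub > 1e-12]
        if pos.size == 0:
            break
        smallest = pos[np.argmin(c[pos])]
        if c[smallest] < share - 1e-9 and pos.size * cap > 0.5 + 1e-12:
            active[smallest] = False
            # also drop exact zeros; they cannot re-enter the optimum
            active[idx[c_sub <= 1e-12]] = False
            pruned = True
            continue
        break
    xKx = _quad(Kmm, q_vec, r_const, c)
    final_status = status if status == "infeasible-relaxed" else ("pruned-optimal" if pruned else "optimal")
    return ContributionSolution(
        candidate_ids=np.asarray(problem.candidate_ids),
        contributions=c,
        objective=float(g @ c),
        xKx=xKx,
        bound=bound,
        status=final_status,
    )


# ---------------------------------------------------------------------------
# matings


def contributions_to_matings(
    solution: ContributionSolution,
    dam_ids: np.ndarray,
    seed: int | np.random.Generator = 0,
    mating_share: float | None = None,
) -> list[tuple[int, int]]:
    """Convert contributions to one (sire, dam) pair per dam.

    Contributions are rounded to integer mating counts by largest-remainder
    rounding; dams are then shuffled and assigned to sires in blocks, so a
    permutation of ``dam_ids`` changes the pairing but never the per-sire
    counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "matings")
    dam_ids = np.asarray(dam_ids)
    n_matings = dam_ids.size
    share = mating_share if mating_share is not None else 0.5 / n_matings
    raw = solution.contributions / share
    counts = np.floor(raw + 1e-9).astype(int)
    remainder = raw - counts
    missing = n_matings - counts.sum()
    if missing < 0:
        raise ValueError("contributions exceed the number of matings")
    for i in np.argsort(-remainder)[:missing]:
        counts[i] += 1
    order = rng.permutation(n_matings)
    shuffled = dam_ids[order]
    matings = []
    pos = 0
    for sire, k in zip(solution.candidate_ids, counts):
        for _ in range(k):
            matings.append((int(sire), int(shuffled[pos])))
            pos += 1
    if pos != n_matings:
        raise ValueError("rounding failed to cover all matings")
    return matings
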