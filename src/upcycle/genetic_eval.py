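"""Genomic evaluation: VanRaden GRM, GBLUP, SNP-effect backsolving, REML.

The single-trait animal model is ``y = 1*mu + g + e`` with
``Var(g) = G * sigma2_g`` and ``G`` the method-1 VanRaden genomic
relationship matrix, ``G = ZZ' / (2 * sum p_j (1-p_j))`` where ``Z`` centres
allele counts by twice the reference allele frequencies.  Which reference
frequencies are used is a policy choice (training population for breeding
value estimation, an older elite generation for the optimum-contribution
kinship matrix, the sampled animals for variance components) and is carried
along explicitly so the deliberate inconsistency between consumers is
auditable.

For the closed-loop simulation, :class:`TrainingStore` evaluates the model
in marker dimension through the Woodbury identity, which is algebraically
identical to the animal-model solve but avoids factorising the n x n
covariance matrix every generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

__all__ = [
    "GrmSpec",
    "EvaluationResult",
    "grm_vanraden1",
    "center_genotypes",
    "solve_gblup",
    "backsolve_snp_effects",
    "indirect_gebv",
    "estimate_variance_components",
    "reml_loglik",
    "TrainingStore",
]

FREQ_CLAMP = (0.001, 0.999)
RIDGE = 1e-8


@dataclass
class GrmSpec:
    """Reference-allele-frequency policy and the frequencies themselves."""

    ref_freq_policy: str  # 'training-population' | 'elite-5-generations-ago' | 'vce-sample'
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        allowed = {"training-population", "elite-5-generations-ago", "vce-sample"}
        if self.ref_freq_policy not in allowed:
            raise ValueError(f"unknown policy {self.ref_freq_policy!r}")


@dataclass
class EvaluationResult:
    gebv: np.ndarray
    snp_effects: np.ndarray
    sigma2_g: float
    sigma2_e: float
    training_ids: np.ndarray
    ref_freqs: np.ndarray = field(default=None, repr=False)

    def gebv_of(self, ids: np.ndarray) -> np.ndarray:
        lookup = {int(i): k for k, i in enumerate(self.training_ids)}
        return self.gebv[[lookup[int(i)] for i in ids]]


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), *FREQ_CLAMP)


def center_genotypes(genotypes: np.ndarray, ref_freqs: np.ndarray) -> tuple[np.ndarray, float]:
    """Return (Z, denom): centred allele counts and 2*sum(p(1-p)).

    Reference frequencies are clamped to [0.001, 0.999] for centring and the
    denominator; loci whose raw reference frequency is exactly 0 or 1 carry
    no information and their columns are zeroed outright, so monomorphic
    loci get marker effects of exactly zero.
    """
    raw = np.asarray(ref_freqs, dtype=float)
    p = _clamp(raw)
    Z = np.asarray(genotypes, dtype=float) - 2.0 * p
    mono = (raw <= 0.0) | (raw >= 1.0)
    if mono.any():
        Z[:, mono] = 0.0
    denom = float(2.0 * np.sum(p[~mono] * (1.0 - p[~mono])))
    if denom == 0.0:
        raise ValueError("all reference frequencies monomorphic: zero VanRaden denominator")
    return Z, denom


def grm_vanraden1(genotypes: np.ndarray, ref_freqs: np.ndarray) -> np.ndarray:
    """Method-1 VanRaden GRM: G = ZZ' / (2 sum p(1-p)).

    ``genotypes`` holds allele counts in {0,1,2}, one row per animal.
    Reference frequencies are clamped to [0.001, 0.999] before centring.
    """
    Z, denom = center_genotypes(genotypes, ref_freqs)
    return (Z @ Z.T) / denom


def solve_gblup(
    phenotypes: np.ndarray,
    G: np.ndarray,
    sigma2_g: float,
    sigma2_e: float,
    ridge: float = RIDGE,
) -> np.ndarray:
    """BLUP of genetic values for the model y = 1*mu + g + e.

    Solved through the phenotypic covariance V = G*sigma2_g + I*sigma2_e
    with a GLS mean: g_hat = sigma2_g * G V^-1 (y - 1*mu_hat).  In the
    shrinkage limit sigma2_g -> 0 all values go to zero.
    """
    y = np.asarray(phenotypes, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotypes")
    n = y.size
    V = sigma2_g * G + (sigma2_e + ridge) * np.eye(n)
    c = cho_factor(V, lower=True)
    Vi_y = cho_solve(c, y)
    Vi_1 = cho_solve(c, np.ones(n))
    mu = float(np.ones(n) @ Vi_y) / float(np.ones(n) @ Vi_1)
    return sigma2_g * (G @ (Vi_y - mu * Vi_1))


def backsolve_snp_effects(
    gebv: np.ndarray, chip_genotypes: np.ndarray, ref_freqs: np.ndarray
) -> np.ndarray:
    """Marker effects from animal GBLUP solutions: a = Z' G^- g_hat / denom.

    Uses a pseudo-inverse when G is singular (more animals than markers);
    because GBLUP solutions lie in the column space of G, the reconstruction
    Z a = g_hat still holds exactly in that case.
    """
    Z, denom = center_genotypes(chip_genotypes, ref_freqs)
    G = (Z @ Z.T) / denom
    cond = np.linalg.cond(G)
    if cond > 1e10:
        warnings.warn(f"G nearly singular (cond={cond:.2e}); using pseudo-inverse", stacklevel=2)
    Gi_g = np.linalg.pinv(G, hermitian=True, rcond=1e-10) @ np.asarray(gebv, dtype=float)
    return (Z.T @ Gi_g) / denom


def indirect_gebv(
    snp_effects: np.ndarray, chip_genotypes: np.ndarray, ref_freqs: np.ndarray
) -> np.ndarray:
    """Predictions from marker effects alone: gebv = Z_new @ a.

    Used for animals outside the training window (archived boars).  New
    genotypes are centred with the same reference frequencies used when the
    effects were backsolved.
    """
    a = np.asarray(snp_effects, dtype=float)
    if np.asarray(chip_genotypes).shape[1] != a.size:
        raise ValueError("chip mismatch between genotypes and SNP effects")
    Z, _ = center_genotypes(chip_genotypes, ref_freqs)
    return Z @ a


# ---------------------------------------------------------------------------
# REML


def reml_loglik(y: np.ndarray, d: np.ndarray, Uty: np.ndarray, Ut1: np.ndarray, h: float) -> float:
    """Restricted log-likelihood at heritability ``h``, total variance profiled out.

    ``d`` are eigenvalues of G and ``Uty``, ``Ut1`` the rotated data/design.
    """
    n = y.size
    v = h * d + (1.0 - h)
    iv = 1.0 / v
    s11 = float(Ut1 @ (iv * Ut1))
    s1y = float(Ut1 @ (iv * Uty))
    syy = float(Uty @ (iv * Uty))
    rss = syy - s1y * s1y / s11
    if rss <= 0:
        return -np.inf
    sigma2 = rss / (n - 1)
    return -0.5 * (np.sum(np.log(v)) + np.log(s11) + (n - 1) * (np.log(sigma2) + 1.0))


def estimate_variance_components(
    sample_phenotypes: np.ndarray,
    sample_G: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float]:
    """REML estimates (sigma2_g, sigma2_e) for the one-random-effect model.

    The profile restricted likelihood over the heritability ratio is
    maximised after a single eigendecomposition of G; the total variance has
    a closed-form optimum given the ratio.  Pass ``eig=(values, vectors)``
    to reuse a decomposition across calls on the same G.
    """
    y = np.asarray(sample_phenotypes, dtype=float)
    d, U = eig if eig is not None else eigh(sample_G)
    d = np.maximum(d, 0.0)
    Uty = U.T @ y
    Ut1 = U.T @ np.ones(y.size)
    obj = lambda h: -reml_loglik(y, d, Uty, Ut1, h)
    res = minimize_scalar(obj, bounds=(1e-6, 1.0 - 1e-6), method="bounded", options={"xatol": 1e-8})
    h = float(res.x)
    v = h * d + (1.0 - h)
    iv = 1.0 / v
    s11 = float(Ut1 @ (iv * Ut1))
    s1y = float(Ut1 @ (iv * Uty))
    syy = float(Uty @ (iv * Uty))
    sigma2 = (syy - s1y * s1y / s11) / (y.size - 1)
    return h * sigma2, (1.0 - h) * sigma2


# ---------------------------------------------------------------------------
# sliding-window training store (closed-loop engine)


class TrainingStore:
    """Sliding window of training cohorts with cached cross-products.

    Holds the chip genotypes and phenotypes of the current and previous
    ``window`` generations.  Marker cross-products M'M are cached per cohort
    so that assembling Z'Z under this generation's reference frequencies is
    cheap, and the mixed model is solved in marker dimension:

        V^-1 x = (x - Z C^-1 Z'x) / sigma2_e,   C = Z'Z + (sigma2_e/a) I

    with ``a = sigma2_g / denom``.  GEBVs are ``Z a_hat`` with
    ``a_hat = a Z' V^-1 (y - 1 mu_hat)``, which simultaneously yields the
    backsolved SNP effects used for indirect prediction.
    """

    def __init__(self, window: int = 5):
        self.window = int(window)
        self._cohorts: list[dict] = []  # oldest first

    def add_cohort(
        self,
        generation: int,
        ids: np.ndarray,
        M: np.ndarray,
        y: np.ndarray,
        elite_mask: np.ndarray | None = None,
    ) -> None:
        M = np.asarray(M, dtype=np.float64)
        self._cohorts.append(
            {
                "generation": int(generation),
                "ids": np.asarray(ids, dtype=np.int64),
                "M": M,
                "y": np.asarray(y, dtype=float),
                "MtM": M.T @ M,
                "colsum": M.sum(axis=0),
                "Mty": M.T @ np.asarray(y, dtype=float),
                "elite_mask": (
                    np.ones(M.shape[0], dtype=bool) if elite_mask is None else np.asarray(elite_mask, dtype=bool)
                ),
            }
        )
        while len(self._cohorts) > self.window + 1:
            self._cohorts.pop(0)

    @property
    def training_ids(self) -> np.ndarray:
        return np.concatenate([c["ids"] for c in self._cohorts])

    def training_freqs(self) -> np.ndarray:
        n = sum(c["M"].shape[0] for c in self._cohorts)
        s = sum(c["colsum"] for c in self._cohorts)
        return s / (2.0 * n)

    def evaluate(self, sigma2_g: float, sigma2_e: float) -> EvaluationResult:
        if not self._cohorts:
            raise ValueError("no training cohorts")
        p = _clamp(self.training_freqs())
        denom = float(2.0 * np.sum(p * (1.0 - p)))
        n = sum(c["M"].shape[0] for c in self._cohorts)
        m = p.size
        colsum = sum(c["colsum"] for c in self._cohorts)
        # Z'Z assembled from cached M'M:  Z = M - 2 1 p'
        MtM = sum(c["MtM"] for c in self._cohorts)
        ZtZ = MtM - 2.0 * np.outer(p, colsum) - 2.0 * np.outer(colsum, p) + 4.0 * n * np.outer(p, p)
        a = sigma2_g / denom
        se = sigma2_e + RIDGE * sigma2_g  # diagonal ridge on G absorbed here
        C = ZtZ + (se / a) * np.eye(m)
        cf = cho_factor(C, lower=True)

        y = np.concatenate([c["y"] for c in self._cohorts])
        sy, s1 = float(y.sum()), float(n)
        Mty = sum(c["Mty"] for c in self._cohorts)
        Zty = Mty - 2.0 * p * sy
        Zt1 = colsum - 2.0 * p * s1
        # V^-1 y and V^-1 1 in the quantities needed for the GLS mean
        w_y = cho_solve(cf, Zty)
        w_1 = cho_solve(cf, Zt1)
        one_Vi_y = (sy - float(Zt1 @ w_y)) / se
        one_Vi_1 = (s1 - float(Zt1 @ w_1)) / se
        mu = one_Vi_y / one_Vi_1
        Ztr = Zty - mu * Zt1
        w_r = cho_solve(cf, Ztr)
        # a_hat = a Z'V^-1 r with V^-1 r = (r - Z w_r)/se
        effects = a * (Ztr - ZtZ @ w_r) / se
        gebv = np.concatenate(
            [c["M"] @ effects - (2.0 * p @ effects) for c in self._cohorts]
        )
        return EvaluationResult(
            gebv=gebv,
            snp_effects=effects,
            sigma2_g=float(sigma2_g),
            sigma2_e=float(sigma2_e),
            training_ids=self.training_ids,
            ref_freqs=p,
        )

    def vce_sample(
        self, n_sample: int, depth: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Random elite (phenotypes, genotypes) from the most recent ``depth+1`` cohorts."""
        recent = self._cohorts[-(depth + 1):]
        M = np.concatenate([c["M"][c["elite_mask"]] for c in recent])
        y = np.concatenate([c["y"][c["elite_mask"]] for c in recent])
        if y.size > n_sample:
            idx = rng.choice(y.size, n_sample, replace=False)
            M, y = M[idx], y[idx]
        return y, M
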