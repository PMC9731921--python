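"""Zero-augmented multi-species occupancy model (MSOM).

The community model follows the Dorazio–Royle construction. The observed
n-species detection matrix is augmented with ``nz`` all-zero rows standing
for hypothetical never-detected community members; each of the M = n + nz
rows carries an inclusion indicator w_i ~ Bernoulli(Omega). Included species
have logit-normal occupancy and detection effects,

    logit(psi_i) ~ Normal(mu_lpsi, sigma_lpsi),
    logit(p_i)   ~ Normal(mu_lp,  sigma_lp),

latent presence z_ij ~ Bernoulli(w_i * psi_i) at each of J stations, and
detections y_ij ~ Binomial(K_j, z_ij * p_i) over K_j trap-night occasions
(detection is constant across occasions — the null model — so the
occasion-level Bernoullis collapse to a binomial with identical likelihood).
Total species richness is N = sum_i w_i; station richness is sum_i z_ij.

Priors: Omega ~ Uniform(0,1); mu_lpsi, mu_lp ~ Normal(0, 1.5) on the logit
scale; sigma_lpsi, sigma_lp ~ Uniform(0, 5).

Inference is Metropolis-within-Gibbs: exact conditional draws for z_ij, w_i
(with z marginalised) and Omega (Beta), conjugate normal draws for the
community means, and random-walk Metropolis for each logit effect and for
the community SDs on the log scale. Proposal scales adapt during burn-in
only, so the post-burn-in kernel satisfies detailed balance.

``exact_posterior_small`` provides an independent brute-force oracle for
tiny instances: it enumerates every (w, z) configuration, integrates the
species effects by Gauss–Hermite quadrature and Omega analytically, and
returns the exact richness posterior for cross-checking the sampler.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, expit, gammaln, logit, roots_hermitenorm

from .events import DetectionData

__all__ = [
    "AugmentedData",
    "ModelState",
    "MCMCConfig",
    "Priors",
    "PosteriorChains",
    "PosteriorSummary",
    "PRESETS",
    "augment",
    "complete_data_log_density",
    "fit_msom",
    "exact_posterior_small",
    "gelman_rubin",
    "summarize_posterior",
]

LOGIT_CLAMP = 35.0  # |logit| beyond this is numerically saturated


@dataclass
class AugmentedData:
    """Detection data plus ``nz`` all-zero augmentation rows."""

    y: np.ndarray            # (M, J)
    K: np.ndarray            # (J,)
    n_observed: int
    nz: int
    species: list[str]       # names of the observed rows

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.K = np.asarray(self.K, dtype=int)
        if self.y.shape[0] != self.n_observed + self.nz:
            raise ValueError("M must equal n_observed + nz")
        if self.nz and self.y[self.n_observed:].any():
            raise ValueError("augmentation rows must be all zero")
        if np.any(self.y > self.K[None, :]):
            raise ValueError("y_ij must not exceed K_j")

    @property
    def M(self) -> int:
        return self.y.shape[0]

    @property
    def J(self) -> int:
        return self.y.shape[1]


def augment(detection: DetectionData, nz: int = 10) -> AugmentedData:
    """Append ``nz`` all-zero species rows for richness estimation."""
    if nz < 0:
        raise ValueError("nz must be nonnegative")
    n, J = detection.y.shape
    y = np.vstack([detection.y, np.zeros((nz, J), dtype=int)])
    return AugmentedData(
        y=y, K=detection.K.copy(), n_observed=n, nz=nz,
        species=list(detection.species),
    )


@dataclass(frozen=True)
class Priors:
    """Hyperpriors of the community model."""

    mu_sd: float = 1.5       # Normal(0, mu_sd) for mu_lpsi, mu_lp
    sigma_max: float = 5.0   # Uniform(0, sigma_max) for sigma_lpsi, sigma_lp


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; ``n_iter`` counts post-burn-in iterations."""

    n_chains: int = 7
    n_iter: int = 1_000_000
    burn_in: int = 5_000
    thin: int = 100
    seed: int = 0
    step_logit: float = 1.0   # initial RW scale for lpsi_i / lp_i
    step_logsigma: float = 0.3

    def __post_init__(self) -> None:
        if self.thin < 1 or self.n_iter < 1 or self.burn_in < 0:
            raise ValueError("invalid MCMC configuration")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_stored(self) -> int:
        return self.n_iter // self.thin


PRESETS: dict[str, MCMCConfig] = {
    # settings used for the headline analysis: hours-scale
    "paper": MCMCConfig(n_chains=7, n_iter=1_000_000, burn_in=5_000, thin=100),
    # reduced settings for tests and desk runs
    "desk": MCMCConfig(n_chains=3, n_iter=20_000, burn_in=2_000, thin=10),
}


@dataclass
class ModelState:
    """One full configuration of the latent variables and parameters."""

    Omega: float
    w: np.ndarray        # (M,)
    lpsi: np.ndarray     # (M,)
    lp: np.ndarray       # (M,)
    z: np.ndarray        # (M, J)
    mu_lpsi: float
    sigma_lpsi: float
    mu_lp: float
    sigma_lp: float


def _log_bernoulli(x: np.ndarray, prob: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(x == 1, np.log(prob), np.log1p(-prob))


def complete_data_log_density(
    state: ModelState, data: AugmentedData, priors: Priors = Priors()
) -> float:
    """Joint log density of data and latents at ``state`` (including priors).

    Returns -inf for structurally impossible states (a detection where
    z_ij = 0, or z_ij = 1 under w_i = 0). Binomial coefficients are
    included so the value matches term-by-term hand computation.
    """
    y, K = data.y, data.K
    w, z = state.w, state.z
    if np.any((y > 0) & (z == 0)) or np.any(z[w == 0] == 1):
        return -np.inf
    psi = expit(state.lpsi)
    p = expit(state.lp)

    ld = 0.0
    # priors
    if not (0 < state.Omega < 1):
        return -np.inf
    if not (0 < state.sigma_lpsi < priors.sigma_max):
        return -np.inf
    if not (0 < state.sigma_lp < priors.sigma_max):
        return -np.inf
    for mu in (state.mu_lpsi, state.mu_lp):
        ld += -0.5 * (mu / priors.mu_sd) ** 2 - 0.5 * math.log(
            2 * math.pi * priors.mu_sd**2
        )
    ld -= math.log(priors.sigma_max) * 2  # the two uniform sigma priors
    # species effects
    for lvec, mu, sd in (
        (state.lpsi, state.mu_lpsi, state.sigma_lpsi),
        (state.lp, state.mu_lp, state.sigma_lp),
    ):
        ld += float(
            np.sum(
                -0.5 * ((lvec - mu) / sd) ** 2
                - 0.5 * math.log(2 * math.pi * sd**2)
            )
        )
    # inclusion
    ld += float(np.sum(_log_bernoulli(w, np.full(data.M, state.Omega))))
    # occupancy: z_ij ~ Bern(w_i * psi_i)
    occ_prob = w[:, None] * psi[:, None] * np.ones_like(z, dtype=float)
    ld += float(np.sum(_log_bernoulli(z, occ_prob)))
    # detection: y_ij ~ Binom(K_j, z_ij * p_i); z=0 cells contribute 0
    det_p = z * p[:, None]
    lchoose = gammaln(K + 1)[None, :] - gammaln(y + 1) - gammaln(K[None, :] - y + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = lchoose + y * np.log(det_p) + (K[None, :] - y) * np.log1p(-det_p)
    term = np.where(z == 1, term, 0.0)
    ld += float(np.sum(term))
    return ld


# ---------------------------------------------------------------------------
# sampler


def _log_expit(x: np.ndarray) -> np.ndarray:
    """log(sigmoid(x)), stable."""
    return -np.logaddexp(0.0, -x)


@dataclass
class PosteriorChains:
    """Thinned post-burn-in draws, one leading axis per chain.

    ``params`` holds arrays of shape (n_chains, n_stored) for scalars
    (Omega, mu_lpsi, sigma_lpsi, mu_lp, sigma_lp, N) and
    (n_chains, n_stored, M) for vectors (lpsi, lp, w); ``site_richness``
    is (n_chains, n_stored, J). ``z`` is stored only when requested.
    """

    params: dict[str, np.ndarray]
    data: AugmentedData
    config: MCMCConfig
    z: np.ndarray | None = None  # (C, S, M, J) when store_z

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled across chains (chain axis flattened)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])


def _run_chain(
    data: AugmentedData,
    config: MCMCConfig,
    rng: np.random.Generator,
    priors: Priors,
    fixed: dict[str, float],
    store_z: bool,
) -> dict[str, np.ndarray]:
    y, K = data.y, data.K
    M, J = data.M, data.J
    n_obs = data.n_observed
    observed = np.zeros(M, dtype=bool)
    observed[:n_obs] = True
    detected_cells = y > 0
    all_zero_row = ~detected_cells.any(axis=1)

    fix = dict(fixed)
    mu_lpsi = fix.get("mu_lpsi", rng.normal(0, 0.5))
    sigma_lpsi = fix.get("sigma_lpsi", 1.0)
    mu_lp = fix.get("mu_lp", rng.normal(0, 0.5))
    sigma_lp = fix.get("sigma_lp", 1.0)
    Omega = fix.get("omega", rng.uniform(0.2, 0.8))

    lpsi = mu_lpsi + sigma_lpsi * rng.normal(size=M)
    lp = mu_lp + sigma_lp * rng.normal(size=M)
    w = np.ones(M, dtype=int)
    z = detected_cells.astype(int)
    z |= rng.random((M, J)) < 0.5
    step_psi = np.full(M, config.step_logit)
    step_p = np.full(M, config.step_logit)
    step_sig = np.array([config.step_logsigma, config.step_logsigma])
    acc_psi = np.zeros(M)
    acc_p = np.zeros(M)
    acc_sig = np.zeros(2)
    elig_psi = np.zeros(M)
    elig_p = np.zeros(M)
    n_sig = 0
    ADAPT_EVERY, TARGET = 50, 0.44

    S = config.n_stored
    out = {
        "Omega": np.empty(S),
        "mu_lpsi": np.empty(S),
        "sigma_lpsi": np.empty(S),
        "mu_lp": np.empty(S),
        "sigma_lp": np.empty(S),
        "N": np.empty(S, dtype=int),
        "lpsi": np.empty((S, M)),
        "lp": np.empty((S, M)),
        "w": np.empty((S, M), dtype=np.int8),
        "site_richness": np.empty((S, J), dtype=np.int16),
    }
    z_store = np.empty((S, M, J), dtype=np.int8) if store_z else None

    total_iter = config.burn_in + config.n_iter
    s_ix = 0
    for it in range(total_iter):
        adapting = it < config.burn_in
        psi = expit(lpsi)
        p = expit(lp)

        # --- lpsi: random-walk MH per species (prior draw where w_i = 0)
        sz = z.sum(axis=1)
        if sigma_lpsi > 0:
            prop = lpsi + step_psi * rng.normal(size=M)
            prop = np.clip(prop, -LOGIT_CLAMP, LOGIT_CLAMP)
            loglik = lambda l: sz * _log_expit(l) + (J - sz) * _log_expit(-l)  # noqa: E731
            logpost_cur = loglik(lpsi) - 0.5 * ((lpsi - mu_lpsi) / sigma_lpsi) ** 2
            logpost_new = loglik(prop) - 0.5 * ((prop - mu_lpsi) / sigma_lpsi) ** 2
            accept = np.log(rng.random(M)) < logpost_new - logpost_cur
            accept &= w == 1
            lpsi = np.where(accept, prop, lpsi)
            free = w == 0
            if free.any():
                lpsi[free] = mu_lpsi + sigma_lpsi * rng.normal(size=int(free.sum()))
            acc_psi += accept
            elig_psi += w == 1
        else:
            lpsi = np.full(M, mu_lpsi)
        psi = expit(lpsi)

        # --- lp: random-walk MH per species (prior draw where no occupied site)
        sy = np.where(z == 1, y, 0).sum(axis=1)
        sk = (z * K[None, :]).sum(axis=1)
        if sigma_lp > 0:
            informative = sk > 0
            prop = lp + step_p * rng.normal(size=M)
            prop = np.clip(prop, -LOGIT_CLAMP, LOGIT_CLAMP)
            loglik = lambda l: sy * _log_expit(l) + (sk - sy) * _log_expit(-l)  # noqa: E731
            logpost_cur = loglik(lp) - 0.5 * ((lp - mu_lp) / sigma_lp) ** 2
            logpost_new = loglik(prop) - 0.5 * ((prop - mu_lp) / sigma_lp) ** 2
            accept = np.log(rng.random(M)) < logpost_new - logpost_cur
            accept &= informative
            lp = np.where(accept, prop, lp)
            if (~informative).any():
                lp[~informative] = mu_lp + sigma_lp * rng.normal(
                    size=int((~informative).sum())
                )
            acc_p += accept
            elig_p += informative
        else:
            lp = np.full(M, mu_lp)
        p = expit(lp)

        # --- w for all-zero rows, with z marginalised out:
        # P(y_i = 0 | w_i = 1) = prod_j [psi (1-p)^K_j + 1 - psi]
        log_q = _log_expit(-lp)  # log(1 - p)
        site_term = np.log(
            psi[:, None] * np.exp(log_q[:, None] * K[None, :]) + (1.0 - psi[:, None])
        )
        logL1 = site_term.sum(axis=1)
        cand = all_zero_row & ~observed
        if cand.any():
            if Omega >= 1.0:
                w[cand] = 1
            elif Omega <= 0.0:
                w[cand] = 0
            else:
                num = np.log(Omega) + logL1[cand]
                den = np.logaddexp(num, math.log1p(-Omega))
                w[cand] = rng.random(int(cand.sum())) < np.exp(num - den)
        w[observed] = 1

        # --- z: exact conditional
        # y_ij > 0 -> z = 1; else Bern(psi q^K / (psi q^K + 1 - psi)) if w=1
        log_qK = log_q[:, None] * K[None, :]
        cond = psi[:, None] * np.exp(log_qK)
        cond = cond / (cond + (1.0 - psi[:, None]))
        z = (rng.random((M, J)) < cond).astype(int)
        z[detected_cells] = 1
        z[w == 0] = 0

        # --- Omega ~ Beta(1 + sum w, 1 + M - sum w)
        if "omega" not in fix:
            nw = int(w.sum())
            Omega = rng.beta(1 + nw, 1 + M - nw)

        # --- community means: conjugate normal draws
        if "mu_lpsi" not in fix and sigma_lpsi > 0:
            prec = M / sigma_lpsi**2 + 1 / priors.mu_sd**2
            mean = (lpsi.sum() / sigma_lpsi**2) / prec
            mu_lpsi = rng.normal(mean, 1 / math.sqrt(prec))
        if "mu_lp" not in fix and sigma_lp > 0:
            prec = M / sigma_lp**2 + 1 / priors.mu_sd**2
            mean = (lp.sum() / sigma_lp**2) / prec
            mu_lp = rng.normal(mean, 1 / math.sqrt(prec))

        # --- community SDs: MH on log sigma, Uniform(0, sigma_max) prior
        for k, (name, lvec, mu) in enumerate(
            (("sigma_lpsi", lpsi, mu_lpsi), ("sigma_lp", lp, mu_lp))
        ):
            if name in fix:
                continue
            sig = sigma_lpsi if k == 0 else sigma_lp
            prop = sig * math.exp(step_sig[k] * rng.normal())
            if prop < priors.sigma_max:
                ss = float(np.sum((lvec - mu) ** 2))
                # target x Jacobian of the log transform
                cur_ld = -M * math.log(sig) - ss / (2 * sig**2) + math.log(sig)
                new_ld = -M * math.log(prop) - ss / (2 * prop**2) + math.log(prop)
                if math.log(rng.random()) < new_ld - cur_ld:
                    if k == 0:
                        sigma_lpsi = prop
                    else:
                        sigma_lp = prop
                    acc_sig[k] += 1
        n_sig += 1

        # --- adapt proposal scales during burn-in only
        if adapting and (it + 1) % ADAPT_EVERY == 0:
            step_psi *= np.exp((acc_psi / np.maximum(elig_psi, 1) - TARGET) * 0.5)
            step_p *= np.exp((acc_p / np.maximum(elig_p, 1) - TARGET) * 0.5)
            step_sig *= np.exp((acc_sig / max(n_sig, 1) - TARGET) * 0.5)
            np.clip(step_psi, 0.01, 10.0, out=step_psi)
            np.clip(step_p, 0.01, 10.0, out=step_p)
            np.clip(step_sig, 0.01, 5.0, out=step_sig)
            acc_psi[:] = 0
            acc_p[:] = 0
            acc_sig[:] = 0
            elig_psi[:] = 0
            elig_p[:] = 0
            n_sig = 0

        if not adapting and (it - config.burn_in) % config.thin == 0:
            if s_ix < S:
                out["Omega"][s_ix] = Omega
                out["mu_lpsi"][s_ix] = mu_lpsi
                out["sigma_lpsi"][s_ix] = sigma_lpsi
                out["mu_lp"][s_ix] = mu_lp
                out["sigma_lp"][s_ix] = sigma_lp
                out["N"][s_ix] = int(w.sum())
                out["lpsi"][s_ix] = lpsi
                out["lp"][s_ix] = lp
                out["w"][s_ix] = w
                out["site_richness"][s_ix] = z.sum(axis=0)
                if store_z:
                    z_store[s_ix] = z
                s_ix += 1
    if store_z:
        out["z"] = z_store
    return out


def fit_msom(
    data: AugmentedData,
    config: MCMCConfig = PRESETS["desk"],
    priors: Priors = Priors(),
    fixed: dict[str, float] | None = None,
    store_z: bool = False,
) -> PosteriorChains:
    """Sample the MSOM posterior.

    ``fixed`` may pin hyperparameters (keys among ``omega``, ``mu_lpsi``,
    ``sigma_lpsi``, ``mu_lp``, ``sigma_lp``); a sigma fixed at 0 collapses
    the corresponding species effects to the fixed mean, which is how the
    single-parameter textbook checks are run. Deterministic for a fixed
    config (per-chain streams are spawned from ``config.seed``).
    """
    fixed = dict(fixed or {})
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [
        _run_chain(data, config, np.random.default_rng(s), priors, fixed, store_z)
        for s in seeds
    ]
    params: dict[str, np.ndarray] = {}
    for name in (
        "Omega", "mu_lpsi", "sigma_lpsi", "mu_lp", "sigma_lp", "N",
        "lpsi", "lp", "w", "site_richness",
    ):
        params[name] = np.stack([c[name] for c in chains])
    z = np.stack([c["z"] for c in chains]) if store_z else None
    return PosteriorChains(params=params, data=data, config=config, z=z)


# ---------------------------------------------------------------------------
# exact oracle for tiny instances


def exact_posterior_small(
    data: AugmentedData,
    mu_lpsi: float,
    sigma_lpsi: float,
    mu_lp: float,
    sigma_lp: float,
    n_quad: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact richness posterior on a tiny instance by brute enumeration.

    Enumerates every inclusion/occupancy configuration (w, z), integrates
    each species' logit-normal effects by ``n_quad``-point Gauss–Hermite
    quadrature, and integrates Omega ~ Uniform(0,1) analytically via the
    Beta function. Hyperparameters are fixed (pass the same values to
    ``fit_msom(fixed=...)`` for a like-for-like comparison). Returns
    ``(n_values, pmf)`` with the posterior P(N = n).

    Refuses instances beyond M <= 4, J <= 3, K <= 3 or n_quad > 10.
    """
    M, J = data.M, data.J
    if M > 4 or J > 3 or int(data.K.max()) > 3 or n_quad > 10:
        raise ValueError(
            "instance too large for exact enumeration "
            f"(need M<=4, J<=3, K<=3, n_quad<=10; got M={M}, J={J}, "
            f"K={int(data.K.max())}, n_quad={n_quad})"
        )
    y, K = data.y, data.K
    nodes, weights = roots_hermitenorm(n_quad)
    weights = weights / weights.sum()
    psi_grid = expit(mu_lpsi + sigma_lpsi * nodes) if sigma_lpsi > 0 else expit(
        np.array([mu_lpsi])
    )
    p_grid = expit(mu_lp + sigma_lp * nodes) if sigma_lp > 0 else expit(
        np.array([mu_lp])
    )
    wpsi = weights if sigma_lpsi > 0 else np.array([1.0])
    wp = weights if sigma_lp > 0 else np.array([1.0])

    def binom_pmf(yv: int, kv: int, prob: np.ndarray) -> np.ndarray:
        return (
            math.comb(kv, yv) * prob**yv * (1.0 - prob) ** (kv - yv)
        )

    # per-species table: value of the z-row factor for every z pattern
    z_patterns = list(itertools.product((0, 1), repeat=J))
    factor_w1 = np.zeros((M, len(z_patterns)))
    row_all_zero = ~ (y > 0).any(axis=1)
    for i in range(M):
        for pix, zrow in enumerate(z_patterns):
            if any(y[i, j] > 0 and zrow[j] == 0 for j in range(J)):
                continue  # impossible: detection without presence
            occ = np.ones_like(psi_grid)
            for j in range(J):
                occ *= psi_grid if zrow[j] else (1.0 - psi_grid)
            det = np.ones_like(p_grid)
            for j in range(J):
                if zrow[j]:
                    det *= binom_pmf(int(y[i, j]), int(K[j]), p_grid)
                elif y[i, j] > 0:
                    det *= 0.0
            factor_w1[i, pix] = float(np.dot(wpsi, occ)) * float(np.dot(wp, det))

    zero_pattern = z_patterns.index(tuple([0] * J))
    mass = np.zeros(M + 1)
    for w_cfg in itertools.product((0, 1), repeat=M):
        if any(w_cfg[i] == 0 and not row_all_zero[i] for i in range(M)):
            continue
        nw = sum(w_cfg)
        # integral of Omega^nw (1-Omega)^(M-nw) dOmega
        log_omega_int = betaln(nw + 1, M - nw + 1)
        per_species = []
        ok = True
        for i in range(M):
            if w_cfg[i] == 1:
                tot = float(factor_w1[i].sum())  # sums over all z rows
            else:
                # w=0 forces z row to zero; y row is all zero here
                tot = 1.0
            if tot == 0.0:
                ok = False
                break
            per_species.append(tot)
        if not ok:
            continue
        mass[nw] += math.exp(log_omega_int) * math.prod(per_species)
    total = mass.sum()
    if total <= 0:
        raise ValueError("data have zero likelihood under the model")
    pmf = mass / total
    return np.arange(M + 1), pmf


# ---------------------------------------------------------------------------
# diagnostics and summaries


def gelman_rubin(draws: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``draws`` has shape (n_chains, L). Uses the classic formula
    R-hat = sqrt(((L-1)/L * W + B/L) / W) with W the mean within-chain
    variance and B = L * variance of the chain means. Returns NaN when the
    within-chain variance is zero (constant parameter).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 10:
        raise ValueError("need >= 2 chains of equal length >= 10")
    L = draws.shape[1]
    W = float(np.mean(np.var(draws, axis=1, ddof=1)))
    B = L * float(np.var(np.mean(draws, axis=1), ddof=1))
    if W == 0.0:
        return float("nan")
    return float(np.sqrt(((L - 1) / L * W + B / L) / W))


def rhat_table(chains: PosteriorChains) -> dict[str, float]:
    """R-hat for every monitored parameter.

    Covers Omega, the four hyperparameters, N, and the per-species logit
    effects of observed species; constant parameters (e.g. w of observed
    species) are excluded.
    """
    out: dict[str, float] = {}
    for name in ("Omega", "mu_lpsi", "sigma_lpsi", "mu_lp", "sigma_lp", "N"):
        arr = chains.params[name].astype(float)
        if np.ptp(arr) == 0:
            continue
        out[name] = gelman_rubin(arr)
    n_obs = chains.data.n_observed
    for i in range(n_obs):
        sp = chains.data.species[i]
        out[f"lpsi[{sp}]"] = gelman_rubin(chains.params["lpsi"][:, :, i])
        out[f"lp[{sp}]"] = gelman_rubin(chains.params["lp"][:, :, i])
    return {k: v for k, v in out.items() if not math.isnan(v)}


def _lower_median(draws: np.ndarray) -> float:
    s = np.sort(draws)
    return float(s[(len(s) - 1) // 2])


@dataclass
class PosteriorSummary:
    """Derived estimands of the fitted community model."""

    species: list[str]
    psi_mean: np.ndarray
    psi_sd: np.ndarray
    p_mean: np.ndarray
    p_sd: np.ndarray
    omega_mean: float
    N_median: float
    N_ci: tuple[float, float]
    site_richness_mean: np.ndarray
    site_richness_ci: np.ndarray      # (J, 2)
    mean_species_psi: float           # mean of the per-species psi-hat
    hyper_mean_psi: float             # posterior mean of logit^-1(mu_lpsi)
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    @property
    def converged(self) -> bool:
        return bool(self.rhat) and self.max_rhat < 1.1

    def species_table(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        return pd.DataFrame(
            {
                "species": self.species,
                "psi_mean": np.round(self.psi_mean, 2),
                "psi_se": np.round(self.psi_sd, 2),
                "p_mean": np.round(self.p_mean, 2),
                "p_se": np.round(self.p_sd, 2),
            }
        )


def summarize_posterior(chains: PosteriorChains) -> PosteriorSummary:
    """Posterior means/intervals for the reporting quantities.

    Species-level psi/p are summarised for observed species only (the
    community table); richness N is summarised by the lower median and the
    empirical 2.5/97.5 percentiles; station richness by the posterior mean
    and 95% interval. Two community-occupancy functionals are reported:
    the mean of the species-level posterior means and the posterior mean of
    logit^-1(mu_lpsi), which weight the community differently.
    """
    n_obs = chains.data.n_observed
    if chains.params["Omega"].size == 0:
        raise ValueError("empty chains")
    lpsi = chains.stacked("lpsi")[:, :n_obs]
    lp = chains.stacked("lp")[:, :n_obs]
    psi, p = expit(lpsi), expit(lp)
    N = chains.stacked("N").astype(float)
    site = chains.stacked("site_richness").astype(float)
    ci = np.percentile(site, [2.5, 97.5], axis=0).T
    psi_mean = psi.mean(axis=0)
    return PosteriorSummary(
        species=list(chains.data.species),
        psi_mean=psi_mean,
        psi_sd=psi.std(axis=0, ddof=1),
        p_mean=p.mean(axis=0),
        p_sd=p.std(axis=0, ddof=1),
        omega_mean=float(chains.stacked("Omega").mean()),
        N_median=_lower_median(N),
        N_ci=tuple(np.percentile(N, [2.5, 97.5])),
        site_richness_mean=site.mean(axis=0),
        site_richness_ci=ci,
        mean_species_psi=float(psi_mean.mean()),
        hyper_mean_psi=float(expit(chains.stacked("mu_lpsi")).mean()),
        rhat=rhat_table(chains),
    )
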