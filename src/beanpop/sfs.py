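"""Site-frequency spectra, Watterson expectations, runs of homozygosity,
and simulation-based composite-likelihood demographic fitting.

The fitting machinery follows the fastsimcoal2 recipe at desk scale:
the expected SFS under a candidate parameter vector is estimated by
coalescent Monte Carlo over independent loci, the observed SFS enters a
multinomial composite log-likelihood

    ln L = sum_i  xi_i  ln p_hat_i

over polymorphic entries, and scenarios are compared by AIC weight.
Expected spectra use tskit branch-length spectra (the expectation of the
mutational process given the genealogy), which removes the mutation-
placement noise from the Monte Carlo at no cost in correctness and lets
desk-scale replicate counts stand in for very large simulation budgets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from .datatypes import MISSING, GenotypeDataset, PopulationMap, SiteAnnotation
from .demography import DemographicModel, build_scenario

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# observed SFS
# ---------------------------------------------------------------------------

@dataclass
class SFS:
    """Per-population derived-allele-count spectrum.

    ``counts[i]`` is the number of sites with derived count i+1 (unfolded,
    entries 1..n-1) or minor count i+1 (folded, entries 1..n//2).
    """

    population: str
    category: str
    n: int  # gene copies
    counts: np.ndarray
    folded: bool = False

    @property
    def S(self) -> int:
        return int(self.counts.sum())


def _project_hypergeometric(j: int, m: int, n: int) -> np.ndarray:
    """P(i derived in subsample of n | j derived in sample of m), i=0..n."""
    i = np.arange(n + 1)
    with np.errstate(invalid="ignore"):
        log_p = (
            gammaln(j + 1) - gammaln(i + 1) - gammaln(j - i + 1)
            + gammaln(m - j + 1) - gammaln(n - i + 1) - gammaln(m - j - (n - i) + 1)
            - (gammaln(m + 1) - gammaln(n + 1) - gammaln(m - n + 1))
        )
    bad = (i > j) | ((n - i) > (m - j))
    log_p[bad] = -np.inf
    return np.exp(log_p)


def compute_sfs(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    annotation: SiteAnnotation,
    population: str,
    category: str = "all",
    polarization: str = "unfolded",
    projection: int | None = None,
) -> SFS:
    """Observed SFS for one population and SNV category.

    Unfolded spectra need ancestral states (sites with unknown state drop
    out). Missing data are handled either by complete cases (default:
    only sites where every member is genotyped) or, with ``projection=n``,
    by hypergeometric downsampling of each site to n gene copies.
    """
    idx = popmap.indices(dataset, population)
    if not idx:
        raise ValueError(f"population {population!r} has no samples in dataset")
    site_mask = np.ones(dataset.n_sites, dtype=bool)
    if category != "all":
        site_mask &= annotation.category == category
    if polarization == "unfolded":
        g = annotation.derived_dosage(dataset)[idx][:, site_mask]
    elif polarization == "folded":
        g = dataset.genotypes[idx][:, site_mask]
    else:
        raise ValueError("polarization must be 'unfolded' or 'folded'")

    called = g != MISSING
    m_full = 2 * len(idx)
    if projection is None:
        complete = called.all(axis=0)
        der = g[:, complete].sum(axis=0)
        n = m_full
        spectrum = np.bincount(der[(der > 0) & (der < n)], minlength=n)[1:n]
        spectrum = spectrum.astype(float)
    else:
        n = int(projection)
        if n > m_full:
            raise ValueError(
                f"projection {n} exceeds population gene copies {m_full}"
            )
        spectrum = np.zeros(n + 1)
        copies = 2 * called.sum(axis=0)
        der = np.where(called, g, 0).sum(axis=0)
        for m_j, d_j in zip(copies, der):
            if m_j < n:
                continue  # too much missing data to project this site
            spectrum += _project_hypergeometric(int(d_j), int(m_j), n)
        spectrum = spectrum[1:n]
    if polarization == "folded":
        full = np.zeros(n + 1)
        full[1:n] = spectrum
        folded = np.array(
            [full[i] + (full[n - i] if n - i != i else 0) for i in range(1, n // 2 + 1)]
        )
        return SFS(population, category, n, folded, folded=True)
    return SFS(population, category, n, spectrum, folded=False)


def watterson_expected(sfs: SFS) -> tuple[float, np.ndarray]:
    """Watterson's theta_W = S / a_n and the neutral expectation
    xi_i = theta_W / i for i = 1..n-1."""
    if sfs.n < 2 or sfs.S < 1:
        raise ValueError("need n >= 2 and at least one segregating site")
    i = np.arange(1, sfs.n)
    a_n = float(np.sum(1.0 / i))
    theta_w = sfs.S / a_n
    return theta_w, theta_w / i


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------

def detect_roh(
    dataset: GenotypeDataset,
    sample: str,
    min_length_bp: int = 500_000,
    max_het: int = 1,
    min_snvs: int = 25,
) -> tuple[pd.DataFrame, int]:
    """Runs of homozygosity for one sample: maximal runs of consecutive
    genotyped sites containing at most ``max_het`` heterozygous calls,
    emitted when they span >= ``min_length_bp`` and >= ``min_snvs`` sites.
    Returns the segment table and the total length in bp."""
    i = dataset.sample_index(sample)
    rows = []
    for c in dataset.chromosomes:
        on = np.flatnonzero(dataset.chrom == c)
        g = dataset.genotypes[i, on]
        pos = dataset.pos[on]
        called = g != MISSING
        g, pos = g[called], pos[called]
        if len(g) == 0:
            continue
        het_idx = np.flatnonzero(g == 1)
        # candidate runs between het positions, allowing max_het inside:
        # a maximal run spans from just after het k to just before het
        # k + max_het + 1
        boundaries = np.concatenate([[-1], het_idx, [len(g)]])
        for k in range(len(boundaries) - max_het - 1):
            lo = boundaries[k] + 1
            hi = boundaries[k + max_het + 1] - 1
            if hi < lo:
                continue
            span = int(pos[hi] - pos[lo] + 1)
            n_snv = hi - lo + 1
            if span >= min_length_bp and n_snv >= min_snvs:
                rows.append(
                    {
                        "sample": sample,
                        "chrom": c,
                        "start": int(pos[lo]),
                        "end": int(pos[hi]),
                        "n_snvs": n_snv,
                        "n_het": int(np.sum(g[lo : hi + 1] == 1)),
                    }
                )
    table = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_snvs", "n_het"]
    )
    if len(table) > 1:
        # overlapping candidates (nested het windows) are merged per chrom
        merged_rows = []
        for c, grp in table.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            cur = None
            for _, r in grp.iterrows():
                if cur is None or r["start"] > cur["end"]:
                    if cur is not None:
                        merged_rows.append(cur)
                    cur = r.to_dict()
                else:
                    cur["end"] = max(cur["end"], r["end"])
                    cur["n_snvs"] = max(cur["n_snvs"], r["n_snvs"])
            if cur is not None:
                merged_rows.append(cur)
        table = pd.DataFrame(merged_rows)[table.columns]
    total = int((table["end"] - table["start"] + 1).sum()) if len(table) else 0
    return table, total


# ---------------------------------------------------------------------------
# expected SFS under a scenario
# ---------------------------------------------------------------------------

def expected_sfs_from_model(
    model: DemographicModel,
    n_per_population: dict[str, int],
    n_sims: int = 200,
    seed: int = 1,
    joint: bool = False,
    prob_floor_scale: float = 10.0,
) -> np.ndarray:
    """Monte-Carlo expected SFS entry probabilities under a scenario.

    Simulates ``n_sims`` independent non-recombining loci and averages
    the branch-length frequency spectrum (the conditional expectation of
    the mutation count per entry given each genealogy). Returns
    probabilities over polymorphic entries: a vector of length n-1 for a
    marginal spectrum, or an (n1+1, n2+1) matrix with fixed corners
    zeroed for ``joint=True``. Zero entries are clamped to a small floor
    (1 / (``prob_floor_scale`` * n_sims * entries)) before normalization
    so that log-likelihoods stay finite.
    """
    demography = model.to_msprime()
    pops = [lbl for lbl, _ in model.populations if n_per_population.get(lbl, 0) > 0]
    samples = {lbl: n_per_population[lbl] for lbl in pops}
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=1,
        num_replicates=n_sims,
        random_seed=int(seed),
    )
    acc = None
    for ts in reps:
        sets = [ts.samples(population=[p.id for p in demography.populations
                                       if p.name == lbl][0]) for lbl in pops]
        if joint and len(sets) > 1:
            afs = ts.allele_frequency_spectrum(
                sample_sets=sets, mode="branch", polarised=True, span_normalise=False
            )
        else:
            flat = np.concatenate(sets)
            afs = ts.allele_frequency_spectrum(
                sample_sets=[flat], mode="branch", polarised=True,
                span_normalise=False,
            )
        acc = afs if acc is None else acc + afs
    acc = acc / n_sims
    if joint and acc.ndim == 2:
        acc[0, 0] = 0.0
        acc[-1, -1] = 0.0
        probs = acc
    else:
        probs = acc[1:-1]
    total = probs.sum()
    if total <= 0:
        raise RuntimeError("degenerate expected SFS (no branch length)")
    probs = probs / total
    floor = 1.0 / (prob_floor_scale * n_sims * probs.size)
    probs = np.maximum(probs, floor)
    return probs / probs.sum()


def composite_loglik(observed: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial composite ln L = sum xi_i ln p_i over polymorphic
    entries (monomorphic classes excluded by construction)."""
    obs = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(probs, dtype=float).ravel()
    mask = obs > 0
    return float(np.sum(obs[mask] * np.log(p[mask])))


def loglik_upper_bound(observed: np.ndarray) -> float:
    """ln L at the empirical proportions — the multinomial maximum."""
    obs = np.asarray(observed, dtype=float).ravel()
    obs = obs[obs > 0]
    return float(np.sum(obs * np.log(obs / obs.sum())))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    model_name: str
    parameters: dict[str, float]
    free_params: list[str]
    loglik: float
    aic: float
    n_free: int
    converged: bool = True
    bootstrap: pd.DataFrame | None = None


@dataclass
class FitConfig:
    """Desk-scale optimizer settings.

    ``n_sims`` coalescent replicates per likelihood evaluation with a
    fixed seed (common random numbers keep the Monte-Carlo surface
    smooth); sizes and times are optimized on a log10 scale within the
    given bounds; ``n_restarts`` Nelder-Mead starts for multi-parameter
    fits (1-D fits use bounded scalar minimization).
    """

    n_sims: int = 100
    n_restarts: int = 3
    maxiter: int = 60
    seed: int = 1
    joint: bool = True
    #: optimizer tolerance on log10 parameters
    xatol: float = 1e-2
    #: for marginal spectra: keep entries 1..k and pool the tail into one
    #: class before the likelihood (rare classes carry the recent-history
    #: signal; the tail mostly adds Monte-Carlo noise)
    tail_lump: int | None = None


def fit_model(
    observed: np.ndarray,
    template: str,
    free_params: dict[str, tuple[float, float]],
    fixed_params: dict[str, float],
    n_per_population: dict[str, int],
    config: FitConfig | None = None,
) -> ModelFit:
    """Maximize the composite likelihood over the free parameters of a
    named scenario template.

    ``observed`` is a marginal (length n-1) or joint ((n1+1) x (n2+1))
    spectrum matching ``config.joint``. All parameters are positive and
    searched on log10 scale within their bounds. Returns the best fit
    found (with ``converged=False`` after optimizer failure rather than
    raising)."""
    config = config or FitConfig()
    names = list(free_params)
    lo = np.log10([free_params[k][0] for k in names])
    hi = np.log10([free_params[k][1] for k in names])

    def transform(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float).ravel()
        if config.tail_lump is not None and not config.joint:
            k = config.tail_lump
            v = np.concatenate([v[:k], [v[k:].sum()]])
        return v

    observed_t = transform(observed)

    def build(theta_log: np.ndarray) -> DemographicModel:
        params = dict(fixed_params)
        params.update({k: 10.0 ** v for k, v in zip(names, theta_log)})
        return build_scenario(template, params)

    def neg_loglik(theta_log: np.ndarray) -> float:
        theta_log = np.clip(theta_log, lo, hi)
        try:
            model = build(theta_log)
        except ValueError:
            return 1e12
        probs = transform(
            expected_sfs_from_model(
                model,
                n_per_population,
                n_sims=config.n_sims,
                seed=config.seed,
                joint=config.joint,
            )
        )
        return -composite_loglik(observed_t, probs / probs.sum())

    converged = True
    if len(names) == 1:
        res = minimize_scalar(
            lambda x: neg_loglik(np.array([x])),
            bounds=(lo[0], hi[0]),
            method="bounded",
            options={"maxiter": config.maxiter, "xatol": config.xatol},
        )
        best_x, best_f = np.array([res.x]), res.fun
    else:
        rng = np.random.default_rng(config.seed)
        best_x, best_f = None, np.inf
        starts = [0.5 * (lo + hi)] + [
            lo + rng.random(len(names)) * (hi - lo)
            for _ in range(config.n_restarts - 1)
        ]
        for x0 in starts:
            res = minimize(
                neg_loglik,
                x0,
                method="Nelder-Mead",
                options={"maxiter": config.maxiter, "xatol": config.xatol,
                         "fatol": 1e-3},
            )
            if res.fun < best_f:
                best_x, best_f = np.clip(res.x, lo, hi), res.fun
        if best_x is None:
            warnings.warn("optimizer failed on all restarts; returning midpoint")
            best_x, best_f = 0.5 * (lo + hi), neg_loglik(0.5 * (lo + hi))
            converged = False

    fitted = dict(fixed_params)
    fitted.update({k: float(10.0 ** v) for k, v in zip(names, best_x)})
    lnl = -best_f
    ub = loglik_upper_bound(observed_t)
    assert lnl <= ub + 1e-6, "composite lnL exceeded the multinomial maximum"
    k = len(names)
    return ModelFit(
        model_name=template,
        parameters=fitted,
        free_params=names,
        loglik=lnl,
        aic=2 * k - 2 * lnl,
        n_free=k,
        converged=converged,
    )


class ProfileGrid:
    """Precomputed 1-D composite-likelihood profile for one free parameter.

    For repeated fits of the same one-parameter family (e.g. a recovery
    experiment), the expected spectrum at each grid value is computed
    once at high precision with common random numbers; each observed
    spectrum is then scored against the grid and the optimum refined by
    quadratic interpolation of ln L around the best grid point.
    """

    def __init__(
        self,
        template: str,
        param: str,
        bounds: tuple[float, float],
        fixed_params: dict[str, float],
        n_per_population: dict[str, int],
        grid_size: int = 17,
        n_sims: int = 20_000,
        seed: int = 1,
        joint: bool = False,
        tail_lump: int | None = None,
    ) -> None:
        self.param = param
        self.tail_lump = tail_lump
        self.joint = joint
        self.grid = np.logspace(
            np.log10(bounds[0]), np.log10(bounds[1]), grid_size
        )
        self.log_probs = []
        for value in self.grid:
            model = build_scenario(template, {**fixed_params, param: value})
            p = self._transform(
                expected_sfs_from_model(
                    model, n_per_population, n_sims=n_sims, seed=seed,
                    joint=joint,
                )
            )
            self.log_probs.append(np.log(p / p.sum()))

    def _transform(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float).ravel()
        if self.tail_lump is not None and not self.joint:
            k = self.tail_lump
            v = np.concatenate([v[:k], [v[k:].sum()]])
        return v

    def fit(self, observed: np.ndarray) -> float:
        obs = self._transform(observed)
        lnl = np.array([np.sum(obs * lp) for lp in self.log_probs])
        k = int(np.argmax(lnl))
        if 0 < k < len(self.grid) - 1:
            # quadratic refinement on the log10 parameter scale
            x = np.log10(self.grid[k - 1 : k + 2])
            y = lnl[k - 1 : k + 2]
            denom = (y[0] - 2 * y[1] + y[2])
            if denom < 0:
                shift = 0.5 * (y[0] - y[2]) / denom
                return float(10 ** (x[1] + shift * (x[2] - x[1])))
        return float(self.grid[k])


def model_selection(fits: list[ModelFit]) -> pd.DataFrame:
    """AIC table with Akaike weights across fits of the same observed SFS."""
    aic = np.array([f.aic for f in fits])
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    return pd.DataFrame(
        {
            "model": [f.model_name for f in fits],
            "k": [f.n_free for f in fits],
            "loglik": [f.loglik for f in fits],
            "AIC": aic,
            "delta_AIC": delta,
            "weight": w,
        }
    ).sort_values("AIC", ignore_index=True)


def simulate_observed_sfs(
    model: DemographicModel,
    n_per_population: dict[str, int],
    n_segregating: int,
    seed: int,
    joint: bool = True,
    n_sims: int = 400,
) -> np.ndarray:
    """Simulate an observed SFS with ``n_segregating`` sites: a
    multinomial draw from the model's expected polymorphic-entry
    probabilities estimated with an independent seed stream."""
    rng = np.random.default_rng(seed)
    probs = expected_sfs_from_model(
        model,
        n_per_population,
        n_sims=n_sims,
        seed=int(rng.integers(1, 2**31 - 1)),
        joint=joint,
    )
    flat = rng.multinomial(n_segregating, probs.ravel())
    return flat.reshape(probs.shape).astype(float)


def parametric_bootstrap(
    best: ModelFit,
    free_params: dict[str, tuple[float, float]],
    n_per_population: dict[str, int],
    n_segregating: int,
    n_boot: int = 50,
    seed: int = 1,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Re-fit ``n_boot`` datasets simulated at the fitted parameters;
    returns mean and percentile 95% CI per free parameter. Failed
    replicates are dropped (count reported in the attrs)."""
    if n_boot < 2:
        warnings.warn("n_boot < 2: interval collapses to the point estimate")
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    model = build_scenario(best.model_name, best.parameters)
    fixed = {k: v for k, v in best.parameters.items() if k not in free_params}
    rows = {k: [] for k in free_params}
    n_failed = 0
    for b in range(n_boot):
        obs = simulate_observed_sfs(
            model,
            n_per_population,
            n_segregating,
            seed=int(rng.integers(1, 2**31 - 1)),
            joint=config.joint,
        )
        try:
            cfg = FitConfig(
                n_sims=config.n_sims,
                n_restarts=config.n_restarts,
                maxiter=config.maxiter,
                seed=int(rng.integers(1, 2**31 - 1)),
                joint=config.joint,
            )
            fit = fit_model(
                obs, best.model_name, free_params, fixed, n_per_population, cfg
            )
        except Exception:  # a bad replicate must not kill the bootstrap
            n_failed += 1
            continue
        for k in free_params:
            rows[k].append(fit.parameters[k])
    out = pd.DataFrame(
        {
            "parameter": list(free_params),
            "mean": [float(np.mean(rows[k])) if rows[k] else np.nan for k in free_params],
            "ci_low": [
                float(np.percentile(rows[k], 2.5)) if rows[k] else np.nan
                for k in free_params
            ],
            "ci_high": [
                float(np.percentile(rows[k], 97.5)) if rows[k] else np.nan
                for k in free_params
            ],
            "n_ok": [len(rows[k]) for k in free_params],
        }
    )
    out.attrs["n_failed"] = n_failed
    return out
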